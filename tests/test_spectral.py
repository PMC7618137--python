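"""STFT power, ERD baseline correction, ITPC, and PAC modulation index."""

import numpy as np
import pytest

from retrocue.spectral import (
    _amp_extraction_band,
    erd,
    itpc,
    mi_from_distribution,
    pac_mi,
    remove_phase_locked,
    stft_tfr,
)
from retrocue.synth import SynthConfig, generate_epochs
from tests.conftest import make_epochs


def oscillation_epochs(freq, amps, srate=250.0, n_trials=1, phase=0.0, t0=-2000.0,
                       n_sec=4.4):
    """Trials of a sinusoid with a per-sample amplitude envelope ``amps``."""
    t = np.arange(0, n_sec, 1.0 / srate)
    x = amps * np.cos(2 * np.pi * freq * t + phase)
    return make_epochs(np.tile(x, (n_trials, 1, 1)), srate=srate, t0=t0)


class TestStft:
    def test_sinusoid_peaks_at_its_frequency(self):
        e = oscillation_epochs(10.0, 1.0)
        tfr = stft_tfr(e)
        mean_over_time = tfr.power[0].mean(axis=1)
        assert tfr.freqs[np.argmax(mean_over_time)] == pytest.approx(10.0)

    def test_power_scales_quadratically(self):
        e1 = oscillation_epochs(10.0, 1.0)
        e2 = oscillation_epochs(10.0, 2.0)
        p1 = stft_tfr(e1).power.max()
        p2 = stft_tfr(e2).power.max()
        assert p2 == pytest.approx(4 * p1, rel=1e-9)

    def test_white_noise_spectrum_flat(self):
        rng = np.random.default_rng(0)
        e = make_epochs(rng.standard_normal((30, 1, 1101)), srate=250.0)
        tfr = stft_tfr(e, freqs=np.arange(10.0, 100.0, 2.0))
        mean_psd = tfr.power[0].mean(axis=1)
        slope = np.polyfit(tfr.freqs, mean_psd / mean_psd.mean(), 1)[0]
        assert abs(slope) < 0.005  # per-Hz relative trend

    def test_parseval_total_power(self):
        """Integrated one-sided PSD of white noise matches its variance."""
        rng = np.random.default_rng(1)
        e = make_epochs(rng.standard_normal((40, 1, 1101)), srate=250.0)
        freqs = np.arange(2.0, 125.0, 0.5)
        tfr = stft_tfr(e, freqs=freqs)
        total = tfr.power[0].mean(axis=1).sum() * 0.5  # integrate over df
        # the unresolved 0-2 Hz sliver holds ~1.6% of white-noise variance
        assert total == pytest.approx(123.0 / 125.0, rel=0.05)

    def test_window_must_resolve_lowest_frequency(self):
        e = oscillation_epochs(10.0, 1.0)
        with pytest.raises(ValueError, match="cannot resolve"):
            stft_tfr(e, freqs=np.array([1.0, 2.0]), window_ms=500.0)


class TestErd:
    def test_stationary_signal_centered_on_zero(self):
        e = oscillation_epochs(10.0, 1.0, n_trials=3)
        tfr = erd(stft_tfr(e))
        i10 = np.argmin(np.abs(tfr.freqs - 10.0))
        assert np.abs(tfr.corrected[0, i10]).max() < 0.01

    def _erd_epochs(self, post_gain):
        t = np.arange(0, 4.4, 1.0 / 250.0)
        times = -2000.0 + 1000.0 * t
        amps = np.where(times >= 0, post_gain, 1.0)
        return oscillation_epochs(10.0, amps)

    def test_halved_amplitude_gives_log_quarter(self):
        tfr = erd(stft_tfr(self._erd_epochs(0.5)))
        i10 = np.argmin(np.abs(tfr.freqs - 10.0))
        post = tfr.times >= 300.0
        got = tfr.corrected[0, i10, post].mean()
        assert got == pytest.approx(np.log10(0.25), rel=0.10)

    def test_doubled_power_gives_log_two(self):
        tfr = erd(stft_tfr(self._erd_epochs(np.sqrt(2.0))))
        i10 = np.argmin(np.abs(tfr.freqs - 10.0))
        post = tfr.times >= 300.0
        assert tfr.corrected[0, i10, post].mean() == pytest.approx(
            np.log10(2.0), rel=0.10
        )

    def test_zero_power_floored_with_warning(self):
        e = make_epochs(np.zeros((2, 1, 1101)), srate=250.0)
        with pytest.warns(RuntimeWarning, match="floored"):
            erd(stft_tfr(e))


class TestItpc:
    def test_identical_trials_reach_upper_bound(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(1101)
        e = make_epochs(np.tile(x, (20, 1, 1)), srate=250.0)
        m = itpc(stft_tfr(e, keep_complex=True))
        assert np.all(m.itpc >= 1.0 - 1e-9)

    def test_amplitude_scaling_invariance(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal((10, 1, 1101))
        scales = rng.uniform(0.5, 5.0, 10)[:, None, None]
        m1 = itpc(stft_tfr(make_epochs(base, srate=250.0), keep_complex=True))
        m2 = itpc(stft_tfr(make_epochs(base * scales, srate=250.0), keep_complex=True))
        assert np.allclose(m1.itpc, m2.itpc, atol=1e-12)

    def test_opposite_phases_cancel(self):
        x = np.cos(2 * np.pi * 10.0 * np.arange(0, 4.4, 1 / 250.0))
        e = make_epochs(np.stack([x[None], -x[None]]), srate=250.0)
        m = itpc(stft_tfr(e, keep_complex=True))
        i10 = np.argmin(np.abs(m.freqs - 10.0))
        assert m.itpc[0, i10].max() < 1e-9

    def test_random_phases_match_rayleigh_expectation(self):
        """Mean ITPC of n uniform phases approaches sqrt(pi)/2/sqrt(n)."""
        rng = np.random.default_rng(4)
        n = 100
        t = np.arange(0, 4.4, 1 / 250.0)
        data = np.stack(
            [np.cos(2 * np.pi * 10.0 * t + rng.uniform(0, 2 * np.pi))[None]
             for _ in range(n)]
        )
        m = itpc(stft_tfr(make_epochs(data, srate=250.0), keep_complex=True))
        i10 = np.argmin(np.abs(m.freqs - 10.0))
        expected = np.sqrt(np.pi) / 2.0 / np.sqrt(n)
        assert m.itpc[0, i10].mean() == pytest.approx(expected, rel=0.35)

    def test_bounds_on_arbitrary_input(self):
        rng = np.random.default_rng(5)
        e = make_epochs(rng.standard_normal((7, 2, 1101)), srate=250.0)
        m = itpc(stft_tfr(e, keep_complex=True))
        assert np.all((m.itpc >= 0.0) & (m.itpc <= 1.0))

    def test_requires_complex_coefficients(self):
        e = make_epochs(np.random.default_rng(0).standard_normal((3, 1, 1101)),
                        srate=250.0)
        with pytest.raises(ValueError, match="keep_complex"):
            itpc(stft_tfr(e))

    def test_phase_locked_synthetic_evoked_has_unit_itpc(self):
        """Jitter-free evoked response with noise off: perfectly coherent Fz."""
        cfg = SynthConfig(
            n_trials_per_condition=10,
            srate=250.0,
            rng_seed=6,
            noise_sd=0.0,
            evoked_jitter_sd=0.0,
            theta_bg_amplitude=0.0,
            alpha_amplitude=0.0,
            pattern_snr={k: 0.0 for k in (
                "target_orientation", "nontarget_orientation",
                "target_color", "target_space")},
        )
        e, _ = generate_epochs(cfg)
        m = itpc(stft_tfr(e, channels=["Fz"], keep_complex=True))
        assert m.average("Fz", (3.0, 7.0), (100.0, 700.0)) == pytest.approx(1.0)


class TestRemovePhaseLocked:
    def test_identical_trials_zeroed(self):
        e = make_epochs(np.tile(np.arange(100.0), (4, 2, 1)), srate=250.0)
        out = remove_phase_locked(e, by_condition=False)
        assert np.allclose(out.data, 0.0)

    def test_residual_mean_zero(self):
        rng = np.random.default_rng(7)
        e = make_epochs(1.0 + rng.standard_normal((20, 2, 100)), srate=250.0)
        out = remove_phase_locked(e, by_condition=False)
        assert np.allclose(out.data.mean(axis=0), 0.0, atol=1e-12)

    def test_nonlocked_power_nearly_preserved(self):
        """Random-phase oscillation loses only ~1/n of its power."""
        rng = np.random.default_rng(8)
        n = 40
        t = np.arange(0, 2.0, 1 / 250.0)
        data = np.stack(
            [np.cos(2 * np.pi * 10 * t + rng.uniform(0, 2 * np.pi))[None]
             for _ in range(n)]
        )
        e = make_epochs(data, srate=250.0)
        out = remove_phase_locked(e, by_condition=False)
        ratio = (out.data**2).mean() / (e.data**2).mean()
        # the subtracted mean carries O(1/n) of the power (chi-square spread)
        assert 1.0 - 8.0 / n < ratio <= 1.0 + 1e-12

    def test_single_trial_warns(self):
        e = make_epochs(np.ones((1, 1, 50)), srate=250.0)
        with pytest.warns(RuntimeWarning, match="single-trial"):
            out = remove_phase_locked(e, by_condition=False)
        assert np.allclose(out.data, 0.0)


class TestPac:
    def test_mi_limits(self):
        assert mi_from_distribution(np.ones(18)) == pytest.approx(0.0, abs=1e-12)
        one_bin = np.zeros(18)
        one_bin[4] = 3.7
        assert mi_from_distribution(one_bin) == pytest.approx(1.0)

    def test_mi_zero_iff_uniform(self):
        p = np.ones(18)
        p[0] += 1e-6
        assert mi_from_distribution(p) > 0

    def _coupled(self, depth, seed=0, n=10):
        cfg = SynthConfig(
            n_trials_per_condition=n,
            srate=250.0,
            rng_seed=seed,
            pac_depth={"valid": depth, "neutral": depth},
        )
        return generate_epochs(cfg)[0]

    def test_mi_invariant_to_global_scaling(self):
        e = self._coupled(0.6, seed=1, n=6)
        r1 = pac_mi(e, condition="valid")
        e.data *= 10.0
        r2 = pac_mi(e, condition="valid")
        assert np.allclose(r1.mi, r2.mi, atol=1e-12)

    def test_mi_increases_with_coupling_depth(self):
        depths = [0.0, 0.3, 0.6, 0.9]
        mis = np.array(
            [[pac_mi(self._coupled(d, seed=s), condition="valid").mi_mean
              for d in depths] for s in range(3)]
        )
        means = mis.mean(axis=0)
        assert np.all(np.diff(means) > 0)

    def test_window_shorter_than_six_cycles_rejected(self):
        e = self._coupled(0.5, n=4)
        with pytest.raises(ValueError, match="6 cycles"):
            pac_mi(e, window=(0.0, 800.0))

    def test_bin_distribution_normalized(self):
        e = self._coupled(0.5, n=4)
        r = pac_mi(e, condition="valid")
        assert np.allclose(r.bin_amplitude.sum(axis=1), 1.0)

    def test_amp_band_widening(self):
        assert _amp_extraction_band((8.0, 12.0), 5.0) == (4.0, 16.0)
        assert _amp_extraction_band((30.0, 60.0), 5.0) == (30.0, 60.0)
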
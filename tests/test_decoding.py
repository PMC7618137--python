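"""Downsampling, pseudo-trial binning, decoding, generalization, spread time."""

import numpy as np
import pytest

from retrocue.decoding import (
    DecodingSpec,
    decode_generalization,
    decode_timecourse,
    downsample_epochs,
    make_bins,
    shuffle_labels,
    spread_time,
    GeneralizationMap,
)
from retrocue.synth import SynthConfig, generate_epochs
from tests.conftest import make_epochs


class TestDownsample:
    def test_constant_preserved(self):
        e = make_epochs(np.full((1, 2, 100), 3.0), srate=250.0)
        out = downsample_epochs(e, 50.0)
        assert np.allclose(out.data, 3.0)
        assert out.srate == 50.0
        assert out.n_times == 20

    def test_ramp_blocks_average_to_midpoints(self):
        e = make_epochs(np.arange(100, dtype=float)[None, None, :], srate=1000.0)
        out = downsample_epochs(e, 50.0)
        assert np.allclose(out.data[0, 0], np.arange(9.5, 100, 20.0))

    def test_nyquist_alternation_cancels(self):
        x = np.tile([1.0, -1.0], 50)
        e = make_epochs(x[None, None, :], srate=1000.0)
        out = downsample_epochs(e, 50.0)
        assert np.allclose(out.data, 0.0)

    def test_times_are_block_centers(self):
        e = make_epochs(np.zeros((1, 1, 40)), srate=1000.0, t0=0.0)
        out = downsample_epochs(e, 50.0)
        assert np.allclose(out.times, [9.5, 29.5])

    def test_indivisible_rate_suggests_alternative(self):
        e = make_epochs(np.zeros((1, 1, 100)), srate=250.0)
        with pytest.raises(ValueError, match="nearest divisible"):
            downsample_epochs(e, 60.0)


class TestMakeBins:
    def test_nine_trials_three_equal_bins(self):
        bins = make_bins(np.zeros(9, dtype=int), 3, rng=0)
        (lab, groups), = bins
        assert sorted(len(g) for g in groups) == [3, 3, 3]
        assert sorted(np.concatenate(groups)) == list(range(9))

    def test_ten_trials_near_equal_split(self):
        (_, groups), = make_bins(np.zeros(10, dtype=int), 3, rng=1)
        assert [len(g) for g in groups] == [4, 3, 3]

    def test_underfilled_label_named_in_error(self):
        labels = np.array([0, 0, 0, 7, 7])
        with pytest.raises(ValueError, match="7"):
            make_bins(labels, 3, rng=0)

    def test_reproducible_given_seed(self):
        labels = np.repeat(np.arange(4), 5)
        a = make_bins(labels, 3, rng=42)
        b = make_bins(labels, 3, rng=42)
        for (_, ga), (_, gb) in zip(a, b):
            for x, y in zip(ga, gb):
                assert np.array_equal(x, y)


def _pattern_epochs(n_per_cond=24, snr=5.0, seed=0, window=(500.0, 1500.0)):
    """Synthetic epochs with a strong orientation code and nothing else."""
    return generate_epochs(
        SynthConfig(
            n_trials_per_condition=n_per_cond,
            srate=250.0,
            rng_seed=seed,
            noise_sd=0.0 if snr == np.inf else 10.0,
            pattern_snr={
                "target_orientation": 1.0 if snr == np.inf else snr,
                "nontarget_orientation": 0.0,
                "target_color": 0.0,
                "target_space": 0.0,
            },
            pattern_window={
                "target_orientation": window,
                "nontarget_orientation": window,
                "target_color": window,
                "target_space": window,
            },
            evoked_amplitude=0.0,
            evoked_condition_scale={"valid": 0.0, "neutral": 0.0},
            theta_bg_amplitude=0.0,
            alpha_amplitude=0.0,
        )
    )[0]


class TestDecodeTimecourse:
    def test_noiseless_pattern_decodes_perfectly_in_window(self):
        e = _pattern_epochs(snr=np.inf).crop((400.0, 1600.0))
        spec = DecodingSpec(n_iterations=1, rng_seed=0)
        with pytest.warns(RuntimeWarning):  # constant features outside window
            curve = decode_timecourse(e, spec, condition="valid")
        # blocks fully inside the 500-1500 ms pattern window decode perfectly
        inside = (curve.times >= 510) & (curve.times <= 1490)
        assert np.allclose(curve.accuracy[inside], 1.0)
        # blocks fully outside have constant features -> chance fallback
        outside = (curve.times < 495) | (curve.times > 1520)
        assert np.allclose(curve.accuracy[outside], curve.chance)

    def test_shuffled_labels_sit_at_chance(self):
        e = _pattern_epochs(snr=2.0).crop((700.0, 1100.0))
        spec = DecodingSpec(n_iterations=2, rng_seed=1)
        accs = []
        for s in range(10):
            curve = decode_timecourse(
                shuffle_labels(e, "target_orientation", seed=s), spec
            )
            accs.append(curve.accuracy.mean())
        mean = np.mean(accs)
        se = np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert abs(mean - 0.125) < 3 * max(se, 1e-3)

    def test_accuracy_monotone_in_pattern_snr(self):
        """In-window accuracy rank-increases with injected SNR."""
        from scipy.stats import kendalltau

        snrs = [0.0, 0.5, 1.0, 2.0]
        means = []
        for snr in snrs:
            accs = []
            for seed in range(3):
                e = _pattern_epochs(snr=snr, seed=seed).crop((700.0, 1300.0))
                spec = DecodingSpec(n_iterations=2, rng_seed=seed)
                accs.append(decode_timecourse(e, spec, "valid").accuracy.mean())
            means.append(np.mean(accs))
        tau, _ = kendalltau(snrs, means)
        assert tau > 0
        assert means[-1] > means[0] + 0.1

    def test_determinism(self):
        e = _pattern_epochs(snr=1.0).crop((700.0, 900.0))
        spec = DecodingSpec(n_iterations=2, rng_seed=7)
        c1 = decode_timecourse(e, spec, "valid")
        c2 = decode_timecourse(e, spec, "valid")
        assert np.array_equal(c1.accuracy, c2.accuracy)

    def test_unknown_feature_rejected(self):
        with pytest.raises(ValueError, match="unknown feature"):
            DecodingSpec(feature="target_phase")


class TestGeneralization:
    def test_diagonal_equals_timecourse_under_shared_folds(self):
        e = _pattern_epochs(snr=1.5).crop((600.0, 1200.0))
        spec = DecodingSpec(n_iterations=2, rng_seed=3, downsample_to=25.0)
        curve = decode_timecourse(e, spec, "valid")
        gmap = decode_generalization(e, spec, "valid")
        assert np.max(np.abs(np.diag(gmap.acc) - curve.accuracy)) < 1e-12

    def test_time_invariant_code_generalizes_off_diagonal(self):
        e = _pattern_epochs(snr=np.inf).crop((600.0, 1400.0))
        spec = DecodingSpec(n_iterations=1, rng_seed=0, downsample_to=25.0)
        gmap = decode_generalization(e, spec, "valid")
        assert np.allclose(gmap.acc, 1.0)

    def test_disjoint_codes_stay_on_diagonal(self):
        """Two orthogonal patterns in disjoint windows do not cross-generalize."""
        rng = np.random.default_rng(0)
        n_lab, n_rep, n_ch = 4, 6, 20
        labels = np.repeat(np.arange(n_lab), n_rep)
        p1 = rng.standard_normal((n_ch, n_lab))
        p2 = rng.standard_normal((n_ch, n_lab))
        data = 0.01 * rng.standard_normal((n_lab * n_rep, n_ch, 100))
        data[:, :, :50] += p1[:, labels].T[:, :, None]
        data[:, :, 50:] += p2[:, labels].T[:, :, None]
        table = __import__("pandas").DataFrame({"target_color_idx": labels})
        e = make_epochs(data, srate=250.0, t0=0.0, table=table)
        spec = DecodingSpec(
            feature="target_color", n_iterations=1, rng_seed=0, downsample_to=25.0
        )
        gmap = decode_generalization(e, spec)
        half = gmap.acc.shape[0] // 2
        on_blocks = np.r_[gmap.acc[:half, :half].ravel(), gmap.acc[half:, half:].ravel()]
        off_blocks = np.r_[gmap.acc[:half, half:].ravel(), gmap.acc[half:, :half].ravel()]
        assert on_blocks.mean() > 0.9
        assert off_blocks.mean() < gmap.chance + 0.15


class TestSpreadTime:
    def brute_force(self, acc, chance):
        spread = []
        for row in acc:
            count = 0
            for v in row:
                if v > chance:
                    count += 1
            spread.append(count)
        return np.array(spread)

    def test_formula_examples(self):
        gmap = GeneralizationMap(
            times=np.arange(3.0),
            acc=np.array([[0.30, 0.10, 0.125]] * 3),
            chance=0.125,
            feature="target_orientation",
        )
        prof = spread_time(gmap)
        assert prof.spd[0].tolist() == [1, 0, 0]
        assert prof.spread_time.tolist() == [1, 1, 1]

    def test_all_above_and_all_at_chance(self):
        times = np.arange(5.0)
        above = GeneralizationMap(times, np.full((5, 5), 0.6), 0.5, "target_space")
        at = GeneralizationMap(times, np.full((5, 5), 0.5), 0.5, "target_space")
        assert spread_time(above).spread_time.tolist() == [5] * 5
        assert spread_time(at).spread_time.tolist() == [0] * 5

    def test_matches_brute_force_on_random_maps(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            acc = rng.random((8, 8))
            gmap = GeneralizationMap(np.arange(8.0), acc, 0.25, "target_color")
            assert np.array_equal(
                spread_time(gmap).spread_time, self.brute_force(acc, 0.25)
            )
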
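"""Oscillatory measures: time-frequency power / ERD, ITPC, and theta-alpha PAC.

Spectral estimates use a short-time Fourier transform of Hanning-tapered
segments (default 500 ms window, 20 ms step, zero-padded to a 0.5 Hz grid).
Phase-locked activity (the condition ERP) can be removed beforehand so that
power reflects non-phase-locked oscillations. Event-related
desynchronization (ERD) is log10 power minus the mean log10 power of a
pre-stimulus baseline, so negative values mean desynchronization.

Inter-trial phase coherence (ITPC) at a time-frequency cell is the modulus
of the across-trial mean of unit-normalized complex coefficients: 0 for
random phases, 1 for identical phases, independent of amplitude.

Phase-amplitude coupling uses the modulation-index convention: band-passed
(zero-phase FIR) theta phase at a frontal channel and alpha amplitude at
parieto-occipital channels via the Hilbert transform, amplitudes pooled
across trials and binned by phase (default 18 bins of 20 degrees), and

    MI = (log N - H) / log N

with H the entropy of the normalized phase-bin amplitude distribution;
MI = 0 for a uniform distribution, 1 for all amplitude in one bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from retrocue.containers import EpochSet, PARIETO_OCCIPITAL

DEFAULT_FREQS = np.arange(2.0, 30.0 + 1e-9, 0.5)
TFR_BASELINE = (-1800.0, -1400.0)
THETA_BAND = (3.0, 7.0)
ALPHA_BAND = (8.0, 12.0)
PAC_WINDOW = (0.0, 1500.0)


@dataclass
class TFRResult:
    """Trial-averaged time-frequency power, optionally with complex coefficients."""

    freqs: np.ndarray
    times: np.ndarray                  # segment-center times, ms
    power: np.ndarray                  # channels x freqs x times, PSD units
    channel_names: list[str]
    n_trials: int
    coefficients: np.ndarray | None = None   # trials x channels x freqs x times
    corrected: np.ndarray | None = None      # log-baseline-corrected power
    baseline_window: tuple[float, float] | None = None
    phase_locked_removed: bool = False

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in TFR") from None

    def band_window_mean(
        self,
        channels: list[str],
        band: tuple[float, float],
        window: tuple[float, float],
        corrected: bool = True,
    ) -> float:
        """Mean (corrected) power over a band x window x channel set."""
        arr = self.corrected if corrected else self.power
        if arr is None:
            raise ValueError("no baseline-corrected power; run erd() first")
        ci = [self.channel_index(c) for c in channels]
        fm = (self.freqs >= band[0]) & (self.freqs <= band[1])
        tm = (self.times >= window[0]) & (self.times <= window[1])
        if not fm.any() or not tm.any():
            raise ValueError("band or window selects no TFR cells")
        return float(arr[np.ix_(ci, np.flatnonzero(fm), np.flatnonzero(tm))].mean())


@dataclass
class ITPCMap:
    itpc: np.ndarray                   # channels x freqs x times in [0, 1]
    freqs: np.ndarray
    times: np.ndarray
    channel_names: list[str]
    n_trials: int
    n_excluded_cells: int = 0

    def average(
        self,
        channel: str = "Fz",
        band: tuple[float, float] = THETA_BAND,
        window: tuple[float, float] = (100.0, 700.0),
    ) -> float:
        """Scalar summary: ITPC averaged over a band x window at one channel."""
        ci = self.channel_names.index(channel)
        fm = (self.freqs >= band[0]) & (self.freqs <= band[1])
        tm = (self.times >= window[0]) & (self.times <= window[1])
        if not fm.any() or not tm.any():
            raise ValueError("band or window selects no ITPC cells")
        return float(self.itpc[ci][np.ix_(np.flatnonzero(fm), np.flatnonzero(tm))].mean())


@dataclass
class PACResult:
    phase_bin_edges: np.ndarray        # n_bins + 1 edges over (-pi, pi]
    bin_amplitude: np.ndarray          # amp-channels x n_bins, rows sum to 1
    mi: np.ndarray                     # modulation index per amplitude channel
    mi_mean: float
    amp_channels: list[str]
    phase_channel: str
    phase_band: tuple[float, float]
    amp_band: tuple[float, float]
    window: tuple[float, float]


def remove_phase_locked(e: EpochSet, by_condition: bool = True) -> EpochSet:
    """Subtract each condition's mean ERP from its trials.

    The residual carries only non-phase-locked activity; spectral power
    computed on it is uncontaminated by the evoked response. With a single
    trial in a condition the subtraction zeroes that trial (warned).
    """
    out = e.copy()
    if by_condition and "condition" in e.trial_table.columns:
        groups = [
            np.flatnonzero(e.trial_table["condition"].to_numpy() == c)
            for c in e.trial_table["condition"].unique()
        ]
    else:
        groups = [np.arange(e.n_trials)]
    for idx in groups:
        if idx.size == 1:
            warnings.warn(
                "single-trial condition: ERP subtraction zeroes the trial",
                RuntimeWarning,
            )
        out.data[idx] -= e.data[idx].mean(axis=0, keepdims=True)
    return out


def stft_tfr(
    e: EpochSet,
    freqs: np.ndarray | None = None,
    window_ms: float = 500.0,
    step_ms: float = 20.0,
    channels: list[str] | None = None,
    keep_complex: bool = False,
) -> TFRResult:
    """Hanning-tapered short-time Fourier transform of every trial.

    Segments are zero-padded so the frequency grid matches the requested
    ``freqs`` spacing (0.5 Hz by default). Power is one-sided PSD averaged
    over trials; per-trial complex coefficients are retained on request
    (restrict ``channels`` to keep memory bounded). Only segment centers
    with full window support are computed, so the time axis starts half a
    window into the epoch.
    """
    freqs = DEFAULT_FREQS if freqs is None else np.asarray(freqs, float)
    n_win = int(round(window_ms / 1000.0 * e.srate))
    if n_win < 2:
        raise ValueError("STFT window shorter than 2 samples")
    if freqs.min() < 1000.0 / window_ms:
        raise ValueError(
            f"window of {window_ms:g} ms cannot resolve {freqs.min():g} Hz; "
            f"need >= one cycle ({1000.0 / freqs.min():g} ms)"
        )
    df = float(np.min(np.diff(freqs))) if freqs.size > 1 else 0.5
    nfft = max(n_win, int(round(e.srate / df)))
    grid = np.fft.rfftfreq(nfft, d=1.0 / e.srate)
    bin_idx = np.array([int(np.argmin(np.abs(grid - f))) for f in freqs])
    if np.max(np.abs(grid[bin_idx] - freqs)) > df / 2:
        raise ValueError("requested frequencies not representable on the FFT grid")

    if channels is None:
        ch_idx = np.arange(e.n_channels)
        ch_names = list(e.channel_names)
    else:
        ch_idx = e.channel_indices(channels)
        ch_names = list(channels)

    taper = np.hanning(n_win)
    step = max(1, int(round(step_ms / 1000.0 * e.srate)))
    half = n_win // 2
    starts = np.arange(0, e.n_times - n_win + 1, step)
    if starts.size == 0:
        raise ValueError(
            f"epoch of {e.n_times} samples shorter than the {n_win}-sample STFT window"
        )
    centers = starts + half
    t_out = e.times[centers]

    scale = 2.0 / (e.srate * np.sum(taper**2))  # one-sided PSD normalization
    x = e.data[:, ch_idx, :]
    power = np.zeros((ch_idx.size, freqs.size, starts.size))
    coefs = (
        np.zeros((e.n_trials, ch_idx.size, freqs.size, starts.size), dtype=complex)
        if keep_complex
        else None
    )
    for k, s in enumerate(starts):
        seg = x[:, :, s:s + n_win] * taper
        spec = np.fft.rfft(seg, n=nfft, axis=-1)[..., bin_idx]
        power[:, :, k] = scale * np.mean(np.abs(spec) ** 2, axis=0)
        if keep_complex:
            coefs[:, :, :, k] = spec
    return TFRResult(
        freqs=freqs,
        times=t_out,
        power=power,
        channel_names=ch_names,
        n_trials=e.n_trials,
        coefficients=coefs,
    )


def erd(tfr: TFRResult, baseline: tuple[float, float] = TFR_BASELINE) -> TFRResult:
    """Log-baseline-corrected power (event-related desynchronization).

    corrected = log10(power) - mean over the baseline window of log10(power),
    per channel x frequency. Zero power cells are floored at machine epsilon
    before the log (warned). Negative corrected values indicate
    desynchronization relative to baseline.
    """
    tm = (tfr.times >= baseline[0]) & (tfr.times <= baseline[1])
    if not tm.any():
        raise ValueError(
            f"baseline {baseline} ms outside the TFR time range "
            f"{tfr.times[0]:g}..{tfr.times[-1]:g} ms"
        )
    power = tfr.power
    if np.any(power <= 0):
        warnings.warn("non-positive power cells floored before log", RuntimeWarning)
        power = np.maximum(power, np.finfo(float).tiny)
    logp = np.log10(power)
    corrected = logp - logp[:, :, tm].mean(axis=-1, keepdims=True)
    return TFRResult(
        freqs=tfr.freqs,
        times=tfr.times,
        power=tfr.power,
        channel_names=list(tfr.channel_names),
        n_trials=tfr.n_trials,
        coefficients=tfr.coefficients,
        corrected=corrected,
        baseline_window=baseline,
        phase_locked_removed=tfr.phase_locked_removed,
    )


def itpc(tfr: TFRResult) -> ITPCMap:
    """Inter-trial phase coherence from per-trial STFT coefficients.

    Per cell, the modulus of the across-trial mean of unit-normalized
    coefficients. Trials with an exactly zero coefficient at a cell carry no
    phase and are excluded there (count reported). Requires >= 2 trials.
    """
    if tfr.coefficients is None:
        raise ValueError("stft_tfr must be run with keep_complex=True for ITPC")
    if tfr.n_trials < 2:
        raise ValueError("ITPC needs at least 2 trials")
    c = tfr.coefficients
    mag = np.abs(c)
    valid = mag > 0
    unit = np.where(valid, c / np.where(valid, mag, 1.0), 0.0)
    n_eff = valid.sum(axis=0)
    excluded = int(np.sum(~valid))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.abs(unit.sum(axis=0)) / np.where(n_eff > 0, n_eff, 1)
    out[n_eff == 0] = 0.0
    out = np.clip(out, 0.0, 1.0)
    return ITPCMap(
        itpc=out,
        freqs=tfr.freqs,
        times=tfr.times,
        channel_names=list(tfr.channel_names),
        n_trials=tfr.n_trials,
        n_excluded_cells=excluded,
    )


# -- phase-amplitude coupling ----------------------------------------------

def _fir_bandpass(
    x: np.ndarray,
    band: tuple[float, float],
    srate: float,
    transition_hz: float = 2.0,
) -> np.ndarray:
    """Zero-phase FIR band-pass along the last axis (Kaiser design)."""
    lo, hi = band
    numtaps, beta = signal.kaiserord(40.0, transition_hz / (srate / 2.0))
    numtaps += 1 - numtaps % 2  # odd length keeps the group delay integral
    numtaps = max(numtaps, 11)
    padlen = min(3 * numtaps, x.shape[-1] - 1)
    if x.shape[-1] <= padlen:
        raise ValueError(
            f"signal of {x.shape[-1]} samples too short for a {numtaps}-tap "
            f"filter ({transition_hz:g} Hz transition at {srate:g} Hz)"
        )
    b = signal.firwin(
        numtaps, [lo, hi], pass_zero=False, fs=srate, window=("kaiser", beta)
    )
    return signal.filtfilt(b, [1.0], x, axis=-1, padlen=padlen)


def _amp_extraction_band(
    amp_band: tuple[float, float], phase_center_hz: float
) -> tuple[float, float]:
    """Widen the amplitude band to pass the coupling's modulation sidebands.

    Amplitude modulated at the phase frequency lives at carrier +- phase
    frequency; an extraction band narrower than that erases any genuine
    coupling before it can be measured. The band is therefore widened
    around its center to a half-width of at least the phase-band center
    frequency plus a 1 Hz guard (a no-op when the requested band is already
    wide enough).
    """
    center = 0.5 * (amp_band[0] + amp_band[1])
    half = 0.5 * (amp_band[1] - amp_band[0])
    needed = phase_center_hz + 1.0
    if half >= needed:
        return amp_band
    return (max(center - needed, 0.5), center + needed)


def mi_from_distribution(bin_means: np.ndarray) -> float:
    """Modulation index of a phase-bin amplitude distribution.

    Normalizes the (non-negative) bin means to sum 1 and returns
    (log N - H) / log N; 0 for uniform, 1 for a single occupied bin.
    """
    p = np.asarray(bin_means, dtype=float)
    if np.any(p < 0):
        raise ValueError("bin amplitudes must be non-negative")
    total = p.sum()
    n = p.size
    if total <= 0:
        return 0.0
    p = p / total
    nz = p > 0
    h = float(-(p[nz] * np.log(p[nz])).sum())
    return float((np.log(n) - h) / np.log(n))


def pac_mi(
    e: EpochSet,
    phase_channel: str = "Fz",
    amp_channels: list[str] | None = None,
    phase_band: tuple[float, float] = THETA_BAND,
    amp_band: tuple[float, float] = ALPHA_BAND,
    window: tuple[float, float] = PAC_WINDOW,
    n_bins: int = 18,
    condition: str | None = None,
    widen_amp_band: bool = True,
) -> PACResult:
    """Theta-phase / alpha-amplitude coupling via the modulation index.

    Band-passes the phase and amplitude channels (zero-phase FIR), extracts
    analytic phase and amplitude with the Hilbert transform over the whole
    epoch, pools the window's samples across kept trials, bins amplitudes by
    phase, and computes the entropy-based modulation index per amplitude
    channel plus their mean. The measurement window must span at least six
    cycles of the phase band's center frequency for a stable estimate.

    With ``widen_amp_band`` (default) the amplitude extraction band is
    widened so the coupling's modulation sidebands (carrier +- phase
    frequency) survive filtering — the standard validity requirement for
    phase-amplitude coupling with nested bands like theta and alpha; see
    :func:`_amp_extraction_band`.
    """
    amp_channels = list(PARIETO_OCCIPITAL) if amp_channels is None else list(amp_channels)
    f_center = 0.5 * (phase_band[0] + phase_band[1])
    extraction_band = (
        _amp_extraction_band(amp_band, f_center) if widen_amp_band else amp_band
    )
    min_ms = 6.0 / f_center * 1000.0
    if window[1] - window[0] < min_ms:
        raise ValueError(
            f"PAC window {window} ms spans fewer than 6 cycles of the "
            f"{f_center:g} Hz phase band center (need >= {min_ms:g} ms)"
        )
    e.require_window(window, "PAC window")
    sub = e.kept_trials()
    if condition is not None:
        sub = sub.select_trials(sub.trial_table["condition"].to_numpy() == condition)
    if sub.n_trials == 0:
        raise ValueError("no kept trials for PAC")

    pi_ = sub.channel_index(phase_channel)
    ai = sub.channel_indices(amp_channels)
    tmask = sub.time_mask(window)

    phase_sig = _fir_bandpass(sub.data[:, pi_, :], phase_band, sub.srate)
    amp_sig = _fir_bandpass(sub.data[:, ai, :], extraction_band, sub.srate)
    phase = np.angle(signal.hilbert(phase_sig, axis=-1))[:, tmask].ravel()
    amp = np.abs(signal.hilbert(amp_sig, axis=-1))[:, :, tmask]
    amp = amp.transpose(1, 0, 2).reshape(len(amp_channels), -1)  # ch x samples

    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    idx = np.clip(((phase + np.pi) / (2 * np.pi) * n_bins).astype(int), 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    bin_means = np.zeros((len(amp_channels), n_bins))
    for c in range(len(amp_channels)):
        sums = np.bincount(idx, weights=amp[c], minlength=n_bins)
        bin_means[c] = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    totals = bin_means.sum(axis=1, keepdims=True)
    norm = np.where(totals > 0, bin_means / np.where(totals > 0, totals, 1.0), 0.0)
    mi = np.array([mi_from_distribution(bin_means[c]) for c in range(len(amp_channels))])
    return PACResult(
        phase_bin_edges=edges,
        bin_amplitude=norm,
        mi=mi,
        mi_mean=float(mi.mean()),
        amp_channels=amp_channels,
        phase_channel=phase_channel,
        phase_band=phase_band,
        amp_band=amp_band,
        window=window,
    )


def pac_surrogates(
    e: EpochSet,
    n_surrogates: int = 200,
    seed: int = 0,
    **pac_kwargs,
) -> np.ndarray:
    """Phase-shuffled surrogate null for the modulation index.

    Circularly shifts the pooled phase sample stream by a random offset per
    surrogate (preserving both marginals while destroying the phase-amplitude
    alignment) and returns the surrogate mean-MI distribution.
    """
    amp_channels = pac_kwargs.pop("amp_channels", None) or list(PARIETO_OCCIPITAL)
    phase_channel = pac_kwargs.pop("phase_channel", "Fz")
    phase_band = pac_kwargs.pop("phase_band", THETA_BAND)
    amp_band = pac_kwargs.pop("amp_band", ALPHA_BAND)
    window = pac_kwargs.pop("window", PAC_WINDOW)
    n_bins = pac_kwargs.pop("n_bins", 18)
    condition = pac_kwargs.pop("condition", None)
    widen = pac_kwargs.pop("widen_amp_band", True)
    if pac_kwargs:
        raise TypeError(f"unknown arguments: {sorted(pac_kwargs)}")
    f_center = 0.5 * (phase_band[0] + phase_band[1])
    extraction_band = (
        _amp_extraction_band(amp_band, f_center) if widen else amp_band
    )

    sub = e.kept_trials()
    if condition is not None:
        sub = sub.select_trials(sub.trial_table["condition"].to_numpy() == condition)
    pi_ = sub.channel_index(phase_channel)
    ai = sub.channel_indices(amp_channels)
    tmask = sub.time_mask(window)
    phase = np.angle(
        signal.hilbert(_fir_bandpass(sub.data[:, pi_, :], phase_band, sub.srate), axis=-1)
    )[:, tmask].ravel()
    amp = np.abs(
        signal.hilbert(
            _fir_bandpass(sub.data[:, ai, :], extraction_band, sub.srate), axis=-1
        )
    )[:, :, tmask].transpose(1, 0, 2).reshape(len(ai), -1)

    rng = np.random.default_rng(seed)
    n = phase.size
    out = np.empty(n_surrogates)
    for s in range(n_surrogates):
        shift = int(rng.integers(1, n))
        ph = np.roll(phase, shift)
        idx = np.clip(((ph + np.pi) / (2 * np.pi) * n_bins).astype(int), 0, n_bins - 1)
        counts = np.bincount(idx, minlength=n_bins)
        mis = []
        for c in range(len(ai)):
            sums = np.bincount(idx, weights=amp[c], minlength=n_bins)
            mis.append(
                mi_from_distribution(np.where(counts > 0, sums / np.maximum(counts, 1), 0.0))
            )
        out[s] = float(np.mean(mis))
    return out
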
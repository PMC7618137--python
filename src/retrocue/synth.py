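"""Ground-truth-known synthetic EEG epochs and behavior.

The generator emulates the statistical structure of a retrospective-cue
working-memory EEG experiment: on each trial two colored oriented bars are
encoded, a retro-cue (valid, pointing at the target, or neutral) appears
during retention, and the participant later reports the target orientation
on a continuous dial. Epochs are time-locked to cue onset.

What is injected, each with an independent knob:

- 1/f^beta Gaussian background noise per channel, optionally spatially mixed.
- Label-dependent spatial patterns (target orientation / non-target
  orientation / target color / target side), each a fixed random unit-norm
  channel vector per label scaled by ``pattern_snr x noise_sd`` and active
  only inside its pattern window. These give linear decodability with
  tunable difficulty.
- A phase-locked fronto-central evoked response (an N2-like deflection, a
  sustained late negativity, and a theta burst) that drives ERP components
  and frontal theta inter-trial phase coherence; optional trial jitter.
- Parieto-occipital alpha whose post-cue amplitude drops by
  ``alpha_erd_depth`` (event-related desynchronization) and whose retention
  amplitude is modulated by the Fz theta phase with depth ``pac_depth``
  (Tort-style synthetic coupling: amplitude = 1 + depth * cos(theta phase)).
- Behavioral reports drawn from the 3-component mixture (target von Mises /
  non-target von Mises / uniform guessing) with condition-specific
  parameters, and shifted-log-normal response times.

All randomness derives from ``rng_seed``; identical configs give
bit-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from retrocue.behavior import kappa_from_sd, wrap_orientation
from retrocue.containers import (
    EpochSet,
    FRONTOCENTRAL_9,
    HEOG_NAME,
    PARIETO_OCCIPITAL,
    STANDARD_60,
)

logger = logging.getLogger(__name__)

#: The eight bar orientations of the task, degrees.
ORIENTATIONS_DEG = np.array(
    [-78.75, -56.25, -33.75, -11.25, 11.25, 33.75, 56.25, 78.75]
)

CONDITIONS = ("valid", "neutral")

#: Analysis windows every downstream stage assumes (ms relative to cue).
BASELINE_TFR_WINDOW = (-1800.0, -1400.0)
RETENTION_WINDOW = (0.0, 1500.0)


@dataclass
class SynthConfig:
    """Study conditions for the synthetic experiment.

    Defaults emulate the task scale of the emulated study: 560 trials per
    condition, 60-channel 10-20 montage plus an HEOG channel, 1000 Hz, epochs
    -2000..2400 ms around cue onset. Effect magnitudes (SNRs, ERD depths,
    coupling depths, mixture parameters) are calibration choices for a
    realistic mid-size effect, with the valid condition uniformly "better"
    than neutral.
    """

    n_trials_per_condition: int = 560
    n_channels: int = 60
    srate: float = 1000.0
    epoch_window: tuple[float, float] = (-2000.0, 2400.0)

    # background noise
    noise_sd: float = 10.0          # microvolts RMS per channel
    noise_exponent: float = 1.0     # 1/f^beta spectral slope
    channel_mixing: float = 0.0     # 0 = independent channels

    # label-dependent spatial patterns
    pattern_snr: dict = field(
        default_factory=lambda: {
            "target_orientation": 1.0,
            "nontarget_orientation": 0.0,
            "target_color": 0.8,
            "target_space": 0.8,
        }
    )
    pattern_window: dict = field(
        default_factory=lambda: {
            "target_orientation": (500.0, 1500.0),
            "nontarget_orientation": (500.0, 1500.0),
            "target_color": (100.0, 1500.0),
            "target_space": (100.0, 1500.0),
        }
    )

    # phase-locked fronto-central evoked response
    evoked_amplitude: float = -4.0  # microvolts, negative-going
    evoked_jitter_sd: float = 0.0   # ms; 0 = perfectly phase-locked
    evoked_condition_scale: dict = field(
        default_factory=lambda: {"valid": 1.0, "neutral": 0.6}
    )
    evoked_rt_slope: float = 0.0    # extra evoked gain per -1 SD of RT
    theta_burst_scale: float = 0.8  # theta burst amplitude re |evoked_amplitude|

    # oscillations
    theta_freq: float = 5.0
    alpha_freq: float = 10.0
    theta_bg_amplitude: float = 3.0     # ongoing random-phase theta at Fz, uV
    alpha_amplitude: float = 8.0        # pre-cue parieto-occipital alpha, uV
    alpha_erd_depth: dict = field(
        default_factory=lambda: {"valid": 0.5, "neutral": 0.3}
    )
    pac_depth: dict = field(default_factory=lambda: {"valid": 0.4, "neutral": 0.2})

    # behavior: (p_target, p_nontarget, p_uniform, SD degrees) per condition
    mixture_params: dict = field(
        default_factory=lambda: {
            "valid": (0.88, 0.04, 0.08, 14.0),
            "neutral": (0.78, 0.07, 0.15, 19.0),
        }
    )
    # RT: shift + median * exp(sigma * z), ms
    rt_params: dict = field(
        default_factory=lambda: {
            "valid": (300.0, 600.0, 0.35),
            "neutral": (300.0, 900.0, 0.35),
        }
    )

    # occasional large-amplitude artifacts for rejection screening
    artifact_frac_eeg: float = 0.0
    artifact_frac_heog: float = 0.0

    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels != len(STANDARD_60):
            raise ValueError(
                f"the synthetic montage has {len(STANDARD_60)} EEG channels; "
                f"got n_channels={self.n_channels}"
            )
        for cond in CONDITIONS:
            p_t, p_nt, p_u, sd = self.mixture_params[cond]
            if abs(p_t + p_nt + p_u - 1.0) > 1e-9:
                raise ValueError(
                    f"mixture probabilities for {cond!r} sum to "
                    f"{p_t + p_nt + p_u}, not 1"
                )
            if sd <= 0:
                raise ValueError(f"mixture SD for {cond!r} must be > 0")
            if not 0 <= self.pac_depth[cond] <= 1:
                raise ValueError("pac_depth must lie in [0, 1]")
            if self.alpha_erd_depth[cond] < 0:
                raise ValueError("alpha_erd_depth must be >= 0")
        for feat, snr in self.pattern_snr.items():
            if snr < 0:
                raise ValueError(f"pattern_snr[{feat!r}] must be >= 0")
        lo, hi = self.epoch_window
        for name, (wlo, whi) in (
            ("spectral baseline", BASELINE_TFR_WINDOW),
            ("retention", RETENTION_WINDOW),
        ):
            if wlo < lo or whi > hi:
                raise ValueError(
                    f"epoch_window {self.epoch_window} does not contain the "
                    f"{name} window {wlo:g}..{whi:g} ms"
                )
        for feat, win in self.pattern_window.items():
            if win[0] < lo or win[1] > hi:
                raise ValueError(
                    f"pattern window {win} for {feat!r} lies outside the "
                    f"epoch window {self.epoch_window}"
                )


@dataclass
class GroundTruth:
    """Everything the generator injected, for recovery tests."""

    condition: np.ndarray            # str per trial
    target_ori_idx: np.ndarray       # 0..7
    nontarget_ori_idx: np.ndarray    # 0..7, differs from target
    target_color_idx: np.ndarray     # 0..3
    nontarget_color_idx: np.ndarray  # 0..3, differs from target
    target_side: np.ndarray          # 0 = left, 1 = right
    patterns: dict                   # feature -> channels x labels matrix
    mixture_params: dict
    pac_depth: dict
    alpha_erd_depth: dict
    rt_z: np.ndarray                 # standard-normal RT latent per trial
    evoked_scale: np.ndarray         # per-trial evoked gain


def _balanced_labels(n: int, n_labels: int, rng: np.random.Generator) -> np.ndarray:
    """Random label sequence with counts balanced within +-1."""
    if n % n_labels != 0:
        logger.warning(
            "%d trials not divisible by %d labels; balancing within +-1 trial",
            n,
            n_labels,
        )
    reps = np.tile(np.arange(n_labels), n // n_labels + 1)[:n]
    return rng.permutation(reps)


def _derange_against(base: np.ndarray, n_labels: int, rng: np.random.Generator) -> np.ndarray:
    """Balanced labels with no position equal to ``base`` (swap fix-up)."""
    out = _balanced_labels(base.size, n_labels, rng)
    for i in np.flatnonzero(out == base):
        if out[i] != base[i]:
            continue
        for j in range(out.size):
            if out[j] != base[i] and out[i] != base[j]:
                out[i], out[j] = out[j], out[i]
                break
    return out


def _pink_noise_into(out, rng, exponent, srate, chunk=64):
    """Fill ``out`` (trials x channels x time) with unit-variance 1/f^beta noise.

    Generated trial-chunk by trial-chunk to keep the complex FFT
    intermediates bounded regardless of trial count.
    """
    n_trials, n_ch, n_times = out.shape
    n_f = n_times // 2 + 1
    freqs = np.fft.rfftfreq(n_times, d=1.0 / srate)
    scale = np.ones(n_f)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0  # no DC
    for start in range(0, n_trials, chunk):
        stop = min(start + chunk, n_trials)
        shape = (stop - start, n_ch, n_f)
        spec = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        x = np.fft.irfft(spec * scale, n=n_times, axis=-1)
        sd = x.std(axis=-1, keepdims=True)
        sd[sd == 0] = 1.0
        out[start:stop] = x / sd
    return out


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _evoked_waveform(t_ms: np.ndarray, cfg: SynthConfig) -> np.ndarray:
    """Unit-gain evoked time course: N2 bump + sustained late negativity."""
    n2 = np.exp(-0.5 * ((t_ms - 340.0) / 25.0) ** 2)
    plateau = _sigmoid((t_ms - 600.0) / 30.0) * _sigmoid((1300.0 - t_ms) / 30.0)
    return n2 + 0.6 * plateau


def _theta_burst(t_ms: np.ndarray, cfg: SynthConfig) -> np.ndarray:
    """Phase-locked theta burst after the cue (unit amplitude envelope)."""
    env = np.exp(-0.5 * ((t_ms - 400.0) / 200.0) ** 2)
    return env * np.sin(2 * np.pi * cfg.theta_freq * t_ms / 1000.0)


def _spatial_weights(channel_names: list[str]) -> dict[str, np.ndarray]:
    """Fixed topographies for the evoked response and posterior alpha."""
    n = len(channel_names)
    evoked = np.full(n, 0.1)
    alpha = np.zeros(n)
    for i, name in enumerate(channel_names):
        if name in FRONTOCENTRAL_9:
            evoked[i] = 1.0
        elif name[0] in ("F", "C") and name != HEOG_NAME:
            evoked[i] = 0.4
        if name in PARIETO_OCCIPITAL:
            alpha[i] = 1.0
    return {"evoked": evoked, "alpha": alpha}


def _make_truth(cfg: SynthConfig, rng: np.random.Generator) -> GroundTruth:
    """Draw every per-trial label and latent (cheap; no EEG arrays)."""
    n_per = cfg.n_trials_per_condition
    n_trials = 2 * n_per
    condition = np.repeat(CONDITIONS, n_per).astype(object)
    tgt_ori = np.concatenate([_balanced_labels(n_per, 8, rng) for _ in CONDITIONS])
    nt_ori = np.concatenate(
        [_derange_against(tgt_ori[i * n_per:(i + 1) * n_per], 8, rng) for i in range(2)]
    )
    tgt_col = np.concatenate([_balanced_labels(n_per, 4, rng) for _ in CONDITIONS])
    nt_col = np.concatenate(
        [_derange_against(tgt_col[i * n_per:(i + 1) * n_per], 4, rng) for i in range(2)]
    )
    side = np.concatenate([_balanced_labels(n_per, 2, rng) for _ in CONDITIONS])
    rt_z = rng.standard_normal(n_trials)

    patterns: dict[str, np.ndarray] = {}
    for feat, n_labels in (
        ("target_orientation", 8),
        ("nontarget_orientation", 8),
        ("target_color", 4),
        ("target_space", 2),
    ):
        mat = rng.standard_normal((len(STANDARD_60), n_labels))
        mat /= np.linalg.norm(mat, axis=0, keepdims=True)
        patterns[feat] = mat

    cond_scale = np.array(
        [cfg.evoked_condition_scale[c] for c in condition], dtype=float
    )
    evoked_scale = np.clip(cond_scale * (1.0 + cfg.evoked_rt_slope * (-rt_z)), 0.0, None)
    return GroundTruth(
        condition=np.asarray(condition),
        target_ori_idx=tgt_ori,
        nontarget_ori_idx=nt_ori,
        target_color_idx=tgt_col,
        nontarget_color_idx=nt_col,
        target_side=side,
        patterns=patterns,
        mixture_params=dict(cfg.mixture_params),
        pac_depth=dict(cfg.pac_depth),
        alpha_erd_depth=dict(cfg.alpha_erd_depth),
        rt_z=rt_z,
        evoked_scale=evoked_scale,
    )


def generate_truth(cfg: SynthConfig) -> GroundTruth:
    """Per-trial ground truth only (for behavior-only studies, no EEG cost).

    Identical to the truth returned by :func:`generate_epochs` for the same
    config (labels are drawn before any signal synthesis).
    """
    return _make_truth(cfg, np.random.default_rng(cfg.rng_seed))


def generate_epochs(cfg: SynthConfig) -> tuple[EpochSet, GroundTruth]:
    """Generate one synthetic participant's epoched EEG.

    Returns the EpochSet (60 EEG channels + HEOG; valid trials first, then
    neutral, each block internally shuffled over labels) and the
    :class:`GroundTruth` describing every injected effect.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    n_per = cfg.n_trials_per_condition
    n_trials = 2 * n_per
    channel_names = STANDARD_60 + [HEOG_NAME]
    n_ch = len(channel_names)

    step = 1000.0 / cfg.srate
    times = np.arange(cfg.epoch_window[0], cfg.epoch_window[1] + step / 2, step)
    n_times = times.size

    truth = _make_truth(cfg, rng)
    condition = truth.condition
    tgt_ori, nt_ori = truth.target_ori_idx, truth.nontarget_ori_idx
    tgt_col, nt_col, side = (
        truth.target_color_idx,
        truth.nontarget_color_idx,
        truth.target_side,
    )

    # -- background noise --------------------------------------------------
    data = np.zeros((n_trials, n_ch, n_times))
    if cfg.noise_sd > 0:
        _pink_noise_into(data, rng, cfg.noise_exponent, cfg.srate)
        if cfg.channel_mixing > 0:
            mix = rng.standard_normal((n_ch, n_ch)) / np.sqrt(n_ch)
            for start in range(0, n_trials, 64):
                stop = min(start + 64, n_trials)
                mixed = data[start:stop] + cfg.channel_mixing * np.einsum(
                    "ij,tjs->tis", mix, data[start:stop]
                )
                data[start:stop] = mixed / mixed.std(axis=-1, keepdims=True)
        data *= cfg.noise_sd

    # -- label-dependent spatial patterns ----------------------------------
    label_arrays = {
        "target_orientation": tgt_ori,
        "nontarget_orientation": nt_ori,
        "target_color": tgt_col,
        "target_space": side,
    }
    for feat, labels in label_arrays.items():
        mat = truth.patterns[feat]
        snr = cfg.pattern_snr.get(feat, 0.0)
        if snr <= 0:
            continue
        w_lo, w_hi = cfg.pattern_window[feat]
        tmask = (times >= w_lo) & (times <= w_hi)
        # SNR is relative to the noise floor; with noise off, 1 uV reference
        amp = snr * (cfg.noise_sd if cfg.noise_sd > 0 else 1.0)
        data[:, : len(STANDARD_60), tmask] += (
            amp * mat[:, labels].T[:, :, None]
        )

    # -- phase-locked evoked response --------------------------------------
    weights = _spatial_weights(channel_names)
    evoked_scale = truth.evoked_scale
    base_wave = (
        cfg.evoked_amplitude * _evoked_waveform(times, cfg)
        + abs(cfg.evoked_amplitude) * cfg.theta_burst_scale * _theta_burst(times, cfg)
    )
    if cfg.evoked_jitter_sd > 0:
        shifts = np.round(
            rng.normal(0.0, cfg.evoked_jitter_sd, n_trials) / step
        ).astype(int)
    else:
        shifts = np.zeros(n_trials, dtype=int)
    for i in range(n_trials):
        wave = np.roll(base_wave, shifts[i]) if shifts[i] else base_wave
        data[i] += evoked_scale[i] * np.outer(weights["evoked"], wave)

    # -- ongoing theta at Fz + alpha with ERD and theta-phase coupling -----
    fz = channel_names.index("Fz")
    t_s = times / 1000.0
    post = (times >= 0) & (times <= RETENTION_WINDOW[1])
    erd_transition = _sigmoid(times / 50.0)  # smooth onset of the ERD
    for i in range(n_trials):
        phi0 = rng.uniform(0, 2 * np.pi)
        theta_phase = 2 * np.pi * cfg.theta_freq * t_s + phi0
        if cfg.theta_bg_amplitude > 0:
            data[i, fz] += cfg.theta_bg_amplitude * np.cos(theta_phase)
        if cfg.alpha_amplitude > 0:
            depth = cfg.alpha_erd_depth[condition[i]]
            pac = cfg.pac_depth[condition[i]]
            envelope = cfg.alpha_amplitude * (1.0 - depth * erd_transition)
            if pac > 0:
                envelope = envelope * np.where(
                    post, 1.0 + pac * np.cos(theta_phase), 1.0
                )
            psi0 = rng.uniform(0, 2 * np.pi, weights["alpha"].sum().astype(int))
            po_idx = np.flatnonzero(weights["alpha"] > 0)
            carrier = np.cos(
                2 * np.pi * cfg.alpha_freq * t_s[None, :] + psi0[:, None]
            )
            data[i, po_idx] += envelope[None, :] * carrier

    # -- occasional large artifacts ---------------------------------------
    heog = channel_names.index(HEOG_NAME)
    if cfg.artifact_frac_eeg > 0:
        bad = rng.random(n_trials) < cfg.artifact_frac_eeg
        for i in np.flatnonzero(bad):
            ch = rng.integers(0, len(STANDARD_60))
            t0 = rng.integers(0, n_times - 100)
            data[i, ch, t0:t0 + 100] += rng.choice([-1, 1]) * 150.0
    if cfg.artifact_frac_heog > 0:
        bad = rng.random(n_trials) < cfg.artifact_frac_heog
        for i in np.flatnonzero(bad):
            t0 = rng.integers(0, n_times - 200)
            data[i, heog, t0:t0 + 200] += rng.choice([-1, 1]) * 80.0

    table = pd.DataFrame(
        {
            "condition": condition,
            "target_ori_idx": tgt_ori,
            "nontarget_ori_idx": nt_ori,
            "target_ori_deg": ORIENTATIONS_DEG[tgt_ori],
            "nontarget_ori_deg": ORIENTATIONS_DEG[nt_ori],
            "target_color_idx": tgt_col,
            "nontarget_color_idx": nt_col,
            "target_side": side,
        }
    )
    epochs = EpochSet(
        data=data,
        srate=cfg.srate,
        times=times,
        channel_names=channel_names,
        trial_table=table,
    )
    return epochs, truth


def generate_behavior(cfg: SynthConfig, truth: GroundTruth) -> pd.DataFrame:
    """Draw per-trial continuous reports and RTs from the ground truth.

    Reports follow the 3-component process of each trial's condition: with
    probability ``p_target`` a von Mises draw (concentration matched to the
    configured SD) around the target orientation, with ``p_nontarget``
    around the non-target, otherwise uniform on the 180-degree circle. RTs
    are shifted log-normal, tied to the same latent that scales the evoked
    response when ``evoked_rt_slope`` is non-zero.
    """
    n = truth.condition.size
    if n == 0:
        raise ValueError("ground truth contains no trials")
    rng = np.random.default_rng(
        np.random.SeedSequence((cfg.rng_seed, 0xBE4A))
    )
    target = ORIENTATIONS_DEG[truth.target_ori_idx]
    nontarget = ORIENTATIONS_DEG[truth.nontarget_ori_idx]
    report = np.empty(n)
    component = np.empty(n, dtype=object)
    u = rng.random(n)
    for cond in CONDITIONS:
        p_t, p_nt, p_u, sd = cfg.mixture_params[cond]
        if sd <= 0:
            raise ValueError(f"mixture SD for {cond!r} must be > 0")
        kappa = kappa_from_sd(sd)
        mask = truth.condition == cond
        # von Mises noise on the doubled circle, halved back to orientation
        vm = np.degrees(rng.vonmises(0.0, kappa, mask.sum())) / 2.0
        uni = rng.uniform(-90.0, 90.0, mask.sum())
        pick_t = u[mask] < p_t
        pick_nt = (u[mask] >= p_t) & (u[mask] < p_t + p_nt)
        rep = np.where(
            pick_t,
            target[mask] + vm,
            np.where(pick_nt, nontarget[mask] + vm, uni),
        )
        report[mask] = wrap_orientation(rep)
        component[mask] = np.where(pick_t, "target", np.where(pick_nt, "nontarget", "uniform"))

    rt = np.empty(n)
    for cond in CONDITIONS:
        shift, median, sigma = cfg.rt_params[cond]
        mask = truth.condition == cond
        rt[mask] = shift + median * np.exp(sigma * truth.rt_z[mask])

    return pd.DataFrame(
        {
            "condition": truth.condition,
            "target_deg": target,
            "nontarget_deg": nontarget,
            "report_deg": report,
            "rt_ms": rt,
            "true_component": component,
        }
    )


def attach_behavior(epochs: EpochSet, behavior: pd.DataFrame) -> EpochSet:
    """Merge behavioral columns into the epoch trial table (same order)."""
    if len(behavior) != epochs.n_trials:
        raise ValueError("behavior table length does not match trial count")
    out = epochs.copy()
    for col in ("target_deg", "nontarget_deg", "report_deg", "rt_ms"):
        out.trial_table[col] = behavior[col].to_numpy()
    return out


def null_config(**overrides) -> SynthConfig:
    """A configuration with every injected effect switched off.

    Downstream detectors (decoding, ITPC condition contrast, PAC, cluster
    tests) should stay at their null level on data from this config.
    """
    base = dict(
        pattern_snr={
            "target_orientation": 0.0,
            "nontarget_orientation": 0.0,
            "target_color": 0.0,
            "target_space": 0.0,
        },
        evoked_amplitude=0.0,
        evoked_condition_scale={"valid": 0.0, "neutral": 0.0},
        alpha_erd_depth={"valid": 0.0, "neutral": 0.0},
        pac_depth={"valid": 0.0, "neutral": 0.0},
        mixture_params={
            "valid": (0.8, 0.05, 0.15, 16.0),
            "neutral": (0.8, 0.05, 0.15, 16.0),
        },
        rt_params={
            "valid": (300.0, 750.0, 0.35),
            "neutral": (300.0, 750.0, 0.35),
        },
    )
    base.update(overrides)
    return SynthConfig(**base)
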
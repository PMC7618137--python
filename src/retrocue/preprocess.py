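"""Deterministic epoch conditioning and artifact screening.

Order contract (enforced by the pipeline driver, each op callable standalone):
bandpass -> baseline correction -> artifact rejection. Rejection only flags
trials in the trial table; sample values are never mutated. Ocular ICA
correction is out of scope here: data are accepted as already cleaned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from retrocue.containers import EpochSet, HEOG_NAME


def bandpass(e: EpochSet, lo: float, hi: float, order: int = 4) -> EpochSet:
    """Zero-phase band-pass filtered copy (DC removed).

    A forward-backward (zero-phase) Butterworth filter of the given order;
    phase preservation keeps ERP latencies intact. Raises when the epoch is
    too short for the filter's edge padding, naming the minimum length.
    """
    nyq = e.srate / 2.0
    if not 0 < lo < hi < nyq:
        raise ValueError(f"need 0 < lo < hi < Nyquist ({nyq:g} Hz); got {lo}..{hi}")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=e.srate, output="sos")
    min_len = 3 * (2 * sos.shape[0] + 1)
    if e.n_times <= min_len:
        raise ValueError(
            f"epoch has {e.n_times} samples but the zero-phase filter needs "
            f"more than {min_len}; use a longer epoch or a lower order"
        )
    # maximal odd-reflection padding: the low cutoff's transient is long
    # relative to the epoch, so the default short padding is not enough
    data = signal.sosfiltfilt(sos, e.data, axis=-1, padlen=e.n_times - 1)
    return e.copy(data=np.ascontiguousarray(data))


def baseline_correct(e: EpochSet, window: tuple[float, float] = (-200.0, 0.0)) -> EpochSet:
    """Subtract the per-trial, per-channel mean over ``window`` (ms)."""
    e.require_window(window, "baseline window")
    mask = e.time_mask(window)
    data = e.data - e.data[:, :, mask].mean(axis=-1, keepdims=True)
    return e.copy(data=data)


def reject_artifacts(
    e: EpochSet,
    amp_thresh: float = 80.0,
    heog_thresh: float = 50.0,
    heog_channel: str | None = HEOG_NAME,
) -> EpochSet:
    """Flag trials whose voltages exceed the amplitude screens.

    A trial is flagged when any EEG sample strictly exceeds ``+-amp_thresh``
    microvolts, or any sample at the horizontal-EOG channel strictly exceeds
    ``+-heog_thresh``. Comparisons are strict to match "exceeding". Flags go
    into ``trial_table['reject_flag']``; the data are retained untouched.
    Pass ``heog_channel=None`` to disable the EOG screen.
    """
    out = e.copy()
    eeg_idx = np.arange(e.n_channels)
    if heog_channel is not None:
        heog_i = e.channel_index(heog_channel)  # raises if missing
        eeg_idx = eeg_idx[eeg_idx != heog_i]
        heog_bad = np.abs(e.data[:, heog_i, :]).max(axis=-1) > heog_thresh
    else:
        heog_bad = np.zeros(e.n_trials, dtype=bool)
    eeg_bad = np.abs(e.data[:, eeg_idx, :]).max(axis=(1, 2)) > amp_thresh
    out.trial_table["reject_flag"] = eeg_bad | heog_bad
    return out


@dataclass
class ParticipantScreen:
    """Participant-level inclusion decision and its two statistics."""

    keep: bool
    reject_fraction: float
    mean_heog_uv: float


def screen_participant(
    e: EpochSet,
    max_reject_frac: float = 0.40,
    heog_mean_thresh: float = 3.2,
    heog_channel: str | None = HEOG_NAME,
) -> ParticipantScreen:
    """Exclude a participant for excessive rejection or residual HEOG drift.

    Excluded when strictly more than ``max_reject_frac`` of trials are
    flagged, or when the across-trial mean HEOG amplitude (time-averaged,
    signed) strictly exceeds ``+-heog_mean_thresh`` microvolts.
    """
    if "reject_flag" not in e.trial_table.columns:
        raise ValueError("run reject_artifacts first (no reject_flag column)")
    frac = float(e.trial_table["reject_flag"].mean())
    if heog_channel is not None:
        mean_heog = float(e.data[:, e.channel_index(heog_channel), :].mean())
    else:
        mean_heog = 0.0
    keep = frac <= max_reject_frac and abs(mean_heog) <= heog_mean_thresh
    return ParticipantScreen(keep=keep, reject_fraction=frac, mean_heog_uv=mean_heog)


def rereference_average_mastoid(
    e: EpochSet, mastoids: tuple[str, str] = ("M1", "M2")
) -> EpochSet:
    """Re-reference imported data to the average of the two mastoids.

    Synthetic data are generated already referenced; this is for data
    imported from recordings referenced elsewhere.
    """
    idx = e.channel_indices(list(mastoids))
    ref = e.data[:, idx, :].mean(axis=1, keepdims=True)
    return e.copy(data=e.data - ref)
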
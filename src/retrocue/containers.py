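"""Epoched-EEG container and its on-disk format.

The :class:`EpochSet` is the common currency of the pipeline: a trials x
channels x time float array (microvolts), a uniform time axis in milliseconds
relative to retro-cue onset, 10-20 channel names, and a per-trial metadata
table. On disk an EpochSet is one ``data.npy`` array plus a JSON sidecar
(channel names, sampling rate, time axis, schema version) and the trial
table as CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SCHEMA_VERSION = 1

#: 60-channel 10-20 montage used by the synthetic generator (EEG only).
STANDARD_60 = [
    "Fp1", "Fpz", "Fp2", "AF3", "AF4",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POz", "PO4", "PO6", "PO8",
    "O1", "Oz", "O2",
]

#: Fronto-central sites used for the N2 / N600 event-related components.
FRONTOCENTRAL_9 = ["F1", "Fz", "F2", "FC1", "FCz", "FC2", "C1", "Cz", "C2"]

#: Parieto-occipital sites used for alpha power / ERD and PAC amplitude.
PARIETO_OCCIPITAL = [
    "P3", "P4", "PO3", "PO4", "PO5", "PO6", "P7", "P8",
    "PO7", "PO8", "O1", "O2", "Pz", "Oz",
]

HEOG_NAME = "HEOG"


@dataclass
class EpochSet:
    """Trials x channels x time EEG epochs with per-trial metadata.

    Parameters
    ----------
    data
        Array of shape (n_trials, n_channels, n_times), microvolts.
    srate
        Sampling rate in Hz.
    times
        Time axis in ms relative to cue onset; strictly increasing and
        uniformly spaced at 1000/srate ms.
    channel_names
        Unique channel labels; may include a horizontal-EOG channel.
    trial_table
        One row per trial (condition, labels, report, RT, reject flag ...).
    """

    data: np.ndarray
    srate: float
    times: np.ndarray
    channel_names: list[str]
    trial_table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x time")
        n_trials, n_channels, n_times = self.data.shape
        if len(self.channel_names) != n_channels:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {n_channels} channels"
            )
        if len(set(self.channel_names)) != n_channels:
            raise ValueError("channel names must be unique")
        if self.times.shape != (n_times,):
            raise ValueError("times length must match data's last dimension")
        dt = np.diff(self.times)
        step = 1000.0 / self.srate
        if n_times > 1 and not np.allclose(dt, step, rtol=0, atol=1e-6 * step):
            raise ValueError("times must be uniformly spaced at 1000/srate ms")
        if self.trial_table is None or (
            len(self.trial_table) == 0 and len(self.trial_table.columns) == 0
        ):
            self.trial_table = pd.DataFrame(index=range(n_trials))
        if len(self.trial_table) != n_trials:
            raise ValueError("trial_table row count must equal number of trials")
        self.trial_table = self.trial_table.reset_index(drop=True)

    # -- basic accessors ---------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in montage") from None

    def channel_indices(self, names: list[str]) -> np.ndarray:
        return np.array([self.channel_index(n) for n in names], dtype=int)

    def time_mask(self, window: tuple[float, float]) -> np.ndarray:
        """Boolean mask over the time axis, endpoints inclusive."""
        lo, hi = window
        if lo > hi:
            raise ValueError(f"window {window} is empty (start > end)")
        mask = (self.times >= lo) & (self.times <= hi)
        if not mask.any():
            raise ValueError(
                f"window {window} ms contains no samples of the "
                f"epoch span {self.times[0]:g}..{self.times[-1]:g} ms"
            )
        return mask

    def require_window(self, window: tuple[float, float], what: str = "window") -> None:
        lo, hi = window
        if lo < self.times[0] or hi > self.times[-1]:
            raise ValueError(
                f"{what} {lo:g}..{hi:g} ms lies outside the epoch span "
                f"{self.times[0]:g}..{self.times[-1]:g} ms"
            )

    def copy(self, data: np.ndarray | None = None) -> "EpochSet":
        return EpochSet(
            data=self.data.copy() if data is None else data,
            srate=self.srate,
            times=self.times.copy(),
            channel_names=list(self.channel_names),
            trial_table=self.trial_table.copy(),
        )

    def crop(self, window: tuple[float, float]) -> "EpochSet":
        """Time-cropped copy (endpoints inclusive)."""
        mask = self.time_mask(window)
        return EpochSet(
            data=self.data[:, :, mask],
            srate=self.srate,
            times=self.times[mask],
            channel_names=list(self.channel_names),
            trial_table=self.trial_table.copy(),
        )

    def select_trials(self, mask: np.ndarray) -> "EpochSet":
        mask = np.asarray(mask)
        return EpochSet(
            data=self.data[mask],
            srate=self.srate,
            times=self.times.copy(),
            channel_names=list(self.channel_names),
            trial_table=self.trial_table.loc[np.asarray(mask)].reset_index(drop=True),
        )

    def kept_trials(self) -> "EpochSet":
        """Trials not flagged by artifact rejection (all trials if unflagged)."""
        if "reject_flag" not in self.trial_table.columns:
            return self
        return self.select_trials(~self.trial_table["reject_flag"].to_numpy(bool))


def save_epochs(e: EpochSet, out_dir: str | Path) -> Path:
    """Write an EpochSet to ``out_dir`` (data.npy + sidecar.json + trials.csv)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.save(out / "data.npy", e.data)
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "srate": float(e.srate),
        "times_ms": [float(t) for t in e.times],
        "channel_names": list(e.channel_names),
    }
    (out / "sidecar.json").write_text(json.dumps(sidecar, indent=1))
    e.trial_table.to_csv(out / "trials.csv", index=False)
    return out


def load_epochs(in_dir: str | Path) -> EpochSet:
    """Read an EpochSet written by :func:`save_epochs`.

    Raises a clear error (no partial load) when the sidecar is missing or
    declares an unknown schema version.
    """
    src = Path(in_dir)
    sidecar_path = src / "sidecar.json"
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"missing sidecar.json in {src}; not a valid EpochSet container"
        )
    sidecar = json.loads(sidecar_path.read_text())
    version = sidecar.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(
            f"container schema version {version} not supported "
            f"(expected {SCHEMA_VERSION}); migrate the container first"
        )
    data = np.load(src / "data.npy")
    trials_path = src / "trials.csv"
    table = pd.read_csv(trials_path) if trials_path.stat().st_size > 1 else pd.DataFrame()
    return EpochSet(
        data=data,
        srate=sidecar["srate"],
        times=np.array(sidecar["times_ms"], dtype=float),
        channel_names=list(sidecar["channel_names"]),
        trial_table=table,
    )
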
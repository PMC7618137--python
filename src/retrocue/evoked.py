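"""Event-related potential components: frontal N2, N600, and RT-binned ERPs.

Components are mean amplitudes over a time window and a fixed set of nine
fronto-central electrodes (F1, Fz, F2, FC1, FCz, FC2, C1, Cz, C2): N2 over
320-360 ms and N600 over 600-1300 ms after cue onset, window endpoints
inclusive on the sample grid. Amplitudes are reported signed (both
components are negative-going by convention, but no sign is imposed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from retrocue.containers import EpochSet, FRONTOCENTRAL_9


@dataclass
class Erp:
    """Trial-averaged waveform (channels x time) for one condition."""

    data: np.ndarray
    times: np.ndarray
    channel_names: list[str]
    n_trials: int
    n_rejected: int
    condition: str | None = None


@dataclass
class ErpComponent:
    name: str
    window: tuple[float, float]
    electrodes: list[str] = field(default_factory=lambda: list(FRONTOCENTRAL_9))


N2 = ErpComponent("N2", (320.0, 360.0))
#: Methods window; a 600-1200 ms variant is sometimes used for topographies.
N600 = ErpComponent("N600", (600.0, 1300.0))


def average_erp(
    e: EpochSet,
    condition: str | None = None,
    baseline: tuple[float, float] | None = (-200.0, 0.0),
) -> Erp:
    """Arithmetic mean over kept (non-rejected) trials of one condition.

    The baseline window is re-asserted on the average (subtracting its mean
    commutes with trial averaging). Raises when no kept trial matches.
    """
    sub = e.kept_trials()
    n_rejected = e.n_trials - sub.n_trials
    if condition is not None:
        sub = sub.select_trials(sub.trial_table["condition"].to_numpy() == condition)
    if sub.n_trials == 0:
        raise ValueError(f"no kept trials for condition {condition!r}")
    wave = sub.data.mean(axis=0)
    if baseline is not None:
        mask = sub.time_mask(baseline)
        wave = wave - wave[:, mask].mean(axis=-1, keepdims=True)
    return Erp(
        data=wave,
        times=sub.times.copy(),
        channel_names=list(sub.channel_names),
        n_trials=sub.n_trials,
        n_rejected=n_rejected,
        condition=condition,
    )


def component_amplitude(erp: Erp, comp: ErpComponent) -> float:
    """Mean amplitude (microvolts) over the component's window and sites."""
    lo, hi = comp.window
    mask = (erp.times >= lo) & (erp.times <= hi)
    if not mask.any():
        raise ValueError(
            f"{comp.name} window {comp.window} outside the epoch span "
            f"{erp.times[0]:g}..{erp.times[-1]:g} ms"
        )
    missing = [c for c in comp.electrodes if c not in erp.channel_names]
    if missing:
        raise KeyError(f"electrode(s) {missing} not in montage")
    idx = [erp.channel_names.index(c) for c in comp.electrodes]
    return float(erp.data[np.ix_(idx, np.flatnonzero(mask))].mean())


def rt_bin_erp(
    e: EpochSet,
    n_bins: int = 3,
    component: ErpComponent = N2,
    by_condition: bool = True,
    baseline: tuple[float, float] | None = (-200.0, 0.0),
) -> pd.DataFrame:
    """Split trials into RT tertiles and measure the component per bin.

    Kept trials are stably sorted by RT (ties keep trial order) and split
    into ``n_bins`` near-equal bins, remainder to the earliest (fastest)
    bins; binning is within condition by default. Returns one row per
    (condition, bin) with trial count, mean RT, and component amplitude.
    """
    sub = e.kept_trials()
    if "rt_ms" not in sub.trial_table.columns:
        raise ValueError("trial table has no rt_ms column")
    groups = (
        sub.trial_table["condition"].unique() if by_condition else [None]
    )
    rows = []
    for cond in groups:
        g = (
            sub.select_trials(sub.trial_table["condition"].to_numpy() == cond)
            if cond is not None
            else sub
        )
        if g.n_trials < n_bins:
            raise ValueError(
                f"{g.n_trials} trials cannot fill {n_bins} RT bins"
                + (f" for condition {cond!r}" if cond is not None else "")
            )
        order = np.argsort(g.trial_table["rt_ms"].to_numpy(), kind="stable")
        for b, idx in enumerate(np.array_split(order, n_bins)):
            binned = g.select_trials(idx)
            erp = average_erp(binned, baseline=baseline)
            rows.append(
                {
                    "condition": cond,
                    "rt_bin": b,
                    "n_trials": idx.size,
                    "mean_rt_ms": float(binned.trial_table["rt_ms"].mean()),
                    "component": component.name,
                    "amplitude_uv": component_amplitude(erp, component),
                }
            )
    return pd.DataFrame(rows)
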
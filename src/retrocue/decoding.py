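"""Time-resolved multivariate decoding, temporal generalization, spread time.

The decoding protocol: epochs are downsampled to 50 Hz by averaging
non-overlapping blocks of adjacent samples; same-label trials are randomly
arranged into three bins and averaged into pseudo-trials; a linear SVM on
all EEG channels is trained and tested by stratified 3-fold cross-validation
at each time point; the whole procedure is repeated for ten iterations with
fresh random binning, and accuracies are averaged over folds and iterations.
Chance is exactly 1/n_labels (12.5% for the 8 orientations, 25% for the 4
colors, 50% for the 2 sides).

Temporal generalization trains at one time point and tests at every other
(always on disjoint pseudo-trials), yielding an ACC(t_train, t_test) map.
The spread-time index thresholds that map at chance,

    Spd(t_train, t_test) = 1 if ACC(t_train, t_test) > chance else 0
    Spreadtime(t_train)  = sum over t_test of Spd(t_train, t_test),

counting the test time points to which a training-time code generalizes —
larger values mean a more temporally stable representation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from retrocue.containers import EpochSet, HEOG_NAME

#: feature name -> (trial-table column, number of labels)
FEATURES = {
    "target_orientation": ("target_ori_idx", 8),
    "nontarget_orientation": ("nontarget_ori_idx", 8),
    "target_color": ("target_color_idx", 4),
    "target_space": ("target_side", 2),
}


@dataclass
class DecodingSpec:
    """Parameters of the decoding protocol."""

    feature: str = "target_orientation"
    n_bins: int = 3
    n_folds: int = 3
    n_iterations: int = 10
    downsample_to: float = 50.0
    electrodes: list[str] | None = None  # None: all channels except HEOG
    C: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.feature not in FEATURES:
            raise ValueError(
                f"unknown feature {self.feature!r}; choose from {sorted(FEATURES)}"
            )
        if self.n_bins < self.n_folds:
            raise ValueError("need n_bins >= n_folds for disjoint train/test")

    @property
    def n_labels(self) -> int:
        return FEATURES[self.feature][1]

    @property
    def chance(self) -> float:
        return 1.0 / self.n_labels

    @property
    def label_column(self) -> str:
        return FEATURES[self.feature][0]


@dataclass
class DecodingCurve:
    times: np.ndarray            # ms, downsampled grid
    accuracy: np.ndarray         # mean over folds and iterations
    per_iteration: np.ndarray    # n_iterations x n_times
    chance: float
    feature: str
    condition: str | None = None


@dataclass
class GeneralizationMap:
    times: np.ndarray
    acc: np.ndarray              # train-time x test-time
    chance: float
    feature: str
    condition: str | None = None


@dataclass
class SpreadTimeProfile:
    times: np.ndarray
    spd: np.ndarray              # binary train x test matrix
    spread_time: np.ndarray      # integer per train time
    chance: float


def downsample_epochs(e: EpochSet, to: float) -> EpochSet:
    """Average non-overlapping blocks of adjacent samples down to ``to`` Hz.

    The source rate must be an integer multiple of the target rate (1000 Hz
    to 50 Hz averages blocks of 20 samples); new time stamps are the block
    centers. A trailing partial block is dropped.
    """
    ratio = e.srate / to
    if abs(ratio - round(ratio)) > 1e-9:
        near = e.srate / max(1, round(ratio))
        raise ValueError(
            f"sampling rate {e.srate:g} Hz is not divisible by {to:g} Hz; "
            f"nearest divisible target is {near:g} Hz"
        )
    block = int(round(ratio))
    n_blocks = e.n_times // block
    data = (
        e.data[:, :, : n_blocks * block]
        .reshape(e.n_trials, e.n_channels, n_blocks, block)
        .mean(axis=-1)
    )
    times = e.times[: n_blocks * block].reshape(n_blocks, block).mean(axis=-1)
    return EpochSet(
        data=data,
        srate=to,
        times=times,
        channel_names=list(e.channel_names),
        trial_table=e.trial_table.copy(),
    )


def make_bins(
    labels: np.ndarray, n_bins: int, rng: np.random.Generator | int
) -> list[tuple[int, list[np.ndarray]]]:
    """Randomly partition each label's trials into ``n_bins`` near-equal bins.

    Returns ``[(label, [trial index arrays, one per bin]), ...]`` sorted by
    label. Remainder trials go to the earliest bins. Reproducible given the
    generator / seed; raises if any label has fewer than ``n_bins`` trials,
    naming the label.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    labels = np.asarray(labels)
    out = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if idx.size < n_bins:
            raise ValueError(
                f"label {lab!r} has only {idx.size} trials; need >= {n_bins} for binning"
            )
        out.append((lab, list(np.array_split(rng.permutation(idx), n_bins))))
    return out


def shuffle_labels(e: EpochSet, feature: str, seed: int) -> EpochSet:
    """Copy of ``e`` with the feature's label column randomly permuted.

    Breaks any label-signal association while keeping marginals; used for
    empirical chance calibration.
    """
    column = FEATURES[feature][0]
    rng = np.random.default_rng(seed)
    out = e.copy()
    vals = out.trial_table[column].to_numpy()
    out.trial_table[column] = rng.permutation(vals)
    return out


def _prepare(e: EpochSet, spec: DecodingSpec, condition: str | None):
    e = e.kept_trials()
    if condition is not None:
        e = e.select_trials(e.trial_table["condition"].to_numpy() == condition)
    if e.srate != spec.downsample_to:
        e = downsample_epochs(e, spec.downsample_to)
    if spec.electrodes is None:
        names = [c for c in e.channel_names if c != HEOG_NAME]
    else:
        names = list(spec.electrodes)
    ch = e.channel_indices(names)
    X = e.data[:, ch, :]
    y = e.trial_table[spec.label_column].to_numpy()
    return X, y, e.times


def _pseudotrials(X, y, spec: DecodingSpec, rng):
    """Bin-averaged pseudo-trials with a stratified fold assignment."""
    Xp, yp, fold = [], [], []
    for lab, bins in make_bins(y, spec.n_bins, rng):
        for b, idx in enumerate(bins):
            Xp.append(X[idx].mean(axis=0))
            yp.append(lab)
            fold.append(b % spec.n_folds)
    return np.stack(Xp), np.asarray(yp), np.asarray(fold)


def _zscore_train_stats(Xtr):
    mu = Xtr.mean(axis=0, keepdims=True)
    sd = Xtr.std(axis=0, keepdims=True)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return mu, sd


def _decode(
    e: EpochSet,
    spec: DecodingSpec,
    condition: str | None,
    generalize: bool,
):
    X, y, times = _prepare(e, spec, condition)
    n_times = times.size
    shape = (spec.n_iterations, n_times, n_times) if generalize else (spec.n_iterations, n_times)
    acc = np.zeros(shape)

    for it in range(spec.n_iterations):
        rng = np.random.default_rng(np.random.SeedSequence((spec.rng_seed, it)))
        Xp, yp, fold = _pseudotrials(X, y, spec, rng)
        fold_acc = np.zeros((spec.n_folds,) + shape[1:])
        for f in range(spec.n_folds):
            tr = fold != f
            te = ~tr
            assert not np.any(tr & te), "train/test pseudo-trial overlap"
            mu, sd = _zscore_train_stats(Xp[tr])
            Ztr = (Xp[tr] - mu) / sd
            Zte = (Xp[te] - mu) / sd
            y_tr, y_te = yp[tr], yp[te]
            n_te = Zte.shape[0]
            for t in range(n_times):
                Xt = Ztr[:, :, t]
                if np.ptp(Xt) == 0.0:
                    warnings.warn(
                        "constant training features; falling back to chance",
                        RuntimeWarning,
                    )
                    if generalize:
                        fold_acc[f, t, :] = spec.chance
                    else:
                        fold_acc[f, t] = spec.chance
                    continue
                clf = SVC(kernel="linear", C=spec.C)
                clf.fit(Xt, y_tr)
                if generalize:
                    # predict every test time in one call
                    flat = np.moveaxis(Zte, 2, 0).reshape(n_times * n_te, -1)
                    pred = clf.predict(flat).reshape(n_times, n_te)
                    fold_acc[f, t, :] = (pred == y_te[None, :]).mean(axis=1)
                else:
                    pred = clf.predict(Zte[:, :, t])
                    fold_acc[f, t] = (pred == y_te).mean()
        acc[it] = fold_acc.mean(axis=0)
    return times, acc


def decode_timecourse(
    e: EpochSet, spec: DecodingSpec, condition: str | None = None
) -> DecodingCurve:
    """Time-resolved cross-validated decoding accuracy.

    Runs the full protocol (fresh binning per iteration, stratified folds,
    per-time-point z-scoring with training statistics, linear SVM) and
    averages accuracy over folds and iterations.
    """
    times, acc = _decode(e, spec, condition, generalize=False)
    return DecodingCurve(
        times=times,
        accuracy=acc.mean(axis=0),
        per_iteration=acc,
        chance=spec.chance,
        feature=spec.feature,
        condition=condition,
    )


def decode_generalization(
    e: EpochSet, spec: DecodingSpec, condition: str | None = None
) -> GeneralizationMap:
    """Full train-time x test-time accuracy map (temporal generalization).

    Shares the binning and fold construction of :func:`decode_timecourse`
    for the same spec and seed, so the map's diagonal equals the
    time-resolved curve.
    """
    times, acc = _decode(e, spec, condition, generalize=True)
    return GeneralizationMap(
        times=times,
        acc=acc.mean(axis=0),
        chance=spec.chance,
        feature=spec.feature,
        condition=condition,
    )


def spread_time(gmap: GeneralizationMap) -> SpreadTimeProfile:
    """Threshold the generalization map at chance and count per training time.

    ``Spd`` is 1 where accuracy strictly exceeds chance (accuracy equal to
    chance counts 0); ``spread_time`` is the row sum over test times.
    """
    spd = (gmap.acc > gmap.chance).astype(int)
    return SpreadTimeProfile(
        times=gmap.times,
        spd=spd,
        spread_time=spd.sum(axis=1),
        chance=gmap.chance,
    )
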
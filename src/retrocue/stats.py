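"""Cluster-based permutation tests across time, FDR, and group comparisons.

The cluster test controls the family-wise error over a time series of
comparisons without assuming independence: pointwise t statistics are
thresholded (two-sided pointwise p < 0.05 by default), contiguous
supra-threshold samples of consistent sign form clusters scored by their
summed t ("mass"), and observed masses are compared to the permutation null
of the maximum absolute cluster mass under random sign flips of the
unit-level effect curves (units are subjects, or independent generator seeds
for synthetic runs). Permutation p-values use the +1 correction,
p = (1 + #{null >= observed}) / (1 + n_permutations), so p is never 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class ClusterTestResult:
    """Clusters (half-open index ranges), masses, permutation null, p-values."""

    clusters: list[tuple[int, int]]
    cluster_stats: np.ndarray
    p_values: np.ndarray
    null_distribution: np.ndarray
    n_permutations: int
    alpha: float
    threshold: float
    times: np.ndarray | None = None

    def significant(self) -> list[tuple[int, int]]:
        return [c for c, p in zip(self.clusters, self.p_values) if p < self.alpha]


def find_clusters(tvals: np.ndarray, threshold: float):
    """Contiguous runs of |t| > threshold with consistent sign.

    Returns (list of (start, stop) half-open ranges, array of summed t per
    cluster), sorted by start index.
    """
    tvals = np.asarray(tvals, dtype=float)
    above = np.where(np.isfinite(tvals), np.abs(tvals) > threshold, False)
    sign = np.sign(tvals)
    clusters, masses = [], []
    i = 0
    n = tvals.size
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j < n and above[j] and sign[j] == sign[i]:
            j += 1
        clusters.append((i, j))
        masses.append(float(tvals[i:j].sum()))
        i = j
    return clusters, np.asarray(masses)


def _one_sample_t(data: np.ndarray):
    """Pointwise one-sample t of units x time data against zero."""
    n = data.shape[0]
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    return t


def _sign_flip_null(
    data: np.ndarray, threshold: float, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Max |cluster mass| under random sign flips of unit curves (vectorized t)."""
    n, _ = data.shape
    sumsq = (data**2).sum(axis=0)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    mean_s = signs @ data / n
    var_s = (sumsq - n * mean_s**2) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = mean_s / np.sqrt(var_s / n)
    null = np.zeros(n_perm)
    for p in range(n_perm):
        _, masses = find_clusters(t_perm[p], threshold)
        if masses.size:
            null[p] = np.abs(masses).max()
    return null


def _cluster_test(
    data: np.ndarray,
    n_perm: int,
    seed: int,
    alpha: float,
    cluster_p: float,
    times: np.ndarray | None,
) -> ClusterTestResult:
    if n_perm <= 0:
        raise ValueError("n_perm must be a positive integer")
    n = data.shape[0]
    if n < 5:
        raise ValueError(f"need >= 5 units for a cluster permutation test, got {n}")
    threshold = float(sps.t.ppf(1.0 - cluster_p / 2.0, df=n - 1))
    tvals = _one_sample_t(data)
    if not np.any(np.isfinite(tvals)):
        warnings.warn(
            "degenerate t statistics (zero variance everywhere); no clusters",
            RuntimeWarning,
        )
        return ClusterTestResult(
            clusters=[],
            cluster_stats=np.array([]),
            p_values=np.array([]),
            null_distribution=np.zeros(n_perm),
            n_permutations=n_perm,
            alpha=alpha,
            threshold=threshold,
            times=times,
        )
    clusters, masses = find_clusters(tvals, threshold)
    rng = np.random.default_rng(seed)
    null = _sign_flip_null(data, threshold, n_perm, rng)
    p = np.array(
        [(1 + np.sum(null >= abs(m))) / (1 + n_perm) for m in masses]
    )
    return ClusterTestResult(
        clusters=clusters,
        cluster_stats=masses,
        p_values=p,
        null_distribution=null,
        n_permutations=n_perm,
        alpha=alpha,
        threshold=threshold,
        times=times,
    )


def cluster_permutation_vs_chance(
    curves: np.ndarray,
    chance: float,
    n_perm: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    cluster_p: float = 0.05,
    times: np.ndarray | None = None,
) -> ClusterTestResult:
    """Cluster permutation test of unit accuracy curves against chance.

    ``curves`` is units x time (subjects, or independent generator seeds on
    synthetic data). The null sign-flips each unit's accuracy-minus-chance
    curve, exchangeable when accuracy is symmetric around chance under H0.
    """
    curves = np.asarray(curves, dtype=float)
    if curves.ndim != 2:
        raise ValueError("curves must be a units x time array")
    return _cluster_test(curves - chance, n_perm, seed, alpha, cluster_p, times)


def cluster_permutation_paired(
    a_curves: np.ndarray,
    b_curves: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    cluster_p: float = 0.05,
    times: np.ndarray | None = None,
) -> ClusterTestResult:
    """Paired cluster permutation test between two within-unit conditions.

    Uses the paired t on a - b; the null flips condition labels within unit
    (sign flips of the difference curves).
    """
    a = np.asarray(a_curves, dtype=float)
    b = np.asarray(b_curves, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("paired inputs must be equal-shape units x time arrays")
    return _cluster_test(a - b, n_perm, seed, alpha, cluster_p, times)


def fdr_correct(p, q: float = 0.05):
    """Benjamini-Hochberg step-up FDR correction.

    Returns (rejection mask, adjusted p-values); empty input gives empty
    arrays.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.array([], dtype=bool), np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    cohens_d: float


def ttest(x, y=None, paired: bool = True, popmean: float = 0.0) -> TTestResult:
    """One-sample / paired / independent t-test with Cohen's d.

    With ``y=None`` tests ``x`` against ``popmean``; with ``paired=True``
    tests the within-unit differences. d is mean/SD of the tested scores
    (pooled SD for the independent case).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need n >= 3")
    if y is None:
        d = x - popmean
    elif paired:
        y = np.asarray(y, dtype=float)
        if y.shape != x.shape:
            raise ValueError("paired samples must have equal length")
        d = x - y
    else:
        y = np.asarray(y, dtype=float)
        sp = np.sqrt(
            ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1))
            / (x.size + y.size - 2)
        )
        if sp == 0:
            raise ValueError("zero pooled variance")
        res = sps.ttest_ind(x, y)
        return TTestResult(
            t=float(res.statistic),
            df=x.size + y.size - 2,
            p=float(res.pvalue),
            cohens_d=float((x.mean() - y.mean()) / sp),
        )
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            # identical paired samples: no effect by convention
            return TTestResult(t=0.0, df=d.size - 1, p=1.0, cohens_d=0.0)
        raise ValueError("zero variance in the tested scores")
    res = sps.ttest_1samp(d, 0.0)
    return TTestResult(
        t=float(res.statistic),
        df=d.size - 1,
        p=float(res.pvalue),
        cohens_d=float(d.mean() / sd),
    )


def pearson_r(x, y):
    """Pearson correlation (r, p). Raises on zero variance or n < 3."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size != x.size:
        raise ValueError("need equal-length samples with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def rm_anova_2x2(data: np.ndarray):
    """Thin 2x2 repeated-measures ANOVA convenience.

    ``data`` is units x 2 x 2 (factor A x factor B). Each effect's F equals
    the squared paired t of the corresponding within-unit contrast
    (df = 1, n-1). Returns a dict of (F, df1, df2, p) per effect.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 3 or data.shape[1:] != (2, 2):
        raise ValueError("data must be units x 2 x 2")
    n = data.shape[0]
    contrasts = {
        "A": data[:, 0, :].mean(axis=1) - data[:, 1, :].mean(axis=1),
        "B": data[:, :, 0].mean(axis=1) - data[:, :, 1].mean(axis=1),
        "AxB": (data[:, 0, 0] - data[:, 0, 1]) - (data[:, 1, 0] - data[:, 1, 1]),
    }
    out = {}
    for name, c in contrasts.items():
        res = sps.ttest_1samp(c, 0.0)
        out[name] = {
            "F": float(res.statistic**2),
            "df1": 1,
            "df2": n - 1,
            "p": float(res.pvalue),
        }
    return out
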
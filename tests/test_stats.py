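"""Cluster permutation machinery, FDR, and standard group tests."""

import numpy as np
import pytest

from retrocue.stats import (
    cluster_permutation_paired,
    cluster_permutation_vs_chance,
    fdr_correct,
    find_clusters,
    pearson_r,
    rm_anova_2x2,
    ttest,
)


class TestFindClusters:
    def test_single_run(self):
        t = np.array([0.0, 3.0, 3.5, 0.5, -3.0])
        clusters, masses = find_clusters(t, 2.0)
        assert clusters == [(1, 3), (4, 5)]
        assert masses.tolist() == [6.5, -3.0]

    def test_sign_change_splits_cluster(self):
        t = np.array([3.0, 3.0, -3.0, -3.0])
        clusters, masses = find_clusters(t, 2.0)
        assert clusters == [(0, 2), (2, 4)]
        assert masses.tolist() == [6.0, -6.0]

    def test_nothing_above_threshold(self):
        clusters, masses = find_clusters(np.zeros(10), 2.0)
        assert clusters == [] and masses.size == 0


class TestClusterVsChance:
    def test_strong_window_detected(self):
        """An injected above-chance window yields one covering cluster."""
        rng = np.random.default_rng(0)
        hits = 0
        for seed in range(10):
            curves = 0.125 + 0.01 * rng.standard_normal((10, 50))
            curves[:, 20:30] += 0.10
            res = cluster_permutation_vs_chance(
                curves, 0.125, n_perm=500, seed=seed
            )
            sig = res.significant()
            if len(sig) == 1:
                a, b = sig[0]
                overlap = max(0, min(b, 30) - max(a, 20))
                hits += overlap >= 8
        assert hits >= 9

    def test_identical_curves_degenerate(self):
        curves = np.full((6, 20), 0.125)
        with pytest.warns(RuntimeWarning, match="degenerate"):
            res = cluster_permutation_vs_chance(curves, 0.125, n_perm=100, seed=0)
        assert res.clusters == []

    def test_zero_permutations_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            cluster_permutation_vs_chance(np.zeros((6, 10)), 0.0, n_perm=0, seed=0)

    def test_too_few_units_rejected(self):
        with pytest.raises(ValueError, match=">= 5"):
            cluster_permutation_vs_chance(np.zeros((3, 10)), 0.0, n_perm=10, seed=0)

    def test_deterministic_null(self):
        rng = np.random.default_rng(1)
        curves = 0.5 + 0.1 * rng.standard_normal((8, 30))
        r1 = cluster_permutation_vs_chance(curves, 0.5, n_perm=200, seed=9)
        r2 = cluster_permutation_vs_chance(curves, 0.5, n_perm=200, seed=9)
        assert np.array_equal(r1.null_distribution, r2.null_distribution)
        assert np.array_equal(r1.p_values, r2.p_values)

    def test_p_values_never_zero(self):
        rng = np.random.default_rng(2)
        curves = 0.5 + np.abs(rng.standard_normal((8, 30)))  # absurdly strong
        res = cluster_permutation_vs_chance(curves, 0.5, n_perm=100, seed=0)
        assert np.all(res.p_values >= 1.0 / 101.0)


class TestClusterPaired:
    def test_equal_inputs_give_no_clusters(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal((7, 25))
        with pytest.warns(RuntimeWarning):
            res = cluster_permutation_paired(a, a.copy(), n_perm=100, seed=0)
        assert res.clusters == []

    def test_offset_window_localized(self):
        rng = np.random.default_rng(4)
        a = rng.standard_normal((10, 40)) * 0.1
        b = rng.standard_normal((10, 40)) * 0.1
        a[:, 10:20] += 1.0
        res = cluster_permutation_paired(a, b, n_perm=500, seed=1)
        sig = res.significant()
        assert len(sig) >= 1
        start, stop = sig[0]
        assert start >= 8 and stop <= 22

    def test_antisymmetry_under_swap(self):
        rng = np.random.default_rng(5)
        a = rng.standard_normal((8, 30))
        b = rng.standard_normal((8, 30)) + 0.5
        r_ab = cluster_permutation_paired(a, b, n_perm=300, seed=2)
        r_ba = cluster_permutation_paired(b, a, n_perm=300, seed=2)
        assert r_ab.clusters == r_ba.clusters
        assert np.allclose(r_ab.cluster_stats, -r_ba.cluster_stats)
        assert np.allclose(r_ab.p_values, r_ba.p_values)

    def test_unequal_shapes_rejected(self):
        with pytest.raises(ValueError, match="equal-shape"):
            cluster_permutation_paired(np.zeros((6, 10)), np.zeros((6, 11)))


def brute_force_bh(p, q):
    """Step-up BH by direct enumeration of the rejection thresholds."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p)
    k_max = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= q * k / m:
            k_max = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_max]] = True
    return reject


class TestFdr:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.001, 0.001, 0.001], [True, True, True]),
            ([0.9, 0.8, 0.7], [False, False, False]),
            ([0.01, 0.02, 0.03, 0.5], [True, True, True, False]),
        ],
    )
    def test_examples(self, p, expected):
        reject, _ = fdr_correct(p, q=0.05)
        assert reject.tolist() == expected

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            m = rng.integers(1, 13)
            p = rng.random(m)
            reject, _ = fdr_correct(p, q=0.05)
            assert np.array_equal(reject, brute_force_bh(p, 0.05))

    def test_empty_input(self):
        reject, p_adj = fdr_correct([])
        assert reject.size == 0 and p_adj.size == 0

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_correct([0.5, 1.2])


class TestBasicTests:
    def test_identical_paired_samples(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = ttest(x, x.copy(), paired=True)
        assert res.t == 0.0 and res.cohens_d == 0.0 and res.p == 1.0

    def test_matches_scipy_formatting(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(20) + 0.5
        y = rng.standard_normal(20)
        res = ttest(x, y, paired=True)
        d = x - y
        assert res.cohens_d == pytest.approx(d.mean() / d.std(ddof=1))
        assert res.df == 19

    def test_zero_variance_nonzero_mean_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            ttest(np.array([1.0, 1.0, 1.0]), np.array([0.0, 0.0, 0.0]))

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            ttest(np.array([1.0, 2.0]))

    def test_perfect_correlation(self):
        r, _ = pearson_r([1.0, 2.0, 3.0], [2.0, 4.0, 6.0])
        assert r == pytest.approx(1.0)

    def test_pearson_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_rm_anova_detects_main_effect(self):
        rng = np.random.default_rng(8)
        data = rng.standard_normal((12, 2, 2)) * 0.2
        data[:, 0, :] += 2.0  # factor A main effect
        out = rm_anova_2x2(data)
        assert out["A"]["p"] < 0.001
        assert out["B"]["p"] > 0.01
        assert out["A"]["df2"] == 11


def test_null_calibration_quick():
    """Under chance-level curves the test rarely reports clusters."""
    rng = np.random.default_rng(9)
    false_alarms = 0
    n_rep = 40
    for rep in range(n_rep):
        curves = 0.125 + 0.02 * rng.standard_normal((10, 40))
        res = cluster_permutation_vs_chance(curves, 0.125, n_perm=300, seed=rep)
        false_alarms += len(res.significant()) > 0
    # nominal 5% FWER; allow generous binomial slack at n=40
    assert false_alarms <= 7
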
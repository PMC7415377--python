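import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu
from skbio import DistanceMatrix

from phycohealth import (
    FeatureTable, ancom, distance_to_centroid, faith_pd, faith_pd_series,
    logratio_correlation, pairwise_distances, pcoa, permanova, rarefy,
)


def make_table(counts, prefix_s="s", prefix_a="t"):
    counts = np.asarray(counts)
    return FeatureTable(pd.DataFrame(
        counts, index=[f"{prefix_s}{i}" for i in range(counts.shape[0])],
        columns=[f"{prefix_a}{j}" for j in range(counts.shape[1])]))


class TestFaithPD:
    def test_single_tip_hand_traversal(self, toy_tree):
        assert faith_pd({"A"}, toy_tree) == pytest.approx(2.0)

    def test_all_tips_total_length(self, toy_tree):
        assert faith_pd({"A", "B", "C", "D"}, toy_tree) == pytest.approx(10.0)

    def test_empty_sample_is_zero(self, toy_tree):
        assert faith_pd(set(), toy_tree) == 0.0

    def test_missing_tip_lists_offenders(self, toy_tree):
        with pytest.raises(ValueError, match="X"):
            faith_pd({"A", "X"}, toy_tree)

    def test_monotone_under_taxon_addition(self, toy_tree):
        subsets = [{"A"}, {"A", "B"}, {"A", "B", "C"}, {"A", "B", "C", "D"}]
        values = [faith_pd(s, toy_tree) for s in subsets]
        assert all(a <= b for a, b in zip(values, values[1:]))

    def test_series_uses_presence(self, toy_tree):
        table = FeatureTable(pd.DataFrame(
            [[3, 0, 0, 0], [1, 1, 1, 1]], index=["s1", "s2"],
            columns=["A", "B", "C", "D"]))
        out = faith_pd_series(table, toy_tree)
        assert out["s1"] == pytest.approx(2.0)
        assert out["s2"] == pytest.approx(10.0)


class TestDistances:
    def test_identity_axiom_all_metrics(self, toy_tree, rng):
        counts = rng.integers(0, 20, size=(4, 4)) + 1
        table = FeatureTable(pd.DataFrame(
            counts, index=[f"s{i}" for i in range(4)],
            columns=["A", "B", "C", "D"]))
        for metric in ("jaccard", "braycurtis", "unweighted_unifrac",
                       "weighted_unifrac"):
            dm = pairwise_distances(table, metric, tree=toy_tree)
            np.testing.assert_allclose(np.diag(dm.data), 0.0)
            np.testing.assert_allclose(dm.data, dm.data.T)

    def test_jaccard_hand_value(self):
        table = make_table([[1, 1, 1, 0], [0, 1, 1, 1]])
        dm = pairwise_distances(table, "jaccard")
        assert dm[("s0", "s1")] == pytest.approx(0.5)

    def test_braycurtis_hand_value(self):
        table = make_table([[2, 0, 1], [1, 1, 1]])
        dm = pairwise_distances(table, "braycurtis")
        assert dm[("s0", "s1")] == pytest.approx(1 / 3)

    def test_unifrac_zero_for_identical_samples(self, toy_tree):
        table = FeatureTable(pd.DataFrame(
            [[2, 3, 0, 1], [2, 3, 0, 1]], index=["s0", "s1"],
            columns=["A", "B", "C", "D"]))
        for metric in ("unweighted_unifrac", "weighted_unifrac"):
            dm = pairwise_distances(table, metric, tree=toy_tree)
            assert dm[("s0", "s1")] == pytest.approx(0.0)

    def test_jaccard_triangle_inequality_exhaustive(self):
        # all presence patterns over 3 taxa for 5 samples, brute force
        patterns = [p for p in itertools.product([0, 1], repeat=3) if any(p)]
        for combo in itertools.combinations(patterns, 3):
            table = make_table(np.array(combo) * 5)
            d = pairwise_distances(table, "jaccard").data
            assert d[0, 2] <= d[0, 1] + d[1, 2] + 1e-12

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError):
            pairwise_distances(make_table([[1, 2], [3, 4]]), "euclidean")

    def test_rarefaction_even_depth(self):
        table = make_table([[50, 30, 20], [10, 5, 85]])
        out = rarefy(table, depth=40, seed=0)
        np.testing.assert_array_equal(out.counts.sum(axis=1), [40, 40])


class TestPCoA:
    def test_recovers_planted_euclidean_geometry(self, rng):
        points = rng.normal(size=(5, 2))
        dist = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
        dm = DistanceMatrix(dist, ids=[f"s{i}" for i in range(5)])
        res = pcoa(dm)
        coords = res.coordinates.to_numpy()
        rec = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        np.testing.assert_allclose(rec, dist, atol=1e-8)

    def test_all_zero_matrix_gives_zero_coordinates(self):
        dm = DistanceMatrix(np.zeros((3, 3)), ids=["a", "b", "c"])
        res = pcoa(dm)
        assert res.coordinates.shape[1] == 0 or np.allclose(res.coordinates, 0)

    def test_eigenvalues_sorted_and_coordinates_centered(self, rng):
        counts = rng.integers(0, 30, size=(6, 8)) + 1
        dm = pairwise_distances(make_table(counts), "braycurtis")
        res = pcoa(dm)
        assert (np.diff(res.eigenvalues) <= 1e-12).all()
        np.testing.assert_allclose(res.coordinates.mean(axis=0), 0.0, atol=1e-9)


def brute_force_pseudo_f(dist, groups):
    """Anderson's partition computed directly from the distance matrix."""
    groups = np.asarray(groups)
    n = len(groups)
    a = len(set(groups.tolist()))
    d2 = dist ** 2
    ss_t = d2[np.triu_indices(n, 1)].sum() / n
    ss_w = 0.0
    for g in set(groups.tolist()):
        idx = np.where(groups == g)[0]
        sub = d2[np.ix_(idx, idx)]
        ss_w += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_a = ss_t - ss_w
    return (ss_a / (a - 1)) / (ss_w / (n - a))


class TestPermanova:
    def test_pseudo_f_matches_brute_force_partition(self, rng):
        counts = rng.integers(0, 40, size=(4, 6)) + 1
        dm = pairwise_distances(make_table(counts), "braycurtis")
        groups = ["x", "x", "y", "y"]
        f, _ = permanova(dm, groups, n_perm=99, seed=0)
        assert f == pytest.approx(brute_force_pseudo_f(dm.data, groups), rel=1e-10)

    def test_seeded_p_value_reproducible(self, rng):
        counts = rng.integers(0, 40, size=(8, 6)) + 1
        dm = pairwise_distances(make_table(counts), "braycurtis")
        groups = ["x"] * 4 + ["y"] * 4
        p1 = permanova(dm, groups, n_perm=199, seed=7)[1]
        p2 = permanova(dm, groups, n_perm=199, seed=7)[1]
        assert p1 == p2

    def test_singleton_group_rejected(self, rng):
        counts = rng.integers(0, 40, size=(3, 4)) + 1
        dm = pairwise_distances(make_table(counts), "braycurtis")
        with pytest.raises(ValueError):
            permanova(dm, ["x", "x", "y"])

    def test_zero_permutations_rejected(self, rng):
        counts = rng.integers(0, 40, size=(4, 4)) + 1
        dm = pairwise_distances(make_table(counts), "braycurtis")
        with pytest.raises(ValueError):
            permanova(dm, ["x", "x", "y", "y"], n_perm=0)


class TestDistanceToCentroid:
    def test_planted_geometry(self):
        # 4 points on a line: distances to the centroid of the first pair
        points = np.array([[0.0], [2.0], [5.0], [9.0]])
        dist = np.abs(points - points.T)
        dm = DistanceMatrix(dist, ids=["a", "b", "c", "d"])
        out = distance_to_centroid(dm, ["ref", "ref", "q", "q"], "ref")
        np.testing.assert_allclose(out.to_numpy(), [1.0, 1.0, 4.0, 8.0],
                                   atol=1e-8)

    def test_sample_order_invariance(self, rng):
        counts = rng.integers(0, 30, size=(6, 5)) + 1
        table = make_table(counts)
        dm = pairwise_distances(table, "braycurtis")
        groups = ["g1", "g1", "g1", "g2", "g2", "g2"]
        out1 = distance_to_centroid(dm, groups, "g1")
        perm = [3, 1, 4, 0, 5, 2]
        dm2 = DistanceMatrix(dm.data[np.ix_(perm, perm)],
                             ids=[dm.ids[i] for i in perm])
        out2 = distance_to_centroid(dm2, [groups[i] for i in perm], "g1")
        for sid in dm.ids:
            assert out1[sid] == pytest.approx(out2[sid], abs=1e-9)

    def test_unknown_reference_rejected(self, rng):
        counts = rng.integers(0, 30, size=(4, 4)) + 1
        dm = pairwise_distances(make_table(counts), "braycurtis")
        with pytest.raises(ValueError):
            distance_to_centroid(dm, ["a", "a", "b", "b"], "zzz")


def brute_force_w(counts, groups, pseudocount, alpha):
    n, D = counts.shape
    in_a = np.asarray(groups) == groups[0]
    w = np.zeros(D, dtype=int)
    for i in range(D):
        for j in range(D):
            if i == j:
                continue
            lr = np.log((counts[:, i] + pseudocount) / (counts[:, j] + pseudocount))
            p = mannwhitneyu(lr[in_a], lr[~in_a], alternative="two-sided").pvalue
            w[i] += p < alpha
    return w


class TestAncom:
    def test_w_matches_brute_force_double_loop(self, rng):
        counts = rng.integers(0, 60, size=(12, 5)) + 1
        table = make_table(counts)
        groups = ["a"] * 6 + ["b"] * 6
        res = ancom(table, groups)
        expected = brute_force_w(counts, groups, 1.0, 0.05)
        np.testing.assert_array_equal(res.w.to_numpy(), expected)

    def test_w_bounds(self, rng):
        counts = rng.integers(0, 60, size=(10, 6)) + 1
        res = ancom(make_table(counts), ["a"] * 5 + ["b"] * 5)
        assert ((res.w >= 0) & (res.w <= 5)).all()

    def test_scale_invariance_of_detection(self, rng):
        from phycohealth.synthetic_data import (
            generate_mixture_counts, make_separated_components)
        al = make_separated_components(1, 10, seed=6, support=5,
                                       alpha_dominant=5, alpha_background=0.5)
        X, _ = generate_mixture_counts(al, 24, depth=6000, seed=6)
        groups = ["a"] * 12 + ["b"] * 12
        res1 = ancom(make_table(X), groups)
        scaled = X.copy()
        scaled[0] *= 10  # compositional data: per-sample scale is arbitrary
        res2 = ancom(make_table(scaled), groups)
        pd.testing.assert_series_equal(res1.detected, res2.detected)

    def test_requires_two_groups_and_min_size(self, rng):
        counts = rng.integers(1, 10, size=(6, 4))
        with pytest.raises(ValueError):
            ancom(make_table(counts), ["a"] * 6)
        with pytest.raises(ValueError):
            ancom(make_table(counts), ["a", "a", "b", "b", "b", "b"])


class TestLogRatioCorrelation:
    def test_planted_linear_relation(self, rng):
        n = 40
        variable = rng.normal(size=n)
        log_ratio = 2.0 * variable + rng.normal(0, 0.01, size=n)
        num = np.round(1000 * np.exp(log_ratio)).astype(int)
        den = np.full(n, 1000)
        counts = np.column_stack([num, den, rng.integers(1, 10, n)])
        res = logratio_correlation(make_table(counts), ["t0"], ["t1"], variable)
        assert res.r > 0.99
        assert res.slope == pytest.approx(2.0, rel=0.05)

    def test_pearson_matches_textbook_formula(self):
        counts = np.column_stack([[10, 20, 40, 80, 160], [10] * 5])
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = logratio_correlation(make_table(counts), ["t0"], ["t1"], x,
                                   pseudocount=0.0)
        y = np.log(counts[:, 0] / counts[:, 1])
        r_hand = (((x - x.mean()) * (y - y.mean())).sum()
                  / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
        assert res.r == pytest.approx(r_hand, rel=1e-12)

    def test_constant_ratio_rejected(self):
        counts = np.column_stack([[5, 10, 20], [5, 10, 20], [1, 1, 1]])
        with pytest.raises(ValueError, match="zero variance"):
            logratio_correlation(make_table(counts), ["t0"], ["t1"],
                                 [1.0, 2.0, 3.0], pseudocount=0.0)

    def test_overlapping_sets_rejected(self):
        counts = np.ones((3, 3), dtype=int)
        with pytest.raises(ValueError, match="disjoint"):
            logratio_correlation(make_table(counts), ["t0"], ["t0", "t1"],
                                 [1.0, 2.0, 3.0])
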
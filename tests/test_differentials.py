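import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from phycohealth import (
    build_design_matrix, fit_multinomial_differentials, flag_outliers,
    generate_differential_counts, summarize_by_order, TaxonomyMap,
)
from phycohealth.differentials import DifferentialTable


@pytest.fixture(scope="module")
def planted_fit():
    table, covs, truth = generate_differential_counts(
        200, 30, depth=8000, seed=17)
    design = build_design_matrix(covs.reset_index(), ["effect", "null"])
    diffs = fit_multinomial_differentials(table, design, seed=17)
    return table, covs, truth, design, diffs


class TestDesignMatrix:
    def test_standardization_recorded_and_applied(self):
        md = pd.DataFrame({"sample_id": ["a", "b", "c", "d"],
                           "temp": [10.0, 20.0, 30.0, 40.0],
                           "bac": [True, False, True, False]})
        design = build_design_matrix(md, ["temp", "bac"])
        col = design.matrix[:, 1]
        assert col.mean() == pytest.approx(0.0)
        assert col.std() == pytest.approx(1.0)
        np.testing.assert_array_equal(design.matrix[:, 2], [1, 0, 1, 0])
        mu, sd = design.standardization["temp"]
        np.testing.assert_allclose(col * sd + mu, md["temp"])

    def test_missing_covariates_dropped_with_manifest(self):
        md = pd.DataFrame({"sample_id": ["a", "b", "c"],
                           "x": [1.0, np.nan, 3.0]})
        design = build_design_matrix(md, ["x"])
        assert design.dropped_samples == ["b"]
        assert design.sample_ids == ["a", "c"]

    def test_constant_covariate_rejected(self):
        md = pd.DataFrame({"sample_id": ["a", "b"], "x": [2.0, 2.0]})
        with pytest.raises(ValueError, match="constant"):
            build_design_matrix(md, ["x"])


class TestFit:
    def test_intercept_only_matches_clr_of_pooled_composition(self):
        table, covs, _ = generate_differential_counts(
            120, 20, depth=5000, effect_covariates=(), null_covariates=(), seed=5)
        design = build_design_matrix(covs.assign(sample_id=covs.index).reset_index(drop=True)[["sample_id"]], [])
        diffs = fit_multinomial_differentials(table, design, seed=0)
        totals = table.counts.sum(axis=0).astype(float)
        clr = np.log(totals) - np.log(totals).mean()
        np.testing.assert_allclose(diffs.differentials["Intercept"].to_numpy(),
                                   clr, atol=1e-3)

    def test_centering_invariant(self, planted_fit):
        *_, diffs = planted_fit
        sums = diffs.differentials.sum(axis=0)
        assert (sums.abs() < 1e-8).all()

    def test_zscores_standardized(self, planted_fit):
        *_, diffs = planted_fit
        assert diffs.zscores.mean().abs().max() < 1e-9
        np.testing.assert_allclose(diffs.zscores.std(ddof=0), 1.0, rtol=1e-9)

    def test_planted_effect_recovery(self, planted_fit):
        _, _, truth, _, diffs = planted_fit
        rho = spearmanr(diffs.differentials["effect"], truth.loc["effect"]).statistic
        assert rho >= 0.8
        assert (diffs.differentials["effect"].abs().mean()
                > diffs.differentials["null"].abs().mean())

    def test_permuted_covariate_destroys_recovery(self, planted_fit):
        # negative control: a permuted copy of the effect covariate, fitted
        # alongside the true one, must carry no trace of the planted pattern
        table, covs, truth, _, _ = planted_fit
        rng = np.random.default_rng(0)
        augmented = covs.copy()
        augmented["permuted"] = rng.permutation(augmented["effect"].to_numpy())
        design = build_design_matrix(augmented.reset_index(),
                                     ["effect", "permuted", "null"])
        diffs = fit_multinomial_differentials(table, design, seed=17)
        rho = spearmanr(diffs.differentials["permuted"],
                        truth.loc["effect"]).statistic
        assert abs(rho) < 0.2
        # and the planted signal itself is still recovered
        rho_true = spearmanr(diffs.differentials["effect"],
                             truth.loc["effect"]).statistic
        assert rho_true >= 0.8

    def test_bitwise_reproducible_given_seed(self, planted_fit):
        table, _, _, design, diffs = planted_fit
        again = fit_multinomial_differentials(table, design, seed=17)
        np.testing.assert_array_equal(again.differentials.to_numpy(),
                                      diffs.differentials.to_numpy())

    def test_misaligned_samples_rejected(self, planted_fit):
        table, covs, *_ = planted_fit
        md = covs.reset_index().iloc[:50]
        md["sample_id"] = [f"other{i}" for i in range(50)]
        design = build_design_matrix(md, ["effect"])
        with pytest.raises(ValueError, match="sample sets"):
            fit_multinomial_differentials(table, design)


def _table_from(values, covs=("c",)):
    frame = pd.DataFrame({c: values for c in covs},
                         index=[f"a{i}" for i in range(len(values))])
    z = frame.apply(lambda col: (col - col.mean()) / col.std(ddof=0)
                    if col.std(ddof=0) > 0 else col * 0.0)
    return DifferentialTable(frame, z, 0.0, 0, True, 0)


class TestFlagOutliers:
    def test_degenerate_equal_values_no_flags(self):
        flags = flag_outliers(_table_from([1.0] * 10))
        assert not flags["c"].any()

    def test_single_extreme_value_flagged(self):
        values = [0.001 * i for i in range(99)] + [10.0]
        flags = flag_outliers(_table_from(values), "zscore", 3)
        assert flags["c"].sum() == 1
        assert bool(flags["c"].iloc[-1])

    def test_zero_threshold_flags_everything_off_mean(self):
        values = [0.0, 1.0, 2.0, 4.0]
        flags = flag_outliers(_table_from(values), "zscore", 0)
        expected = [v != np.mean(values) for v in values]
        assert flags["c"].tolist() == expected

    def test_iqr_whisker_rule(self):
        values = list(np.linspace(-1, 1, 20)) + [50.0]
        flags = flag_outliers(_table_from(values), "iqr")
        assert flags["c"].sum() == 1

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            flag_outliers(_table_from([1.0, 2.0]), "mad")


class TestOrderSummary:
    def _taxonomy(self):
        tm = TaxonomyMap()
        tm.lineages = {
            "a0": ("B", "P", "C", "Rhizobiales"),
            "a1": ("B", "P", "C", "Rhizobiales"),
            "a2": ("B", "P", "C", "Rhizobiales"),
            "a3": ("B", "P", "C", "Bacillales"),
        }
        return tm

    def test_counts_by_order_and_sign(self):
        diffs = _table_from([2.0, 1.5, -1.0, 3.0])
        flags = pd.DataFrame({"c": [True, True, True, False]}, index=diffs.differentials.index)
        out = summarize_by_order(diffs, flags, self._taxonomy(), "c")
        assert out.loc["Rhizobiales", "positive"] == 2
        assert out.loc["Rhizobiales", "negative"] == 1
        assert out.to_numpy().sum() == int(flags["c"].sum())

    def test_empty_flags_empty_summary(self):
        diffs = _table_from([1.0, 2.0, 3.0, 4.0])
        flags = pd.DataFrame({"c": [False] * 4}, index=diffs.differentials.index)
        out = summarize_by_order(diffs, flags, self._taxonomy(), "c")
        assert out.empty

    def test_unclassified_grouped_under_sentinel(self):
        diffs = _table_from([5.0, 1.0, 1.0, 1.0])
        flags = pd.DataFrame({"c": [True, False, False, False]}, index=diffs.differentials.index)
        out = summarize_by_order(diffs, flags, TaxonomyMap(), "c")
        assert list(out.index) == ["Unassigned"]
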
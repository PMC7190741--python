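import math

import numpy as np
import pandas as pd
import pytest

import matnet as mn
from matnet.growthstats import (
    FOLD_PRESETS,
    MetaboliteProfile,
    accumulation_pvalues,
    accumulation_report,
    assay_report,
    cluster_linkages,
    cluster_order,
    fold_changes,
    growth_test,
)

from .oracles import ward_merge_heights


class TestGrowthTest:
    def test_identical_groups_give_p_one(self):
        res = growth_test([0.5, 0.5, 0.5], [0.5, 0.5, 0.5])
        assert res.pvalue == 1.0
        assert res.stars == ""

    def test_matches_welch_closed_form(self):
        treat = np.array([0.10, 0.11, 0.12])
        ctrl = np.array([0.30, 0.31, 0.32])
        res = growth_test(treat, ctrl)
        se = math.sqrt(treat.var(ddof=1) / 3 + ctrl.var(ddof=1) / 3)
        expected_t = (treat.mean() - ctrl.mean()) / se
        assert res.statistic == pytest.approx(expected_t, rel=1e-12)
        assert res.stars == "***"

    def test_sign_flips_but_p_is_symmetric(self):
        rng = np.random.default_rng(0)
        a, b = rng.random(4), rng.random(4) + 0.3
        fwd = growth_test(a, b)
        rev = growth_test(b, a)
        assert fwd.statistic == pytest.approx(-rev.statistic)
        assert fwd.pvalue == pytest.approx(rev.pvalue)

    def test_degenerate_zero_variance_unequal_means(self, caplog):
        res = growth_test([0.5, 0.5], [0.2, 0.2])
        assert res.pvalue == 0.0
        assert math.isinf(res.statistic) and res.statistic > 0

    def test_requires_two_replicates(self):
        with pytest.raises(ValueError, match="2 replicates"):
            growth_test([0.5], [0.4, 0.5])

    def test_null_rejection_rate_is_nominal(self):
        """Type-I error of the Welch test at alpha=0.05 over 1000 null draws."""
        rng = np.random.default_rng(42)
        rejections = 0
        for _ in range(1000):
            a = 0.2 + 0.01 * rng.standard_normal(3)
            b = 0.2 + 0.01 * rng.standard_normal(3)
            rejections += growth_test(a, b).pvalue < 0.05
        assert 0.03 < rejections / 1000 < 0.07

    def test_assay_report_recovers_planted_significance_pattern(self):
        table = mn.generate_assay(mn.AssaySpec(), seed=2)
        report = assay_report(table).set_index("condition")
        # late-harvest supernatants carry real gains, early ones do not
        assert report.loc["supernatant_12h", "stars"] == "***"
        assert report.loc["supernatant_24h", "stars"] == "***"
        assert report.loc["supernatant_8h", "pvalue"] < 0.05
        assert report.loc["supernatant_0h", "pvalue"] > 0.05


def small_profile(matrix, timepoints=(0.0, 12.0), reps=2, noise=None):
    rows = []
    matrix = np.asarray(matrix, dtype=float)
    for c in range(matrix.shape[0]):
        for t, tp in enumerate(timepoints):
            for r in range(reps):
                value = matrix[c, t]
                if noise is not None:
                    value = value + noise[c, t, r]
                rows.append({"compound": f"c{c}", "timepoint_h": tp,
                             "replicate": r + 1, "intensity": value})
    return MetaboliteProfile(pd.DataFrame(rows))


class TestFoldChanges:
    def test_noise_free_doubling_gives_exactly_two(self):
        profile = small_profile([[10.0, 20.0], [3.0, 6.0]])
        folds = fold_changes(profile, 0.0, 12.0)
        assert folds["fold"].tolist() == [2.0, 2.0]

    def test_reference_equal_to_target_gives_unit_folds(self):
        profile = small_profile([[10.0, 20.0]])
        assert fold_changes(profile, 12.0, 12.0)["fold"].tolist() == [1.0]

    def test_zero_reference_flags_undefined(self, caplog):
        profile = small_profile([[0.0, 5.0], [2.0, 4.0]])
        folds = fold_changes(profile, 0.0, 12.0)
        assert not folds.loc["c0", "defined"]
        assert np.isnan(folds.loc["c0", "fold"])
        assert folds.loc["c1", "fold"] == 2.0

    def test_missing_timepoint_rejected(self):
        profile = small_profile([[1.0, 2.0]])
        with pytest.raises(ValueError, match="8.0"):
            fold_changes(profile, 0.0, 8.0)

    def test_folds_invariant_under_global_scaling(self):
        rng = np.random.default_rng(1)
        base = rng.random((4, 2)) + 0.5
        f1 = fold_changes(small_profile(base), 0.0, 12.0)["fold"]
        f2 = fold_changes(small_profile(base * 37.5), 0.0, 12.0)["fold"]
        pd.testing.assert_series_equal(f1, f2)

    def test_planted_extreme_fold_recovered(self):
        """The 78.9-fold planted compound is recovered within 10% over seeds."""
        spec = mn.MetabolomeSpec()
        folds = []
        for seed in range(20):
            profile, _ = mn.generate_metabolome(spec, seed)
            folds.append(fold_changes(profile, 0.0, 24.0).loc["deoxycytidine",
                                                              "fold"])
        assert np.mean(folds) == pytest.approx(78.9, rel=0.10)

    def test_stationary_vs_exponential_preset(self):
        assert FOLD_PRESETS["stationary_vs_exponential"] == (12.0, 24.0)


class TestAccumulation:
    def test_constant_compound_is_never_significant(self):
        profile = small_profile([[5.0, 5.0]])
        assert accumulation_pvalues(profile)["c0"] == 1.0
        assert mn.accumulation_filter(profile) == set()

    def test_matches_scipy_anova_on_varying_compound(self):
        from scipy import stats

        noise = np.array([[[0.1, -0.1], [0.2, -0.3]]])
        profile = small_profile([[5.0, 9.0]], noise=noise)
        p = accumulation_pvalues(profile)["c0"]
        groups = [np.array([5.1, 4.9]), np.array([9.2, 8.7])]
        assert p == pytest.approx(stats.f_oneway(*groups).pvalue)

    def test_null_rejection_rate_is_nominal(self):
        spec = mn.MetabolomeSpec(n_compounds=1000, n_accumulating=0)
        profile, _ = mn.generate_metabolome(spec, 123)
        rate = len(mn.accumulation_filter(profile)) / 1000
        assert 0.03 < rate < 0.07

    def test_report_combines_folds_and_significance(self):
        profile, truth = mn.generate_metabolome(
            mn.MetabolomeSpec(n_compounds=20, n_accumulating=5), seed=4)
        report = accumulation_report(profile, 0.0, 24.0)
        assert {"fold", "pvalue", "significant"} <= set(report.columns)
        strong = truth[truth > 5].index
        assert report.loc[strong, "significant"].all()

    def test_alpha_validation(self):
        profile = small_profile([[1.0, 2.0]])
        with pytest.raises(ValueError, match="alpha"):
            mn.accumulation_filter(profile, alpha=1.5)


class TestClusterOrder:
    def test_identical_rows_merge_first(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0],
                          [1.0, 2.0, 3.0],
                          [9.0, 1.0, 4.0]],
                         index=["a", "b", "c"], columns=[0, 4, 8])
        row_z, _, _, _ = cluster_linkages(m)
        assert row_z[0, 2] == pytest.approx(0.0)  # first merge at distance 0
        rows, _ = cluster_order(m)
        assert abs(rows.index("a") - rows.index("b")) == 1  # adjacent leaves

    def test_forced_topology_joins_close_pair_before_outlier(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0, 4.0],
                          [1.1, 2.1, 3.1, 4.1],
                          [4.0, 1.0, 0.5, 9.0]],
                         index=["a", "b", "c"], columns=[0, 4, 8, 12])
        rows, _ = cluster_order(m)
        assert rows.index("c") in (0, 2)  # outlier is a leaf on its own side

    def test_merge_heights_match_lance_williams_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(10):
            m = pd.DataFrame(rng.random((6, 4)))
            row_z, _, scaled, constant = cluster_linkages(m)
            expected = ward_merge_heights(scaled[~constant])
            np.testing.assert_allclose(np.sort(row_z[:, 2]), np.sort(expected),
                                       atol=1e-9)

    def test_constant_row_scaled_to_zero_and_ordered_last(self, caplog):
        m = pd.DataFrame([[1.0, 2.0, 3.0],
                          [3.0, 1.0, 2.0],
                          [5.0, 5.0, 5.0]],
                         index=["a", "b", "flat"], columns=[0, 4, 8])
        with caplog.at_level("WARNING"):
            rows, cols = cluster_order(m)
        assert rows[-1] == "flat"
        assert sorted(cols) == [0, 4, 8]

    def test_deterministic_leaf_order(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(rng.random((8, 5)))
        assert cluster_order(m) == cluster_order(m.copy())

    def test_single_row_rejected(self):
        with pytest.raises(ValueError, match="2 rows"):
            cluster_order(pd.DataFrame([[1.0, 2.0]]))
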
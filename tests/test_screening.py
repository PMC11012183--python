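"""Triple-test screening: balanced subsets, test calibration, recovery."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from ruleout import (
    CohortSpec,
    FeatureCounts,
    ScreenConfig,
    build_balanced_subset,
    generate_cohort,
    screen_auc,
    screen_mi,
    screen_t,
    select_features,
)
from ruleout._rng import child_rng

LABELS_208 = np.array([1] * 208 + [0] * 208)
FAST = ScreenConfig(n_bootstrap=300, n_permutation=100, seed=0)


class TestBalancedSubset:
    def test_four_cells_of_per_cell_each(self, default_cohort):
        subset = build_balanced_subset(default_cohort, per_cell=104, seed=1)
        assert len(subset) == 416
        sex = default_cohort.sex.loc[subset]
        label = default_cohort.label.loc[subset]
        for lab in (0, 1):
            for sx in (0, 1):
                assert ((label == lab) & (sex == sx)).sum() == 104
        assert not subset.has_duplicates

    def test_exhaustive_cell_fully_included(self, small_cohort):
        cells = small_cohort.sex.groupby([small_cohort.label, small_cohort.sex]).count()
        smallest = int(cells.min())
        subset = build_balanced_subset(small_cohort, per_cell=smallest, seed=2)
        lab, sx = cells.idxmin()
        cell_ids = small_cohort.features.index[
            (small_cohort.label == lab) & (small_cohort.sex == sx)
        ]
        assert set(cell_ids) <= set(subset)

    def test_deficient_cell_named(self, small_cohort):
        cells = small_cohort.sex.groupby([small_cohort.label, small_cohort.sex]).count()
        smallest = int(cells.min())
        with pytest.raises(ValueError, match="CAD"):
            build_balanced_subset(small_cohort, per_cell=smallest + 1, seed=2)

    def test_deterministic_given_seed(self, default_cohort):
        a = build_balanced_subset(default_cohort, 50, seed=5)
        b = build_balanced_subset(default_cohort, 50, seed=5)
        c = build_balanced_subset(default_cohort, 50, seed=6)
        assert list(a) == list(b)
        assert list(a) != list(c)

    def test_screen_only_subjects_eligible_modelling_excluded(self):
        spec = CohortSpec(n_pos=300, n_neg=120, n_screen_only_neg=120, seed=4)
        c = generate_cohort(spec)
        subset = build_balanced_subset(c, per_cell=30, seed=4)
        neg_in_subset = c.role.loc[subset][c.label.loc[subset] == 0]
        assert (neg_in_subset == "feature_selection_only").all()


class TestTTest:
    def test_type_one_error_calibrated(self):
        # Under the null the pass rate at p < 0.01 is about 1%.
        rng = np.random.default_rng(0)
        passes = sum(
            screen_t(rng.standard_normal(416), LABELS_208, 0.01).passed for _ in range(2000)
        )
        rate = passes / 2000
        assert 0.004 < rate < 0.018

    def test_power_at_medium_effect(self):
        # Noncentral-t oracle: power at d=0.5, n=208/208, alpha=0.01.
        d, n = 0.5, 208
        ncp = d * np.sqrt(n / 2)
        df = 2 * n - 2
        crit = stats.t.ppf(1 - 0.005, df)
        power = 1 - stats.nct.cdf(crit, df, ncp) + stats.nct.cdf(-crit, df, ncp)
        assert power > 0.99
        rng = np.random.default_rng(1)
        hits = sum(
            screen_t(
                np.concatenate([rng.standard_normal(n) + d, rng.standard_normal(n)]),
                LABELS_208,
                0.01,
            ).passed
            for _ in range(100)
        )
        assert hits >= 97

    def test_degenerate_constant_vectors(self):
        res = screen_t(np.ones(416), LABELS_208, 0.01)
        assert res.p_value == 1.0 and not res.passed


class TestAucScreen:
    def test_perfect_separation(self):
        values = np.concatenate([np.ones(208), np.zeros(208)])
        res = screen_auc(values, LABELS_208, FAST)
        assert res.auc_point == 1.0 and res.lower_ci == 1.0 and res.passed

    def test_null_pass_rate_small(self):
        rng = np.random.default_rng(2)
        cfg = dataclasses.replace(FAST, n_bootstrap=500)
        passes = sum(
            screen_auc(
                rng.standard_normal(416), LABELS_208, cfg, rng=child_rng(2, "auc", i)
            ).passed
            for i in range(200)
        )
        assert passes / 200 < 0.05

    def test_inverse_branch(self):
        # Population AUC 0.25 <=> Gaussian shift Phi^{-1}(0.25)*sqrt(2).
        rng = np.random.default_rng(3)
        shift = stats.norm.ppf(0.25) * np.sqrt(2)
        values = np.concatenate([rng.standard_normal(208) + shift, rng.standard_normal(208)])
        res = screen_auc(values, LABELS_208, FAST)
        assert res.auc_point < 0.35
        assert res.upper_ci < 0.48 and res.passed

    def test_bootstrap_requires_min_resamples(self):
        with pytest.raises(ValueError, match="n_bootstrap"):
            screen_auc(np.arange(416.0), LABELS_208, dataclasses.replace(FAST, n_bootstrap=50))


class TestMiScreen:
    def test_independence_ratio_near_one(self):
        rng = np.random.default_rng(4)
        ratios = [
            screen_mi(rng.standard_normal(416), LABELS_208, FAST, rng=child_rng(4, "mi", i)).mi_ratio
            for i in range(50)
        ]
        assert abs(np.mean(ratios) - 1.0) < 0.25
        passes = [
            screen_mi(rng.standard_normal(416), LABELS_208, FAST, rng=child_rng(5, "mi", i)).passed
            for i in range(100)
        ]
        assert np.mean(passes) < 0.10

    def test_deterministic_relationship_passes(self):
        values = LABELS_208.astype(float)
        res = screen_mi(values, LABELS_208, FAST)
        assert res.mi_ratio > 1.2 and res.passed

    def test_variance_ratio_signal_caught_by_mi_not_t(self):
        # Equal-mean, variance-ratio-4 features: invisible to the t-test,
        # detected by MI with high probability.
        rng = np.random.default_rng(6)
        mi_hits = t_hits = 0
        n_rep = 40
        for i in range(n_rep):
            values = np.concatenate([2.0 * rng.standard_normal(208), rng.standard_normal(208)])
            mi_hits += screen_mi(values, LABELS_208, FAST, rng=child_rng(6, "mi", i)).passed
            t_hits += screen_t(values, LABELS_208, 0.01).passed
        assert mi_hits / n_rep > 0.9
        assert t_hits / n_rep < 0.15

    def test_constant_values_fail(self):
        res = screen_mi(np.full(416, 3.0), LABELS_208, FAST)
        assert res.mi_ratio == 0.0 and not res.passed


class TestSelectFeatures:
    @pytest.fixture(scope="class")
    def planted_cohort(self):
        # 20 linear (d=0.8), 20 nonlinear, 10 inverse, 150 null features.
        spec = CohortSpec(
            features_per_category={
                "conduction": FeatureCounts(20, 20, 10, 0),
                "perfusion": FeatureCounts(0, 0, 0, 150),
            },
            linear_effect=0.8,
            nonlinear_effect=4.0,
            seed=13,
        )
        return generate_cohort(spec)

    @pytest.fixture(scope="class")
    def planted_result(self, planted_cohort):
        cfg = ScreenConfig(n_bootstrap=500, n_permutation=100, seed=13)
        subset = build_balanced_subset(planted_cohort, cfg.per_cell, seed=13)
        return select_features(planted_cohort, subset, cfg)

    def test_recall_and_false_selection(self, planted_cohort, planted_result):
        roles = planted_cohort.feature_meta["role"]
        selected = set(planted_result.selected)
        non_null = set(roles.index[roles != "null"])
        null = set(roles.index[roles == "null"])
        recall = len(selected & non_null) / len(non_null)
        false_rate = len(selected & null) / len(null)
        assert recall > 0.80
        assert false_rate < 0.10

    def test_combo_counts_partition_selection(self, planted_result):
        assert sum(planted_result.combo_counts.values()) == len(planted_result.selected)
        flags = planted_result.table[["pass_t", "pass_auc", "pass_mi"]]
        assert set(planted_result.selected) == set(flags.index[flags.any(axis=1)])

    def test_statistics_use_subset_only(self, planted_cohort):
        # Perturbing subjects outside the balanced subset changes nothing.
        cfg = ScreenConfig(n_bootstrap=300, n_permutation=100, seed=17)
        subset = build_balanced_subset(planted_cohort, 104, seed=17)
        sub_cohort = planted_cohort
        res_a = select_features(sub_cohort, subset, cfg)
        outside = sub_cohort.features.index.difference(subset)
        perturbed = sub_cohort.subset(sub_cohort.features.index)
        perturbed.features.loc[outside] += 100.0
        res_b = select_features(perturbed, subset, cfg)
        assert res_a.table.equals(res_b.table)

    def test_monotone_in_thresholds(self, planted_result):
        # Loosening p and AUC thresholds never shrinks the selected set.
        table = planted_result.table
        strict = set(planted_result.selected)
        loose_pass = (
            (table["t_p_value"] < 0.05)
            | (table["auc_lower_ci"] > 0.51)
            | (table["auc_upper_ci"] < 0.49)
            | table["pass_mi"]
        )
        loose = set(table.index[loose_pass])
        assert strict <= loose

    def test_all_null_selection_is_small(self):
        spec = CohortSpec(
            n_pos=300,
            n_neg=300,
            features_per_category={"perfusion": FeatureCounts(0, 0, 0, 60)},
            seed=19,
        )
        c = generate_cohort(spec)
        cfg = ScreenConfig(n_bootstrap=300, n_permutation=100, per_cell=70, seed=19)
        subset = build_balanced_subset(c, 70, seed=19)
        res = select_features(c, subset, cfg)
        assert len(res.selected) <= 6  # ~ combined test sizes on 60 nulls

    def test_dominant_feature_selected_by_all_tests(self):
        spec = CohortSpec(
            n_pos=150,
            n_neg=150,
            features_per_category={"conduction": FeatureCounts(1, 0, 0, 10)},
            linear_effect=6.0,
            seed=23,
        )
        c = generate_cohort(spec)
        cfg = ScreenConfig(n_bootstrap=300, n_permutation=100, per_cell=30, seed=23)
        res = select_features(c, build_balanced_subset(c, 30, seed=23), cfg)
        roles = c.feature_meta["role"]
        strong = roles.index[roles == "linear"][0]
        row = res.table.loc[strong]
        assert row[["pass_t", "pass_auc", "pass_mi"]].all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ScreenConfig(auc_lower_bound=0.49)
        with pytest.raises(ValueError):
            ScreenConfig(mi_ratio_bound=0.9)
        with pytest.raises(ValueError):
            ScreenConfig(per_cell=1)
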
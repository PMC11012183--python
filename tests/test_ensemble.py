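"""OOF engine: weights, folds, stacking contract, leakage, determinism."""

import numpy as np
import pandas as pd
import pytest

from ruleout import (
    ModelBank,
    TrainConfig,
    compute_sample_weights,
    predict_bank,
    roc_auc,
    run_oof,
    stratified_folds,
    train_stack,
)
from conftest import make_manual_cohort

FAST_TRAIN = TrainConfig(n_iterations=2, rf_n_trees=30, en_penalty_strength=0.01, seed=0)


class TestSampleWeights:
    def test_study_cell_counts(self):
        # Cells (F-:331, M-:182, F+:171, M+:470), N=1154 -> N/(4 n_c).
        label = np.array([0] * 331 + [0] * 182 + [1] * 171 + [1] * 470)
        sex = np.array([1] * 331 + [0] * 182 + [1] * 171 + [0] * 470)
        w = compute_sample_weights(label, sex)
        assert w[0] == pytest.approx(0.8716, abs=1e-4)  # female CAD-
        assert w[331] == pytest.approx(1.5852, abs=1e-4)  # male CAD-
        assert w[513] == pytest.approx(1.6871, abs=1e-4)  # female CAD+
        assert w[684] == pytest.approx(0.6138, abs=1e-4)  # male CAD+
        for lab in (0, 1):
            for sx in (0, 1):
                mass = w[(label == lab) & (sex == sx)].sum()
                assert mass == pytest.approx(1154 / 4, abs=1e-9)

    def test_balanced_cells_give_unit_weights(self):
        label = np.array([0, 0, 1, 1] * 10)
        sex = np.array([0, 1, 0, 1] * 10)
        assert np.allclose(compute_sample_weights(label, sex), 1.0)

    def test_empty_cell_named(self):
        label = np.array([0, 0, 1, 1])
        sex = np.array([0, 1, 0, 0])
        with pytest.raises(ValueError, match="female CAD\\+"):
            compute_sample_weights(label, sex)


class TestStratifiedFolds:
    def test_study_sized_counts(self):
        label = np.array([1] * 641 + [0] * 513)
        folds = stratified_folds(label, 5, seed=1)
        for f in range(5):
            mask = folds == f
            assert mask.sum() in (230, 231)
            assert label[mask].sum() in (128, 129)

    def test_exact_divisibility(self):
        label = np.array([1, 0] * 5)
        folds = stratified_folds(label, 5, seed=2)
        for f in range(5):
            assert label[folds == f].sum() == 1
            assert (folds == f).sum() == 2

    def test_partition_property(self):
        label = np.array([1] * 37 + [0] * 53)
        folds = stratified_folds(label, 4, seed=3)
        assert folds.min() == 0 and folds.max() == 3
        assert len(folds) == 90

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="fewer than k"):
            stratified_folds(np.array([1] * 3 + [0] * 50), 5)


class TestTrainStack:
    def test_stack_is_mean_of_base_predictions(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((60, 4))
        y = (X[:, 0] > 0).astype(int)
        model = train_stack(X, y, config=FAST_TRAIN)
        en_p, rf_p = model.predict_parts(X)
        np.testing.assert_allclose(model.predict(X), (en_p + rf_p) / 2)

    def test_constant_labels_predict_constant(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((40, 3))
        model = train_stack(X, np.zeros(40), config=FAST_TRAIN)
        assert np.allclose(model.predict(X), 0.0, atol=1e-6)

    def test_strong_signal_generalizes(self):
        # Single linear feature at d=2.0: held-out AUC above 0.9.
        rng = np.random.default_rng(2)

        def draw(n):
            y = np.repeat([1, 0], n // 2)
            X = rng.standard_normal((n, 1)) + 2.0 * y[:, None]
            return X, y

        X, y = draw(300)
        Xt, yt = draw(300)
        model = train_stack(X, y, config=FAST_TRAIN)
        assert roc_auc(model.predict(Xt), yt) > 0.9

    def test_nonfinite_features_rejected(self):
        X = np.ones((10, 2))
        X[0, 0] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            train_stack(X, np.repeat([0, 1], 5), config=FAST_TRAIN)


class TestRunOof:
    def test_model_count_and_provenance(self, small_cohort):
        fids = list(small_cohort.features.columns[:6])
        bank, oof = run_oof(small_cohort, fids, FAST_TRAIN)
        assert len(bank) == FAST_TRAIN.k_folds * FAST_TRAIN.n_iterations
        for m in bank.models:
            assert 0 <= m.fold < FAST_TRAIN.k_folds
            assert 0 <= m.iteration < FAST_TRAIN.n_iterations

    def test_single_iteration_naive_prediction(self, small_cohort):
        cfg = TrainConfig(n_iterations=1, rf_n_trees=20, en_penalty_strength=0.01, seed=1)
        _, oof = run_oof(small_cohort, list(small_cohort.features.columns[:4]), cfg)
        assert oof.per_iteration.shape[1] == 1
        assert oof.oof_score.equals(oof.per_iteration.iloc[:, 0].rename("oof_score"))

    def test_determinism(self, small_cohort):
        fids = list(small_cohort.features.columns[:5])
        _, a = run_oof(small_cohort, fids, FAST_TRAIN)
        _, b = run_oof(small_cohort, fids, FAST_TRAIN)
        pd.testing.assert_series_equal(a.oof_score, b.oof_score)

    def test_no_leakage_null_auc(self):
        # Label-independent features: OOF AUC statistically indistinguishable
        # from 0.5 across replicates.
        aucs = []
        for seed in range(8):
            rng = np.random.default_rng(100 + seed)
            c = make_manual_cohort(240, rng, label=np.repeat([1, 0], 120), n_features=8)
            cfg = TrainConfig(n_iterations=2, rf_n_trees=25, en_penalty_strength=0.05, seed=seed)
            _, oof = run_oof(c, list(c.features.columns), cfg)
            aucs.append(roc_auc(oof.oof_score.to_numpy(), c.label.to_numpy()))
        mean = np.mean(aucs)
        half_width = 1.96 * np.std(aucs, ddof=1) / np.sqrt(len(aucs))
        assert mean - half_width <= 0.5 <= mean + half_width

    def test_naivety_fold_model_unchanged_without_outside_subject(self):
        # 3-fold toy with fixed folds: removing a subject leaves every model
        # whose training never saw it bit-identical in its predictions.
        rng = np.random.default_rng(7)
        n = 60
        c = make_manual_cohort(n, rng, label=np.repeat([1, 0], n // 2), n_features=3)
        folds = np.tile([0, 1, 2], n // 3)
        cfg = TrainConfig(k_folds=3, n_iterations=1, rf_n_trees=20, en_penalty_strength=0.05, seed=3)
        bank_full, _ = run_oof(c, list(c.features.columns), cfg, folds_per_iteration=[folds])

        drop_pos = 0  # subject in fold 0
        keep = np.ones(n, bool)
        keep[drop_pos] = False
        c_red = c.subset(c.features.index[keep])
        bank_red, _ = run_oof(
            c_red, list(c.features.columns), cfg, folds_per_iteration=[folds[keep]]
        )
        probe = rng.standard_normal((20, 3))
        # fold-0 models trained without the dropped subject in both runs
        m_full = [m for m in bank_full.models if m.fold == 0][0]
        m_red = [m for m in bank_red.models if m.fold == 0][0]
        np.testing.assert_allclose(m_full.predict(probe), m_red.predict(probe))

    def test_weighting_reduces_sex_score_gap(self):
        # Sex-imbalanced cohort with sex-correlated (label-null) features:
        # weighting shrinks the sex difference in mean control scores.
        rng = np.random.default_rng(11)
        n = 600
        label = np.repeat([1, 0], n // 2)
        sex = np.where(
            label == 1, rng.random(n) < 0.267, rng.random(n) < 0.645
        ).astype(int)
        X = rng.standard_normal((n, 6)) + 1.5 * sex[:, None]
        c = make_manual_cohort(n, rng, sex=sex, label=label, feature_values=X)
        gaps = {}
        for weighted in (True, False):
            cfg = TrainConfig(
                n_iterations=2, rf_n_trees=40, en_penalty_strength=0.01,
                use_sample_weights=weighted, seed=5,
            )
            _, oof = run_oof(c, list(c.features.columns), cfg)
            s = oof.oof_score.to_numpy()
            neg = label == 0
            gaps[weighted] = abs(s[neg & (sex == 1)].mean() - s[neg & (sex == 0)].mean())
        assert gaps[True] < gaps[False]

    def test_empty_selection_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="non-empty"):
            run_oof(small_cohort, [], FAST_TRAIN)


class TestPredictBank:
    def test_median_and_mean_compression(self, small_cohort):
        fids = list(small_cohort.features.columns[:4])
        bank, _ = run_oof(small_cohort, fids, FAST_TRAIN)
        X = small_cohort.features[fids].iloc[:10]
        per_model = np.stack([m.predict(X) for m in bank.models])
        np.testing.assert_allclose(predict_bank(bank, X), np.median(per_model, axis=0))
        np.testing.assert_allclose(
            predict_bank(bank, X, compression="mean"), per_model.mean(axis=0)
        )

    def test_three_model_toy_median(self, small_cohort):
        fids = list(small_cohort.features.columns[:4])
        bank, _ = run_oof(
            small_cohort, fids,
            TrainConfig(k_folds=3, n_iterations=1, rf_n_trees=5, en_penalty_strength=0.1, seed=9),
        )
        assert len(bank) == 3
        X = small_cohort.features[fids].iloc[:5]
        per_model = np.stack([m.predict(X) for m in bank.models])
        np.testing.assert_allclose(predict_bank(bank, X), np.median(per_model, axis=0))

    def test_new_subject_auc_close_to_oof(self):
        # Fresh subjects from the same strong-signal population score close
        # to the OOF estimate.
        from ruleout import CohortSpec, FeatureCounts, generate_cohort

        spec = CohortSpec(
            n_pos=200, n_neg=200, linear_effect=1.5,
            features_per_category={"conduction": FeatureCounts(3, 0, 0, 3)},
            seed=31,
        )
        c = generate_cohort(spec)
        cfg = TrainConfig(n_iterations=3, rf_n_trees=50, en_penalty_strength=0.01, seed=31)
        bank, oof = run_oof(c, list(c.features.columns), cfg)
        oof_auc = roc_auc(oof.oof_score.to_numpy(), c.label.to_numpy())
        c_new = generate_cohort(spec.with_(seed=32))
        new_auc = roc_auc(predict_bank(bank, c_new.features), c_new.label.to_numpy())
        assert abs(new_auc - oof_auc) < 0.05

    def test_feature_mismatch_listed(self, small_cohort):
        fids = list(small_cohort.features.columns[:4])
        bank, _ = run_oof(small_cohort, fids, FAST_TRAIN)
        wrong = small_cohort.features[list(small_cohort.features.columns[2:8])]
        with pytest.raises(ValueError, match="feature mismatch"):
            predict_bank(bank, wrong)

    def test_bank_round_trip(self, small_cohort, tmp_path):
        fids = list(small_cohort.features.columns[:4])
        bank, _ = run_oof(small_cohort, fids, FAST_TRAIN)
        bank.save(tmp_path / "bank")
        loaded = ModelBank.load(tmp_path / "bank")
        assert len(loaded) == len(bank)
        X = small_cohort.features[fids].iloc[:8]
        np.testing.assert_allclose(predict_bank(loaded, X), predict_bank(bank, X))

    def test_role_separation_excludes_screen_only_subjects(self):
        from ruleout import CohortSpec, generate_cohort

        spec = CohortSpec(n_pos=150, n_neg=100, n_screen_only_neg=60, seed=41)
        c = generate_cohort(spec)
        bank, oof = run_oof(c, list(c.features.columns[:5]), FAST_TRAIN)
        screen_only = set(c.features.index[c.role == "feature_selection_only"])
        assert not screen_only & set(oof.oof_score.index)
        for m in bank.models:
            assert not screen_only & set(m.train_subjects)
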
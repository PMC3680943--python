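import numpy as np
import pandas as pd
import pytest

from vasculotype import (
    ExpressionMatrix,
    SynthConfig,
    ValidationError,
    generate_cohort,
    lda_predict,
    lda_train,
    loocv_run,
    permute_outcome,
    size_scan,
    subtype_adjust,
    wilcoxon_select,
)

from conftest import make_matrix


def _subtype_series(matrix, labels):
    return pd.Series(labels, index=list(matrix.sample_ids))


class TestSubtypeAdjust:
    def test_forced_arithmetic(self):
        m = make_matrix([[1, 1, 3, 5]])
        subs = _subtype_series(m, ["A", "A", "B", "B"])
        adjusted, delta = subtype_adjust(m, subs, list(m.sample_ids))
        assert delta[0] == pytest.approx(3.0)
        np.testing.assert_allclose(adjusted.values[0], [1, 1, 0, 2])

    def test_equal_means_unchanged(self):
        m = make_matrix([[2, 2, 2, 2]])
        subs = _subtype_series(m, ["A", "A", "B", "B"])
        adjusted, delta = subtype_adjust(m, subs, list(m.sample_ids))
        assert delta[0] == 0
        np.testing.assert_array_equal(adjusted.values, m.values)

    def test_training_means_equal_after_adjustment(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.normal(size=(100, 10)))
        subs = _subtype_series(m, ["A"] * 5 + ["B"] * 5)
        train = list(m.sample_ids)[:8]
        adjusted, _ = subtype_adjust(m, subs, train)
        a_cols = [i for i, s in enumerate(m.sample_ids) if s in train and subs[s] == "A"]
        b_cols = [i for i, s in enumerate(m.sample_ids) if s in train and subs[s] == "B"]
        np.testing.assert_allclose(
            adjusted.values[:, a_cols].mean(axis=1),
            adjusted.values[:, b_cols].mean(axis=1),
            atol=1e-12,
        )

    def test_heldout_b_sample_shifted_too(self):
        m = make_matrix([[0, 0, 4, 4, 4]])
        subs = _subtype_series(m, ["A", "A", "B", "B", "B"])
        train = list(m.sample_ids)[:4]
        adjusted, delta = subtype_adjust(m, subs, train)
        assert delta[0] == pytest.approx(4.0)
        assert adjusted.values[0, 4] == pytest.approx(0.0)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        m = make_matrix(rng.normal(size=(20, 8)))
        subs = _subtype_series(m, ["A"] * 4 + ["B"] * 4)
        once, _ = subtype_adjust(m, subs, list(m.sample_ids))
        twice, delta2 = subtype_adjust(once, subs, list(m.sample_ids))
        np.testing.assert_allclose(delta2, 0, atol=1e-12)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_missing_subtype_in_training_errors(self):
        m = make_matrix([[1, 2, 3]])
        subs = _subtype_series(m, ["A", "A", "B"])
        with pytest.raises(ValidationError, match="subtype B"):
            subtype_adjust(m, subs, list(m.sample_ids)[:2])


class TestWilcoxonSelect:
    def test_planted_genes_found(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=(103, 14))
        values[:3, 7:] += 5.0  # 3 strong outcome genes among 100 nulls
        m = make_matrix(values)
        outcome = pd.Series(["no"] * 7 + ["yes"] * 7, index=list(m.sample_ids))
        assert set(wilcoxon_select(m, outcome, 3)) == {"g0", "g1", "g2"}

    def test_k_equals_gene_count_returns_all(self):
        rng = np.random.default_rng(3)
        m = make_matrix(rng.normal(size=(10, 8)))
        outcome = pd.Series(["no"] * 4 + ["yes"] * 4, index=list(m.sample_ids))
        out = wilcoxon_select(m, outcome, 10)
        assert sorted(out) == sorted(m.gene_ids)

    def test_deterministic_under_ties(self):
        rng = np.random.default_rng(4)
        m = make_matrix(rng.normal(size=(50, 10)))
        outcome = pd.Series(["no"] * 5 + ["yes"] * 5, index=list(m.sample_ids))
        assert wilcoxon_select(m, outcome, 8) == wilcoxon_select(m, outcome, 8)

    def test_k_too_large_errors(self):
        m = make_matrix([[1, 2, 3, 4]])
        outcome = pd.Series(["no", "no", "yes", "yes"], index=list(m.sample_ids))
        with pytest.raises(ValidationError):
            wilcoxon_select(m, outcome, 2)

    def test_single_class_errors(self):
        m = make_matrix([[1, 2, 3, 4]])
        outcome = pd.Series(["no"] * 4, index=list(m.sample_ids))
        with pytest.raises(ValidationError, match="2 outcome classes"):
            wilcoxon_select(m, outcome, 1)


class TestLDA:
    def test_symmetric_1d_boundary(self):
        x = np.array([[-1.5], [-1.0], [-0.5], [0.5], [1.0], [1.5]])
        y = ["no", "no", "no", "yes", "yes", "yes"]
        model = lda_train(x, y, positive_class="yes")
        label, score = lda_predict(model, [0.1])
        assert label == "yes"
        assert score > 0.5
        label2, score2 = lda_predict(model, [-0.1])
        assert label2 == "no"
        assert score2 < 0.5

    def test_duplicated_feature_column_same_predictions(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(12, 1)) + np.repeat([[0], [2]], 6, axis=0)
        y = ["no"] * 6 + ["yes"] * 6
        m1 = lda_train(x, y, positive_class="yes")
        m2 = lda_train(np.hstack([x, x]), y, positive_class="yes")
        assert m2.ridge_eps > 0  # singular without the ridge
        for point in (-0.5, 0.7, 1.3, 2.5):
            l1, s1 = lda_predict(m1, [point])
            l2, s2 = lda_predict(m2, [point, point])
            assert l1 == l2
            assert s1 == pytest.approx(s2, abs=1e-4)

    def test_discriminant_direction_closed_form(self):
        rng = np.random.default_rng(6)
        x0 = rng.normal(size=(4, 2))
        x1 = rng.normal(size=(4, 2)) + [2.0, -1.0]
        x = np.vstack([x0, x1])
        y = ["no"] * 4 + ["yes"] * 4
        model = lda_train(x, y, positive_class="yes")
        # independent pooled-covariance computation by explicit loops
        mu0, mu1 = x0.mean(axis=0), x1.mean(axis=0)
        pooled = np.zeros((2, 2))
        for xc, mu in ((x0, mu0), (x1, mu1)):
            for row in xc:
                dev = (row - mu)[:, None]
                pooled += dev @ dev.T
        pooled /= len(y) - 2
        direction = np.linalg.solve(pooled, mu1 - mu0)
        model_dir = model._cov_inv @ (model.means[1] - model.means[0])
        np.testing.assert_allclose(model_dir, direction, atol=1e-8)

    def test_small_class_errors(self):
        with pytest.raises(ValidationError, match="< 2"):
            lda_train(np.zeros((3, 1)), ["a", "b", "b"])

    def test_zero_features_errors(self):
        with pytest.raises(ValidationError):
            lda_train(np.zeros((4, 0)), ["a", "a", "b", "b"])


class TestLOOCV:
    @pytest.fixture(scope="class")
    def masked_cohort(self):
        m, s, t = generate_cohort(SynthConfig(seed=1))
        tumor = s[s["tissue"] == "tumor_vasculature"].set_index("sample_id")
        return m.subset_samples(list(tumor.index)), tumor

    def test_unmasked_strong_signal_perfect(self):
        m, s, _ = generate_cohort(
            SynthConfig(seed=2, effect_subtype=0.0, effect_recur=3.0, n_de_recur=40)
        )
        tumor = s[s["tissue"] == "tumor_vasculature"].set_index("sample_id")
        tm = m.subset_samples(list(tumor.index))
        report = loocv_run(tm, tumor["subtype"], tumor["recurrence"], k=6, adjust=False)
        assert report.accuracy == pytest.approx(1.0)

    def test_masking_regime_single_seed(self, masked_cohort):
        tm, tumor = masked_cohort
        adjusted = loocv_run(tm, tumor["subtype"], tumor["recurrence"], k=6)
        unadjusted = loocv_run(
            tm, tumor["subtype"], tumor["recurrence"], k=6, adjust=False
        )
        assert adjusted.accuracy >= 15 / 17
        assert adjusted.accuracy > unadjusted.accuracy

    def test_one_fold_per_sample_and_confusion_sums(self, masked_cohort):
        tm, tumor = masked_cohort
        report = loocv_run(tm, tumor["subtype"], tumor["recurrence"], k=6)
        assert sorted(report.folds["sample_id"]) == sorted(tm.sample_ids)
        assert report.confusion.to_numpy().sum() == tm.n_samples
        correct = np.trace(report.confusion.to_numpy())
        assert report.accuracy == pytest.approx(correct / tm.n_samples)

    def test_scores_in_unit_interval(self, masked_cohort):
        tm, tumor = masked_cohort
        report = loocv_run(tm, tumor["subtype"], tumor["recurrence"], k=6)
        assert report.folds["score"].between(0, 1).all()

    def test_strict_subtype_mode_runs(self, masked_cohort):
        tm, tumor = masked_cohort
        report = loocv_run(
            tm, tumor["subtype"], tumor["recurrence"], k=6, strict_subtype=True
        )
        assert report.accuracy >= 13 / 17  # planted structure is strong

    def test_adjustment_direction_irrelevant(self, masked_cohort):
        # shifting A toward B instead of B toward A leaves predictions intact
        tm, tumor = masked_cohort
        flipped = tumor["subtype"].map({"A": "B", "B": "A"})
        a = loocv_run(tm, tumor["subtype"], tumor["recurrence"], k=6)
        b = loocv_run(tm, flipped, tumor["recurrence"], k=6)
        assert a.folds["predicted"].tolist() == b.folds["predicted"].tolist()

    def test_permuted_labels_near_chance(self, masked_cohort):
        tm, tumor = masked_cohort
        accs = []
        for i in range(20):
            perm = np.random.default_rng(i).permutation(
                tumor["recurrence"].to_numpy()
            )
            outcome = pd.Series(perm, index=tumor.index)
            accs.append(
                loocv_run(tm, tumor["subtype"], outcome, k=6).accuracy
            )
        maj = 12 / 17
        se_binomial = np.sqrt(maj * (1 - maj) / 17)
        assert abs(np.mean(accs) - maj) < 2 * se_binomial

    def test_leaky_variant_inflates(self, masked_cohort):
        tm, tumor = masked_cohort
        nested, leaky = [], []
        for i in range(15):
            perm = np.random.default_rng(100 + i).permutation(
                tumor["recurrence"].to_numpy()
            )
            outcome = pd.Series(perm, index=tumor.index)
            nested.append(loocv_run(tm, tumor["subtype"], outcome, k=6).accuracy)
            leaky.append(
                loocv_run(
                    tm, tumor["subtype"], outcome, k=6, select_outside_cv=True
                ).accuracy
            )
        assert np.mean(leaky) > np.mean(nested) + 0.1

    def test_single_outcome_class_errors(self, masked_cohort):
        tm, tumor = masked_cohort
        outcome = pd.Series("no", index=tumor.index)
        with pytest.raises(ValidationError):
            loocv_run(tm, tumor["subtype"], outcome, k=6)


class TestSizeScan:
    def test_singleton_range_consistent(self):
        m, s, _ = generate_cohort(SynthConfig(seed=3, n_genes=300, n_de_tumor=30,
                                              n_de_subtype=40, n_de_recur=10))
        tumor = s[s["tissue"] == "tumor_vasculature"].set_index("sample_id")
        tm = m.subset_samples(list(tumor.index))
        frame, best_k = size_scan(
            tm, tumor["subtype"], tumor["recurrence"], k_range=[2]
        )
        single = loocv_run(tm, tumor["subtype"], tumor["recurrence"], k=2)
        assert frame.iloc[0]["accuracy"] == pytest.approx(single.accuracy)
        assert best_k == 2

    def test_empty_range_errors(self, tumor_view):
        tm, tumor, _ = tumor_view
        with pytest.raises(ValidationError):
            size_scan(tm, tumor["subtype"], tumor["recurrence"], k_range=[])

    def test_argmax_ties_prefer_smallest_k(self):
        m, s, _ = generate_cohort(SynthConfig(seed=4, n_genes=300, n_de_tumor=30,
                                              n_de_subtype=40, n_de_recur=10,
                                              effect_recur=3.0, effect_subtype=0.5))
        tumor = s[s["tissue"] == "tumor_vasculature"].set_index("sample_id")
        tm = m.subset_samples(list(tumor.index))
        frame, best_k = size_scan(
            tm, tumor["subtype"], tumor["recurrence"], k_range=range(2, 6)
        )
        best = frame["accuracy"].max()
        assert best_k == int(frame.loc[frame["accuracy"] == best, "k"].min())
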
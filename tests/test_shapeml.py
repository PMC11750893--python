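"""Shape-function statistics: scores, correlations, regression, classifiers."""

import numpy as np
import pytest
from scipy import stats

from vcohort import (ClinicalRecord, classify, correlate, deform,
                     f_score_select, mode_scores, read_clinical_csv,
                     svm_regress, write_clinical_csv)
from vcohort.ssm import project


class TestModeScores:
    def test_mean_shape_scores_to_zero(self, wall_model):
        scores = mode_scores(wall_model, wall_model.mean[None, :])
        assert np.abs(scores).max() < 1e-9

    def test_deform_then_score_recovers_weights(self, wall_model):
        w = np.array([1.0, -0.5, 2.0])
        surf = deform(wall_model, w)
        scores = project(wall_model, surf.points.ravel())
        expected = np.zeros(wall_model.n_modes)
        expected[:3] = w * wall_model.sigmas[:3]
        assert np.allclose(scores, expected, atol=1e-8)

    def test_training_score_covariance_is_diagonal_spectrum(self, wall_model,
                                                            aligned_wall):
        scores = mode_scores(wall_model, aligned_wall)
        cov = np.cov(scores, rowvar=False)
        assert np.allclose(np.diag(cov), wall_model.variances, rtol=1e-6)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-6 * wall_model.variances[0]

    def test_dimension_mismatch_raises(self, wall_model):
        with pytest.raises(ValueError):
            mode_scores(wall_model, np.zeros((2, 7)))


def _records(values, variable="peak_gradient"):
    return [ClinicalRecord(patient_id=f"p{i}", **{variable: float(v)})
            for i, v in enumerate(values)]


class TestCorrelate:
    def test_variable_equal_to_scores_gives_unit_correlation(self, rng):
        scores = rng.normal(size=(20, 4))
        recs = _records(scores[:, 2] * 10 + 50)
        out = correlate(scores, recs, "peak_gradient")
        assert out[0].mode == 3
        assert out[0].r == pytest.approx(1.0, abs=1e-9)
        assert out[0].p < 1e-12

    def test_negated_scores_give_minus_one(self, rng):
        scores = rng.normal(size=(15, 3))
        recs = _records(60 - scores[:, 0])
        out = correlate(scores, recs, "peak_gradient")
        assert out[0].mode == 1
        assert out[0].r == pytest.approx(-1.0, abs=1e-9)

    def test_matches_textbook_formula_on_hand_data(self):
        scores = np.array([[1.0], [2.0], [4.0], [5.0], [7.0], [9.0]])
        y = np.array([2.0, 1.0, 5.0, 4.0, 9.0, 8.0])
        out = correlate(scores, _records(y), "peak_gradient")
        x = scores[:, 0]
        r_hand = (np.sum((x - x.mean()) * (y - y.mean()))
                  / np.sqrt(np.sum((x - x.mean()) ** 2)
                            * np.sum((y - y.mean()) ** 2)))
        assert out[0].r == pytest.approx(r_hand, abs=1e-12)
        t = r_hand * np.sqrt(4 / (1 - r_hand ** 2))
        p_hand = 2 * stats.t.sf(abs(t), df=4)
        assert out[0].p == pytest.approx(p_hand, rel=1e-9)

    def test_missing_values_pairwise_dropped(self, rng):
        scores = rng.normal(size=(10, 2))
        recs = _records(scores[:, 0] * 5 + 60)
        recs[3].peak_gradient = None
        out = correlate(scores, recs, "peak_gradient")
        assert out[0].r == pytest.approx(1.0, abs=1e-9)

    def test_zero_variance_variable_raises(self, rng):
        scores = rng.normal(size=(8, 2))
        with pytest.raises(ValueError, match="zero variance"):
            correlate(scores, _records(np.full(8, 70.0)), "peak_gradient")


class TestClinicalCsv:
    def test_round_trip(self, tmp_path, rng):
        recs = [ClinicalRecord(patient_id=f"p{i}", age=70 + i,
                               peak_gradient=80.0 + i, device_size=23 + 3 * (i % 2))
                for i in range(6)]
        recs[2].paps = None
        path = str(tmp_path / "clinical.csv")
        write_clinical_csv(recs, path)
        back = read_clinical_csv(path)
        assert [r.patient_id for r in back] == [r.patient_id for r in recs]
        assert back[2].paps is None
        assert back[0].device_size == 23

    def test_invalid_device_size(self):
        with pytest.raises(ValueError):
            ClinicalRecord(patient_id="p", device_size=29)


class TestSvmRegress:
    def test_realizable_linear_target(self, rng):
        scores = rng.normal(size=(40, 8)) * np.linspace(5, 1, 8)
        y = 2.0 * scores[:, 0] + 60.0
        res = svm_regress(scores, y, tuning_iters=12, seed=0)
        assert res.r_squared > 0.99
        assert 1 in res.selected_modes
        assert res.cv_rmse < 0.2 * y.std()

    def test_bitwise_reproducible_for_fixed_seed(self, rng):
        scores = rng.normal(size=(32, 6))
        y = scores[:, 1] - 0.5 * scores[:, 3] + rng.normal(0, 0.5, 32)
        a = svm_regress(scores, y, tuning_iters=8, seed=5)
        b = svm_regress(scores, y, tuning_iters=8, seed=5)
        assert a.hyperparameters == b.hyperparameters
        assert a.cv_rmse == b.cv_rmse
        assert np.array_equal(a.predictions, b.predictions)

    def test_permuted_target_has_no_skill(self, rng):
        scores = rng.normal(size=(40, 6))
        y = 3.0 * scores[:, 0] + 70.0
        r2s = []
        for seed in range(8):
            perm = np.random.default_rng(seed).permutation(len(y))
            res = svm_regress(scores, y[perm], tuning_iters=8, seed=seed)
            r2s.append(res.r_squared)
        assert np.median(r2s) < 0.15  # no spurious predictive skill

    def test_constant_target_raises(self, rng):
        with pytest.raises(ValueError, match="constant"):
            svm_regress(rng.normal(size=(40, 4)), np.full(40, 5.0))

    def test_too_few_subjects_raise(self, rng):
        with pytest.raises(ValueError):
            svm_regress(rng.normal(size=(20, 4)), rng.normal(size=20),
                        folds=10)


class TestFScoreSelect:
    def test_planted_separated_mode_ranks_first(self):
        """A 5-SD class separation wins over pure-noise modes, every seed."""
        for seed in range(50):
            rng = np.random.default_rng(seed)
            labels = np.repeat([23, 26], 15)
            scores = rng.normal(size=(30, 8))
            scores[:, 4] += np.where(labels == 26, 5.0, 0.0)
            top = f_score_select(scores, labels, n_select=3)
            assert top[0] == 4

    def test_null_labels_favor_no_mode(self):
        counts = np.zeros(6)
        for seed in range(120):
            rng = np.random.default_rng(1000 + seed)
            labels = np.repeat([0, 1], 10)
            scores = rng.normal(size=(20, 6))
            counts[f_score_select(scores, labels, n_select=1)[0]] += 1
        freq = counts / counts.sum()
        assert freq.max() < 0.35  # uniform would be 1/6

    def test_single_class_raises(self, rng):
        with pytest.raises(ValueError):
            f_score_select(rng.normal(size=(10, 3)), np.zeros(10))


def _separable_problem(n=40, seed=0):
    rng = np.random.default_rng(seed)
    labels = np.repeat([23, 26], n // 2)
    scores = rng.normal(size=(n, 6))
    scores[:, 1] += np.where(labels == 26, 6.0, 0.0)
    return scores, labels


class TestClassify:
    def test_separable_classes_all_models_excellent(self):
        scores, labels = _separable_problem()
        res = classify(scores, labels, seed=0)
        assert set(res.per_model) == {"MLP", "LR", "KNN", "SVM"}
        for name, m in res.per_model.items():
            assert m.auroc >= 0.95, name

    def test_confusion_matrix_consistency(self):
        scores, labels = _separable_problem(seed=3)
        res = classify(scores, labels, seed=1)
        for m in res.per_model.values():
            cm = m.confusion
            assert cm.sum() == res.test_size
            for k, cls in enumerate(res.classes):
                row, col = cm[k, :].sum(), cm[:, k].sum()
                if row:
                    assert m.recall[cls] == pytest.approx(cm[k, k] / row)
                if col:
                    assert m.precision[cls] == pytest.approx(cm[k, k] / col)

    def test_random_labels_near_chance(self):
        aurocs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            scores = rng.normal(size=(40, 5))
            labels = np.repeat([23, 26], 20)
            res = classify(scores, rng.permutation(labels), seed=seed)
            aurocs.append(np.mean([m.auroc for m in res.per_model.values()]))
        assert abs(np.mean(aurocs) - 0.5) < 0.15

    def test_reproducible_for_fixed_seed(self):
        scores, labels = _separable_problem(seed=4)
        a = classify(scores, labels, seed=7)
        b = classify(scores, labels, seed=7)
        for name in a.per_model:
            assert a.per_model[name].auroc == b.per_model[name].auroc
            assert np.array_equal(a.per_model[name].confusion,
                                  b.per_model[name].confusion)

    def test_tiny_class_raises(self, rng):
        scores = rng.normal(size=(12, 3))
        labels = np.array([23] * 9 + [26] * 3)
        with pytest.raises(ValueError):
            classify(scores, labels)
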
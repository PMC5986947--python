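"""SVM core: training contracts, probability sanity, kernel selection,
scaling invariance and persistence."""

import numpy as np
import pytest

from nifscan import (
    FeatureMatrix,
    KernelSpec,
    load_model,
    predict_scores,
    save_model,
    select_kernel,
    train_svm,
)


def _scaled(X: FeatureMatrix, col: int, factor: float) -> FeatureMatrix:
    Xs = X.X.copy()
    Xs[:, col] *= factor
    return FeatureMatrix(X.scheme, X.params, X.ids, X.labels, Xs)


class TestTrainPredict:
    def test_separable_training_accuracy_is_one(self, separable_binary):
        X, y = separable_binary
        model = train_svm(X, y, seed=0)
        preds = [s.label for s in predict_scores(model, X)]
        assert np.mean(np.asarray(preds) == y) == 1.0

    def test_single_class_rejected(self, separable_binary):
        X, y = separable_binary
        with pytest.raises(ValueError, match="2 classes"):
            train_svm(X, ["A"] * len(X), seed=0)

    def test_row_count_mismatch_rejected(self, separable_binary):
        X, y = separable_binary
        with pytest.raises(ValueError, match="labels"):
            train_svm(X, y[:-1], seed=0)

    def test_same_seed_reproduces_probabilities(self, separable_binary, null_binary):
        X, y = separable_binary
        probe, _ = null_binary
        m1 = train_svm(X, y, seed=3)
        m2 = train_svm(X, y, seed=3)
        p1 = np.array([s.probabilities for s in predict_scores(m1, probe)])
        p2 = np.array([s.probabilities for s in predict_scores(m2, probe)])
        np.testing.assert_array_equal(p1, p2)

    def test_probabilities_normalized_and_argmax_consistent(self, separable_binary):
        X, y = separable_binary
        model = train_svm(X, y, seed=0)
        for score in predict_scores(model, X):
            assert score.probabilities.sum() == pytest.approx(1.0, abs=1e-6)
            assert score.label == score.class_labels[int(np.argmax(score.probabilities))]
            assert 0.0 <= score.max_prob <= 1.0

    def test_empty_query_gives_empty_list(self, separable_binary):
        X, y = separable_binary
        model = train_svm(X, y, seed=0)
        assert predict_scores(model, X.take([])) == []

    def test_dimension_mismatch_named(self, separable_binary):
        X, y = separable_binary
        model = train_svm(X, y, seed=0)
        bad = FeatureMatrix("aac", {}, X.ids, tuple(X.labels[:20]), X.X[:, :20])
        with pytest.raises(ValueError, match="expects ctd"):
            predict_scores(model, bad)

    def test_column_scaling_absorbed_by_standardization(self, separable_binary):
        X, y = separable_binary
        base = train_svm(X, y, seed=1)
        scaled = train_svm(_scaled(X, 5, 10.0), y, seed=1)
        p0 = np.array([s.probabilities for s in predict_scores(base, X)])
        p1 = np.array([s.probabilities for s in predict_scores(scaled, _scaled(X, 5, 10.0))])
        np.testing.assert_allclose(p0, p1, atol=1e-9)


class TestCalibrationSanity:
    def test_no_spurious_confidence_on_null_data(self, null_binary):
        """When the two classes are identically distributed, calibrated
        confidence must stay modest."""
        X, y = null_binary
        model = train_svm(X.take(range(0, 100, 2)), y[0:100:2], seed=0)
        probes = X.take(range(1, 100, 2))
        mean_max = np.mean([s.max_prob for s in predict_scores(model, probes)])
        assert mean_max <= 0.75

    def test_high_confidence_on_separable_data(self, separable_binary):
        X, y = separable_binary
        model = train_svm(X.take(range(0, 100, 2)), y[0:100:2], seed=0)
        probes = X.take(range(1, 100, 2))
        mean_max = np.mean([s.max_prob for s in predict_scores(model, probes)])
        assert mean_max >= 0.9

    def test_multiclass_restriction_agrees_with_binary(self, six_class):
        """A six-class model queried on probes from two classes should argmax
        like a dedicated binary model almost always on separable data."""
        X, y = six_class
        labels = sorted(set(y))[:2]
        mask = np.isin(y, labels)
        idx = np.nonzero(mask)[0]
        multi = train_svm(X, y, seed=0)
        binary = train_svm(X.take(idx), y[idx], seed=0)
        m_pred = [s.label for s in predict_scores(multi, X.take(idx))]
        b_pred = [s.label for s in predict_scores(binary, X.take(idx))]
        agree = np.mean(np.asarray(m_pred) == np.asarray(b_pred))
        assert agree >= 0.9


class TestKernelSelection:
    def test_separable_data_selects_radial(self, separable_binary):
        X, y = separable_binary
        with pytest.warns(UserWarning, match="subset_per_class"):
            spec = select_kernel(X, y, subset_per_class=100, seed=0)
        assert spec.name == "radial"

    def test_winner_stable_across_seeds(self, separable_binary):
        X, y = separable_binary
        winners = set()
        for seed in (1, 2, 3):
            with pytest.warns(UserWarning):
                winners.add(select_kernel(X, y, subset_per_class=100, seed=seed).name)
        assert winners == {"radial"}

    def test_degenerate_tie_breaks_to_radial(self):
        # constant features: every kernel is chance-level, so accuracies tie
        X = FeatureMatrix(
            "aac", {}, tuple(f"s{i}" for i in range(20)),
            tuple(f"f{j}" for j in range(5)),
            np.ones((20, 5)),
        )
        y = ["A"] * 10 + ["B"] * 10
        spec = select_kernel(X, y, subset_per_class=10, seed=0)
        assert spec.name == "radial"

    def test_fewer_than_two_classes_rejected(self, separable_binary):
        X, _ = separable_binary
        with pytest.raises(ValueError):
            select_kernel(X, ["A"] * len(X), seed=0)


class TestKernelSpec:
    @pytest.mark.parametrize("bad", [
        {"name": "rbf"}, {"cost": 0.0}, {"gamma": -1.0}, {"degree": 0},
    ])
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(ValueError):
            KernelSpec(**bad)


class TestPersistence:
    def test_roundtrip_preserves_predictions(self, separable_binary, tmp_path):
        X, y = separable_binary
        model = train_svm(X, y, seed=0)
        path = tmp_path / "model.joblib"
        save_model(model, path)
        back = load_model(path)
        assert back.class_labels == model.class_labels
        assert back.kernel == model.kernel
        p0 = np.array([s.probabilities for s in predict_scores(model, X)])
        p1 = np.array([s.probabilities for s in predict_scores(back, X)])
        np.testing.assert_array_equal(p0, p1)

    def test_unversioned_archive_refused(self, tmp_path):
        import joblib

        path = tmp_path / "bad.joblib"
        joblib.dump({"whatever": 1}, path)
        with pytest.raises(ValueError, match="model archive"):
            load_model(path)
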
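"""Classifier training, cross-validation, probabilities and macro metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from squatmon.classify import (
    ALGORITHMS,
    ConfusionMatrix,
    confusion,
    cross_validate,
    macro_metrics,
    predict_report,
    train,
)
from squatmon.errors import ContractError, DataError, ParameterError
from squatmon.features import FeatureTable
from squatmon.imu_model import SquatLabel

# Real-time six-class confusion matrix (rows = actual, columns = predicted)
REALTIME_CM = np.array(
    [
        [27, 9, 1, 3, 1, 5],
        [3, 39, 10, 0, 9, 1],
        [0, 8, 27, 0, 4, 6],
        [5, 3, 0, 40, 3, 2],
        [2, 15, 1, 0, 41, 0],
        [5, 4, 0, 3, 2, 40],
    ]
)


def _clusters(n_per=60, sep=6.0, d=8, seed=0):
    rng = np.random.default_rng(seed)
    centers = rng.normal(scale=sep, size=(6, d))
    y = np.repeat(np.arange(6), n_per)
    X = centers[y] + rng.normal(size=(len(y), d))
    cols = [f"f{i}" for i in range(d)]
    return FeatureTable(values=pd.DataFrame(X, columns=cols), labels=y), centers


class TestTrain:
    @pytest.mark.parametrize("algo", ALGORITHMS)
    def test_separable_clusters_high_accuracy(self, algo):
        table, _ = _clusters()
        model = train(table, algo=algo, seed=0)
        assert model.holdout.accuracy > 0.95

    def test_conflicting_labels_train_without_error(self):
        X = np.ones((60, 4))
        y = np.repeat(np.arange(6), 10)
        table = FeatureTable(values=pd.DataFrame(X, columns=list("abcd")), labels=y)
        model = train(table, algo="DT", seed=0)
        assert model.holdout.sensitivity <= 0.5  # near class prior

    def test_same_seed_identical_predictions(self):
        table, _ = _clusters()
        X = table.values.to_numpy()
        m1 = train(table, algo="MLP", seed=3)
        m2 = train(table, algo="MLP", seed=3)
        np.testing.assert_array_equal(
            m1.estimator.predict(X), m2.estimator.predict(X)
        )

    def test_class_with_one_row_rejected(self):
        table, _ = _clusters(n_per=10)
        y = table.labels.copy()
        y[y == 5] = 4
        y[0] = 5  # a single row of class 5
        with pytest.raises(DataError):
            train(table, labels=y, algo="DT")


class TestCrossValidate:
    def test_separable_clusters(self):
        table, _ = _clusters(n_per=30)
        _, mean = cross_validate(table, algo="KNN", k=10, seed=0)
        assert mean.accuracy > 0.95

    def test_shuffled_labels_near_chance(self):
        table, _ = _clusters(n_per=30)
        rng = np.random.default_rng(5)
        y = rng.permutation(table.labels)
        _, mean = cross_validate(table, labels=y, algo="KNN", k=10, seed=0)
        assert abs(mean.sensitivity - 1 / 6) < 0.1

    def test_k_boundary(self):
        table, _ = _clusters(n_per=12)
        cross_validate(table, algo="DT", k=12, seed=0)
        with pytest.raises(ParameterError):
            cross_validate(table, algo="DT", k=13, seed=0)


class TestPredictReport:
    def test_probabilities_sum_to_one(self):
        table, centers = _clusters()
        model = train(table, algo="MLP", seed=0)
        _, probs, _ = predict_report(model, centers[0])
        assert probs.shape == (6,)
        assert abs(probs.sum() - 1.0) < 1e-9

    def test_cluster_center_classified_confidently(self):
        table, centers = _clusters()
        model = train(table, algo="MLP", seed=0)
        label, probs, _ = predict_report(model, centers[SquatLabel.VK])
        assert label == SquatLabel.VK and probs[SquatLabel.VK] > 0.9

    def test_boundary_point_reports_mixed_errors(self):
        # moving along the KOT→RH chord, the class probabilities cross;
        # near the crossing both errors exceed the mixed-error threshold
        table, centers = _clusters()
        model = train(table, algo="MLP", seed=0)
        found = False
        for w in np.linspace(0.3, 0.7, 21):
            p = (1 - w) * centers[SquatLabel.KOT] + w * centers[SquatLabel.RH]
            _, probs, advice = predict_report(model, p)
            if "KOT" in advice and "RH" in advice:
                found = True
                break
        assert found

    def test_feature_count_mismatch_rejected(self):
        table, _ = _clusters()
        model = train(table, algo="DT", seed=0)
        with pytest.raises(ContractError):
            predict_report(model, np.zeros(3))


class TestConfusion:
    def test_perfect_predictions_diagonal(self):
        y = np.repeat(np.arange(6), 10)
        cm = confusion(y, y)
        np.testing.assert_array_equal(cm.counts, np.eye(6, dtype=int) * 10)

    def test_single_pair(self):
        cm = confusion([SquatLabel.CO], [SquatLabel.SH])
        assert cm.counts[SquatLabel.CO, SquatLabel.SH] == 1 and cm.n == 1

    def test_unknown_label_rejected(self):
        with pytest.raises(DataError):
            confusion([0, 7], [0, 0])

    def test_expanded_pairs_rebuild_printed_matrix(self):
        truths, preds = [], []
        for i in range(6):
            for j in range(6):
                truths += [i] * REALTIME_CM[i, j]
                preds += [j] * REALTIME_CM[i, j]
        np.testing.assert_array_equal(confusion(truths, preds).counts, REALTIME_CM)


class TestMacroMetrics:
    def test_printed_realtime_metrics_reproduced(self):
        m = macro_metrics(ConfusionMatrix(REALTIME_CM))
        assert m.accuracy == pytest.approx(0.8903, abs=5e-5)
        assert m.specificity == pytest.approx(0.9335, abs=5e-5)
        assert m.sensitivity == pytest.approx(0.6677, abs=5e-5)
        assert m.precision == pytest.approx(0.6881, abs=5e-5)

    def test_identity_matrix_all_ones(self):
        m = macro_metrics(ConfusionMatrix(np.eye(6, dtype=int) * 7))
        assert (m.accuracy, m.specificity, m.sensitivity, m.precision) == (1, 1, 1, 1)

    def test_two_class_hand_computation(self):
        C = np.zeros((6, 6), dtype=int)
        C[0, 0], C[0, 1], C[1, 0], C[1, 1] = 8, 2, 3, 7
        m = macro_metrics(ConfusionMatrix(C))
        assert m.accuracy == pytest.approx(5.5 / 6)
        assert m.specificity == pytest.approx((0.7 + 0.8 + 4) / 6)
        assert m.sensitivity == pytest.approx((0.8 + 0.7) / 2)
        assert m.precision == pytest.approx((8 / 11 + 7 / 9) / 2)

    def test_transposition_swaps_sensitivity_and_precision(self):
        m = macro_metrics(ConfusionMatrix(REALTIME_CM))
        mt = macro_metrics(ConfusionMatrix(REALTIME_CM.T))
        assert mt.accuracy == pytest.approx(m.accuracy)
        assert mt.sensitivity == pytest.approx(m.precision)
        assert mt.precision == pytest.approx(m.sensitivity)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_outputs_always_within_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        C = rng.integers(0, 20, size=(6, 6))
        if C.sum() == 0:
            C[0, 0] = 1
        m = macro_metrics(ConfusionMatrix(C))
        for v in m.as_dict().values():
            assert 0.0 <= v <= 1.0 and np.isfinite(v)

    def test_single_class_data_degenerate_but_finite(self):
        C = np.zeros((6, 6), dtype=int)
        C[2, 2], C[2, 4] = 6, 2
        m = macro_metrics(ConfusionMatrix(C))
        assert m.sensitivity == pytest.approx(6 / 8)
        for v in m.as_dict().values():
            assert np.isfinite(v)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ParameterError):
            macro_metrics(ConfusionMatrix(np.zeros((6, 6), dtype=int)))
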
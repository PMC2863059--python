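"""SVM training, grid search, two-phase tuning, and two-stage routing."""

from dataclasses import replace
from unittest import mock

import numpy as np
import pytest

from seqrate import evaluation, svm_models
from seqrate.feature_assembly import FeatureConfig
from seqrate.io_formats import KineticLabel, ValidationError
from seqrate.svm_models import (
    HyperParams,
    grid_search_classifier,
    load_bundle,
    predict,
    save_bundle,
    train_bundle,
    train_classifier,
    train_regressor,
    tune_regressor,
)


def gaussian_clouds(n=40, sep=6.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 1, size=(n // 2, 2)), rng.normal(sep, 1, size=(n // 2, 2))])
    labels = [KineticLabel.TWO_STATE] * (n // 2) + [KineticLabel.MULTI_STATE] * (n // 2)
    return X, labels


def xor_data(n=60, seed=1):
    rng = np.random.default_rng(seed)
    X = rng.uniform(-1, 1, size=(n, 2))
    X = X[np.min(np.abs(X), axis=1) > 0.15]  # margin around the axes
    labels = [
        KineticLabel.TWO_STATE if x[0] * x[1] > 0 else KineticLabel.MULTI_STATE for x in X
    ]
    return X, labels


class TestClassifier:
    def test_separable_clouds_rbf(self):
        X, labels = gaussian_clouds()
        clf = train_classifier(X, labels, HyperParams(C=1, gamma=0.25))
        codes = np.array([svm_models.LABEL_CODE[l] for l in labels])
        assert np.mean(clf.predict(X) == codes) == 1.0

    def test_separable_clouds_linear(self):
        X, labels = gaussian_clouds()
        clf = train_classifier(X, labels, HyperParams(C=1, gamma=0.25, kernel="linear"))
        codes = np.array([svm_models.LABEL_CODE[l] for l in labels])
        assert np.mean(clf.predict(X) == codes) == 1.0

    def test_xor_rbf_beats_linear(self):
        X, labels = xor_data()
        codes = np.array([svm_models.LABEL_CODE[l] for l in labels])
        rbf = train_classifier(X, labels, HyperParams(C=8, gamma=2.0))
        lin = train_classifier(X, labels, HyperParams(C=8, gamma=2.0, kernel="linear"))
        assert np.mean(rbf.predict(X) == codes) == 1.0
        assert np.mean(lin.predict(X) == codes) < 1.0

    def test_single_class_rejected(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValidationError):
            train_classifier(X, [KineticLabel.TWO_STATE] * 4, HyperParams())

    def test_label_encoding_fixed(self):
        assert svm_models.LABEL_CODE[KineticLabel.TWO_STATE] == 1
        assert svm_models.LABEL_CODE[KineticLabel.MULTI_STATE] == -1


class TestRegressor:
    def test_realizable_linear_function(self):
        x = np.linspace(0, 1, 20).reshape(-1, 1)
        y = 2 * x.ravel()
        hp = HyperParams(C=100, gamma=1.0, epsilon=0.01, kernel="linear")
        reg = train_regressor(x, y, hp)
        assert np.all(np.abs(reg.predict(x) - y) <= hp.epsilon + 0.01)

    def test_constant_targets(self):
        x = np.linspace(0, 1, 10).reshape(-1, 1)
        reg = train_regressor(x, np.full(10, 3.0), HyperParams(C=1, gamma=1, epsilon=0.1))
        assert np.all(np.abs(reg.predict(x) - 3.0) <= 0.1)

    def test_smooth_function_recovery(self):
        rng = np.random.default_rng(2)
        x = np.linspace(0, 2 * np.pi, 60).reshape(-1, 1)
        y = np.sin(x.ravel()) + rng.normal(0, 0.05, size=60)
        reg = train_regressor(x, y, HyperParams(C=10, gamma=1.0, epsilon=0.05))
        assert evaluation.pearson(y, reg.predict(x)) >= 0.95

    def test_too_few_rows(self):
        with pytest.raises(ValidationError):
            train_regressor(np.zeros((2, 1)), [0.0, 1.0], HyperParams())

    def test_determinism(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + rng.normal(0, 0.1, 30)
        probe = rng.normal(size=(10, 3))
        hp = HyperParams(C=4, gamma=0.5, epsilon=0.1)
        p1 = train_regressor(X, y, hp).predict(probe)
        p2 = train_regressor(X, y, hp).predict(probe)
        assert np.max(np.abs(p1 - p2)) <= 1e-10


class TestGridSearchClassifier:
    def test_separable_reaches_ceiling(self):
        X, labels = gaussian_clouds()
        res = grid_search_classifier(X, labels, {"C": [1.0], "gamma": [0.25, 1.0]})
        assert res.best_score == 1.0

    def test_single_point_grid(self):
        X, labels = gaussian_clouds(n=20)
        res = grid_search_classifier(X, labels, {"C": [2.0], "gamma": [0.5]})
        assert (res.best.C, res.best.gamma) == (2.0, 0.5)
        assert len(res.grid) == 1

    def test_argmax_matches_independent_rescoring(self, small_benchmark):
        from seqrate.feature_assembly import ModelRole, assemble_matrix

        X, _ = assemble_matrix(small_benchmark.records, ModelRole.CLASSIFIER)
        labels = [r.kinetic_label for r in small_benchmark.records]
        grid = {"C": [0.5, 4.0], "gamma": [0.125, 1.0]}
        res = grid_search_classifier(X, labels, grid)
        # independent LOOCV loop over the same surface
        rescored = {}
        for C in grid["C"]:
            for gamma in grid["gamma"]:
                rep = evaluation.loocv_classifier(X, labels, HyperParams(C=C, gamma=gamma))
                rescored[(C, gamma)] = rep.accuracy
        for C, gamma, score in res.grid:
            assert rescored[(C, gamma)] == score
        best_indep = max(sorted(rescored), key=lambda k: rescored[k])
        # tie-break: smallest (C, gamma) with max score
        best_ties = [k for k in sorted(rescored) if rescored[k] == max(rescored.values())]
        assert (res.best.C, res.best.gamma) == best_ties[0]

    def test_degenerate_labels_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        with pytest.raises(ValidationError):
            grid_search_classifier(X, [KineticLabel.TWO_STATE] * 10, {"C": [1.0], "gamma": [1.0]})


class TestTuneRegressor:
    @staticmethod
    def _linear_data(n=30, seed=4):
        rng = np.random.default_rng(seed)
        X = rng.uniform(0, 1, size=(n, 2))
        y = 3 * X[:, 0] - X[:, 1] + rng.normal(0, 0.05, n)
        return X, y

    def test_phase2_never_below_phase1(self):
        X, y = self._linear_data()
        res = tune_regressor(
            X, y, {"C": [1.0, 8.0], "gamma": [0.25, 1.0]}, epsilon_sweep=[0.01, 0.1, 0.5]
        )
        phase1_best = max(s for _, _, e, s in res.grid if e == 0.1)
        assert res.best_score >= phase1_best - 1e-9

    def test_reference_operating_point_scorable(self):
        X, y = self._linear_data()
        res = tune_regressor(X, y, {"C": [8.0], "gamma": [0.125]}, epsilon_sweep=[0.1])
        assert (res.best.C, res.best.gamma, res.best.epsilon) == (8.0, 0.125, 0.1)
        assert any((C, g, e) == (8.0, 0.125, 0.1) for C, g, e, s in res.grid)

    def test_single_point_returns_it(self):
        X, y = self._linear_data()
        res = tune_regressor(X, y, {"C": [2.0], "gamma": [0.5]}, epsilon_sweep=[0.2])
        assert (res.best.C, res.best.gamma) == (2.0, 0.5)
        assert res.best.epsilon in (0.1, 0.2)  # phase-1 incumbent or swept value

    def test_constant_targets_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        with pytest.raises(ValidationError):
            tune_regressor(X, np.ones(10), {"C": [1.0], "gamma": [1.0]})


class TestPipelinePredict:
    def test_routing_and_force_label(self, small_benchmark):
        records = small_benchmark.records
        bundle = train_bundle(records)
        probe = records[0]
        with mock.patch.object(
            bundle.reg_two_state, "predict", wraps=bundle.reg_two_state.predict
        ) as two_spy, mock.patch.object(
            bundle.reg_multi_state, "predict", wraps=bundle.reg_multi_state.predict
        ) as multi_spy:
            label, rate = predict(bundle, probe)
            if label is KineticLabel.TWO_STATE:
                assert two_spy.called and not multi_spy.called
            else:
                assert multi_spy.called and not two_spy.called
        # forced label takes the other regressor; values generally differ
        _, rate_forced = predict(bundle, probe, force_label=KineticLabel.MULTI_STATE)
        _, rate_two = predict(bundle, probe, force_label=KineticLabel.TWO_STATE)
        assert rate_forced != rate_two

    def test_bundle_round_trip(self, tmp_path, small_benchmark):
        records = small_benchmark.records
        bundle = train_bundle(records)
        path = tmp_path / "model.joblib"
        save_bundle(bundle, path)
        back = load_bundle(path)
        for rec in records[:4]:
            assert predict(bundle, rec) == predict(back, rec)

    def test_feature_length_mismatch_refused(self, small_benchmark):
        records = small_benchmark.records
        bundle = train_bundle(records)
        # pretend the bundle was configured with an extra GC column
        bundle.feature_config = FeatureConfig(use_gc=True)
        rec = replace_gc(records[0])
        with pytest.raises(ValidationError, match="features"):
            predict(bundle, rec)

    def test_training_requires_annotations(self, small_benchmark):
        records = [r for r in small_benchmark.records]
        import copy

        bad = copy.copy(records[0])
        bad.log_rate = None
        with pytest.raises(ValidationError):
            train_bundle([bad] + records[1:])


def replace_gc(record):
    import copy

    rec = copy.copy(record)
    rec.gc_value = 5.0
    return rec


def test_hyperparams_validation():
    with pytest.raises(ValidationError):
        HyperParams(C=-1)
    with pytest.raises(ValidationError):
        HyperParams(kernel="laplace")
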
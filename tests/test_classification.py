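import numpy as np
import pytest

from pancradiomics.classification import (
    METHODS,
    ClassifierSpec,
    RFEConfig,
    evaluate,
    predict,
    report_from_confusion,
    round_half_up,
    run_bank,
    train_with_rfe,
)
from pancradiomics.feature_grid import FeatureDescriptor, FeatureTable
from pancradiomics.io_preprocess import ValidationError


def _table(values, prefix="glcm", ids=None):
    values = np.asarray(values, dtype=np.float64)
    descs = [FeatureDescriptor(prefix, f"f{i}", bin_count=8) for i in range(values.shape[1])]
    ids = ids or [f"c{i}" for i in range(values.shape[0])]
    return FeatureTable.from_rows(ids, values, descs)


def _planted_dataset(rng, n_per_class=20, n_features=10, sep=4.0):
    """Feature 0 separates the classes; the rest are noise."""
    x_head = rng.normal(0, 1, (n_per_class, n_features))
    x_bt = rng.normal(0, 1, (n_per_class, n_features))
    x_head[:, 0] += sep
    x = np.vstack([x_head, x_bt])
    labels = ["head"] * n_per_class + ["body_tail"] * n_per_class
    return _table(x), labels


class TestRounding:
    @pytest.mark.parametrize(
        "x,expected", [(86.2, 86), (86.5, 87), (87.99, 88), (88.095, 88), (0.5, 1)]
    )
    def test_half_up(self, x, expected):
        assert round_half_up(x) == expected


class TestConfigs:
    def test_rfe_bounds(self):
        with pytest.raises(ValidationError):
            RFEConfig(max_features=0)
        with pytest.raises(ValidationError):
            RFEConfig(step=0)
        with pytest.raises(ValidationError):
            RFEConfig(step=1.5)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValidationError):
            ClassifierSpec("deep_net")


class TestTrainWithRFE:
    @pytest.mark.parametrize("method", METHODS)
    def test_cap_and_planted_feature_recovered(self, method, rng):
        table, labels = _planted_dataset(rng)
        model = train_with_rfe(table, labels, ClassifierSpec(method), RFEConfig(), seed=0)
        assert len(model.selected_features) <= 5
        assert "glcm__f0__b8" in model.selected_features

    def test_deterministic_given_seed(self, rng):
        table, labels = _planted_dataset(rng, n_features=30)
        m1 = train_with_rfe(table, labels, ClassifierSpec("svm"), seed=3)
        m2 = train_with_rfe(table, labels, ClassifierSpec("svm"), seed=3)
        assert m1.selected_features == m2.selected_features

    def test_fewer_features_than_cap_warns_and_uses_all(self, rng):
        table, labels = _planted_dataset(rng, n_features=3)
        with pytest.warns(UserWarning):
            model = train_with_rfe(table, labels, rfe=RFEConfig(max_features=5))
        assert len(model.selected_features) == 3

    def test_identity_when_cap_not_binding(self, rng):
        table, labels = _planted_dataset(rng, n_features=1)
        model = train_with_rfe(table, labels, rfe=RFEConfig(max_features=10))
        assert model.selected_features == ("glcm__f0__b8",)

    def test_single_class_rejected(self, rng):
        table, _ = _planted_dataset(rng)
        with pytest.raises(ValidationError):
            train_with_rfe(table, ["head"] * table.n_cases)

    def test_fractional_step(self, rng):
        table, labels = _planted_dataset(rng, n_features=50)
        model = train_with_rfe(table, labels, ClassifierSpec("lda"), RFEConfig(step=0.3))
        assert len(model.selected_features) <= 5


class TestPredict:
    def _separable(self, rng, n_per_class=20, n_features=8):
        """Five informative features with wide class separation."""
        x_head = rng.normal(0, 1, (n_per_class, n_features))
        x_bt = rng.normal(0, 1, (n_per_class, n_features))
        x_head[:, :5] += 5.0
        labels = ["head"] * n_per_class + ["body_tail"] * n_per_class
        return _table(np.vstack([x_head, x_bt])), labels

    def test_separable_test_set_fully_correct(self, rng):
        train, y_train = self._separable(rng)
        test, y_test = self._separable(rng)
        for method in METHODS:
            model = train_with_rfe(train, y_train, ClassifierSpec(method), seed=0)
            labels, scores = predict(model, test)
            assert labels == y_test, method
            assert np.all((scores >= 0) & (scores <= 1))

    def test_score_tie_resolves_to_head(self, rng):
        # nearest-centroid with mirror-symmetric classes: the midpoint is
        # exactly equidistant from both centroids
        table = _table(
            np.array([[1.0, 0.1], [1.0, -0.1], [-1.0, 0.1], [-1.0, -0.1]])
        )
        model = train_with_rfe(
            table,
            ["head", "head", "body_tail", "body_tail"],
            ClassifierSpec("kmeans"),
            RFEConfig(max_features=2),
        )
        mid = _table(np.array([[0.0, 0.0]]), ids=["m"])
        labels, scores = predict(model, mid)
        assert scores[0] == pytest.approx(0.5)
        assert labels == ["head"]

    def test_missing_descriptor_rejected(self, rng):
        train, y = _planted_dataset(rng)
        model = train_with_rfe(train, y)
        bad = _table(np.random.default_rng(0).random((2, 3)), prefix="other")
        with pytest.raises(ValidationError):
            predict(model, bad)


class TestEvaluate:
    def test_published_confusion_matrix_metrics(self):
        rep = report_from_confusion(tp=50, fp=5, fn=8, tn=37)
        assert rep.rounded == {"accuracy": 87, "sensitivity": 86, "specificity": 88}
        assert rep.accuracy == pytest.approx(87.0)
        assert rep.sensitivity == pytest.approx(100 * 50 / 58)
        assert rep.specificity == pytest.approx(100 * 37 / 42)

    def test_perfect_predictions(self):
        truth = ["head"] * 10 + ["body_tail"] * 10
        scores = [0.9] * 10 + [0.1] * 10
        rep = evaluate(truth, scores, truth)
        assert rep.rounded["accuracy"] == 100
        assert rep.auc == pytest.approx(1.0)

    def test_confusion_marginals_match_class_counts(self, rng):
        truth = ["head"] * 12 + ["body_tail"] * 8
        scores = rng.random(20)
        preds = ["head" if s >= 0.5 else "body_tail" for s in scores]
        rep = evaluate(preds, scores, truth)
        c = rep.confusion
        assert c.sum() == 20
        assert c[0, 0] + c[1, 0] == 12  # true head column
        assert c[0, 1] + c[1, 1] == 8

    def test_random_scores_auc_near_half(self, rng):
        n = 4000
        truth = ["head"] * (n // 2) + ["body_tail"] * (n // 2)
        scores = rng.random(n)
        preds = ["head" if s >= 0.5 else "body_tail" for s in scores]
        rep = evaluate(preds, scores, truth)
        assert rep.auc == pytest.approx(0.5, abs=0.05)

    def test_roc_monotone_and_auc_transform_invariant(self, rng):
        truth = ["head"] * 30 + ["body_tail"] * 30
        scores = np.concatenate([rng.random(30) * 0.8 + 0.2, rng.random(30) * 0.8])
        preds = ["head" if s >= 0.5 else "body_tail" for s in scores]
        rep = evaluate(preds, scores, truth)
        assert np.all(np.diff(rep.roc[:, 0]) >= 0)
        assert np.all(np.diff(rep.roc[:, 1]) >= 0)
        # strictly monotone transform leaves the AUC unchanged
        rep2 = evaluate(preds, 1 / (1 + np.exp(-5 * scores)), truth)
        assert rep2.auc == pytest.approx(rep.auc)
        # accuracy re-derivable from the confusion matrix
        c = rep.confusion
        assert rep.accuracy == pytest.approx(100 * (c[0, 0] + c[1, 1]) / c.sum())

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            evaluate(["head"], [0.6, 0.4], ["head", "body_tail"])


class TestRunBank:
    def test_seven_reports_and_best_above_chance(self, rng):
        train, y_train = _planted_dataset(rng, n_per_class=25, sep=3.0)
        test, y_test = _planted_dataset(rng, n_per_class=25, sep=3.0)
        bank = run_bank(train, y_train, test, y_test, seed=0)
        assert set(bank.reports) == set(METHODS)
        assert len(bank.reports) == 7
        for method, rep in bank.reports.items():
            assert rep.accuracy > 50.0, method
        assert bank.best_report.accuracy == max(r.accuracy for r in bank.reports.values())

    def test_single_feature_table_never_errors(self, rng):
        x = np.vstack([rng.normal(1, 1, (10, 1)), rng.normal(-1, 1, (10, 1))])
        table = _table(x)
        labels = ["head"] * 10 + ["body_tail"] * 10
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            bank = run_bank(table, labels, table, labels, seed=0)
        assert len(bank.reports) == 7
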
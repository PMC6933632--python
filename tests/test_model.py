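"""Random forest / MLP training, cross-validation and importance layout."""

import numpy as np
import pandas as pd
import pytest

import tadbound as tb
from tadbound.model import (
    BoundaryModel,
    EvalReport,
    RFSpec,
    bin_importance,
    cross_validate,
    train_rf,
)


def _toy_matrix(X, y, marks=("A",), bin_number=0, kmer_k=None):
    n_bins = 2 * bin_number + 1
    cols = [f"{m}@{o}" for m in marks for o in range(-bin_number, bin_number + 1)]
    if kmer_k:
        cols += tb.KmerSpec(kmer_k).words
    df = pd.DataFrame(np.asarray(X, dtype=float), columns=cols)
    return tb.FeatureMatrix(df, np.asarray(y), marks, bin_number, kmer_k)


@pytest.fixture(scope="module")
def separable():
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(-3, 1, (30, 3)), rng.normal(3, 1, (30, 3))])
    y = np.repeat([0, 1], 30)
    return _toy_matrix(X, y, marks=("A",), bin_number=1)


class TestTrainRF:
    def test_separable_training_auc_is_one(self, separable):
        from sklearn.metrics import roc_auc_score

        rf, imp = train_rf(separable, RFSpec(n_estimators=50))
        proba = rf.predict_proba(separable.X)[:, 1]
        assert roc_auc_score(separable.y, proba) == 1.0
        assert np.all(imp >= 0) and imp.sum() == pytest.approx(1.0)

    def test_single_informative_feature_dominates(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(80, 3))
        y = (X[:, 0] > 0).astype(int)
        m = _toy_matrix(X, y, bin_number=1)
        _, imp = train_rf(m, RFSpec(n_estimators=100))
        assert np.argmax(imp) == 0

    def test_single_class_rejected(self):
        m = _toy_matrix(np.ones((4, 1)), [1, 1, 1, 1])
        with pytest.raises(tb.ValidationError):
            train_rf(m)


class TestCrossValidate:
    def test_shuffled_labels_are_null(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(100, 5))
        y = rng.permutation(np.repeat([0, 1], 50))
        m = _toy_matrix(X, y, marks=("A",), bin_number=2)
        report = cross_validate(m, RFSpec(n_estimators=100), folds=5, seed=0)
        assert 0.35 <= report.mean("auc") <= 0.65

    def test_stratified_two_folds_on_four_samples(self):
        m = _toy_matrix(np.arange(8).reshape(4, 2), [0, 1, 0, 1],
                        marks=("A", "B"), bin_number=0)
        report = cross_validate(m, RFSpec(n_estimators=10), folds=2, seed=0)
        assert len(report.folds) == 2
        # each fold holds one sample of each class
        for f in (0, 1):
            held = m.y[report.fold_assignments == f]
            assert sorted(held) == [0, 1]

    def test_too_many_folds_rejected(self, separable):
        with pytest.raises(tb.ValidationError, match="folds"):
            cross_validate(separable, RFSpec(n_estimators=10), folds=40)

    def test_report_metrics_bounded_and_serializable(self, separable, tmp_path):
        report = cross_validate(separable, RFSpec(n_estimators=20), folds=3, seed=1)
        for metric in report.metrics:
            assert 0.0 <= report.mean(metric) <= 1.0
        report.to_json(tmp_path / "r.json")
        import json

        payload = json.loads((tmp_path / "r.json").read_text())
        assert payload["n_folds"] == 3

    def test_rf_report_deterministic_under_seed(self, separable):
        r1 = cross_validate(separable, RFSpec(n_estimators=30), folds=3, seed=7)
        r2 = cross_validate(separable, RFSpec(n_estimators=30), folds=3, seed=7)
        assert r1.folds == r2.folds


class TestBinImportance:
    def test_reshape_189_to_9_by_21(self):
        marks = tb.MARK_ORDER
        imp = np.full(189, 1 / 189)
        table = bin_importance(imp, marks, 10)
        assert table.shape == (9, 21)
        assert list(table.index) == list(marks)
        assert list(table.columns)[0] == "-10" and list(table.columns)[-1] == "10"

    def test_uniform_in_uniform_out(self):
        table = bin_importance(np.ones(15) / 15, ("A", "B", "C"), 2)
        np.testing.assert_allclose(table.to_numpy(), 1 / 15)

    def test_length_mismatch_rejected(self):
        with pytest.raises(tb.ValidationError):
            bin_importance(np.ones(9), ("A", "B"), 2)


class TestBoundaryModel:
    def test_results_summary_and_prediction(self, separable):
        results = BoundaryModel(separable, "rf", RFSpec(n_estimators=30)).fit(
            folds=3, seed=0
        )
        text = results.summary()
        assert "auc" in text and "f_score" in text and "backend: rf" in text
        proba = results.predict_proba(separable)
        assert proba.shape == (60,) and np.all((proba >= 0) & (proba <= 1))

    def test_schema_mismatch_rejected(self, separable):
        results = BoundaryModel(separable, "rf", RFSpec(n_estimators=10)).fit(
            folds=2, seed=0
        )
        other = _toy_matrix(np.ones((4, 2)), [0, 1, 0, 1], marks=("A", "B"),
                            bin_number=0)
        with pytest.raises(tb.SchemaError):
            results.predict_proba(other)

    def test_checkpoint_roundtrip(self, separable, tmp_path):
        results = BoundaryModel(separable, "rf", RFSpec(n_estimators=20)).fit(
            folds=2, seed=0
        )
        p = tmp_path / "model.pkl"
        results.save(p)
        from tadbound.model import BoundaryResults, predict_with_checkpoint

        payload = BoundaryResults.load_checkpoint(p)
        sep = tb.FeatureMatrix(
            separable.data, separable.labels, separable.marks,
            separable.bin_number, None,
            tuple(tb.GenomicLocus("chr1", i * 10, (i + 1) * 10)
                  for i in range(len(separable.data))),
        )
        table = predict_with_checkpoint(payload, sep)
        np.testing.assert_allclose(
            table["probability"].to_numpy(), results.predict_proba(separable)
        )

    def test_mlp_backend_fits(self, separable):
        spec = tb.MLPSpec(epochs=30, seed=0)
        results = BoundaryModel(separable, "mlp", spec).fit(folds=2, seed=0)
        assert results.report.mean("auc") >= 0.9
        with pytest.raises(tb.ValidationError):
            results.bin_importance()
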
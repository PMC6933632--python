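"""Boundary classifiers: random forest and MLP, with cross-validated evaluation.

The central objects follow the model/results convention of statistical
modelling packages: :class:`BoundaryModel` is built from a
:class:`~tadbound.core.FeatureMatrix` and ``fit()`` returns a
:class:`BoundaryResults` carrying per-fold and mean AUC / AUPR / accuracy /
F-score, feature importances (random forest), a per-bin importance matrix and
a ``summary()`` table. The underlying ``train_rf`` / ``train_mlp`` /
``cross_validate`` functions are public for direct use.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    roc_auc_score,
)
from sklearn.model_selection import GridSearchCV, StratifiedKFold

from .core import FeatureMatrix, SchemaError, ValidationError
from .mlp import MLPNetwork, MLPSpec

__all__ = [
    "RFSpec",
    "MLPSpec",
    "EvalReport",
    "train_rf",
    "train_mlp",
    "cross_validate",
    "bin_importance",
    "BoundaryModel",
    "BoundaryResults",
]

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class RFSpec:
    """Random-forest hyperparameters: 500 trees, sqrt(M) features per split."""

    n_estimators: int = 500
    max_features: str | int | float = "sqrt"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_estimators < 1:
            raise ValidationError("n_estimators must be >= 1")


@dataclass
class EvalReport:
    """Cross-validation metrics for one model."""

    model: str
    folds: list[dict[str, float]]
    fold_assignments: np.ndarray
    seed: int

    def mean(self, metric: str) -> float:
        return float(np.mean([f[metric] for f in self.folds]))

    def std(self, metric: str) -> float:
        return float(np.std([f[metric] for f in self.folds], ddof=1)) if len(self.folds) > 1 else 0.0

    @property
    def metrics(self) -> tuple[str, ...]:
        return ("auc", "aupr", "accuracy", "f_score")

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "seed": self.seed,
            "n_folds": len(self.folds),
            "mean": {m: self.mean(m) for m in self.metrics},
            "std": {m: self.std(m) for m in self.metrics},
            "per_fold": self.folds,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _check_trainable(matrix: FeatureMatrix) -> None:
    if len(matrix.data) == 0:
        raise ValidationError("empty feature matrix")
    if len(np.unique(matrix.y)) < 2:
        raise ValidationError("both classes must be present for training")


def train_rf(matrix: FeatureMatrix, spec: RFSpec = RFSpec()):
    """Fit a random forest; returns (model, Gini importances summing to 1)."""
    _check_trainable(matrix)
    rf = RandomForestClassifier(
        n_estimators=spec.n_estimators,
        max_features=spec.max_features,
        random_state=spec.seed,
        n_jobs=1,
    )
    rf.fit(matrix.X, matrix.y)
    return rf, rf.feature_importances_


def train_mlp(matrix: FeatureMatrix, spec: MLPSpec = MLPSpec()) -> MLPNetwork:
    """Fit the MLP classifier by back-propagation."""
    _check_trainable(matrix)
    net = MLPNetwork(spec, n_features=matrix.X.shape[1])
    net.fit(matrix.X, matrix.y)
    return net


def grid_search_rf(
    matrix: FeatureMatrix, param_grid: dict, folds: int = 5, seed: int = 0
) -> RandomForestClassifier:
    """Optional hyperparameter search over the non-tree-count parameters."""
    _check_trainable(matrix)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    gs = GridSearchCV(
        RandomForestClassifier(n_estimators=500, random_state=seed, n_jobs=1),
        param_grid,
        cv=cv,
        scoring="roc_auc",
    )
    gs.fit(matrix.X, matrix.y)
    return gs.best_estimator_


def _fold_metrics(y_true, proba, threshold: float = 0.5) -> dict[str, float]:
    calls = (proba > threshold).astype(int)
    return {
        "auc": float(roc_auc_score(y_true, proba)),
        "aupr": float(average_precision_score(y_true, proba)),
        "accuracy": float(accuracy_score(y_true, calls)),
        "f_score": float(f1_score(y_true, calls, zero_division=0)),
    }


def cross_validate(
    matrix: FeatureMatrix,
    spec: RFSpec | MLPSpec,
    folds: int = 10,
    seed: int = 0,
) -> EvalReport:
    """Stratified k-fold evaluation; metrics computed on held-out predictions."""
    _check_trainable(matrix)
    if folds < 2:
        raise ValidationError("folds must be >= 2")
    counts = np.bincount(matrix.y)
    if folds > counts.min():
        raise ValidationError(
            f"{folds} folds exceed the smaller class size {counts.min()}"
        )
    is_mlp = isinstance(spec, MLPSpec)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    X, y = matrix.X, matrix.y
    assignments = np.full(len(y), -1, dtype=int)
    fold_rows = []
    for f, (tr, te) in enumerate(cv.split(X, y)):
        assignments[te] = f
        sub = FeatureMatrix(
            matrix.data.iloc[tr], y[tr], matrix.marks, matrix.bin_number,
            matrix.kmer_k, tuple(matrix.loci[i] for i in tr) if matrix.loci else (),
        )
        if is_mlp:
            # fresh weights per fold, seeded per fold for reproducibility
            fold_spec = MLPSpec(
                hidden=spec.hidden, threshold=spec.threshold, epochs=spec.epochs,
                batch_size=spec.batch_size, learning_rate=spec.learning_rate,
                seed=spec.seed + f,
            )
            net = train_mlp(sub, fold_spec)
            proba = net.predict_proba(X[te])[:, 1]
            threshold = spec.threshold
        else:
            rf, _ = train_rf(sub, RFSpec(spec.n_estimators, spec.max_features,
                                         spec.seed + f))
            proba = rf.predict_proba(X[te])[:, 1]
            threshold = 0.5
        fold_rows.append(_fold_metrics(y[te], proba, threshold))
    return EvalReport("mlp" if is_mlp else "rf", fold_rows, assignments, seed)


def bin_importance(
    importances: np.ndarray, marks: tuple[str, ...], bin_number: int
) -> pd.DataFrame:
    """Reshape a signal-block importance vector into a marks x bins table.

    The vector must cover exactly the signal block (k-mer importances are
    reported separately); columns are labelled by bin offset.
    """
    n_bins = 2 * bin_number + 1
    imp = np.asarray(importances, dtype=float)
    if imp.size != len(marks) * n_bins:
        raise ValidationError(
            f"{imp.size} importances do not fill a {len(marks)}x{n_bins} layout"
        )
    return pd.DataFrame(
        imp.reshape(len(marks), n_bins),
        index=list(marks),
        columns=[str(o) for o in range(-bin_number, bin_number + 1)],
    )


class BoundaryModel:
    """Boundary-vs-non-boundary classifier over a feature matrix.

    Parameters
    ----------
    matrix : FeatureMatrix
        Labelled design matrix (signal block, optional k-mer block).
    backend : {"rf", "mlp"}
        Random forest (default) or multilayer perceptron.
    spec : RFSpec or MLPSpec, optional
        Hyperparameters; defaults match the backend.
    """

    def __init__(self, matrix: FeatureMatrix, backend: str = "rf",
                 spec: RFSpec | MLPSpec | None = None):
        if backend not in ("rf", "mlp"):
            raise ValidationError(f"unknown backend {backend!r}")
        _check_trainable(matrix)
        self.matrix = matrix
        self.backend = backend
        if spec is None:
            spec = RFSpec() if backend == "rf" else MLPSpec()
        self.spec = spec

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, labels, marks, bin_number,
                       kmer_k=None, **kwargs) -> "BoundaryModel":
        return cls(FeatureMatrix(df, np.asarray(labels), tuple(marks),
                                 bin_number, kmer_k), **kwargs)

    def fit(self, folds: int = 10, seed: int = 0) -> "BoundaryResults":
        """Cross-validate, then refit on all rows; returns the results object."""
        report = cross_validate(self.matrix, self.spec, folds=folds, seed=seed)
        if self.backend == "rf":
            estimator, importances = train_rf(self.matrix, self.spec)
        else:
            estimator = train_mlp(self.matrix, self.spec)
            importances = None
        return BoundaryResults(self, estimator, report, importances)


@dataclass
class BoundaryResults:
    """Fitted classifier plus its cross-validated evaluation."""

    model: BoundaryModel
    estimator: object
    report: EvalReport
    importances: np.ndarray | None = None

    @property
    def feature_names(self) -> list[str]:
        return [str(c) for c in self.model.matrix.data.columns]

    def predict_proba(self, matrix: FeatureMatrix) -> np.ndarray:
        if [str(c) for c in matrix.data.columns] != self.feature_names:
            raise SchemaError("feature columns do not match the fitted model")
        return self.estimator.predict_proba(matrix.X)[:, 1]

    def predict_table(self, matrix: FeatureMatrix,
                      threshold: float = 0.5) -> pd.DataFrame:
        """Per-locus probability and thresholded call."""
        proba = self.predict_proba(matrix)
        loci = matrix.loci
        return pd.DataFrame({
            "chrom": [l.chrom for l in loci],
            "start": [l.start for l in loci],
            "end": [l.end for l in loci],
            "probability": proba,
            "call": (proba > threshold).astype(int),
        })

    def bin_importance(self) -> pd.DataFrame:
        """Signal-block Gini importances reshaped to marks x bin offsets."""
        if self.importances is None:
            raise ValidationError("bin importance requires the rf backend")
        m = self.model.matrix
        n_signal = len(m.marks) * m.n_bins
        return bin_importance(self.importances[:n_signal], m.marks, m.bin_number)

    def kmer_importance(self) -> pd.Series:
        if self.importances is None:
            raise ValidationError("k-mer importance requires the rf backend")
        m = self.model.matrix
        n_signal = len(m.marks) * m.n_bins
        return pd.Series(self.importances[n_signal:], index=m.kmer_columns)

    def summary(self) -> str:
        """Plain-text summary table of the cross-validated metrics."""
        r = self.report
        lines = [
            "Boundary classification results",
            "=" * 47,
            f"backend: {r.model}    folds: {len(r.folds)}    seed: {r.seed}",
            f"samples: {len(self.model.matrix.data)} "
            f"(boundary {int(self.model.matrix.y.sum())}, "
            f"non-boundary {int((1 - self.model.matrix.y).sum())})",
            f"features: {self.model.matrix.data.shape[1]}",
            "-" * 47,
            f"{'metric':<12}{'mean':>10}{'sd':>10}",
        ]
        for metric in r.metrics:
            lines.append(f"{metric:<12}{r.mean(metric):>10.4f}{r.std(metric):>10.4f}")
        lines.append("=" * 47)
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        payload = {
            "version": CHECKPOINT_VERSION,
            "backend": self.model.backend,
            "feature_names": self.feature_names,
            "marks": self.model.matrix.marks,
            "bin_number": self.model.matrix.bin_number,
            "kmer_k": self.model.matrix.kmer_k,
            "estimator": self.estimator,
            "importances": self.importances,
            "report": self.report.to_dict(),
        }
        with open(path, "wb") as fh:
            pickle.dump(payload, fh)

    @staticmethod
    def load_checkpoint(path) -> dict:
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if payload.get("version") != CHECKPOINT_VERSION:
            raise SchemaError(
                f"checkpoint version {payload.get('version')} != {CHECKPOINT_VERSION}"
            )
        return payload


def predict_with_checkpoint(payload: dict, matrix: FeatureMatrix,
                            threshold: float = 0.5) -> pd.DataFrame:
    """Score loci with a loaded checkpoint, enforcing the feature schema."""
    names = [str(c) for c in matrix.data.columns]
    if names != list(payload["feature_names"]):
        raise SchemaError("feature columns do not match the checkpoint schema")
    proba = payload["estimator"].predict_proba(matrix.X)[:, 1]
    loci = matrix.loci
    return pd.DataFrame({
        "chrom": [l.chrom for l in loci],
        "start": [l.start for l in loci],
        "end": [l.end for l in loci],
        "probability": proba,
        "call": (proba > threshold).astype(int),
    })
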
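"""Classification metrics and cross-validated reports.

Accuracy is the fraction of exact matches (the multi-class reading of
(TP+TN)/(TP+TN+FP+FN)); F1 per class is the one-vs-rest 2TP/(2TP+FP+FN),
reported per class and as an unweighted macro average.  Confusion matrices
put true classes on rows and predictions on columns; row normalization
divides by the row total, so the diagonal holds per-class recall.
Cross-validation aggregates per-fold metrics by unweighted mean and also
reports their standard deviation across folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import classifiers
from .classifiers import ModelSpec, TrainConfig, TrainedModel
from .errors import DataError
from .features_fusion import FeatureDataset, kfold_split
from .phase_labeler import N_PHASES


def _check_pair(y_true, y_pred) -> tuple[np.ndarray, np.ndarray]:
    y_true = np.asarray(y_true, dtype=np.int64).ravel()
    y_pred = np.asarray(y_pred, dtype=np.int64).ravel()
    if y_true.size != y_pred.size:
        raise DataError(f"length mismatch: {y_true.size} true vs {y_pred.size} predicted")
    if y_true.size == 0:
        raise DataError("empty label vectors")
    for v in (y_true, y_pred):
        if v.min() < 0 or v.max() >= N_PHASES:
            raise DataError("labels must be phase codes 0..3")
    return y_true, y_pred


def accuracy(y_true, y_pred) -> float:
    """Fraction of samples whose predicted phase equals the true phase."""
    y_true, y_pred = _check_pair(y_true, y_pred)
    return float(np.mean(y_true == y_pred))


def f1_per_class(y_true, y_pred, cls: int) -> float:
    """One-vs-rest F1 = 2TP / (2TP + FP + FN); 0 when the denominator is 0."""
    y_true, y_pred = _check_pair(y_true, y_pred)
    if not 0 <= cls < N_PHASES:
        raise DataError(f"unknown class code {cls}")
    tp = int(np.sum((y_true == cls) & (y_pred == cls)))
    fp = int(np.sum((y_true != cls) & (y_pred == cls)))
    fn = int(np.sum((y_true == cls) & (y_pred != cls)))
    denom = 2 * tp + fp + fn
    if denom == 0:
        warnings.warn(f"class {cls} absent from truth and prediction; F1 := 0",
                      stacklevel=2)
        return 0.0
    return 2 * tp / denom


def macro_f1(y_true, y_pred) -> float:
    """Unweighted mean of the four per-class F1 scores."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(np.mean([f1_per_class(y_true, y_pred, c)
                              for c in range(N_PHASES)]))


def confusion_matrix(y_true, y_pred, normalize: str = "none") -> np.ndarray:
    """4x4 confusion counts (rows = true, columns = predicted).

    ``normalize="row"`` divides each row by its total; rows with no true
    samples stay all-zero.
    """
    y_true, y_pred = _check_pair(y_true, y_pred)
    counts = np.zeros((N_PHASES, N_PHASES), dtype=np.int64)
    np.add.at(counts, (y_true, y_pred), 1)
    if normalize == "none":
        return counts
    if normalize != "row":
        raise DataError(f"normalize must be 'row' or 'none', got {normalize!r}")
    totals = counts.sum(axis=1, keepdims=True)
    out = np.zeros_like(counts, dtype=float)
    np.divide(counts, totals, out=out, where=totals > 0)
    return out


@dataclass
class EvalReport:
    """Metrics of one evaluation (optionally aggregated over folds)."""

    accuracy: float
    per_class_f1: list[float]
    macro_f1: float
    confusion: np.ndarray           # row-normalized proportions
    counts: np.ndarray              # raw confusion counts
    n: int = 0
    accuracy_std: float | None = None
    macro_f1_std: float | None = None
    per_fold: list["EvalReport"] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "per_class_f1": [float(v) for v in self.per_class_f1],
            "macro_f1": self.macro_f1,
            "confusion_row_normalized": np.asarray(self.confusion).tolist(),
            "confusion_counts": np.asarray(self.counts).tolist(),
            "n": self.n,
        }
        if self.accuracy_std is not None:
            d["accuracy_std"] = self.accuracy_std
            d["macro_f1_std"] = self.macro_f1_std
        if self.per_fold:
            d["per_fold"] = [r.to_dict() for r in self.per_fold]
        return d


def evaluate_labels(y_true, y_pred) -> EvalReport:
    """Report from one pair of label vectors."""
    counts = confusion_matrix(y_true, y_pred, "none")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f1s = [f1_per_class(y_true, y_pred, c) for c in range(N_PHASES)]
    return EvalReport(
        accuracy=accuracy(y_true, y_pred),
        per_class_f1=f1s,
        macro_f1=float(np.mean(f1s)),
        confusion=confusion_matrix(y_true, y_pred, "row"),
        counts=counts,
        n=int(np.asarray(y_true).size),
    )


def evaluate_model(trained: TrainedModel, ds: FeatureDataset) -> EvalReport:
    y_pred, _ = classifiers.predict(trained, ds.images)
    return evaluate_labels(ds.labels, y_pred)


def crossval_report(spec: ModelSpec | str, ds: FeatureDataset, k: int = 5,
                    cfg: TrainConfig | None = None,
                    normalize: bool = True) -> EvalReport:
    """k-fold cross-validation: train on k-1 contiguous blocks, test on one.

    Aggregate accuracy and F1 are unweighted means over folds; their
    across-fold standard deviation quantifies stability.  The aggregate
    confusion matrices pool all folds' test predictions.
    """
    cfg = cfg or TrainConfig()
    folds = kfold_split(ds, k, normalize=normalize)
    reports = []
    pooled_counts = np.zeros((N_PHASES, N_PHASES), dtype=np.int64)
    for train_ds, test_ds in folds:
        model = classifiers.build_model(spec)
        trained = classifiers.train(model, train_ds, cfg)
        rep = evaluate_model(trained, test_ds)
        reports.append(rep)
        pooled_counts += rep.counts
    accs = np.array([r.accuracy for r in reports])
    f1s = np.array([r.macro_f1 for r in reports])
    totals = pooled_counts.sum(axis=1, keepdims=True)
    pooled_row = np.zeros_like(pooled_counts, dtype=float)
    np.divide(pooled_counts, totals, out=pooled_row, where=totals > 0)
    return EvalReport(
        accuracy=float(accs.mean()),
        per_class_f1=list(np.mean([r.per_class_f1 for r in reports], axis=0)),
        macro_f1=float(f1s.mean()),
        confusion=pooled_row,
        counts=pooled_counts,
        n=int(sum(r.n for r in reports)),
        accuracy_std=float(accs.std(ddof=0)),
        macro_f1_std=float(f1s.std(ddof=0)),
        per_fold=reports,
    )
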
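"""Maximum-margin relation classifiers and evaluation metrics.

One support-vector classifier per view: the graph view trains on a
precomputed kernel (Gram) matrix, the word-feature view on sparse
Boolean vectors with a linear kernel.  The signed decision margin is the
confidence score consumed by co-training's example selection.  Metrics
are precision / recall / F-score on the 0–100 scale and Cohen's kappa
for inter-annotator agreement.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import sparse
from sklearn.svm import SVC

__all__ = [
    "KernelModel",
    "EvalReport",
    "train",
    "predict_scores",
    "evaluate",
    "f_score_from_pr",
    "cohens_kappa",
]

VIEWS = ("word_features", "graph_kernel")


@dataclass
class KernelModel:
    view: str
    C: float
    svc: SVC
    n_train: int

    def save(self, path: str | Path) -> None:
        Path(path).write_bytes(pickle.dumps(self))

    @classmethod
    def load(cls, path: str | Path) -> "KernelModel":
        model = pickle.loads(Path(path).read_bytes())
        if not isinstance(model, cls):
            raise TypeError(f"{path} does not contain a KernelModel")
        return model


def _is_gram(view_data) -> bool:
    return (
        isinstance(view_data, np.ndarray)
        and view_data.ndim == 2
        and view_data.shape[0] == view_data.shape[1]
    )


def train(view_data, labels: Sequence[int], C: float = 1.0,
          view: str | None = None) -> KernelModel:
    """Fit an SVM on one view.

    ``view_data`` is either a square Gram matrix (graph view, precomputed
    kernel) or a 2-D array / sparse matrix of feature rows (word view,
    linear kernel).  Labels are ±1; single-class input is a hard error.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training requires at least one example of each class")
    if view is None:
        gram = _is_gram(view_data) and not sparse.issparse(view_data)
        view = "graph_kernel" if gram else "word_features"
    elif view == "graph_kernel":
        gram = True
    elif view == "word_features":
        gram = False
    else:
        raise ValueError(f"unknown view {view!r}")
    svc = SVC(kernel="precomputed" if gram else "linear", C=C)
    svc.fit(view_data, y)
    return KernelModel(view=view, C=C, svc=svc, n_train=view_data.shape[0])


def predict_scores(model: KernelModel, instances) -> np.ndarray:
    """Signed decision margins; ordering defines selection confidence.

    For a precomputed-kernel model, ``instances`` must be the cross-kernel
    matrix of shape (n_instances, n_train).
    """
    if model.svc.kernel == "precomputed":
        inst = np.asarray(instances)
        if inst.ndim != 2 or inst.shape[1] != model.n_train:
            raise ValueError(
                f"view mismatch: precomputed-kernel model expects a cross-"
                f"kernel matrix with {model.n_train} columns"
            )
    return np.asarray(model.svc.decision_function(instances), dtype=float)


@dataclass(frozen=True)
class EvalReport:
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    f_score: float

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "precision": self.precision, "recall": self.recall,
            "f_score": self.f_score,
        }

    def __str__(self) -> str:
        return (
            f"P={self.precision:.2f}% R={self.recall:.2f}% "
            f"F={self.f_score:.2f}% (TP={self.tp} FP={self.fp} "
            f"FN={self.fn} TN={self.tn})"
        )


def f_score_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (percent scale); 0 if both 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def evaluate(predictions: Sequence[int], gold: Sequence[int]) -> EvalReport:
    """Count-based precision/recall/F on the 0–100 scale (labels ±1)."""
    pred = np.asarray(predictions)
    y = np.asarray(gold)
    if pred.shape != y.shape:
        raise ValueError(
            f"length mismatch: {pred.shape[0]} predictions vs {y.shape[0]} gold"
        )
    tp = int(np.sum((pred > 0) & (y > 0)))
    fp = int(np.sum((pred > 0) & (y <= 0)))
    fn = int(np.sum((pred <= 0) & (y > 0)))
    tn = int(np.sum((pred <= 0) & (y <= 0)))
    p = 100.0 * tp / (tp + fp) if tp + fp else 0.0
    r = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    return EvalReport(tp, fp, fn, tn, p, r, f_score_from_pr(p, r))


def cohens_kappa(table) -> float:
    """Cohen's kappa for a 2×2 agreement table.

    ``table`` is (a, b, c, d) row-major or a 2×2 array: rows one
    annotator, columns the other.  κ = (p_o − p_e) / (1 − p_e) with
    chance agreement p_e from the marginal products.  Perfect observed
    agreement returns 1 even at degenerate marginals; p_e = 1 without
    perfect agreement is undefined.
    """
    t = np.asarray(table, dtype=float).reshape(2, 2)
    if np.any(t < 0):
        raise ValueError("agreement counts must be nonnegative")
    total = t.sum()
    if total == 0:
        raise ValueError("agreement table is empty")
    p_o = (t[0, 0] + t[1, 1]) / total
    row = t.sum(axis=1) / total
    col = t.sum(axis=0) / total
    p_e = float(row @ col)
    if p_e >= 1.0:
        if p_o == 1.0:
            return 1.0
        raise ValueError("chance agreement is 1 with imperfect observed agreement")
    return float((p_o - p_e) / (1.0 - p_e))
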
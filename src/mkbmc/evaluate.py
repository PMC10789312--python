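"""Evaluation metrics and cross-validation splitting."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

__all__ = ["EvalReport", "auc", "sens_spec", "stratified_folds", "evaluate_scores"]


@dataclass
class EvalReport:
    auc: float
    sensitivity: float
    specificity: float
    cutoff: float
    n: int
    scores: list = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "cutoff": self.cutoff,
            "n": self.n,
        }


def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC; tied scores count 1/2."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes present")
    r = rankdata(s)
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def sens_spec(probs, labels, cutoff: float = 0.5) -> tuple[float, float]:
    """Sensitivity and specificity classifying prob >= cutoff as case."""
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels).astype(int)
    pred = (p >= cutoff).astype(int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        warnings.warn("single-class labels: undefined rate reported as NaN")
    sens = float((pred[y == 1] == 1).sum() / n1) if n1 else float("nan")
    spec = float((pred[y == 0] == 0).sum() / n0) if n0 else float("nan")
    return sens, spec


def stratified_folds(labels, k: int, seed: int = 0) -> np.ndarray:
    """Assign each sample a fold id in 0..k-1, stratified by class.

    Deterministic given *seed*; class proportions per fold are within one
    sample of the overall proportions.
    """
    y = np.asarray(labels).astype(int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"each class needs >= {k} members for {k}-fold stratified CV "
            f"(class counts: {counts.tolist()})"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed))
    folds = np.empty(len(y), dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        folds[test_idx] = f
    return folds


def evaluate_scores(probs, labels, cutoff: float = 0.5) -> EvalReport:
    sens, spec = sens_spec(probs, labels, cutoff)
    return EvalReport(
        auc=auc(probs, labels),
        sensitivity=sens,
        specificity=spec,
        cutoff=cutoff,
        n=len(np.asarray(labels)),
        scores=list(np.asarray(probs, dtype=float)),
    )
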
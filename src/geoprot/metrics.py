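"""Evaluation metrics for protein property prediction.

Multi-label tasks are scored with micro-averaged AUPR (pooling all
(protein, label) decisions), per-label AUPR, and the protein-centric Fmax
used by CAFA: the maximum over score thresholds of the F1 computed from
precision averaged over proteins with at least one predicted label at that
threshold and recall averaged over all proteins. Regression tasks are scored
with Spearman's rank correlation (average ranks on ties).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score


def compute_label_weights(labels: np.ndarray) -> np.ndarray:
    """Per-label loss weights from inverse positive-instance frequency.

    ``w_j = max(1, min(10, sum_i N_i^+ / (l * N_j^+)))`` for an (N, l)
    binary label matrix; a label with no positives gets the clamp limit 10
    with a warning.
    """
    labels = np.asarray(labels, dtype=np.float64)
    if labels.ndim != 2:
        raise ValueError("expected an (N, l) binary label matrix")
    if np.any((labels != 0) & (labels != 1)):
        raise ValueError("labels must be binary")
    n_pos = labels.sum(axis=0)
    l = labels.shape[1]
    total = n_pos.sum()
    w = np.full(l, 10.0)
    has_pos = n_pos > 0
    if not has_pos.all():
        warnings.warn("label(s) with zero positives get the clamp weight 10",
                      stacklevel=2)
    w[has_pos] = np.clip(total / (l * n_pos[has_pos]), 1.0, 10.0)
    return w


def micro_aupr(y_true: np.ndarray, y_score: np.ndarray) -> float:
    """AUPR over all (protein, label) pairs pooled together."""
    y_true = np.asarray(y_true).reshape(-1)
    y_score = np.asarray(y_score).reshape(-1)
    return float(average_precision_score(y_true, y_score))


def per_label_aupr(y_true: np.ndarray, y_score: np.ndarray) -> np.ndarray:
    """AUPR per label; NaN for labels without positives."""
    y_true = np.atleast_2d(np.asarray(y_true, dtype=float))
    y_score = np.atleast_2d(np.asarray(y_score, dtype=float))
    out = np.full(y_true.shape[1], np.nan)
    for j in range(y_true.shape[1]):
        if y_true[:, j].sum() > 0:
            out[j] = average_precision_score(y_true[:, j], y_score[:, j])
    return out


def protein_centric_fmax(y_true: np.ndarray, y_score: np.ndarray) -> float:
    """CAFA protein-centric Fmax.

    At each threshold tau (all distinct scores plus 0 and 1): precision is
    averaged over proteins with >= 1 predicted label at tau, recall over all
    proteins with >= 1 true label; Fmax is the maximum harmonic mean.
    """
    y_true = np.atleast_2d(np.asarray(y_true, dtype=float))
    y_score = np.atleast_2d(np.asarray(y_score, dtype=float))
    annotated = y_true.sum(axis=1) > 0
    if not annotated.any():
        raise ValueError("no annotated proteins")
    thresholds = np.unique(np.concatenate([y_score.reshape(-1), [0.0, 1.0]]))
    best = 0.0
    for tau in thresholds:
        pred = y_score >= tau
        n_pred = pred.sum(axis=1)
        covered = n_pred > 0
        if not covered.any():
            continue
        tp = (pred & (y_true > 0)).sum(axis=1).astype(float)
        precision = float(np.mean(tp[covered] / n_pred[covered]))
        recall = float(np.mean(
            tp[annotated] / y_true[annotated].sum(axis=1)))
        if precision + recall > 0:
            best = max(best, 2 * precision * recall / (precision + recall))
    return best


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation with average ranks on ties.

    Returns NaN (with a warning) when either input is constant, where the
    coefficient is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("Spearman rho undefined for constant input", stacklevel=2)
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def evaluate(predictions: np.ndarray, labels: np.ndarray, task_kind: str) -> dict:
    """Metric table for one prediction set.

    multilabel -> ``micro_aupr``, ``per_label_aupr``, ``fmax`` (predictions
    must be probabilities in [0, 1]); regression -> ``spearman_rho``.
    """
    predictions = np.asarray(predictions, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if task_kind == "multilabel":
        if predictions.min() < 0 or predictions.max() > 1:
            raise ValueError("multilabel predictions must be probabilities in [0, 1]")
        return {
            "micro_aupr": micro_aupr(labels, predictions),
            "per_label_aupr": per_label_aupr(labels, predictions),
            "fmax": protein_centric_fmax(labels, predictions),
        }
    if task_kind == "regression":
        return {"spearman_rho": spearman_rho(predictions.reshape(-1),
                                             labels.reshape(-1))}
    raise ValueError(f"unknown task kind {task_kind!r}")
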
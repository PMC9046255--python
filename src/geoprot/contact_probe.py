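"""Probing language-model attention maps for residue-residue contacts.

Ground truth: two residues are in contact when their CA atoms are within a
distance threshold (default 10 A) and they are at least ``min_sep`` (default
6) positions apart in sequence, which excludes trivially local contacts.
Features: for each eligible pair (i < j), one feature per (layer, head) of
the model's self-attention — the symmetrized value (A[i,j] + A[j,i]) / 2
(optionally with average-product correction). Probe: L1-penalised logistic
regression over pairs pooled across training proteins, with the penalty
strength chosen on a held-out split by log-loss. Evaluation: precision over
the top-L ranked pairs of a test protein (L = protein length).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import train_test_split

from .lm import AttentionMaps
from .structure_io import BackboneStructure

CONTACT_THRESHOLD = 10.0
MIN_SEPARATION = 6


@dataclass
class ContactMap:
    """Symmetric binary contact matrix with its defining parameters."""

    matrix: np.ndarray
    threshold: float = CONTACT_THRESHOLD
    min_separation: int = MIN_SEPARATION

    def __post_init__(self):
        m = np.asarray(self.matrix)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("contact map must be square")
        if not np.array_equal(m, m.T):
            raise ValueError("contact map must be symmetric")
        self.matrix = m.astype(int)

    @property
    def length(self):
        return self.matrix.shape[0]


@dataclass
class PairFeatureTable:
    """Per-pair attention features with optional contact labels."""

    pairs: np.ndarray           # (m, 2) with i < j, j - i >= min_separation
    features: np.ndarray        # (m, layers * heads)
    labels: np.ndarray | None = None
    length: int = 0
    feature_names: list[str] = field(default_factory=list)


def true_contacts(struct: BackboneStructure, threshold: float = CONTACT_THRESHOLD,
                  min_sep: int = MIN_SEPARATION) -> ContactMap:
    """Contacts from CA coordinates: ``d(i,j) <= threshold`` and ``|i-j| >= min_sep``."""
    ca = struct.coords_CA
    L = len(ca)
    if L < min_sep + 1:
        raise ValueError(f"chain too short for separation {min_sep}")
    d = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=-1)
    sep = np.abs(np.arange(L)[:, None] - np.arange(L)[None, :])
    return ContactMap(matrix=((d <= threshold) & (sep >= min_sep)).astype(int),
                      threshold=threshold, min_separation=min_sep)


def eligible_pairs(L: int, min_sep: int = MIN_SEPARATION) -> np.ndarray:
    """All (i, j) with i < j and j - i >= min_sep, row-major order."""
    i, j = np.triu_indices(L, k=min_sep)
    return np.stack([i, j], axis=1)


def attention_pair_features(maps: AttentionMaps, contact_map: ContactMap | None = None,
                            min_sep: int = MIN_SEPARATION,
                            apc: bool = False) -> PairFeatureTable:
    """Symmetrized per-pair attention features, one column per (layer, head).

    ``apc=True`` applies the average-product correction to each map before
    symmetrization (off by default).
    """
    L = maps.length
    if contact_map is not None and contact_map.length != L:
        raise ValueError(
            f"attention maps for {L} residues but contact map for "
            f"{contact_map.length}")
    pairs = eligible_pairs(L, min_sep)
    a = maps.maps.reshape(-1, L, L)
    if apc:
        a = a - (a.sum(1, keepdims=True) * a.sum(2, keepdims=True)
                 / a.sum((1, 2), keepdims=True))
    sym = 0.5 * (a + np.transpose(a, (0, 2, 1)))
    features = sym[:, pairs[:, 0], pairs[:, 1]].T  # (m, layers*heads)
    names = [f"L{l}H{h}" for l in range(maps.n_layers) for h in range(maps.n_heads)]
    labels = None
    if contact_map is not None:
        labels = contact_map.matrix[pairs[:, 0], pairs[:, 1]]
    return PairFeatureTable(pairs=pairs, features=features, labels=labels,
                            length=L, feature_names=names)


def pair_dataset(lm, structures: list[BackboneStructure],
                 min_sep: int = MIN_SEPARATION, apc: bool = False,
                 threshold: float = CONTACT_THRESHOLD) -> list[PairFeatureTable]:
    """Attention features + contact labels for a set of proteins."""
    tables = []
    for s in structures:
        cmap = true_contacts(s, threshold=threshold, min_sep=min_sep)
        tables.append(attention_pair_features(
            lm.attention_maps(s.aa_sequence), cmap, min_sep=min_sep, apc=apc))
    return tables


class AttentionContactProbe(BaseEstimator):
    """L1-penalised logistic regression from attention features to contacts.

    Pairs are pooled across training proteins; the inverse penalty strength
    C is selected from ``c_grid`` by log-loss on an internal held-out split
    of the pooled pairs. C is interpreted against the per-sample-averaged
    loss (the solver's C is divided by the number of training rows), so
    duplicating every training row leaves the solution unchanged. The
    liblinear solver at tolerance 1e-6 with a fixed seed makes the fit
    deterministic.
    """

    def __init__(self, c_grid: tuple = (1.0, 10.0, 100.0, 1000.0), tol: float = 1e-6,
                 holdout_fraction: float = 0.25, seed: int = 0):
        self.c_grid = c_grid
        self.tol = tol
        self.holdout_fraction = holdout_fraction
        self.seed = seed

    def fit(self, tables: list[PairFeatureTable] | np.ndarray, y=None):
        if isinstance(tables, (list, tuple)) and isinstance(tables[0], PairFeatureTable):
            X = np.concatenate([t.features for t in tables], axis=0)
            y = np.concatenate([t.labels for t in tables])
        else:
            X = np.asarray(tables, dtype=float)
            y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("training pairs contain a single class")
        X_tr, X_ho, y_tr, y_ho = train_test_split(
            X, y, test_size=self.holdout_fraction, random_state=self.seed,
            stratify=y)
        best = (np.inf, None, None)
        for C in self.c_grid:
            clf = LogisticRegression(l1_ratio=1.0, C=C / len(y_tr),
                                     solver="liblinear", tol=self.tol,
                                     random_state=self.seed, max_iter=2000)
            clf.fit(X_tr, y_tr)
            ll = log_loss(y_ho, clf.predict_proba(X_ho)[:, 1], labels=[0, 1])
            if ll < best[0]:
                best = (ll, C, clf)
        self.best_C_ = best[1]
        self.holdout_log_loss_ = best[0]
        clf = LogisticRegression(l1_ratio=1.0, C=self.best_C_ / len(y),
                                 solver="liblinear", tol=self.tol,
                                 random_state=self.seed, max_iter=2000)
        clf.fit(X, y)
        self.classifier_ = clf
        self.coef_ = clf.coef_[0]
        self.intercept_ = float(clf.intercept_[0])
        return self

    def predict_proba_pairs(self, table: PairFeatureTable) -> np.ndarray:
        if not hasattr(self, "classifier_"):
            raise RuntimeError("probe is not fitted")
        return self.classifier_.predict_proba(table.features)[:, 1]

    def predict(self, X) -> np.ndarray:
        return self.classifier_.predict(np.asarray(X, dtype=float))

    def score(self, X, y) -> float:
        return float(self.classifier_.score(np.asarray(X, dtype=float), y))


def fit_contact_probe(tables: list[PairFeatureTable],
                      l1_strength: float | None = None,
                      seed: int = 0) -> AttentionContactProbe:
    """Functional wrapper: fit the probe on pooled pair tables.

    ``l1_strength`` fixes the inverse penalty C; ``None`` selects it from
    the default grid by held-out log-loss.
    """
    grid = (l1_strength,) if l1_strength is not None else (1.0, 10.0, 100.0, 1000.0)
    return AttentionContactProbe(c_grid=grid, seed=seed).fit(tables)


def probe_precision(probe: AttentionContactProbe, table: PairFeatureTable,
                    mode: str = "precision_at_L") -> float:
    """Precision of the probe's top-ranked pairs against true contacts.

    ``precision_at_L`` ranks eligible pairs by predicted probability and
    scores the fraction of true contacts among the top ``L`` pairs, where L
    is the protein length; with fewer than L eligible pairs all are used
    (flagged with a warning).
    """
    if mode != "precision_at_L":
        raise ValueError(f"unknown mode {mode!r}")
    if table.labels is None:
        raise ValueError("table has no contact labels")
    if table.labels.sum() == 0:
        warnings.warn("empty contact map: precision is 0", stacklevel=2)
        return 0.0
    probs = probe.predict_proba_pairs(table)
    L = table.length
    if len(probs) < L:
        warnings.warn(
            f"only {len(probs)} eligible pairs for length {L}; using all",
            stacklevel=2)
        top = np.argsort(-probs, kind="stable")
    else:
        top = np.argsort(-probs, kind="stable")[:L]
    return float(table.labels[top].mean())


def precision_from_scores(scores: np.ndarray, table: PairFeatureTable) -> float:
    """Precision@L for externally supplied pair scores (oracle/testing path)."""
    L = table.length
    top = np.argsort(-np.asarray(scores, dtype=float), kind="stable")[:L]
    return float(table.labels[top].mean())


def compare_precisions_wilcoxon(a: np.ndarray, b: np.ndarray):
    """Wilcoxon signed-rank test between paired per-protein precisions."""
    return stats.wilcoxon(np.asarray(a, float), np.asarray(b, float))
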
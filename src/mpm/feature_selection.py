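"""Ontology-supervised PCG filtering: category labels + ReliefF.

The side task is disease-category prediction: each disease receives a label
derived from its ontology tree code (second-level prefix inside the
infection branch, first-level elsewhere; rare categories collapse into
"Others").  ReliefF then scores each PCG feature of the enriched disease
profile matrix by how well it separates nearest same-category neighbours
(hits) from nearest other-category neighbours (misses), and the top-K PCGs
are kept for the downstream heterogeneous network.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .entities_io import OntologyTree

OTHERS_LABEL = "Others"
#: top-level tree codes treated as the infection branch (second-level labels)
INFECTION_TOP_LEVELS: tuple[str, ...] = ("C01",)


@dataclass
class CategoryLabeling:
    """disease_id -> category label (total over the given diseases)."""

    labels: dict[str, str]

    def sizes(self) -> dict[str, int]:
        return dict(Counter(self.labels.values()))

    def label_array(self, disease_ids: list[str]) -> np.ndarray:
        return np.array([self.labels[d] for d in disease_ids])


def assign_disease_categories(tree: OntologyTree, diseases,
                              infection_top_levels=INFECTION_TOP_LEVELS,
                              ) -> CategoryLabeling:
    """Label each disease by its tree-code prefix.

    The label is the two-segment prefix when the top-level code belongs to
    the infection branch, the one-segment prefix otherwise.  A disease with
    several codes takes the label of its lexicographically smallest code;
    diseases absent from the ontology get the reserved "Others" label.
    """
    labels = {}
    for d in diseases:
        codes = tree.codes(d)
        if not codes:
            labels[d] = OTHERS_LABEL
            continue
        code = codes[0]  # lexicographically smallest
        segments = code.split(".")
        if segments[0] in infection_top_levels and len(segments) >= 2:
            labels[d] = ".".join(segments[:2])
        else:
            labels[d] = segments[0]
    return CategoryLabeling(labels)


def collapse_rare_categories(labeling: CategoryLabeling,
                             min_size: int = 10) -> CategoryLabeling:
    """Relabel every category with fewer than ``min_size`` members as "Others"."""
    sizes = labeling.sizes()
    rare = {cat for cat, n in sizes.items() if n < min_size}
    return CategoryLabeling({
        d: (OTHERS_LABEL if cat in rare else cat)
        for d, cat in labeling.labels.items()
    })


@dataclass
class ImportanceVector:
    """Per-feature ReliefF weight and the induced ranking.

    ``ranking`` sorts features by weight descending with a stable
    ascending-index tie-break.
    """

    weights: np.ndarray
    ranking: np.ndarray

    @classmethod
    def from_weights(cls, weights: np.ndarray) -> "ImportanceVector":
        weights = np.asarray(weights, dtype=float)
        return cls(weights=weights, ranking=np.argsort(-weights, kind="stable"))


def relieff_importance(X: np.ndarray, y, k_neighbors: int = 10,
                       n_samples: int | None = None,
                       seed: int | None = None) -> ImportanceVector:
    """Multiclass ReliefF feature importance.

    For each evaluated instance R the k nearest hits (same class) and, per
    other class C, the k nearest misses are found under Manhattan distance
    on range-normalised features.  Weights are decreased by hit diffs and
    increased by prior-weighted miss diffs; with all instances evaluated
    (the default) the estimate is deterministic, ties resolving to the
    smaller sample index.  Classes smaller than ``k_neighbors + 1`` use all
    their available neighbours, normalising by the actual count.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.size == 0:
        raise ValueError("X must be a non-empty 2-d matrix")
    n, p = X.shape
    classes, y_idx = np.unique(y, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("ReliefF requires at least two classes")

    if n_samples is None or n_samples >= n:
        sample_idx = np.arange(n)
    else:
        rng = np.random.default_rng(seed)
        sample_idx = rng.choice(n, size=n_samples, replace=False)
    n_used = len(sample_idx)

    span = X.max(axis=0) - X.min(axis=0)
    safe = np.where(span > 0, span, 1.0)
    Xn = (X - X.min(axis=0)) / safe
    Xn[:, span == 0] = 0.0  # constant features contribute diff 0

    dist = cdist(Xn, Xn, metric="cityblock")
    priors = np.bincount(y_idx, minlength=len(classes)) / n

    W = np.zeros(p)
    k = k_neighbors
    for r in sample_idx:
        order = np.argsort(dist[r], kind="stable")  # ties -> smaller index
        cls_r = y_idx[r]
        hits = order[(y_idx[order] == cls_r) & (order != r)][:k]
        if len(hits):
            W -= np.abs(Xn[hits] - Xn[r]).sum(axis=0) / (n_used * len(hits))
        for c in range(len(classes)):
            if c == cls_r:
                continue
            misses = order[y_idx[order] == c][:k]
            if len(misses):
                factor = priors[c] / (1.0 - priors[cls_r])
                W += factor * np.abs(Xn[misses] - Xn[r]).sum(axis=0) / (n_used * len(misses))
    return ImportanceVector.from_weights(W)


def select_top_pcgs(importance: ImportanceVector, K: int = 100) -> np.ndarray:
    """The K highest-ranked feature indices, in rank order."""
    p = len(importance.weights)
    if K > p:
        raise ValueError(f"K={K} exceeds the number of PCG features ({p})")
    return importance.ranking[:K].copy()
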
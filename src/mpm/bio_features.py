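"""Biological side features: miRNA family one-hot and disease semantic similarity.

Disease semantic similarity follows the Wang measure on the positional
disease ontology.  An ancestor ``t`` of disease ``d`` contributes

    D_d(d) = 1,   D_d(t) = max_{t' child of t on a path to d} delta * D_d(t')

(i.e. delta^k for an ancestor k levels up, maximised over tree positions),
and two diseases are compared through their shared ancestors:

    sim(d1, d2) = sum_{t in T1 ∩ T2} (D_d1(t) + D_d2(t)) / (DV(d1) + DV(d2)),

with DV(d) = sum_{t in T_d} D_d(t).  The contribution factor delta defaults
to 0.5, the standard choice for this measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .entities_io import FamilyMap, OntologyTree, UNKNOWN_FAMILY, code_prefixes

DEFAULT_DELTA = 0.5


def contribution_map(tree: OntologyTree, disease: str,
                     delta: float = DEFAULT_DELTA) -> dict[str, float]:
    """Semantic contribution D_d(t) for every ancestor-or-self node t of d.

    Multi-position diseases take the maximum over their tree codes.
    """
    contrib: dict[str, float] = {disease: 1.0}
    for code in tree.codes(disease):
        prefixes = code_prefixes(code)
        depth = len(prefixes)
        for level, prefix in enumerate(prefixes):
            node = tree.code_to_node.get(prefix, prefix)
            value = delta ** (depth - 1 - level)
            contrib[node] = max(contrib.get(node, 0.0), value)
    return contrib


def semantic_contribution(tree: OntologyTree, disease: str, ancestor: str,
                          delta: float = DEFAULT_DELTA) -> float:
    """D_d(ancestor); raises if ``ancestor`` is not an ancestor-or-self of d."""
    contrib = contribution_map(tree, disease, delta)
    if ancestor not in contrib:
        raise ValueError(f"{ancestor!r} is not an ancestor of {disease!r}")
    return contrib[ancestor]


def semantic_similarity(tree: OntologyTree, d1: str, d2: str,
                        delta: float = DEFAULT_DELTA) -> float:
    """Wang similarity in [0, 1]; symmetric; 1 on the diagonal.

    A disease missing from the ontology is similar only to itself.
    """
    if d1 == d2:
        return 1.0
    if d1 not in tree or d2 not in tree:
        return 0.0
    c1 = contribution_map(tree, d1, delta)
    c2 = contribution_map(tree, d2, delta)
    shared = set(c1) & set(c2)
    if not shared:
        return 0.0
    dv = sum(c1.values()) + sum(c2.values())
    return sum(c1[t] + c2[t] for t in shared) / dv


@dataclass
class SemanticSimilarityMatrix:
    """Similarity rows over a fixed training disease set.

    A disease's feature vector is its similarity to each training disease,
    so an unseen disease still gets features from its ontology position.
    """

    tree: OntologyTree
    disease_ids: list[str]
    delta: float = DEFAULT_DELTA
    matrix: np.ndarray = field(default=None)

    @classmethod
    def fit(cls, tree: OntologyTree, disease_ids,
            delta: float = DEFAULT_DELTA) -> "SemanticSimilarityMatrix":
        disease_ids = list(disease_ids)
        n = len(disease_ids)
        m = np.eye(n)
        maps = {d: contribution_map(tree, d, delta) if d in tree else {d: 1.0}
                for d in disease_ids}
        dvs = {d: sum(c.values()) for d, c in maps.items()}
        for i, a in enumerate(disease_ids):
            for j in range(i + 1, n):
                b = disease_ids[j]
                shared = set(maps[a]) & set(maps[b])
                if shared and a in tree and b in tree:
                    sim = sum(maps[a][t] + maps[b][t] for t in shared) / (dvs[a] + dvs[b])
                else:
                    sim = 0.0
                m[i, j] = m[j, i] = sim
        return cls(tree=tree, disease_ids=disease_ids, delta=delta, matrix=m)

    @property
    def dim(self) -> int:
        return len(self.disease_ids)

    def row(self, disease_id: str) -> np.ndarray:
        """Similarity of ``disease_id`` to each training disease."""
        if disease_id in self.disease_ids:
            return self.matrix[self.disease_ids.index(disease_id)]
        return np.array([semantic_similarity(self.tree, disease_id, d, self.delta)
                         for d in self.disease_ids])


@dataclass
class FamilyEncoder:
    """One-hot family features with a fixed vocabulary and an "unknown" column."""

    families: list[str]
    _index: dict[str, int] = field(default=None, repr=False)

    def __post_init__(self):
        if self._index is None:
            self._index = {f: i for i, f in enumerate(self.families)}

    @classmethod
    def fit(cls, family_map: FamilyMap, training_mirnas) -> "FamilyEncoder":
        vocab = sorted({family_map.family(m) for m in training_mirnas})
        if UNKNOWN_FAMILY not in vocab:
            vocab.append(UNKNOWN_FAMILY)
        return cls(families=vocab)

    @property
    def dim(self) -> int:
        return len(self.families)

    def encode(self, family_map: FamilyMap, mirna_id: str) -> np.ndarray:
        """Indicator row; families outside the vocabulary map to "unknown"."""
        fam = family_map.family(mirna_id)
        col = self._index.get(fam, self._index[UNKNOWN_FAMILY])
        v = np.zeros(self.dim)
        v[col] = 1.0
        return v


def family_one_hot(family_map: FamilyMap, mirna_id: str,
                   encoder: FamilyEncoder) -> np.ndarray:
    return encoder.encode(family_map, mirna_id)
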
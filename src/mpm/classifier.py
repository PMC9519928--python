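"""Pair feature assembly and the Random Forest association classifier.

A miRNA-disease pair (m, d) is represented as the concatenation

    X_md = [E_m | E_d | F_m | S_d]

of the two structural embeddings (zero vectors for entities absent from the
training network), the miRNA family one-hot F_m and the disease semantic
similarity row S_d.  A Random Forest with 350 trees maps X_md to an
association probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .bio_features import FamilyEncoder, SemanticSimilarityMatrix
from .entities_io import EntityRegistry, FamilyMap
from .hetnet import EmbeddingMatrix

Pair = tuple[str, str]


@dataclass
class PairFeaturizer:
    """Bundles the four fitted feature sources behind one callable."""

    embeddings: EmbeddingMatrix
    family_map: FamilyMap
    family_encoder: FamilyEncoder
    similarity: SemanticSimilarityMatrix
    mirna_registry: EntityRegistry
    disease_registry: EntityRegistry

    @property
    def dim(self) -> int:
        return 2 * self.embeddings.dim + self.family_encoder.dim + self.similarity.dim

    def features(self, mirna_id: str, disease_id: str) -> np.ndarray:
        return assemble_pair_features(
            mirna_id, disease_id, self.embeddings, self.family_map,
            self.family_encoder, self.similarity,
            self.mirna_registry, self.disease_registry)

    def matrix(self, pairs) -> np.ndarray:
        return np.array([self.features(m, d) for m, d in pairs])


def assemble_pair_features(mirna_id: str, disease_id: str,
                           embeddings: EmbeddingMatrix,
                           family_map: FamilyMap,
                           family_encoder: FamilyEncoder,
                           similarity: SemanticSimilarityMatrix,
                           mirna_registry: EntityRegistry,
                           disease_registry: EntityRegistry) -> np.ndarray:
    """X_md = [E_m, E_d, F_m, S_d] in that block order."""
    if mirna_id not in mirna_registry:
        raise KeyError(f"unregistered miRNA: {mirna_id!r}")
    if disease_id not in disease_registry:
        raise KeyError(f"unregistered disease: {disease_id!r}")
    e_m = embeddings.vector(mirna_id)
    e_d = embeddings.vector(disease_id)
    f_m = family_encoder.encode(family_map, mirna_id)
    s_d = similarity.row(disease_id)
    return np.concatenate([e_m, e_d, f_m, s_d])


def sample_training_negatives(known_pairs, all_mirnas, all_diseases,
                              ratio: int = 1, seed: int = 0) -> list[Pair]:
    """Uniform unknown pairs, |negatives| = ratio * |known_pairs|, seeded."""
    known = set(known_pairs)
    candidates = [(m, d) for m in sorted(all_mirnas) for d in sorted(all_diseases)
                  if (m, d) not in known]
    need = ratio * len(known)
    if len(candidates) < need:
        raise ValueError(f"need {need} negatives, only {len(candidates)} unknown pairs")
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(candidates), size=need, replace=False)
    return [candidates[i] for i in sorted(picked)]


@dataclass
class TrainedModel:
    forest: RandomForestClassifier
    n_features: int
    manifest: dict = field(default_factory=dict)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"expected feature vectors of length {self.n_features}, got {X.shape}")
        proba = self.forest.predict_proba(X)
        return proba[:, list(self.forest.classes_).index(1)]


def train_model(features: np.ndarray, labels, n_estimators: int = 350,
                seed: int = 0, manifest: dict | None = None) -> TrainedModel:
    """Fit the Random Forest; deterministic given the seed."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels must contain both classes")
    forest = RandomForestClassifier(n_estimators=n_estimators, random_state=seed,
                                    n_jobs=1)
    forest.fit(X, y)
    return TrainedModel(forest=forest, n_features=X.shape[1],
                        manifest=dict(manifest or {}, n_estimators=n_estimators,
                                      seed=seed))


def predict_scores(model: TrainedModel, pairs,
                   featurizer: PairFeaturizer | None = None,
                   X: np.ndarray | None = None) -> pd.DataFrame:
    """Association probabilities for each pair as a prediction table."""
    pairs = list(pairs)
    if X is None:
        if featurizer is None:
            raise ValueError("provide either a featurizer or a feature matrix")
        X = featurizer.matrix(pairs)
    scores = model.predict_proba(X)
    return pd.DataFrame({
        "miRNA_id": [m for m, _ in pairs],
        "disease_id": [d for _, d in pairs],
        "score": scores,
    })
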
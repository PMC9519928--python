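"""Heterogeneous miRNA-disease-PCG adjacency and SDNE structural embeddings.

The undirected network G_mdp stacks three node groups in the fixed order
[miRNAs | diseases | selected PCGs].  Its adjacency is the symmetric block
matrix

        [ 0      A_md   A_mp ]
        [ A_md'  0      A_dp ]
        [ A_mp'  A_dp'  A_p  ]

where A_md are the *training* miRNA-disease associations (weight 1), A_mp /
A_dp carry the enriched association weights, and A_p is the undirected 0/1
projection of the PCG interaction network restricted to the selected PCGs.

SDNE (structural deep network embedding) trains a deep autoencoder on the
adjacency rows.  The second-order loss reconstructs each row with observed
edges up-weighted by ``beta`` (neighbourhood / global structure); the
first-order loss pulls the codes of linked nodes together (local structure);
an L2 penalty regularises the weights:

    L = sum_i ||(x_hat_i - s_i) * b_i||^2
        + alpha * sum_{i<j} s_ij ||y_i - y_j||^2
        + nu * sum_W ||W||^2,      b_ij = beta if s_ij > 0 else 1.

The autoencoder here is a plain numpy MLP (sigmoid activations) trained with
hand-derived gradients and Adam; with a fixed seed the result is bitwise
reproducible.  Because the encoder is a deterministic function of the input
row, two nodes with identical adjacency rows always receive identical codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .entities_io import DirectedInteractionNetwork, EntityRegistry


# ---------------------------------------------------------------------------
# heterogeneous adjacency
# ---------------------------------------------------------------------------


@dataclass
class HeterogeneousAdjacency:
    matrix: np.ndarray
    node_ids: list[str]
    n_mirna: int
    n_disease: int
    n_pcg: int

    @property
    def mirna_slice(self) -> slice:
        return slice(0, self.n_mirna)

    @property
    def disease_slice(self) -> slice:
        return slice(self.n_mirna, self.n_mirna + self.n_disease)

    @property
    def pcg_slice(self) -> slice:
        return slice(self.n_mirna + self.n_disease, len(self.node_ids))


def build_heterogeneous_adjacency(
    train_pairs: set[tuple[str, str]],
    mirna_registry: EntityRegistry,
    disease_registry: EntityRegistry,
    W_mp: np.ndarray,
    W_dp: np.ndarray,
    pcg_net: DirectedInteractionNetwork,
    pk_ids: list[str],
    forbidden_pairs: set[tuple[str, str]] | None = None,
) -> HeterogeneousAdjacency:
    """Assemble the symmetric block adjacency over [miRNAs | diseases | P_K].

    ``W_mp`` / ``W_dp`` are enriched entity x PCG weight matrices over the
    full PCG registry; only the ``pk_ids`` columns enter the network.
    ``forbidden_pairs`` (e.g. the test associations of the current split)
    must not appear in ``train_pairs`` — leakage raises immediately.
    """
    if forbidden_pairs:
        leaked = set(train_pairs) & set(forbidden_pairs)
        if leaked:
            raise ValueError(f"test associations leaked into training network: "
                             f"{sorted(leaked)[:5]}")
    pk_idx = [pcg_net.pcg_registry.index(g) for g in pk_ids]  # KeyError if unknown
    n_m, n_d, n_p = len(mirna_registry), len(disease_registry), len(pk_idx)
    n = n_m + n_d + n_p
    a = np.zeros((n, n))

    for m, d in train_pairs:
        i = mirna_registry.index(m)
        j = n_m + disease_registry.index(d)
        a[i, j] = a[j, i] = 1.0

    mp = np.asarray(W_mp, dtype=float)[:, pk_idx]
    dp = np.asarray(W_dp, dtype=float)[:, pk_idx]
    a[:n_m, n_m + n_d:] = mp
    a[n_m + n_d:, :n_m] = mp.T
    a[n_m:n_m + n_d, n_m + n_d:] = dp
    a[n_m + n_d:, n_m:n_m + n_d] = dp.T

    a[n_m + n_d:, n_m + n_d:] = pcg_net.restricted_undirected(pk_idx)

    node_ids = mirna_registry.ids + disease_registry.ids + list(pk_ids)
    return HeterogeneousAdjacency(matrix=a, node_ids=node_ids,
                                  n_mirna=n_m, n_disease=n_d, n_pcg=n_p)


# ---------------------------------------------------------------------------
# SDNE
# ---------------------------------------------------------------------------


@dataclass
class SdneConfig:
    """SDNE hyperparameters (defaults follow the original SDNE practice)."""

    encoder_sizes: tuple[int, ...] = (1000, 128)
    alpha: float = 0.05          # first-order loss weight
    beta: float = 5.0            # reconstruction penalty for observed edges
    nu: float = 1e-4             # L2 weight regularisation
    epochs: int = 200
    batch_size: int = 256
    learning_rate: float = 1e-3
    seed: int = 0

    @property
    def embedding_dim(self) -> int:
        return self.encoder_sizes[-1]

    def validate(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1 (beta = 1 disables the edge penalty)")
        if not self.encoder_sizes or any(s <= 0 for s in self.encoder_sizes):
            raise ValueError("encoder sizes must be positive")
        for name in ("alpha", "nu"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("epochs", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


@dataclass
class EmbeddingMatrix:
    """Trained node codes; nodes absent from the network map to zeros."""

    node_ids: list[str]
    matrix: np.ndarray
    loss_history: list[float] = field(default_factory=list)
    _index: dict[str, int] = field(default=None, repr=False)

    def __post_init__(self):
        if self._index is None:
            self._index = {nid: i for i, nid in enumerate(self.node_ids)}

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    def vector(self, node_id: str) -> np.ndarray:
        i = self._index.get(node_id)
        if i is None:
            return np.zeros(self.dim)
        return self.matrix[i]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def train_sdne(adj: HeterogeneousAdjacency | np.ndarray,
               cfg: SdneConfig | None = None,
               node_ids: list[str] | None = None) -> EmbeddingMatrix:
    """Train the SDNE autoencoder on a symmetric adjacency; seeded, CPU-only."""
    cfg = cfg or SdneConfig()
    cfg.validate()
    if isinstance(adj, HeterogeneousAdjacency):
        s = adj.matrix
        node_ids = adj.node_ids
    else:
        s = np.asarray(adj, dtype=float)
        node_ids = node_ids if node_ids is not None else [str(i) for i in range(len(s))]
    if s.shape[0] != s.shape[1] or not np.allclose(s, s.T):
        raise ValueError("SDNE requires a symmetric adjacency matrix")
    n = s.shape[0]

    rng = np.random.default_rng(cfg.seed)
    sizes = [n, *cfg.encoder_sizes]          # encoder layers
    dims = list(zip(sizes[:-1], sizes[1:])) + [(cfg.embedding_dim, n)]  # + decoder
    weights, biases = [], []
    for fan_in, fan_out in dims:
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))

    adam_m = [np.zeros_like(w) for w in weights] + [np.zeros_like(b) for b in biases]
    adam_v = [np.zeros_like(w) for w in weights] + [np.zeros_like(b) for b in biases]
    b1, b2, eps = 0.9, 0.999, 1e-8
    step = 0

    def forward(x):
        acts = [x]
        for w, b in zip(weights, biases):
            acts.append(_sigmoid(acts[-1] @ w + b))
        return acts  # acts[-2] is the code y, acts[-1] the reconstruction

    loss_history: list[float] = []
    for epoch in range(cfg.epochs):
        perm = rng.permutation(n)
        epoch_data_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            x = s[idx]
            acts = forward(x)
            y, xhat = acts[-2], acts[-1]
            pen = np.where(x > 0, cfg.beta, 1.0)

            sb = s[np.ix_(idx, idx)]
            lap = np.diag(sb.sum(axis=1)) - sb

            l2nd = float((((xhat - x) * pen) ** 2).sum())
            l1st = float(np.trace(y.T @ lap @ y))
            epoch_data_loss += l2nd + cfg.alpha * l1st

            # backprop
            grads_w = [None] * len(weights)
            grads_b = [None] * len(biases)
            d_out = 2.0 * (xhat - x) * pen * pen            # dL2nd/dxhat
            delta = d_out * xhat * (1.0 - xhat)
            for layer in range(len(weights) - 1, -1, -1):
                grads_w[layer] = acts[layer].T @ delta + 2.0 * cfg.nu * weights[layer]
                grads_b[layer] = delta.sum(axis=0)
                if layer > 0:
                    d_prev = delta @ weights[layer].T
                    if layer == len(weights) - 1:           # entering the code layer
                        d_prev = d_prev + cfg.alpha * 2.0 * (lap @ y)
                    delta = d_prev * acts[layer] * (1.0 - acts[layer])

            step += 1
            params = weights + biases
            grads = grads_w + grads_b
            for i, (p, g) in enumerate(zip(params, grads)):
                adam_m[i] = b1 * adam_m[i] + (1 - b1) * g
                adam_v[i] = b2 * adam_v[i] + (1 - b2) * g * g
                m_hat = adam_m[i] / (1 - b1 ** step)
                v_hat = adam_v[i] / (1 - b2 ** step)
                p -= cfg.learning_rate * m_hat / (np.sqrt(v_hat) + eps)

        reg = cfg.nu * sum(float((w ** 2).sum()) for w in weights)
        total = epoch_data_loss + reg
        if not np.isfinite(total):
            raise RuntimeError(
                f"SDNE loss diverged (epoch {epoch + 1}/{cfg.epochs}, loss={total}); "
                "lower the learning rate or beta")
        loss_history.append(total)

    codes = forward(s)[-2]
    return EmbeddingMatrix(node_ids=list(node_ids), matrix=codes,
                           loss_history=loss_history)


def extract_pair_embeddings(embeddings: EmbeddingMatrix, mirna_id: str,
                            disease_id: str,
                            mirna_registry: EntityRegistry | None = None,
                            disease_registry: EntityRegistry | None = None,
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Codes for a miRNA-disease pair; zero vectors for nodes outside the network."""
    if mirna_registry is not None and mirna_id not in mirna_registry:
        raise KeyError(f"unknown miRNA id: {mirna_id!r}")
    if disease_registry is not None and disease_id not in disease_registry:
        raise KeyError(f"unknown disease id: {disease_id!r}")
    return embeddings.vector(mirna_id), embeddings.vector(disease_id)
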
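"""Degree-normalised message passing over the directed PCG network.

A miRNA's (or disease's) PCG association profile is a weight vector ``w``
over the PCG nodes.  Nodes with a known association keep their input weight;
a node ``i`` with no known association (initial weight 0) receives, at each
iteration,

    w_t(i) = d_in(i)^{-1/2} * sum_{j in Par(i)} w_{t-1}(j) / sqrt(d_out(j))

where ``Par(i)`` are the in-neighbours of ``i`` and the degrees are the
structural degrees of the full interaction network.  The update is
synchronous: every unknown node is recomputed from the complete previous
state, so previously inferred values are overwritten rather than frozen.
The propagation is parameter-free and linear in the weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .entities_io import DirectedInteractionNetwork


@dataclass
class WeightProfile:
    """Per-entity PCG weight vector with the known-association mask."""

    entity_id: str
    w: np.ndarray
    known_mask: np.ndarray

    @classmethod
    def from_weights(cls, entity_id: str, w) -> "WeightProfile":
        w = np.asarray(w, dtype=float)
        return cls(entity_id=entity_id, w=w, known_mask=w > 0)


def propagation_operator(net: DirectedInteractionNetwork) -> sparse.csr_matrix:
    """The linear one-step operator P with P[j, i] = (d_out(j) d_in(i))^(-1/2).

    For a row vector of weights w, one synchronous step over all nodes is
    ``w @ P``; the caller restores known entries afterwards.  Nodes with
    zero in-degree have an all-zero column (empty sum stays 0, never NaN).
    """
    a = net.adjacency()
    d_out = net.out_degree().astype(float)
    d_in = net.in_degree().astype(float)
    with np.errstate(divide="ignore"):
        so = np.where(d_out > 0, 1.0 / np.sqrt(d_out), 0.0)
        si = np.where(d_in > 0, 1.0 / np.sqrt(d_in), 0.0)
    return sparse.csr_matrix(sparse.diags(so) @ a @ sparse.diags(si))


def propagate_once(net: DirectedInteractionNetwork,
                   profile: WeightProfile) -> WeightProfile:
    """One synchronous message-passing step; known entries are conserved."""
    _check_profile(net, profile.w, profile.known_mask)
    p = propagation_operator(net)
    w_new = np.asarray(profile.w @ p).ravel()
    w_new[profile.known_mask] = profile.w[profile.known_mask]
    return WeightProfile(profile.entity_id, w_new, profile.known_mask.copy())


def enrich_profile(net: DirectedInteractionNetwork, profile: WeightProfile,
                   iterations: int = 1) -> WeightProfile:
    """Apply ``iterations`` synchronous steps (t=0 is the identity)."""
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    out = WeightProfile(profile.entity_id, profile.w.astype(float).copy(),
                        profile.known_mask.copy())
    for _ in range(iterations):
        out = propagate_once(net, out)
    return out


def enrich_matrix(net: DirectedInteractionNetwork, profiles: np.ndarray,
                  known_masks: np.ndarray | None = None,
                  iterations: int = 1) -> np.ndarray:
    """Vectorised enrichment: row r equals ``enrich_profile`` on row r.

    ``profiles`` is entity x PCG; ``known_masks`` defaults to nonzero input
    entries (nodes with a known association).
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    w = np.asarray(profiles, dtype=float).copy()
    if w.ndim != 2:
        raise ValueError("profiles must be a 2-d entity x PCG matrix")
    masks = w > 0 if known_masks is None else np.asarray(known_masks, dtype=bool)
    _check_profile(net, w[0] if len(w) else np.zeros(net.n_pcgs), masks[0] if len(masks) else None)
    if masks.shape != w.shape:
        raise ValueError(f"mask shape {masks.shape} != profile shape {w.shape}")
    p = propagation_operator(net)
    known_values = w[masks]
    for _ in range(iterations):
        w = np.asarray(w @ p)
        w[masks] = known_values
    return w


def _check_profile(net, w, mask) -> None:
    if np.asarray(w).shape[-1] != net.n_pcgs:
        raise ValueError(
            f"profile has {np.asarray(w).shape[-1]} entries, network has {net.n_pcgs} PCGs")
    if mask is not None and np.asarray(mask).shape[-1] != net.n_pcgs:
        raise ValueError("known_mask length does not match the PCG registry")
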
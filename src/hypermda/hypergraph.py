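"""Hypernode-mediated heterogeneous hypergraph over miRNA and disease vertices.

A small set of learnable hypernodes is the sole bridge between the two entity
classes: every miRNA and every disease connects to every hypernode with a
cosine-similarity edge weight, while entity-entity and hypernode-hypernode
edges are absent.  Graph convolution on this vertex-expanded graph lets
information flow miRNA -> hypernode -> disease (and back) in two hops, which
is how unknown cross-class associations are explored.

The propagation update for vertex v at layer tau is

    z_v^{tau+1} = sigma( Theta_tau^T  sum_{u in N(v)} A_S(v, u) h_u^tau ),

with A_S the self-looped symmetric degree normalization of the cosine
adjacency — the same normalization the encoder applies to the similarity
graphs.  In matrix form each layer is Z' = sigma(A_S Z Theta).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoder import ACTIVATIONS, NodeEmbeddings

__all__ = [
    "HypernodeSet",
    "HypergraphAdjacency",
    "init_hypernodes",
    "cosine_block",
    "build_hypergraph_adjacency",
    "normalize_hypergraph_adjacency",
    "hypergraph_propagate",
]

DEFAULT_N_HYPERNODES = 64

#: row degrees are clamped here before the inverse square root so kept
#: negative cosine weights cannot produce a non-positive degree
DEGREE_FLOOR = 1e-6


@dataclass
class HypernodeSet:
    """Randomly initialized auxiliary vertices; rows are re-drawn if zero."""

    values: np.ndarray
    seed: int

    @property
    def k(self) -> int:
        return self.values.shape[0]

    def __post_init__(self):
        if self.values.ndim != 2 or self.values.shape[0] < 1:
            raise ValueError("hypernodes must form a non-empty 2-D matrix")
        if (np.linalg.norm(self.values, axis=1) == 0).any():
            raise ValueError("hypernode rows must have positive norm")


@dataclass
class HypergraphAdjacency:
    """Block cosine adjacency over n_m + n_d + k vertices.

    Layout: rows/columns ordered miRNA block, disease block, hypernode block.
    Only the entity-hypernode blocks are non-zero.
    """

    values: np.ndarray
    n_mirna: int
    n_disease: int
    k: int

    def __post_init__(self):
        n = self.n_mirna + self.n_disease + self.k
        if self.values.shape != (n, n):
            raise ValueError("adjacency shape does not match block sizes")


def init_hypernodes(k: int, d: int, seed: int) -> HypernodeSet:
    """Draw k hypernode feature rows ~ N(0, 0.1); zero rows are re-drawn."""
    if k < 1 or d < 1:
        raise ValueError("k and d must be positive")
    rng = np.random.default_rng(seed)
    values = rng.normal(0.0, 0.1, size=(k, d))
    for _ in range(100):
        zero = np.linalg.norm(values, axis=1) == 0
        if not zero.any():
            break
        values[zero] = rng.normal(0.0, 0.1, size=(int(zero.sum()), d))
    return HypernodeSet(values, seed)


def cosine_block(E, V) -> np.ndarray:
    """Cosine similarity between entity embeddings and hypernodes, (n x k).

    Zero-norm entity rows get cosine 0 by convention (they carry no
    direction); hypernode rows are guaranteed non-zero by construction.
    """
    E = E.values if isinstance(E, NodeEmbeddings) else np.asarray(E, dtype=np.float64)
    V = V.values if isinstance(V, HypernodeSet) else np.asarray(V, dtype=np.float64)
    if E.shape[1] != V.shape[1]:
        raise ValueError(f"dimension mismatch: E has d={E.shape[1]}, V has d={V.shape[1]}")
    e_norm = np.linalg.norm(E, axis=1)
    v_norm = np.linalg.norm(V, axis=1)
    if (v_norm == 0).any():
        raise ValueError("hypernode rows must have positive norm")
    safe = np.where(e_norm == 0, 1.0, e_norm)
    out = (E @ V.T) / (safe[:, None] * v_norm[None, :])
    out[e_norm == 0] = 0.0
    return out


def build_hypergraph_adjacency(M, D, V: HypernodeSet,
                               clip_negative: bool = False) -> HypergraphAdjacency:
    """Assemble the symmetric block adjacency from the two cosine blocks."""
    cm = cosine_block(M, V)
    cd = cosine_block(D, V)
    if clip_negative:
        cm = np.maximum(cm, 0.0)
        cd = np.maximum(cd, 0.0)
    n_m, k = cm.shape
    n_d = cd.shape[0]
    A = np.zeros((n_m + n_d + k, n_m + n_d + k))
    A[:n_m, n_m + n_d:] = cm
    A[n_m + n_d:, :n_m] = cm.T
    A[n_m:n_m + n_d, n_m + n_d:] = cd
    A[n_m + n_d:, n_m:n_m + n_d] = cd.T
    return HypergraphAdjacency(A, n_m, n_d, k)


def normalize_hypergraph_adjacency(A: HypergraphAdjacency) -> np.ndarray:
    """Self-looped symmetric normalization D~^{-1/2}(A + I)D~^{-1/2}.

    Degrees are absolute row sums of A + I, floored at a small positive
    constant: with negative cosine weights kept, a signed row sum can vanish
    or go negative, so the signed-graph degree is used.  For a non-negative
    adjacency this is exactly the standard normalization.
    """
    a_tilde = A.values + np.eye(A.values.shape[0])
    deg = np.maximum(np.abs(a_tilde).sum(axis=1), DEGREE_FLOOR)
    inv_sqrt = 1.0 / np.sqrt(deg)
    out = inv_sqrt[:, None] * a_tilde * inv_sqrt[None, :]
    return (out + out.T) / 2.0


def hypergraph_propagate(
    A: HypergraphAdjacency,
    Z0: np.ndarray,
    thetas: list[np.ndarray],
    activation: str = "relu",
    dropout: float = 0.0,
    rng: np.random.Generator | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Run the hypergraph GCN layers; return per-layer entity embeddings.

    Parameters
    ----------
    A
        Block cosine adjacency (normalized internally).
    Z0
        Initial vertex features, rows ordered (miRNA, disease, hypernode).
    thetas
        One weight matrix per layer.
    activation, dropout, rng
        Nonlinearity name; dropout applies only when `rng` is supplied.

    Returns
    -------
    list of (miRNA block, disease block) arrays, one per layer, in the
    association matrix's row/column order.
    """
    if Z0.shape[0] != A.values.shape[0]:
        raise ValueError("Z0 rows must cover all miRNA + disease + hypernode vertices")
    act = ACTIVATIONS[activation]
    a_s = normalize_hypergraph_adjacency(A)
    n_m, n_d = A.n_mirna, A.n_disease
    z = Z0
    outputs: list[tuple[np.ndarray, np.ndarray]] = []
    for layer, theta in enumerate(thetas):
        z = act(a_s @ z @ theta)
        if not np.isfinite(z).all():
            raise FloatingPointError(f"non-finite values in hypergraph layer {layer}")
        if rng is not None and dropout > 0:
            keep = 1.0 - dropout
            z = z * (rng.random(z.shape) < keep) / keep
        outputs.append((z[:n_m], z[n_m:n_m + n_d]))
    return outputs
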
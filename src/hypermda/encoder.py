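"""Per-view GCN encoders over the similarity networks.

Each similarity view is treated as a weighted graph.  Its adjacency gets the
standard self-looped symmetric normalization

    J = P~^{-1/2} (B + I) P~^{-1/2},    P~ = degree matrix of B + I,

node features are randomly initialized dense vectors shared across views,
and each view runs its own small GCN stack H' = sigma(J H W).  The per-view
final-layer embeddings are fused (mean by default) into one embedding per
miRNA and one per disease, which seed the hypergraph stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .similarity import SimilarityMatrix, SimilarityViewSet

__all__ = [
    "NormalizedAdjacency",
    "NodeEmbeddings",
    "EncoderParameters",
    "normalize_adjacency",
    "init_node_features",
    "init_weight",
    "gcn_layer",
    "encode_views",
    "ACTIVATIONS",
]

ACTIVATIONS = {
    "relu": lambda x: np.maximum(x, 0.0),
    "identity": lambda x: x,
    "tanh": np.tanh,
}

FEATURE_INIT_SD = 0.1


@dataclass
class NormalizedAdjacency:
    """Symmetric self-looped normalized adjacency; spectral radius <= 1."""

    values: np.ndarray
    ids: list[str]


@dataclass
class NodeEmbeddings:
    """Dense per-entity vectors; `layer_index` tracks the producing GCN layer."""

    values: np.ndarray
    ids: list[str]
    layer_index: int = 0

    def __post_init__(self):
        if not np.isfinite(self.values).all():
            raise ValueError("embeddings must be finite")
        if self.values.shape[0] != len(self.ids):
            raise ValueError("embedding rows must match identifier count")


@dataclass
class EncoderParameters:
    """Learnable per-view, per-layer weight matrices plus activation/dropout."""

    weights: dict[str, list[np.ndarray]] = field(default_factory=dict)
    activation: str = "relu"
    dropout_rate: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")


def normalize_adjacency(B) -> NormalizedAdjacency:
    """Self-looped symmetric normalization of a similarity/adjacency matrix.

    Accepts a :class:`SimilarityMatrix` or a plain square symmetric
    non-negative array.  An isolated node (zero row) reduces to the pure
    self-loop case: its normalized row is the unit vector on itself.
    """
    if isinstance(B, SimilarityMatrix):
        values, ids = B.values, B.ids
    else:
        values = np.asarray(B, dtype=np.float64)
        ids = [str(i) for i in range(values.shape[0])]
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("adjacency must be square")
    if np.abs(values - values.T).max(initial=0.0) > 1e-8:
        raise ValueError("adjacency must be symmetric")
    if values.min(initial=0.0) < 0:
        raise ValueError("adjacency entries must be non-negative")
    b_tilde = values + np.eye(values.shape[0])
    inv_sqrt_deg = 1.0 / np.sqrt(b_tilde.sum(axis=1))
    J = inv_sqrt_deg[:, None] * b_tilde * inv_sqrt_deg[None, :]
    return NormalizedAdjacency((J + J.T) / 2.0, ids)


def init_node_features(n: int, d: int, seed: int, ids: list[str] | None = None) -> NodeEmbeddings:
    """Random initial node features, N(0, 0.1) entries, deterministic per seed."""
    if n < 1 or d < 1:
        raise ValueError("n and d must be positive")
    rng = np.random.default_rng(seed)
    values = rng.normal(0.0, FEATURE_INIT_SD, size=(n, d))
    return NodeEmbeddings(values, ids or [str(i) for i in range(n)], layer_index=0)


def init_weight(d_in: int, d_out: int, rng: np.random.Generator) -> np.ndarray:
    """Fan-average uniform (Glorot) weight initialization."""
    limit = np.sqrt(6.0 / (d_in + d_out))
    return rng.uniform(-limit, limit, size=(d_in, d_out))


def gcn_layer(J: NormalizedAdjacency, H: NodeEmbeddings, W: np.ndarray,
              activation: str = "relu") -> NodeEmbeddings:
    """One graph-convolution update H' = sigma(J H W)."""
    if J.values.shape[1] != H.values.shape[0] or H.values.shape[1] != W.shape[0]:
        raise ValueError(
            f"non-conformable shapes J{J.values.shape} H{H.values.shape} W{W.shape}"
        )
    out = ACTIVATIONS[activation](J.values @ H.values @ W)
    return NodeEmbeddings(out, H.ids, layer_index=H.layer_index + 1)


def _fuse(stacks: list[np.ndarray], how: str) -> np.ndarray:
    if how == "mean":
        return np.mean(stacks, axis=0)
    if how == "sum":
        return np.sum(stacks, axis=0)
    if how == "concat":
        return np.concatenate(stacks, axis=1)
    raise ValueError(f"unknown view fusion {how!r}")


def encode_views(
    views: SimilarityViewSet,
    params: EncoderParameters,
    init: tuple[NodeEmbeddings, NodeEmbeddings],
    n_layers: int = 2,
    view_fusion: str = "mean",
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, list[NodeEmbeddings]], NodeEmbeddings, NodeEmbeddings]:
    """Run every per-view GCN and fuse final layers into M (miRNA) and D (disease).

    Returns ``(per_view_layers, M, D)`` where `per_view_layers` maps
    ``"mirna/<view>"`` and ``"disease/<view>"`` to the list of layer outputs.
    Dropout is applied after each activation only when `rng` is given and
    ``params.dropout_rate > 0`` (training mode); omit `rng` for the
    deterministic inference path.
    """
    if n_layers < 1:
        raise ValueError("n_layers must be at least 1")
    init_m, init_d = init
    per_view: dict[str, list[NodeEmbeddings]] = {}
    finals: dict[str, list[np.ndarray]] = {"mirna": [], "disease": []}
    for side, side_views, h0 in (
        ("mirna", views.mirna_views, init_m),
        ("disease", views.disease_views, init_d),
    ):
        for view in side_views:
            key = f"{side}/{view.view_name}"
            J = normalize_adjacency(view)
            weights = params.weights[key]
            if len(weights) != n_layers:
                raise ValueError(f"{key}: expected {n_layers} weight matrices")
            h = h0
            layers: list[NodeEmbeddings] = []
            for W in weights:
                h = gcn_layer(J, h, W, params.activation)
                if rng is not None and params.dropout_rate > 0:
                    keep = 1.0 - params.dropout_rate
                    mask = rng.random(h.values.shape) < keep
                    h = NodeEmbeddings(h.values * mask / keep, h.ids, h.layer_index)
                layers.append(h)
            per_view[key] = layers
            finals[side].append(layers[-1].values)
    M = NodeEmbeddings(_fuse(finals["mirna"], view_fusion), views.mirna_ids, n_layers)
    D = NodeEmbeddings(_fuse(finals["disease"], view_fusion), views.disease_ids, n_layers)
    return per_view, M, D
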
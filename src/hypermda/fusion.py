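"""Layer-level attention fusion and the pair-scoring feed-forward head.

Information at different propagation depths matters differently, so the
final per-entity embedding is a convex combination of the per-layer
embeddings.  The combining weights come from a small convolutional combiner:
the L layer outputs are stacked as channels, a width-1 convolution mixes
channels, global average pooling reduces each output channel to a scalar
logit, and a softmax over channels yields the attention weights alpha.
Because the convolution has width 1, pooling commutes with it and the logits
reduce to ``K @ channel_means + b``.

A pair (i, j) is scored by the element-wise product of the fused miRNA and
disease embeddings pushed through a two-layer feed-forward network with a
logistic output, giving an association probability in (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoder import NodeEmbeddings

__all__ = ["LayerStack", "PairScore", "CombinerParams", "FNNParams",
           "layer_attention", "attention_weights", "score_pairs"]


@dataclass
class LayerStack:
    """Ordered per-layer embeddings for one entity class."""

    embeddings: list[NodeEmbeddings]

    def __post_init__(self):
        if not self.embeddings:
            raise ValueError("layer stack must be non-empty")
        shape0, ids0 = self.embeddings[0].values.shape, self.embeddings[0].ids
        for e in self.embeddings[1:]:
            if e.values.shape != shape0 or e.ids != ids0:
                raise ValueError("stack members must share shape and id order")

    def __len__(self):
        return len(self.embeddings)


@dataclass
class PairScore:
    mirna_id: str
    disease_id: str
    probability: float

    def __post_init__(self):
        if not 0.0 < self.probability < 1.0:
            raise ValueError("probability must be strictly inside (0, 1)")


@dataclass
class CombinerParams:
    """Width-1 convolution kernel (L x L) and bias (L,) of the attention combiner."""

    kernel: np.ndarray
    bias: np.ndarray


@dataclass
class FNNParams:
    """Two affine layers with a rectifier between and a scalar logistic output."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray = field(default_factory=lambda: np.zeros(1))


def attention_weights(stack: LayerStack, params: CombinerParams) -> np.ndarray:
    """Softmax channel weights from the pooled width-1 convolution."""
    L = len(stack)
    if params.kernel.shape != (L, L) or params.bias.shape != (L,):
        raise ValueError("combiner parameter shapes must match the stack depth")
    channel_means = np.array([e.values.mean() for e in stack.embeddings])
    logits = params.kernel @ channel_means + params.bias
    e = np.exp(logits - logits.max())
    return e / e.sum()


def layer_attention(stack: LayerStack, params: CombinerParams | None = None) -> NodeEmbeddings:
    """Convex combination of the stacked layer embeddings.

    With `params` omitted, an untrained identity combiner (zero kernel and
    bias, i.e. uniform attention) is used.
    """
    L = len(stack)
    if params is None:
        params = CombinerParams(np.zeros((L, L)), np.zeros(L))
    alpha = attention_weights(stack, params)
    fused = sum(a * e.values for a, e in zip(alpha, stack.embeddings))
    first = stack.embeddings[0]
    return NodeEmbeddings(fused, first.ids, layer_index=stack.embeddings[-1].layer_index)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def score_pairs(
    W_hat: NodeEmbeddings,
    F_hat: NodeEmbeddings,
    pairs: list[tuple[str, str]],
    fnn: FNNParams,
) -> list[PairScore]:
    """Score (miRNA, disease) pairs: sigmoid(FNN(w_i * f_j)), element-wise product.

    Output order matches the input pair order.  Unknown identifiers raise
    ``KeyError`` naming the offender.
    """
    m_index = {name: i for i, name in enumerate(W_hat.ids)}
    d_index = {name: j for j, name in enumerate(F_hat.ids)}
    rows_m, rows_d = [], []
    for mid, did in pairs:
        if mid not in m_index:
            raise KeyError(f"unknown miRNA identifier {mid!r}")
        if did not in d_index:
            raise KeyError(f"unknown disease identifier {did!r}")
        rows_m.append(m_index[mid])
        rows_d.append(d_index[did])
    x = W_hat.values[rows_m] * F_hat.values[rows_d]
    h = np.maximum(x @ fnn.W1 + fnn.b1, 0.0)
    logits = (h @ fnn.W2 + fnn.b2).ravel()
    probs = np.clip(_sigmoid(logits), 1e-12, 1.0 - 1e-12)
    return [
        PairScore(mid, did, float(p)) for (mid, did), p in zip(pairs, probs)
    ]
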
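"""The end-to-end trainable association predictor.

This module wires the pipeline stages — per-view GCN encoders, the
hypernode hypergraph, layer attention and the feed-forward scorer — into a
single differentiable computation over the autodiff engine, so gradients
reach every learnable parameter (encoder weights, hypernode features,
propagation weights, attention combiner, FNN).  The functional modules
(:mod:`~hypermda.encoder`, :mod:`~hypermda.hypergraph`,
:mod:`~hypermda.fusion`) define the same math on plain arrays; the test
suite asserts both routes agree when dropout is off.

The cosine hypergraph adjacency is rebuilt on every forward pass from the
current encoder outputs and hypernode features, so it tracks training.
With the ``no_hypergraph`` ablation the encoder layer outputs feed the layer
attention directly and the hypernode machinery is skipped entirely.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Adam, Tensor, concat_rows, relu, sigmoid, softmax
from .config import ModelConfig
from .encoder import FEATURE_INIT_SD, init_weight, normalize_adjacency
from .similarity import SimilarityViewSet

__all__ = ["AssociationModel"]

_NORM_FLOOR = 1e-12
_DEGREE_FLOOR = 1e-6


def _hcat(parts: list[Tensor]) -> Tensor:
    return concat_rows([p.T for p in parts]).T


def _dropout(x: Tensor, rate: float, rng: np.random.Generator | None) -> Tensor:
    if rng is None or rate <= 0:
        return x
    keep = 1.0 - rate
    mask = (rng.random(x.shape) < keep) / keep
    return x * mask


class AssociationModel:
    """Multi-view GCN + hypernode hypergraph + attention/FNN pair scorer."""

    def __init__(self, views: SimilarityViewSet, config: ModelConfig, seed: int):
        self.config = config
        self.mirna_ids = views.mirna_ids
        self.disease_ids = views.disease_ids
        self.n_m = len(self.mirna_ids)
        self.n_d = len(self.disease_ids)
        d = config.embedding_dim

        ss = np.random.SeedSequence(seed)
        rng_feat, rng_w, self._rng_drop = [
            np.random.default_rng(s) for s in ss.spawn(3)
        ]

        # fixed normalized adjacencies and initial features (non-learnable)
        self._adjacency = {
            f"{side}/{v.view_name}": normalize_adjacency(v).values
            for side, vs in (("mirna", views.mirna_views), ("disease", views.disease_views))
            for v in vs
        }
        self._h0 = {
            "mirna": Tensor(rng_feat.normal(0.0, FEATURE_INIT_SD, (self.n_m, d))),
            "disease": Tensor(rng_feat.normal(0.0, FEATURE_INIT_SD, (self.n_d, d))),
        }

        # learnable parameters
        self.params: dict[str, Tensor] = {}
        for key in self._adjacency:
            for layer in range(config.n_layers):
                self._add_param(f"W/{key}/{layer}", init_weight(d, d, rng_w))

        self.use_hypergraph = config.ablation != "no_hypergraph"
        if self.use_hypergraph:
            self._add_param("hypernodes", rng_w.normal(0.0, 0.1, (config.n_hypernodes, d)))
            for layer in range(config.hyper_layers):
                self._add_param(f"theta/{layer}", init_weight(d, d, rng_w))
            stack_depth = config.hyper_layers + (1 if config.include_encoder_layer else 0)
        else:
            stack_depth = config.n_layers
        self.stack_depth = stack_depth

        for side in ("mirna", "disease"):
            self._add_param(f"att_K/{side}", init_weight(stack_depth, stack_depth, rng_w))
            self._add_param(f"att_b/{side}", np.zeros((stack_depth, 1)))
        h = config.fnn_hidden
        self._add_param("fnn_W1", init_weight(d, h, rng_w))
        self._add_param("fnn_b1", np.zeros((1, h)))
        self._add_param("fnn_W2", init_weight(h, 1, rng_w))
        self._add_param("fnn_b2", np.zeros((1, 1)))

    # ------------------------------------------------------------------ params
    def _add_param(self, name: str, value: np.ndarray):
        self.params[name] = Tensor(value, requires_grad=True)

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    @property
    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # ----------------------------------------------------------------- forward
    def _encode(self, training: bool):
        """Per-view GCNs; returns per-layer fused embeddings per entity class."""
        cfg = self.config
        rng = self._rng_drop if training else None
        fused_layers: dict[str, list[Tensor]] = {"mirna": [], "disease": []}
        for side, names in (("mirna", ("functional", "sequence", "gip")),
                            ("disease", ("semantic", "target", "gip"))):
            per_layer: list[list[Tensor]] = [[] for _ in range(cfg.n_layers)]
            for name in names:
                key = f"{side}/{name}"
                J = self._adjacency[key]
                h = self._h0[side]
                for layer in range(cfg.n_layers):
                    h = relu(J @ h @ self.params[f"W/{key}/{layer}"])
                    h = _dropout(h, cfg.dropout if training else 0.0, rng)
                    per_layer[layer].append(h)
            for layer in range(cfg.n_layers):
                stack = per_layer[layer]
                total = sum(stack[1:], start=stack[0])
                if cfg.view_fusion == "mean":
                    total = total * (1.0 / len(stack))
                elif cfg.view_fusion != "sum":
                    raise NotImplementedError(
                        "the trainable model supports view_fusion 'mean' or 'sum'"
                    )
                fused_layers[side].append(total)
        return fused_layers

    def _cosine_block(self, E: Tensor, V: Tensor) -> Tensor:
        # clamp before the square root: a zero row would otherwise send an
        # infinite gradient through x**0.5 at x=0
        e_norm = (E * E).sum(axis=1, keepdims=True).clip_min(_NORM_FLOOR**2) ** 0.5
        v_norm = (V * V).sum(axis=1, keepdims=True).clip_min(_NORM_FLOOR**2) ** 0.5
        return (E @ V.T) / (e_norm * v_norm.T)

    def _hypergraph_layers(self, M: Tensor, D: Tensor, training: bool) -> list[Tensor]:
        cfg = self.config
        rng = self._rng_drop if training else None
        V = self.params["hypernodes"]
        k = V.shape[0]
        cm = self._cosine_block(M, V)
        cd = self._cosine_block(D, V)
        if cfg.clip_negative:
            cm, cd = cm.clip_min(0.0), cd.clip_min(0.0)
        z_mm = np.zeros((self.n_m, self.n_m))
        z_md = np.zeros((self.n_m, self.n_d))
        z_dd = np.zeros((self.n_d, self.n_d))
        z_kk = np.zeros((k, k))
        A = concat_rows([
            _hcat([Tensor(z_mm), Tensor(z_md), cm]),
            _hcat([Tensor(z_md.T), Tensor(z_dd), cd]),
            _hcat([cm.T, cd.T, Tensor(z_kk)]),
        ])
        a_tilde = A + np.eye(self.n_m + self.n_d + k)
        # absolute-value degrees: with kept negative cosine weights a signed
        # row sum can vanish, so the signed-graph generalization is used; it
        # reduces to the standard normalization when A is non-negative
        deg = a_tilde.abs().sum(axis=1, keepdims=True).clip_min(_DEGREE_FLOOR)
        inv_sqrt = deg ** -0.5
        a_s = inv_sqrt * a_tilde * inv_sqrt.T

        z = concat_rows([M, D, V])
        outputs = []
        for layer in range(cfg.hyper_layers):
            z = relu(a_s @ z @ self.params[f"theta/{layer}"])
            z = _dropout(z, cfg.dropout if training else 0.0, rng)
            outputs.append(z)
        return outputs

    def _attend(self, stack: list[Tensor], side: str) -> Tensor:
        if len(stack) == 1:
            return stack[0]
        L = len(stack)
        means = concat_rows([e.mean().reshape(1, 1) for e in stack])
        logits = self.params[f"att_K/{side}"] @ means + self.params[f"att_b/{side}"]
        alpha = softmax(logits.reshape(1, L)).reshape(L, 1)
        fused = alpha.rows([0]) * stack[0]
        for l in range(1, L):
            fused = fused + alpha.rows([l]) * stack[l]
        return fused

    def forward(self, mirna_idx, disease_idx, training: bool = False) -> Tensor:
        """Association probabilities for index pairs; shape (n_pairs, 1)."""
        cfg = self.config
        fused_layers = self._encode(training)
        M = fused_layers["mirna"][-1]
        D = fused_layers["disease"][-1]

        if self.use_hypergraph:
            hyper = self._hypergraph_layers(M, D, training)
            n_m = self.n_m
            stack_m = [z.rows(np.arange(n_m)) for z in hyper]
            stack_d = [z.rows(np.arange(n_m, n_m + self.n_d)) for z in hyper]
            if cfg.include_encoder_layer:
                stack_m = [M] + stack_m
                stack_d = [D] + stack_d
        else:
            stack_m = fused_layers["mirna"]
            stack_d = fused_layers["disease"]

        W_hat = self._attend(stack_m, "mirna")
        F_hat = self._attend(stack_d, "disease")

        x = W_hat.rows(np.asarray(mirna_idx)) * F_hat.rows(np.asarray(disease_idx))
        h = relu(x @ self.params["fnn_W1"] + self.params["fnn_b1"])
        logits = h @ self.params["fnn_W2"] + self.params["fnn_b2"]
        q = sigmoid(logits)
        # keep q strictly inside (0, 1) so both losses stay finite
        q = q.clip_min(1e-12)
        q = 1.0 - (1.0 - q).clip_min(1e-12)
        return q

    # -------------------------------------------------------------------- loss
    def loss(self, q: Tensor, targets: np.ndarray) -> Tensor:
        cfg = self.config
        t = np.asarray(targets, dtype=np.float64).reshape(-1, 1)
        use_bce = cfg.loss == "bce" or cfg.ablation == "bce_loss"
        if use_bce:
            terms = t * q.log() + (1.0 - t) * (1.0 - q).log()
            return -terms.mean()
        X = (t * q).sum()
        U = float((t * t).sum()) + (q * q).sum()
        eps = cfg.epsilon
        if cfg.loss_form == "classic_dice":
            return 1.0 - (2.0 * X + eps) / (U + eps)
        return 1.0 - (X + eps) / (U - X + eps)

    # ---------------------------------------------------------------- training
    def fit(self, train_pairs, train_labels, log=None) -> list[float]:
        """Mini-batch gradient training; returns the per-epoch mean loss."""
        cfg = self.config
        mi = np.asarray([p[0] for p in train_pairs], dtype=np.intp)
        di = np.asarray([p[1] for p in train_pairs], dtype=np.intp)
        t = np.asarray(train_labels, dtype=np.float64)
        opt = Adam(self.parameters(), lr=cfg.learning_rate)
        rng = np.random.default_rng(self._rng_drop.integers(2**31))
        history = []
        for epoch in range(cfg.epochs):
            order = rng.permutation(t.size)
            losses = []
            for start in range(0, t.size, cfg.batch_size):
                batch = order[start:start + cfg.batch_size]
                opt.zero_grad()
                q = self.forward(mi[batch], di[batch], training=True)
                loss = self.loss(q, t[batch])
                value = loss.item()
                if not np.isfinite(value):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}, batch {start // cfg.batch_size}"
                    )
                loss.backward()
                opt.step()
                losses.append(value)
            history.append(float(np.mean(losses)))
            if log is not None:
                log(epoch, history[-1])
        return history

    def predict(self, mirna_idx, disease_idx) -> np.ndarray:
        """Deterministic (dropout-off) association probabilities."""
        return self.forward(mirna_idx, disease_idx, training=False).data.ravel()
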
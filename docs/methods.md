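# Methods

## Problem and model

`hypermda` predicts missing links in a bipartite miRNA–disease association
network. The working assumption is the standard one in this field: miRNAs
with similar function tend to associate with diseases that are themselves
similar. The model therefore consumes, besides the binary association matrix
`A ∈ {0,1}^{n_m × n_d}`, three similarity views per entity class —
functional, sequence and GIP for miRNAs; semantic, target-based and GIP for
diseases — and proceeds in three stages.

**1. Multi-view GCN encoding.** Each similarity view `B` is treated as a
weighted graph and normalized with self-loops,

    J = P̃^{-1/2} (B + I) P̃^{-1/2},   P̃ = diag(rowsum(B + I)),

whose spectrum lies in [−1, 1]. Node features are initialized at random
(N(0, 0.1), dimension `d = 128`) and each view runs its own two-layer GCN
`H' = σ(J H W)` with rectifier activation and dropout 0.5 after each layer.
The three per-view final embeddings of each class are fused by element-wise
mean into `M` (miRNAs) and `D` (diseases). Mean fusion is the parameter-free
choice; `sum` and `concat` are exposed as `view_fusion` config options. Two
GCN layers per view is the default to avoid over-smoothing; it is
configurable (`n_layers`).

**2. Hypernode hypergraph propagation.** `k = 64` learnable hypernodes
`v_1..v_k` (initialized N(0, 0.1), re-drawn if a row is zero) are the sole
bridge between the classes: the hypergraph adjacency over the
`n_m + n_d + k` vertices has cosine-similarity blocks

    C(M_i, v_k) = ⟨M_i, v_k⟩ / (‖M_i‖‖v_k‖),   C(D_j, v_k) likewise,

in the entity–hypernode positions and zeros elsewhere (entity–entity and
hypernode–hypernode). Propagation applies the same GCN update,
`Z' = σ(Ā_S Z Θ)`, for two layers, where `Ā_S` is the self-looped symmetric
normalization of the cosine adjacency. Per-layer entity embeddings are
retained for the attention stage. The adjacency is rebuilt from the current
encoder outputs and hypernode features on every forward pass, so it tracks
training; hypernode features receive gradients like any other parameter.

**3. Attention fusion and scoring.** The per-layer embeddings (the fused
encoder output is included as layer 0 by default, `include_encoder_layer`)
are combined by layer-level attention: the L layers are stacked as channels,
a width-1 convolution mixes channels, global average pooling yields one
logit per channel, and a softmax gives weights `α` with `α ≥ 0, Σα = 1`.
Because the convolution has width 1, pooling commutes with it and the logits
reduce to `K·(channel means) + b`; the fused embedding is `Σ_l α_l E_l`,
coordinate-wise inside the convex hull of the stack. A pair (i, j) is scored
by `sigmoid(FNN(Ŵ_i ⊙ F̂_j))` where the FNN is two affine layers with a
rectifier between (hidden width = embedding dimension).

**Loss.** Training minimizes the Sorensen-Dice overlap loss per mini-batch,

    L = 1 − (X + ε) / (U − X + ε),   X = Σ t_i q_i,  U = Σ (t_i² + q_i²),

with ε = 1. The denominator `U − X` makes this the soft-Jaccard (IoU) form
even though the loss is conventionally named Sorensen-Dice; both forms are
implemented (`loss_form: as_printed | classic_dice`) with the IoU form the
default for fidelity to the construction this package follows. Binary
cross-entropy is available for the loss ablation.

## GIP kernel

The GIP views are computed internally from the association matrix:
`K[i,j] = exp(−γ‖IP(i) − IP(j)‖²)` with `IP(i)` the i-th row (miRNAs) or
column (diseases) and bandwidth `γ = γ′ / mean_i ‖IP(i)‖²`, `γ′ = 1` — the
bandwidth-normalized construction used throughout this literature. An
association matrix with no links leaves γ undefined and is rejected with a
remediation hint.

## Training protocol

5-fold cross-validation: positives are shuffled and partitioned; negatives
are drawn uniformly without replacement from the zero cells, 1:1 with
positives by default (`neg_ratio`), disjointly between train and test within
each fold and frozen thereafter, so metrics are comparable across ablations.
**Inside each fold the GIP views are recomputed from the association matrix
with that fold's test positives zeroed**, so no training-side computation
sees a test label; the externally supplied views do not depend on the
labels. Optimization is adaptive-moment gradient descent (learning rate
1e-3), batch size 128, 100 epochs. One global seed fans out through named
seed sequences to fold assignment, negative sampling, parameter
initialization and dropout, making a full run bit-reproducible on a fixed
thread count.

Ablations: `bce_loss` swaps only the loss (identical parameter count);
`no_hypergraph` removes hypernodes and propagation entirely and feeds the
per-layer fused encoder embeddings to the layer attention (strictly fewer
parameters).

## Synthetic data

The generator plants the statistical coupling the model exploits and nothing
else. Both classes get non-negative latent factors (entries |N(0,1)|, rank 4
by default); a pair links with probability `sigmoid(a·z_ij + b)` where
`z_ij` is the standardized factor inner product, slope `a = 3`, and `b` is
set by bisection so the expected density matches the target (0.10 by
default). Each external view is the cosine similarity of the class's factors
plus symmetric Gaussian noise (sd 0.1 by default), clipped to [0,1] with
unit diagonal. The default scale, 60 miRNAs × 40 diseases, keeps a full
cross-validation run under a minute on one CPU while preserving the
bipartite imbalance of real catalogues (hundreds of entities per class,
density a few percent).

What the generator does **not** emulate: real sequence composition, ontology
structure behind semantic similarity, hubness/degree heterogeneity of curated
databases, or biased negative sampling (unknown ≠ absent). Passing tests on
this data show the pipeline recovers a planted low-rank signal through the
similarity and association channels; they do not certify performance on
curated biological catalogues.

## Numerical choices

- **Autodiff.** The model trains through a small reverse-mode engine over
  numpy arrays (`hypermda._autodiff`); its gradients are verified against
  central finite differences in the test suite.
- **Signed-degree normalization.** Negative cosine weights are kept by
  default (`clip_negative: false`). A signed row sum can then vanish, so the
  hypergraph normalization uses absolute-value degrees
  `deg(v) = Σ_u |Ã(v,u)|`, floored at 1e-6 — the signed-graph generalization
  that reduces exactly to the standard form for non-negative adjacencies.
- **Numerical guards.** Cosine norms are floored at 1e-12 (zero-norm rows get
  cosine 0); sigmoid is computed in its numerically stable piecewise form;
  predicted probabilities are clamped to (1e-12, 1−1e-12) so both losses
  stay finite; similarity matrices asymmetric by less than 1e-8 are silently
  symmetrized, larger asymmetry is an error.
- **Ties in ranking** are broken by identifier, making candidate lists
  stable across runs.

## Problem sizes used in tests and the acceptance script

Experiments run at the default synthetic scale (60 × 40, rank 4, density
0.10, noise 0.1) with the default model configuration; the ablation
comparison averages three replicate seeds; unit tests use smaller instances
(≤ 20 vertices for the brute-force propagation oracles, 8 × 5 matrices for
the GIP oracle).

## Known limitations

- Dropout at rate 0.5 on a 128-dimensional model trained on a few hundred
  pairs is a strong regularizer; on very small instances reducing `dropout`
  or `embedding_dim` can help.
- The hypergraph stage recomputes a dense (n_m + n_d + k)² adjacency per
  forward pass; the implementation targets desk-scale and catalogue-scale
  data (thousands of entities), not genome-scale graphs.
- `view_fusion: concat` is supported by the functional encoder
  (`encode_views`) but not by the trainable model, where it would triple the
  dimension entering the hypergraph; the trainable path accepts `mean` and
  `sum`.
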
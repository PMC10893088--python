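"""End-to-end model: agreement with the functional modules, determinism,
parameter accounting across ablations."""

import numpy as np
import pytest

import hypermda as h
from hypermda.encoder import EncoderParameters, NodeEmbeddings
from hypermda.fusion import CombinerParams, FNNParams
from hypermda.hypergraph import HypernodeSet
from hypermda.model import AssociationModel


@pytest.fixture(scope="module")
def tiny_views(tiny_dataset):
    ds = tiny_dataset
    return ds, h.assemble_views(
        ds.associations,
        ds.mirna_views["functional"], ds.mirna_views["sequence"],
        ds.disease_views["semantic"], ds.disease_views["target"],
    )


def _config(**kw):
    base = dict(embedding_dim=8, n_hypernodes=4, fnn_hidden=8,
                epochs=2, batch_size=32, dropout=0.5, seed=0)
    base.update(kw)
    return h.ModelConfig(**base)


def test_forward_matches_functional_composition(tiny_views):
    """The autodiff forward pass (dropout off) equals composing the public
    numpy operations with the model's own parameter values."""
    ds, views = tiny_views
    cfg = _config()
    model = AssociationModel(views, cfg, seed=5)
    pairs_idx = ([0, 3, 1], [0, 2, 5])
    q_model = model.predict(*pairs_idx)

    # encoder path via encode_views
    weights = {
        key: [model.params[f"W/{key}/{l}"].data for l in range(cfg.n_layers)]
        for key in model._adjacency
    }
    params = EncoderParameters(weights, cfg.activation, 0.0)
    init_m = NodeEmbeddings(model._h0["mirna"].data, views.mirna_ids, 0)
    init_d = NodeEmbeddings(model._h0["disease"].data, views.disease_ids, 0)
    per_view, M, D = h.encode_views(views, params, (init_m, init_d), cfg.n_layers)

    # hypergraph path via the functional module
    V = HypernodeSet(model.params["hypernodes"].data, seed=0)
    A = h.build_hypergraph_adjacency(M.values, D.values, V, cfg.clip_negative)
    Z0 = np.vstack([M.values, D.values, V.values])
    thetas = [model.params[f"theta/{l}"].data for l in range(cfg.hyper_layers)]
    layers = h.hypergraph_propagate(A, Z0, thetas, cfg.activation)

    # attention + scorer via the functional modules
    stacks = {}
    for side, base, idx in (("mirna", M, 0), ("disease", D, 1)):
        stack = [base] + [
            NodeEmbeddings(layer[idx], base.ids, l + 1) for l, layer in enumerate(layers)
        ]
        combiner = CombinerParams(
            model.params[f"att_K/{side}"].data,
            model.params[f"att_b/{side}"].data.ravel(),
        )
        stacks[side] = h.layer_attention(h.LayerStack(stack), combiner)
    fnn = FNNParams(
        model.params["fnn_W1"].data, model.params["fnn_b1"].data.ravel(),
        model.params["fnn_W2"].data, model.params["fnn_b2"].data.ravel(),
    )
    pairs = [
        (views.mirna_ids[i], views.disease_ids[j])
        for i, j in zip(*pairs_idx)
    ]
    q_functional = [s.probability for s in
                    h.score_pairs(stacks["mirna"], stacks["disease"], pairs, fnn)]
    assert np.allclose(q_model, q_functional, atol=1e-10)


def test_two_identically_seeded_models_agree_after_training(tiny_views):
    ds, views = tiny_views
    folds = h.make_folds(ds.associations, k=3, seed=1)
    outs = []
    for _ in range(2):
        model = AssociationModel(views, _config(), seed=7)
        idx = [(ds.associations.mirna_ids.index(m), ds.associations.disease_ids.index(d))
               for m, d, _ in folds[0].train_pairs]
        labels = [l for _, _, l in folds[0].train_pairs]
        model.fit(idx, labels)
        outs.append(model.predict([0, 1], [0, 1]))
    assert np.array_equal(outs[0], outs[1])


def test_ablation_parameter_counts(tiny_views):
    _, views = tiny_views
    full = AssociationModel(views, _config(), seed=0)
    no_hyper = AssociationModel(views, _config(ablation="no_hypergraph"), seed=0)
    bce = AssociationModel(views, _config(ablation="bce_loss"), seed=0)
    assert no_hyper.n_parameters < full.n_parameters
    assert bce.n_parameters == full.n_parameters


def test_probabilities_strictly_inside_unit_interval(tiny_views):
    _, views = tiny_views
    model = AssociationModel(views, _config(), seed=3)
    q = model.predict(np.arange(5), np.arange(5))
    assert (q > 0).all() and (q < 1).all()


def test_dice_and_bce_losses_agree_with_reference(tiny_views):
    """Model-internal loss values equal the reference implementations."""
    from hypermda._autodiff import Tensor

    _, views = tiny_views
    t = np.array([1.0, 0.0, 1.0, 0.0])
    q = np.array([0.7, 0.3, 0.9, 0.4])
    model = AssociationModel(views, _config(), seed=0)
    assert model.loss(Tensor(q.reshape(-1, 1)), t).item() == pytest.approx(
        h.dice_loss(q, t), abs=1e-12
    )
    model_bce = AssociationModel(views, _config(ablation="bce_loss"), seed=0)
    assert model_bce.loss(Tensor(q.reshape(-1, 1)), t).item() == pytest.approx(
        h.bce_loss(q, t), abs=1e-12
    )


def test_training_reduces_loss(tiny_views):
    ds, views = tiny_views
    folds = h.make_folds(ds.associations, k=3, seed=2)
    model = AssociationModel(views, _config(epochs=20), seed=1)
    idx = [(ds.associations.mirna_ids.index(m), ds.associations.disease_ids.index(d))
           for m, d, _ in folds[0].train_pairs]
    labels = [l for _, _, l in folds[0].train_pairs]
    history = model.fit(idx, labels)
    assert history[-1] < history[0]
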
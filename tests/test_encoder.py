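"""Adjacency normalization and per-view GCN oracles."""

import numpy as np
import pytest

import hypermda as h
from hypermda.encoder import EncoderParameters, init_weight


def brute_force_normalize(B):
    Bt = B + np.eye(B.shape[0])
    deg = Bt.sum(axis=1)
    J = np.zeros_like(Bt)
    for i in range(B.shape[0]):
        for j in range(B.shape[0]):
            J[i, j] = Bt[i, j] / np.sqrt(deg[i] * deg[j])
    return J


def test_normalize_hand_cases():
    assert np.allclose(h.normalize_adjacency(np.array([[0.0]])).values, [[1.0]])
    J2 = h.normalize_adjacency(np.array([[0.0, 1.0], [1.0, 0.0]])).values
    assert np.allclose(J2, [[0.5, 0.5], [0.5, 0.5]])
    B3 = np.zeros((3, 3))
    B3[0, 1] = B3[1, 0] = 1.0
    J3 = h.normalize_adjacency(B3).values
    assert J3[0, 0] == pytest.approx(0.5)
    assert J3[0, 1] == pytest.approx(0.5)
    assert J3[2, 2] == pytest.approx(1.0)
    assert J3[0, 2] == 0.0


def test_normalize_matches_brute_force_on_random_inputs():
    rng = np.random.default_rng(0)
    for _ in range(50):
        n = rng.integers(2, 12)
        B = rng.random((n, n))
        B = (B + B.T) / 2
        J = h.normalize_adjacency(B).values
        assert np.allclose(J, brute_force_normalize(B), atol=1e-10)


def test_normalize_spectral_radius_at_most_one():
    rng = np.random.default_rng(1)
    for _ in range(20):
        n = rng.integers(2, 15)
        B = rng.random((n, n))
        B = (B + B.T) / 2
        eig = np.linalg.eigvalsh(h.normalize_adjacency(B).values)
        assert eig.max() <= 1.0 + 1e-10
        assert eig.min() >= -1.0 - 1e-10


def test_normalize_rejects_negative_and_asymmetric():
    with pytest.raises(ValueError):
        h.normalize_adjacency(np.array([[0.0, -1.0], [-1.0, 0.0]]))
    with pytest.raises(ValueError):
        h.normalize_adjacency(np.array([[0.0, 1.0], [0.5, 0.0]]))


def test_init_node_features_contract():
    a = h.init_node_features(5, 128, seed=3)
    b = h.init_node_features(5, 128, seed=3)
    c = h.init_node_features(5, 128, seed=4)
    assert np.array_equal(a.values, b.values)
    assert a.values.shape == (5, 128)
    assert not np.array_equal(a.values, c.values)
    with pytest.raises(ValueError):
        h.init_node_features(0, 4, seed=0)


def test_gcn_layer_arithmetic():
    J = h.NormalizedAdjacency(np.array([[0.5, 0.5], [0.5, 0.5]]), ["a", "b"])
    H = h.NodeEmbeddings(np.array([[2.0], [4.0]]), ["a", "b"], 0)
    out = h.gcn_layer(J, H, np.array([[1.0]]), activation="identity")
    assert np.allclose(out.values, [[3.0], [3.0]])
    assert out.layer_index == 1


def test_gcn_layer_identity_and_annihilation():
    J = h.NormalizedAdjacency(np.eye(3), ["a", "b", "c"])
    H = h.NodeEmbeddings(np.random.default_rng(0).normal(size=(3, 4)), ["a", "b", "c"], 0)
    assert np.allclose(h.gcn_layer(J, H, np.eye(4), "identity").values, H.values)
    assert np.allclose(h.gcn_layer(J, H, np.zeros((4, 4)), "relu").values, 0.0)


def test_gcn_layer_linear_in_features():
    rng = np.random.default_rng(2)
    J = h.normalize_adjacency((lambda b: (b + b.T) / 2)(rng.random((5, 5))))
    W = rng.normal(size=(3, 3))
    H1 = rng.normal(size=(5, 3))
    H2 = rng.normal(size=(5, 3))
    combo = h.gcn_layer(J, h.NodeEmbeddings(2 * H1 - 3 * H2, J.ids, 0), W, "identity")
    parts = (
        2 * h.gcn_layer(J, h.NodeEmbeddings(H1, J.ids, 0), W, "identity").values
        - 3 * h.gcn_layer(J, h.NodeEmbeddings(H2, J.ids, 0), W, "identity").values
    )
    assert np.allclose(combo.values, parts, atol=1e-12)


def _params_for(views, n_layers, d, seed, activation="relu", dropout=0.0):
    rng = np.random.default_rng(seed)
    weights = {}
    for side, vs in (("mirna", views.mirna_views), ("disease", views.disease_views)):
        for v in vs:
            weights[f"{side}/{v.view_name}"] = [init_weight(d, d, rng) for _ in range(n_layers)]
    return EncoderParameters(weights, activation, dropout)


def test_encode_views_matches_manual_composition(tiny_dataset):
    views = h.assemble_views(
        tiny_dataset.associations,
        tiny_dataset.mirna_views["functional"],
        tiny_dataset.mirna_views["sequence"],
        tiny_dataset.disease_views["semantic"],
        tiny_dataset.disease_views["target"],
    )
    d = 8
    params = _params_for(views, 2, d, seed=0)
    init_m = h.init_node_features(len(views.mirna_ids), d, 1, views.mirna_ids)
    init_d = h.init_node_features(len(views.disease_ids), d, 2, views.disease_ids)
    per_view, M, D = h.encode_views(views, params, (init_m, init_d), n_layers=2)

    finals = []
    for view in views.mirna_views:
        J = h.normalize_adjacency(view)
        e = init_m
        for W in params.weights[f"mirna/{view.view_name}"]:
            e = h.gcn_layer(J, e, W, "relu")
        finals.append(e.values)
        assert np.allclose(per_view[f"mirna/{view.view_name}"][-1].values, e.values)
    assert np.allclose(M.values, np.mean(finals, axis=0), atol=1e-12)
    assert D.values.shape == (len(views.disease_ids), d)


def test_encode_views_identity_fixed_point(tiny_dataset):
    """Identity similarity + identity weights + identity activation is a no-op."""
    n_m = len(tiny_dataset.associations.mirna_ids)
    n_d = len(tiny_dataset.associations.disease_ids)
    mids, dids = tiny_dataset.associations.mirna_ids, tiny_dataset.associations.disease_ids
    from hypermda.similarity import SimilarityMatrix, SimilarityViewSet

    views = SimilarityViewSet(
        [SimilarityMatrix(np.eye(n_m), mids, n) for n in ("functional", "sequence", "gip")],
        [SimilarityMatrix(np.eye(n_d), dids, n) for n in ("semantic", "target", "gip")],
    )
    d = 4
    weights = {
        f"{side}/{name}": [np.eye(d), np.eye(d)]
        for side, names in (("mirna", ("functional", "sequence", "gip")),
                            ("disease", ("semantic", "target", "gip")))
        for name in names
    }
    params = EncoderParameters(weights, "identity", 0.0)
    init_m = h.init_node_features(n_m, d, 5, mids)
    init_d = h.init_node_features(n_d, d, 6, dids)
    _, M, D = h.encode_views(views, params, (init_m, init_d), n_layers=2)
    assert np.allclose(M.values, init_m.values, atol=1e-12)
    assert np.allclose(D.values, init_d.values, atol=1e-12)


def test_encoder_permutation_equivariance(tiny_dataset):
    views = h.assemble_views(
        tiny_dataset.associations,
        tiny_dataset.mirna_views["functional"],
        tiny_dataset.mirna_views["sequence"],
        tiny_dataset.disease_views["semantic"],
        tiny_dataset.disease_views["target"],
    )
    d = 6
    params = _params_for(views, 2, d, seed=4)
    init_m = h.init_node_features(len(views.mirna_ids), d, 1, views.mirna_ids)
    init_d = h.init_node_features(len(views.disease_ids), d, 2, views.disease_ids)
    _, M, _ = h.encode_views(views, params, (init_m, init_d), n_layers=2)

    rng = np.random.default_rng(9)
    perm = rng.permutation(len(views.mirna_ids))
    perm_views = h.SimilarityViewSet(
        [h.SimilarityMatrix(v.values[np.ix_(perm, perm)], [v.ids[p] for p in perm], v.view_name)
         for v in views.mirna_views],
        views.disease_views,
    )
    perm_init_m = h.NodeEmbeddings(init_m.values[perm], [init_m.ids[p] for p in perm], 0)
    _, Mp, _ = h.encode_views(perm_views, params, (perm_init_m, init_d), n_layers=2)
    assert np.allclose(Mp.values, M.values[perm], atol=1e-10)
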
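"""Equivariant encoder: formula oracles, equivariance contract,
locality, determinism."""

import numpy as np
import pytest

from protacdeg import chem_io
from protacdeg.egnn import (EgnnEncoder, EuclideanTransform, GraphBatch,
                            check_equivariance, random_transform)
from protacdeg.featurize import ATOM_FEATURE_DIM
from protacdeg.synthetic import random_molecule

RNG = np.random.default_rng(1234)


def make_encoder(n_layers=1, d_hidden=8, rng=None, **kw):
    rng = rng or np.random.default_rng(0)
    return EgnnEncoder(ATOM_FEATURE_DIM, d_hidden, n_layers,
                       chem_io.EDGE_ATTR_DIM, rng, coord_gate_zero_init=False, **kw)


# ---------------------------------------------------------------------------
# independent naive-loop oracle
# ---------------------------------------------------------------------------

def _mlp_np(mlp, x):
    """Evaluate an MLP with plain NumPy, independent of the autodiff path."""
    def _silu(v):
        return v / (1.0 + np.exp(-v))

    for i, layer in enumerate(mlp.layers):
        x = x @ layer.W.value + layer.b.value
        if i < len(mlp.layers) - 1:
            x = _silu(x)
    return x


def naive_layer(layer, g, h, x, normalize=False):
    """Double-loop evaluation of one message-passing layer."""
    n = len(h)
    adj = g.adjacency
    attr = {}
    for e, (i, j) in enumerate(g.edges):
        attr[(i, j)] = attr[(j, i)] = g.edge_attr[e]
    m = {}
    for i in range(n):
        for j in range(n):
            if adj[i, j]:
                d2 = np.sum((x[i] - x[j]) ** 2)
                inp = np.concatenate([attr[(i, j)], h[i], h[j], [d2]])
                m[(i, j)] = _mlp_np(layer.phi_e, inp)
    x_new = x.copy()
    for i in range(n):
        delta = np.zeros(3)
        for j in range(n):
            if adj[i, j]:
                diff = x[i] - x[j]
                norm = np.sqrt(np.sum(diff ** 2) + 1e-16)
                delta += diff / (norm + 1e-8) * _mlp_np(layer.phi_x, m[(i, j)])[0]
        if normalize and adj[i].sum() > 0:
            delta /= adj[i].sum()
        x_new[i] = x[i] + delta
    h_new = np.zeros((n, layer.phi_h.layers[-1].b.value.shape[0]))
    for i in range(n):
        mi = np.zeros_like(_mlp_np(layer.phi_e, np.zeros(
            layer.phi_e.layers[0].W.value.shape[0])))
        for j in range(n):
            if adj[i, j]:
                mi = mi + m[(i, j)]
        h_new[i] = _mlp_np(layer.phi_h, np.concatenate([h[i], mi]))
    return h_new, x_new


def naive_encode(encoder, g):
    h, x = g.features.astype(float), g.coords.astype(float)
    for layer in encoder.layers:
        h, x = naive_layer(layer, g, h, x, encoder.normalize_coord_update)
    return h, x


@pytest.mark.parametrize("n_layers,normalize", [(1, False), (2, False), (1, True),
                                                (3, False)])
def test_layer_outputs_match_naive_loop(n_layers, normalize):
    for trial in range(7):
        g, _ = random_molecule(int(RNG.integers(3, 12)), rng=RNG)
        enc = make_encoder(n_layers=n_layers, rng=np.random.default_rng(trial),
                           normalize_coord_update=normalize)
        h, x = enc(GraphBatch.from_graphs([g]))
        h_ref, x_ref = naive_encode(enc, g)
        np.testing.assert_allclose(h.value, h_ref, atol=1e-6)
        np.testing.assert_allclose(x.value, x_ref, atol=1e-6)


def test_edge_message_depends_on_distance_only():
    """Translating both endpoints leaves the message unchanged; the
    coordinate dependence enters only through the squared distance."""
    g, _ = random_molecule(5, seed=2)
    enc = make_encoder()
    layer = enc.layers[0]
    i, j = g.edges[0]
    h = g.features
    d2 = np.sum((g.coords[i] - g.coords[j]) ** 2)
    inp = np.concatenate([g.edge_attr[0], h[i], h[j], [d2]])
    m1 = _mlp_np(layer.phi_e, inp)
    # same squared distance, different absolute positions -> same message
    m2 = _mlp_np(layer.phi_e, np.concatenate([g.edge_attr[0], h[i], h[j], [d2]]))
    np.testing.assert_allclose(m1, m2)
    # coincident atoms: distance 0 is a valid input
    m0 = _mlp_np(layer.phi_e, np.concatenate([g.edge_attr[0], h[i], h[i], [0.0]]))
    assert np.all(np.isfinite(m0))


def test_isolated_node_coords_unchanged():
    g, _ = random_molecule(6, seed=4)
    # detach node 0: remove all incident edges
    mask = ~np.any(g.edges == 0, axis=1)
    g.edges = g.edges[mask]
    g.edge_kind = [k for k, m in zip(g.edge_kind, mask) if m]
    g.edge_attr = g.edge_attr[mask]
    enc = make_encoder()
    _, x = enc(GraphBatch.from_graphs([g]))
    np.testing.assert_allclose(x.value[0], g.coords[0])


def test_symmetric_pair_updates_preserve_centroid():
    feats = np.tile(np.zeros(ATOM_FEATURE_DIM), (2, 1))
    feats[:, 0] = 1.0
    attr = np.zeros((1, chem_io.EDGE_ATTR_DIM))
    attr[0, 0] = 1.0
    attr[0, -1] = 2.0
    g = chem_io.MoleculeGraph(kind="PROTAC", coords=np.array([[1.0, 0, 0], [-1.0, 0, 0]]),
                              features=feats, edges=np.array([[0, 1]]),
                              edge_kind=["bond"], edge_attr=attr, elements=["C", "C"])
    enc = make_encoder()
    _, x = enc(GraphBatch.from_graphs([g]))
    np.testing.assert_allclose(x.value.mean(axis=0), [0, 0, 0], atol=1e-12)
    np.testing.assert_allclose(x.value[0], -x.value[1], atol=1e-12)


def test_coincident_atoms_never_nan():
    feats = np.zeros((2, ATOM_FEATURE_DIM))
    attr = np.zeros((1, chem_io.EDGE_ATTR_DIM))
    g = chem_io.MoleculeGraph(kind="PROTAC", coords=np.zeros((2, 3)),
                              features=feats, edges=np.array([[0, 1]]),
                              edge_kind=["bond"], edge_attr=attr, elements=["C", "C"])
    h, x = make_encoder()(GraphBatch.from_graphs([g]))
    assert np.all(np.isfinite(h.value)) and np.all(np.isfinite(x.value))


def test_zero_layers_is_identity():
    g, _ = random_molecule(5, seed=6)
    enc = EgnnEncoder(ATOM_FEATURE_DIM, 8, 0, chem_io.EDGE_ATTR_DIM,
                      np.random.default_rng(0))
    h, x = enc(GraphBatch.from_graphs([g]))
    np.testing.assert_array_equal(h.value, g.features)
    np.testing.assert_array_equal(x.value, g.coords)


def test_permutation_equivariance():
    g, _ = random_molecule(7, seed=8)
    enc = make_encoder(n_layers=2)
    h1, x1 = enc(GraphBatch.from_graphs([g]))
    perm = np.random.default_rng(3).permutation(g.n_nodes)
    inv = np.argsort(perm)
    g2 = chem_io.MoleculeGraph(
        kind="PROTAC", coords=g.coords[perm], features=g.features[perm],
        edges=np.sort(inv[g.edges], axis=1), edge_kind=list(g.edge_kind),
        edge_attr=g.edge_attr.copy(), elements=[g.elements[p] for p in perm])
    h2, x2 = enc(GraphBatch.from_graphs([g2]))
    np.testing.assert_allclose(h2.value, h1.value[perm], atol=1e-10)
    np.testing.assert_allclose(x2.value, x1.value[perm], atol=1e-10)


def test_two_layer_encode_composes_single_layers():
    g, _ = random_molecule(5, seed=10)
    enc = make_encoder(n_layers=2)
    h, x, trace = enc(GraphBatch.from_graphs([g]), return_trace=True)
    assert len(trace) == 3
    np.testing.assert_array_equal(trace[0][0].value, g.features)
    h1, x1 = naive_layer(enc.layers[0], g, g.features.astype(float),
                         g.coords.astype(float))
    np.testing.assert_allclose(trace[1][0].value, h1, atol=1e-6)
    h2, x2 = naive_layer(enc.layers[1], g, h1, x1)
    np.testing.assert_allclose(h.value, h2, atol=1e-6)
    np.testing.assert_allclose(x.value, x2, atol=1e-6)


def test_locality_zeroed_neighborhood():
    """Removing all edges of one node leaves other nodes' 1-layer
    outputs unchanged."""
    g, _ = random_molecule(8, seed=12)
    enc = make_encoder(n_layers=1)
    v = 0
    mask = ~np.any(g.edges == v, axis=1)
    g_cut = chem_io.MoleculeGraph(
        kind="PROTAC", coords=g.coords, features=g.features,
        edges=g.edges[mask], edge_kind=[k for k, m in zip(g.edge_kind, mask) if m],
        edge_attr=g.edge_attr[mask], elements=list(g.elements))
    h1, _ = enc(GraphBatch.from_graphs([g]))
    h2, _ = enc(GraphBatch.from_graphs([g_cut]))
    neighbors = set(g.edges[~mask].ravel())
    untouched = [i for i in range(g.n_nodes) if i not in neighbors]
    np.testing.assert_allclose(h2.value[untouched], h1.value[untouched])


def test_determinism_bitwise():
    g, _ = random_molecule(9, seed=14)
    enc = make_encoder(n_layers=3)
    h1, x1 = enc(GraphBatch.from_graphs([g]))
    h2, x2 = enc(GraphBatch.from_graphs([g]))
    assert np.array_equal(h1.value, h2.value)
    assert np.array_equal(x1.value, x2.value)


def test_dimension_mismatch_raises_before_compute():
    g, _ = random_molecule(4, seed=16)
    enc = EgnnEncoder(ATOM_FEATURE_DIM + 1, 8, 1, chem_io.EDGE_ATTR_DIM,
                      np.random.default_rng(0))
    with pytest.raises(ValueError, match="features have size"):
        enc(GraphBatch.from_graphs([g]))


# ---------------------------------------------------------------------------
# equivariance contract
# ---------------------------------------------------------------------------

def test_identity_transform_is_exact():
    g, _ = random_molecule(6, seed=18)
    enc = make_encoder(n_layers=2)
    t = EuclideanTransform(rotation=np.eye(3), translation=np.zeros(3))
    rep = check_equivariance(g, enc, t)
    assert rep["feature_invariance_max"] == 0.0
    assert rep["coord_equivariance_max"] == 0.0


@pytest.mark.parametrize("reflect", [False, True])
def test_random_transform_equivariance(reflect):
    rng = np.random.default_rng(21 + reflect)
    for _ in range(10):
        g, _ = random_molecule(int(rng.integers(3, 12)), rng=rng)
        enc = make_encoder(n_layers=2, rng=rng)
        rep = check_equivariance(g, enc, random_transform(rng, reflect=reflect))
        assert rep["passed"], rep
        assert rep["feature_invariance_max"] <= 1e-8
        assert rep["coord_equivariance_max"] <= 1e-8


def test_nonorthogonal_transform_rejected():
    with pytest.raises(ValueError, match="orthogonal"):
        EuclideanTransform(rotation=np.diag([2.0, 1.0, 1.0]), translation=np.zeros(3))
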
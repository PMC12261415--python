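"""E(3)-equivariant graph encoder.

Each layer passes messages along edges and updates both node features
and node coordinates:

    m_ij = phi_e(a_ij, h_i, h_j, ||x_i - x_j||^2)
    dx_i = sum_j (x_i - x_j) / (||x_i - x_j|| + eps) * phi_x(m_ij)
    x_i  <- x_i + dx_i
    m_i  = sum_j m_ij
    h_i  <- phi_h(h_i || m_i)

Features depend on geometry only through interatomic distances, so they
are invariant under any rigid motion or reflection of the input, while
the coordinate stream is equivariant: rotating/translating the input
rotates/translates the output coordinates identically.  The coordinate
sum is unnormalized by default, with an optional 1/n_i (mean over
neighbors) variant.

Graphs are processed as disjoint unions (:class:`GraphBatch`), so a
whole minibatch runs through one set of array operations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, segment_sum
from .nn import MLP

__all__ = ["GraphBatch", "EuclideanTransform", "EgnnEncoder",
           "random_transform", "check_equivariance"]

_EPS_NORM = 1e-8  # added to the distance before dividing the difference vector


@dataclass
class GraphBatch:
    """Disjoint union of molecule graphs with directed edges.

    Every undirected edge {i, j} appears twice, once per direction;
    ``edge_recv[e]`` is the node receiving message ``e`` from
    ``edge_send[e]``.
    """

    features: np.ndarray      # (N, d_in)
    coords: np.ndarray        # (N, 3)
    edge_recv: np.ndarray     # (E,)
    edge_send: np.ndarray     # (E,)
    edge_attr: np.ndarray     # (E, d_edge)
    node_graph: np.ndarray    # (N,) graph id per node
    n_graphs: int

    @property
    def n_nodes(self) -> int:
        return self.features.shape[0]

    @property
    def neighbor_counts(self) -> np.ndarray:
        c = np.zeros(self.n_nodes)
        np.add.at(c, self.edge_recv, 1.0)
        return c

    @classmethod
    def from_graphs(cls, graphs) -> "GraphBatch":
        feats, coords, recv, send, attr, gid = [], [], [], [], [], []
        offset = 0
        for g_idx, g in enumerate(graphs):
            n = g.n_nodes
            feats.append(g.features)
            coords.append(g.coords)
            if len(g.edges):
                e = g.edges + offset
                recv.append(np.concatenate([e[:, 0], e[:, 1]]))
                send.append(np.concatenate([e[:, 1], e[:, 0]]))
                attr.append(np.concatenate([g.edge_attr, g.edge_attr]))
            gid.append(np.full(n, g_idx))
            offset += n
        d_edge = graphs[0].edge_attr.shape[1]
        return cls(
            features=np.concatenate(feats).astype(float),
            coords=np.concatenate(coords).astype(float),
            edge_recv=np.concatenate(recv) if recv else np.zeros(0, dtype=int),
            edge_send=np.concatenate(send) if send else np.zeros(0, dtype=int),
            edge_attr=np.concatenate(attr) if attr else np.zeros((0, d_edge)),
            node_graph=np.concatenate(gid),
            n_graphs=len(list(graphs)),
        )


@dataclass
class EuclideanTransform:
    """Rigid motion (optionally improper): x -> rotation @ x + translation."""

    rotation: np.ndarray   # (3, 3), orthogonal, det ±1
    translation: np.ndarray  # (3,)

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-6):
            raise ValueError("rotation matrix is not orthogonal")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def random_transform(rng: np.random.Generator, reflect: bool | None = None,
                     translation_scale: float = 10.0) -> EuclideanTransform:
    """Random rotation (or rotoreflection) + translation."""
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if reflect is None:
        reflect = bool(rng.integers(2))
    if (np.linalg.det(q) < 0) != reflect:
        q[:, 0] = -q[:, 0]
    return EuclideanTransform(rotation=q,
                              translation=rng.normal(scale=translation_scale, size=3))


class _EgnnLayer:
    def __init__(self, d_in: int, d_hidden: int, d_edge: int,
                 rng: np.random.Generator, geometric: bool,
                 coord_gate_zero_init: bool = True):
        self.geometric = geometric
        d_msg_in = d_edge + 2 * d_in + (1 if geometric else 0)
        self.phi_e = MLP([d_msg_in, d_hidden, d_hidden], rng)
        self.phi_x = MLP([d_hidden, d_hidden, 1], rng,
                         zero_init_last=coord_gate_zero_init)
        self.phi_h = MLP([d_in + d_hidden, d_hidden, d_hidden], rng)

    def __call__(self, h: Tensor, x: Tensor, batch: GraphBatch,
                 normalize: bool) -> tuple:
        n = batch.n_nodes
        if len(batch.edge_recv) == 0:
            zero_m = Tensor(np.zeros((n, self.phi_e.layers[-1].b.value.shape[0])))
            return self.phi_h(concat([h, zero_m], axis=-1)), x

        hi = h.take(batch.edge_recv)
        hj = h.take(batch.edge_send)
        attr = Tensor(batch.edge_attr)
        if self.geometric:
            diff = x.take(batch.edge_recv) - x.take(batch.edge_send)
            d2 = (diff * diff).sum(axis=1, keepdims=True)
            m = self.phi_e(concat([attr, hi, hj, d2], axis=-1))
            norm = (d2 + 1e-16) ** 0.5
            unit = diff * ((norm + _EPS_NORM) ** -1.0)
            contrib = unit * self.phi_x(m)
            dx = segment_sum(contrib, batch.edge_recv, n)
            if normalize:
                ni = np.maximum(batch.neighbor_counts, 1.0)
                dx = dx * (1.0 / ni)[:, None]
            x = x + dx
        else:
            m = self.phi_e(concat([attr, hi, hj], axis=-1))

        mi = segment_sum(m, batch.edge_recv, n)
        h = self.phi_h(concat([h, mi], axis=-1))
        return h, x

    def parameters(self):
        ps = self.phi_e.parameters() + self.phi_h.parameters()
        if self.geometric:
            ps += self.phi_x.parameters()
        return ps


class EgnnEncoder:
    """Stack of L equivariant layers mapping (H, X) -> (H', X_L).

    ``geometric=False`` gives the non-geometric ablation: coordinates
    are ignored entirely (no distance input, no coordinate updates, and
    the distance column of the edge attributes is zeroed), reducing the
    layer to plain relational message passing.
    """

    def __init__(self, d_in: int, d_hidden: int, n_layers: int, d_edge: int,
                 rng: np.random.Generator, geometric: bool = True,
                 normalize_coord_update: bool = False,
                 coord_gate_zero_init: bool = True):
        self.d_in = d_in
        self.d_hidden = d_hidden
        self.n_layers = n_layers
        self.geometric = geometric
        self.normalize_coord_update = normalize_coord_update
        self.layers = [
            _EgnnLayer(d_in if l == 0 else d_hidden, d_hidden, d_edge, rng,
                       geometric, coord_gate_zero_init=coord_gate_zero_init)
            for l in range(n_layers)
        ]

    def __call__(self, batch: GraphBatch, return_trace: bool = False):
        if batch.features.shape[1] != self.d_in:
            raise ValueError(
                f"graph features have size {batch.features.shape[1]}, "
                f"encoder expects {self.d_in}")
        if not self.geometric:
            batch = GraphBatch(
                features=batch.features, coords=batch.coords,
                edge_recv=batch.edge_recv, edge_send=batch.edge_send,
                edge_attr=np.concatenate(
                    [batch.edge_attr[:, :-1], np.zeros((len(batch.edge_attr), 1))],
                    axis=1),
                node_graph=batch.node_graph, n_graphs=batch.n_graphs)
        h = Tensor(batch.features)
        x = Tensor(batch.coords)
        trace = [(h, x)]
        for layer in self.layers:
            h, x = layer(h, x, batch, self.normalize_coord_update)
            trace.append((h, x))
        if return_trace:
            return h, x, trace
        return h, x

    def encode_graph(self, graph) -> tuple:
        """Run a single graph; returns (H, X_L) as NumPy arrays."""
        h, x = self(GraphBatch.from_graphs([graph]))
        return h.value, x.value

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]


def check_equivariance(graph, encoder: EgnnEncoder,
                       transform: EuclideanTransform, tol: float = 1e-8) -> dict:
    """Executable equivariance contract.

    Runs the encoder on the graph and on its transformed copy and
    checks (a) feature invariance — the node embeddings agree — and
    (b) coordinate equivariance — output coordinates of the transformed
    input equal the transformed output coordinates.  Returns the two
    maxima, per-node worst offenders, and a pass flag.
    """
    base = GraphBatch.from_graphs([graph])
    h1, x1 = encoder(base)
    moved = GraphBatch(
        features=base.features, coords=transform.apply(base.coords),
        edge_recv=base.edge_recv, edge_send=base.edge_send,
        edge_attr=base.edge_attr, node_graph=base.node_graph,
        n_graphs=base.n_graphs)
    h2, x2 = encoder(moved)

    feat_err = np.abs(h2.value - h1.value)
    coord_err = np.abs(x2.value - transform.apply(x1.value))
    report = {
        "feature_invariance_max": float(feat_err.max()),
        "coord_equivariance_max": float(coord_err.max()),
        "worst_feature_node": int(feat_err.max(axis=1).argmax()),
        "worst_coord_node": int(coord_err.max(axis=1).argmax()),
        "tol": tol,
    }
    report["passed"] = (report["feature_invariance_max"] <= tol
                        and report["coord_equivariance_max"] <= tol)
    return report
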
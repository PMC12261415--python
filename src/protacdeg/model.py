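"""Mutual attention pooling and the ternary-complex classifier.

Pooling computes a per-node relevance weight from the interaction of
the node embedding with the graph's attribute vector:

    q_i = WQ h_i,   k = WK f,
    w_i = softmax_i(a^T tanh(q_i || k)),
    z   = sum_i w_i h_i + f.

The PROTAC attribute vector f_P comes from the descriptor/fingerprint
encoder; protein graphs have no chemical descriptors, so their
attributes f_T and f_E are free learned vectors.  The three graph
embeddings are concatenated (z = z_P || z_T || z_E) and a two-layer
perceptron produces logits over {low, high} degradation activity.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, log_softmax, segment_softmax, segment_sum, tanh
from .egnn import EgnnEncoder, GraphBatch
from .featurize import ATOM_FEATURE_DIM, AttributeEncoder
from .nn import MLP, Linear, Parameter

__all__ = ["MutualAttentionPool", "DegradationModel", "edge_attention_map",
           "fuse_and_classify"]


class MutualAttentionPool:
    """Attention readout of node embeddings keyed by the attribute vector.

    ``mean_pool=True`` switches to the ablation variant: uniform weights
    1/N, i.e. z = mean(H) + f.
    """

    def __init__(self, d_hidden: int, d_attr: int, d_attention: int,
                 rng: np.random.Generator, mean_pool: bool = False):
        self.WQ = Parameter(rng.uniform(-1, 1, (d_hidden, d_attention)) / np.sqrt(d_hidden))
        self.WK = Parameter(rng.uniform(-1, 1, (d_attr, d_attention)) / np.sqrt(d_attr))
        self.a = Parameter(rng.uniform(-1, 1, (2 * d_attention,)) / np.sqrt(2 * d_attention))
        self.mean_pool = mean_pool

    def __call__(self, H: Tensor, F: Tensor, node_graph: np.ndarray,
                 n_graphs: int) -> tuple:
        """Pool node embeddings per graph.

        ``H`` is (N, d') over all nodes of the batch, ``F`` is
        (n_graphs, d_attr); returns (z of shape (n_graphs, d'), weights
        of shape (N,) summing to 1 within each graph).
        """
        if self.mean_pool:
            counts = np.zeros(n_graphs)
            np.add.at(counts, node_graph, 1.0)
            w = Tensor(1.0 / counts[node_graph])
        else:
            q = H @ self.WQ
            k = (F @ self.WK).take(node_graph)
            logits = tanh(concat([q, k], axis=-1)) @ self.a
            w = segment_softmax(logits, node_graph, n_graphs)
        z = segment_sum(w.reshape(-1, 1) * H, node_graph, n_graphs) + F
        return z, w

    def parameters(self):
        return [] if self.mean_pool else [self.WQ, self.WK, self.a]


def fuse_and_classify(zP: Tensor, zT: Tensor, zE: Tensor, head: MLP) -> tuple:
    """Concatenate the three graph embeddings and classify.

    Returns (logits over {low, high}, probability of the high class).
    """
    if not (zP.shape[-1] == zT.shape[-1] == zE.shape[-1]):
        raise ValueError("graph embeddings must share the hidden size")
    logits = head(concat([zP, zT, zE], axis=-1))
    logp = log_softmax(logits, axis=-1)
    return logits, np.exp(logp.value[..., 1])


def edge_attention_map(graph, weights: np.ndarray) -> np.ndarray:
    """Average the attention weights of an edge's endpoints:
    value(e_ij) = (w_i + w_j) / 2.  Returns one scalar per edge of the
    graph, for visualization export."""
    weights = np.asarray(weights)
    if len(weights) != graph.n_nodes:
        raise ValueError("weights length must equal node count")
    if len(graph.edges) == 0:
        return np.zeros(0)
    return 0.5 * (weights[graph.edges[:, 0]] + weights[graph.edges[:, 1]])


def write_attention_mol2(graph, weights: np.ndarray, path) -> None:
    """Write a mol2 copy of a PROTAC graph with each atom's attention
    weight in the charge column, for external molecular viewers."""
    weights = np.asarray(weights)
    if len(weights) != graph.n_nodes:
        raise ValueError("weights length must equal node count")
    lines = ["@<TRIPOS>MOLECULE", "attention_annotated",
             f"{graph.n_nodes} {len(graph.edges)} 0 0 0", "SMALL", "USER_CHARGES", "",
             "@<TRIPOS>ATOM"]
    for i, (el, xyz, w) in enumerate(zip(graph.elements, graph.coords, weights),
                                     start=1):
        lines.append(f"{i:>7d} {el}{i:<3d} {xyz[0]:>10.4f} {xyz[1]:>10.4f} "
                     f"{xyz[2]:>10.4f} {el}.3 1 LIG {w:>10.6f}")
    lines.append("@<TRIPOS>BOND")
    for b, (i, j) in enumerate(graph.edges, start=1):
        lines.append(f"{b:>6d} {i + 1:>5d} {j + 1:>5d} 1")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


class DegradationModel:
    """Full ternary-complex classifier.

    Three entity-specific equivariant encoders (PROTAC, POI, E3), one
    mutual-attention pool per entity, the attribute encoder for the
    PROTAC, learned attribute vectors for the two proteins, and a
    2-layer classification head on the concatenated embedding.
    """

    ENTITIES = ("PROTAC", "POI", "E3")

    def __init__(self, config, n_desc: int, seed: int):
        from .config import ModelConfig  # noqa: F401  (typing aid)

        rng = np.random.default_rng(seed)
        c = config
        self.config = config
        d = c.d_hidden
        from .chem_io import EDGE_ATTR_DIM

        self.encoders = {
            ent: EgnnEncoder(ATOM_FEATURE_DIM, d, c.n_layers, EDGE_ATTR_DIM, rng,
                             geometric=c.geometric,
                             normalize_coord_update=c.normalize_coord_update)
            for ent in self.ENTITIES
        }
        self.attr_encoder = AttributeEncoder(n_desc, c.fp_bits, d, rng)
        self.protein_attrs = {
            "POI": Parameter(rng.normal(scale=0.1, size=d)),
            "E3": Parameter(rng.normal(scale=0.1, size=d)),
        }
        self.pools = {
            ent: MutualAttentionPool(d, d, c.d_attention, rng,
                                     mean_pool=not c.attention_pooling)
            for ent in self.ENTITIES
        }
        self.head = MLP([3 * d, d, 2], rng)

    # -- forward --------------------------------------------------------
    def forward(self, batches: dict, desc_z: np.ndarray, fps: np.ndarray,
                return_weights: bool = False):
        """Run a batch.

        ``batches`` maps entity name -> :class:`GraphBatch` (same number
        of graphs each); ``desc_z`` are standardized selected
        descriptors (B, n_desc) and ``fps`` fingerprints (B, n_bits).
        Returns (logits (B,2), z (B,3d'), per-entity attention weights).
        """
        b = batches["PROTAC"].n_graphs
        fP = self.attr_encoder(Tensor(desc_z), Tensor(fps))
        zs, ws = {}, {}
        for ent in self.ENTITIES:
            H, _ = self.encoders[ent](batches[ent])
            if ent == "PROTAC":
                F = fP
            else:
                F = self.protein_attrs[ent].reshape(1, -1) * np.ones((b, 1))
            zs[ent], ws[ent] = self.pools[ent](H, F, batches[ent].node_graph, b)
        z = concat([zs["PROTAC"], zs["POI"], zs["E3"]], axis=-1)
        logits = self.head(z)
        if return_weights:
            return logits, z, ws
        return logits, z

    def predict_proba(self, batches: dict, desc_z, fps) -> np.ndarray:
        logits, _ = self.forward(batches, desc_z, fps)
        logp = log_softmax(logits, axis=-1)
        return np.exp(logp.value[:, 1])

    def loss(self, logits: Tensor, labels: np.ndarray,
             class_weights: np.ndarray) -> Tensor:
        """Class-weighted cross-entropy on the two logits."""
        labels = np.asarray(labels, dtype=int)
        onehot = np.zeros((len(labels), 2))
        onehot[np.arange(len(labels)), labels] = 1.0
        w = class_weights[labels]
        logp = log_softmax(logits, axis=-1)
        nll = -(logp * onehot).sum(axis=-1)
        return (nll * w).sum() * (1.0 / w.sum())

    # -- parameters and serialization -----------------------------------
    def parameters(self):
        ps = []
        for ent in self.ENTITIES:
            ps += self.encoders[ent].parameters()
            ps += self.pools[ent].parameters()
        ps += self.attr_encoder.parameters()
        ps += [self.protein_attrs["POI"], self.protein_attrs["E3"]]
        ps += self.head.parameters()
        return ps

    def state_arrays(self) -> list:
        return [p.value.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("checkpoint does not match model architecture")
        for p, a in zip(params, arrays):
            if p.value.shape != a.shape:
                raise ValueError("checkpoint parameter shape mismatch")
            p.value = np.array(a, dtype=float)

    def save(self, path, extra: dict | None = None) -> None:
        import hashlib
        import json

        cfg = json.dumps(self.config.to_dict(), sort_keys=True)
        arrays = {f"p{i}": a for i, a in enumerate(self.state_arrays())}
        meta = {"config": cfg,
                "config_hash": hashlib.sha256(cfg.encode()).hexdigest(),
                **(extra or {})}
        np.savez(path, __meta__=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path, n_desc: int):
        import json

        from .config import ModelConfig

        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["__meta__"]))
        config = ModelConfig.from_dict(json.loads(meta["config"]))
        model = cls(config, n_desc=n_desc, seed=0)
        model.load_state_arrays([data[f"p{i}"] for i in range(len(model.parameters()))])
        return model
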
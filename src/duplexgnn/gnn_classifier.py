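"""Graph classifier: message-passing layers, global pooling, FC softmax head.

Three node-embedding families are supported:

* ``GCN``  — spectral convolution with the self-loop renormalisation
  sigma(D^-1/2 (A+I) D^-1/2 H W);
* ``SAGE`` — mean neighbourhood aggregation (self excluded), concatenation,
  linear map, nonlinearity, then row-wise L2 normalisation;
* ``GAT``  — single-head attention, LeakyReLU(0.2) scores, self-loop in the
  neighbourhood, softmax-normalised coefficients.

All layers use ReLU internally; the head pools node embeddings (ADD / MEAN /
MAX), applies L_FC fully connected layers with ReLU between them and
Dropout(R_D) after every but the last one, and ends in a 2-way softmax.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .duplex_graph import DuplexGraph

__all__ = [
    "ClassifierConfig",
    "ModelParameters",
    "init_parameters",
    "parameter_shapes",
    "Batch",
    "collate",
    "forward_batch",
    "forward",
    "gcn_layer",
    "sage_layer",
    "gat_layer",
    "global_pool",
]

EMBEDDING_FAMILIES = ("GCN", "GAT", "SAGE")
POOLING_OPS = ("ADD", "MEAN", "MAX")
LEAKY_SLOPE = 0.2


@dataclass(frozen=True)
class ClassifierConfig:
    """Architecture hyperparameters.

    The three tuned reference configurations are (family, L_GNN, D_GNN,
    L_FC, D_FC, pooling, dropout): GCN 3/128/2/512/MAX/0.4,
    GAT 5/256/2/128/ADD/0.4, SAGE 5/256/3/256/ADD/0.4.
    """

    e_gnn: str = "GAT"
    l_gnn: int = 5
    d_gnn: int = 256
    l_fc: int = 2
    d_fc: int = 128
    p_h: str = "ADD"
    r_d: float = 0.4
    input_dim: int = 16

    def __post_init__(self):
        if self.e_gnn not in EMBEDDING_FAMILIES:
            raise ValueError(f"e_gnn must be one of {EMBEDDING_FAMILIES}, got {self.e_gnn!r}")
        if self.p_h not in POOLING_OPS:
            raise ValueError(f"p_h must be one of {POOLING_OPS}, got {self.p_h!r}")
        for name in ("l_gnn", "d_gnn", "l_fc", "d_fc", "input_dim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0.0 <= self.r_d < 1.0):
            raise ValueError(f"r_d must be in [0, 1), got {self.r_d}")

    def as_dict(self) -> dict:
        return {
            "e_gnn": self.e_gnn, "l_gnn": self.l_gnn, "d_gnn": self.d_gnn,
            "l_fc": self.l_fc, "d_fc": self.d_fc, "p_h": self.p_h,
            "r_d": self.r_d, "input_dim": self.input_dim,
        }


@dataclass
class ModelParameters:
    """Trainable weights; shapes are dictated by a ClassifierConfig."""

    gnn: list[dict[str, Tensor]]
    fc: list[dict[str, Tensor]]

    def tensors(self) -> list[Tensor]:
        out: list[Tensor] = []
        for layer in self.gnn + self.fc:
            out.extend(layer.values())
        return out

    def shapes(self) -> list[dict[str, tuple[int, ...]]]:
        return [{k: v.data.shape for k, v in layer.items()}
                for layer in self.gnn + self.fc]

    def copy_arrays(self) -> list[np.ndarray]:
        return [t.data.copy() for t in self.tensors()]

    def load_arrays(self, arrays: list[np.ndarray]) -> None:
        tensors = self.tensors()
        if len(arrays) != len(tensors):
            raise ValueError("parameter count mismatch")
        for t, a in zip(tensors, arrays):
            if t.data.shape != a.shape:
                raise ValueError("parameter shape mismatch")
            t.data = a.copy()

    def save(self, path: str | Path) -> None:
        np.savez(path, *[t.data for t in self.tensors()])

    @staticmethod
    def load(path: str | Path, config: "ClassifierConfig") -> "ModelParameters":
        params = init_parameters(config, np.random.default_rng(0))
        with np.load(path) as data:
            params.load_arrays([data[k] for k in data.files])
        return params


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape: tuple[int, ...]) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


def parameter_shapes(config: ClassifierConfig) -> list[dict[str, tuple[int, ...]]]:
    """Expected parameter shapes, for config-fidelity inspection."""
    shapes: list[dict[str, tuple[int, ...]]] = []
    f_in = config.input_dim
    for _ in range(config.l_gnn):
        if config.e_gnn == "SAGE":
            layer = {"W": (2 * f_in, config.d_gnn)}
        elif config.e_gnn == "GAT":
            layer = {"W": (f_in, config.d_gnn), "a": (2 * config.d_gnn,)}
        else:
            layer = {"W": (f_in, config.d_gnn)}
        shapes.append(layer)
        f_in = config.d_gnn
    width = config.d_gnn
    for i in range(config.l_fc):
        out = 2 if i == config.l_fc - 1 else config.d_fc
        shapes.append({"W": (width, out), "b": (out,)})
        width = out
    return shapes


def init_parameters(config: ClassifierConfig, rng: np.random.Generator) -> ModelParameters:
    gnn: list[dict[str, Tensor]] = []
    f_in = config.input_dim
    for _ in range(config.l_gnn):
        if config.e_gnn == "SAGE":
            layer = {"W": _glorot(rng, 2 * f_in, config.d_gnn, (2 * f_in, config.d_gnn))}
        elif config.e_gnn == "GAT":
            layer = {
                "W": _glorot(rng, f_in, config.d_gnn, (f_in, config.d_gnn)),
                "a": _glorot(rng, 2 * config.d_gnn, 1, (2 * config.d_gnn,)),
            }
        else:
            layer = {"W": _glorot(rng, f_in, config.d_gnn, (f_in, config.d_gnn))}
        gnn.append(layer)
        f_in = config.d_gnn
    fc: list[dict[str, Tensor]] = []
    width = config.d_gnn
    for i in range(config.l_fc):
        out = 2 if i == config.l_fc - 1 else config.d_fc
        fc.append({
            "W": _glorot(rng, width, out, (width, out)),
            "b": Tensor(np.zeros(out), requires_grad=True),
        })
        width = out
    return ModelParameters(gnn=gnn, fc=fc)


# ---------------------------------------------------------------------------
# batching
# ---------------------------------------------------------------------------

@dataclass
class Batch:
    """Several duplex graphs merged into one block-diagonal graph."""

    features: np.ndarray        # (V_total, F)
    src: np.ndarray             # directed arcs, both directions, no self-loops
    dst: np.ndarray
    graph_id: np.ndarray        # (V_total,)
    n_graphs: int
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.features.shape[0]

    def _degrees(self) -> np.ndarray:
        if "deg" not in self._cache:
            deg = np.zeros(self.n_nodes, dtype=np.int64)
            np.add.at(deg, self.dst, 1)
            self._cache["deg"] = deg
        return self._cache["deg"]

    def gcn_arcs(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(src, dst, per-arc coefficient) with self-loops added."""
        if "gcn" not in self._cache:
            loops = np.arange(self.n_nodes)
            src = np.concatenate([self.src, loops])
            dst = np.concatenate([self.dst, loops])
            d_tilde = self._degrees() + 1.0
            coef = 1.0 / np.sqrt(d_tilde[src] * d_tilde[dst])
            self._cache["gcn"] = (src, dst, coef[:, None])
        return self._cache["gcn"]

    def sage_inverse_counts(self) -> np.ndarray:
        if "sage_inv" not in self._cache:
            deg = self._degrees().astype(np.float64)
            inv = np.divide(1.0, deg, out=np.zeros_like(deg), where=deg > 0)
            self._cache["sage_inv"] = inv[:, None]
        return self._cache["sage_inv"]

    def gat_arcs(self) -> tuple[np.ndarray, np.ndarray]:
        if "gat" not in self._cache:
            loops = np.arange(self.n_nodes)
            self._cache["gat"] = (np.concatenate([self.src, loops]),
                                  np.concatenate([self.dst, loops]))
        return self._cache["gat"]

    def graph_sizes(self) -> np.ndarray:
        if "sizes" not in self._cache:
            sizes = np.zeros(self.n_graphs, dtype=np.int64)
            np.add.at(sizes, self.graph_id, 1)
            self._cache["sizes"] = sizes
        return self._cache["sizes"]


def _directed_arcs(edges: list[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    if not edges:
        return np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp)
    e = np.asarray(edges, dtype=np.intp)
    return (np.concatenate([e[:, 0], e[:, 1]]),
            np.concatenate([e[:, 1], e[:, 0]]))


def collate(graphs: list[DuplexGraph]) -> Batch:
    """Merge graphs into one batch with offset node indices."""
    if not graphs:
        raise ValueError("cannot collate an empty list of graphs")
    feats, srcs, dsts, gids = [], [], [], []
    offset = 0
    for gid, g in enumerate(graphs):
        src, dst = _directed_arcs(g.edges)
        feats.append(g.node_features)
        srcs.append(src + offset)
        dsts.append(dst + offset)
        gids.append(np.full(g.n_nodes, gid, dtype=np.intp))
        offset += g.n_nodes
    return Batch(
        features=np.vstack(feats),
        src=np.concatenate(srcs),
        dst=np.concatenate(dsts),
        graph_id=np.concatenate(gids),
        n_graphs=len(graphs),
    )


# ---------------------------------------------------------------------------
# layers (Tensor level)
# ---------------------------------------------------------------------------

_ACTIVATIONS = {
    "relu": ad.relu,
    "identity": lambda t: t,
}


def _gcn_t(h: Tensor, w: Tensor, batch: Batch, activation: str) -> Tensor:
    src, dst, coef = batch.gcn_arcs()
    hw = ad.matmul(h, w)
    msg = ad.mul(ad.gather_rows(hw, src), Tensor(coef))
    return _ACTIVATIONS[activation](ad.scatter_sum(msg, dst, batch.n_nodes))


def _sage_t(h: Tensor, w: Tensor, batch: Batch, activation: str) -> Tensor:
    summed = ad.scatter_sum(ad.gather_rows(h, batch.src), batch.dst, batch.n_nodes)
    h_neigh = ad.mul(summed, Tensor(batch.sage_inverse_counts()))
    z = ad.matmul(ad.concat_cols(h, h_neigh), w)
    return ad.l2_normalize_rows(_ACTIVATIONS[activation](z))


def _gat_t(h: Tensor, w: Tensor, a: Tensor, batch: Batch, activation: str) -> Tensor:
    src, dst = batch.gat_arcs()
    hw = ad.matmul(h, w)
    scores = ad.leaky_relu(ad.gat_edge_scores(hw, a, src, dst), LEAKY_SLOPE)
    alpha = ad.segment_softmax(scores, dst, batch.n_nodes)
    msg = ad.mul(ad.gather_rows(hw, src), ad.expand_col(alpha))
    return _ACTIVATIONS[activation](ad.scatter_sum(msg, dst, batch.n_nodes))


def _pool_t(h: Tensor, batch: Batch, p_h: str) -> Tensor:
    if p_h == "ADD":
        return ad.scatter_sum(h, batch.graph_id, batch.n_graphs)
    if p_h == "MEAN":
        summed = ad.scatter_sum(h, batch.graph_id, batch.n_graphs)
        inv = 1.0 / batch.graph_sizes().astype(np.float64)
        return ad.mul(summed, Tensor(inv[:, None]))
    if p_h == "MAX":
        return ad.segment_max(h, batch.graph_id, batch.n_graphs)
    raise ValueError(f"unknown pooling operator {p_h!r}")


def forward_batch(batch: Batch, params: ModelParameters, config: ClassifierConfig,
                  mode: str = "EVAL", rng: np.random.Generator | None = None) -> Tensor:
    """Logits (n_graphs, 2) for a merged batch.  mode is TRAIN or EVAL."""
    if mode not in ("TRAIN", "EVAL"):
        raise ValueError(f"mode must be TRAIN or EVAL, got {mode!r}")
    if len(params.gnn) != config.l_gnn or len(params.fc) != config.l_fc:
        raise ValueError("parameters do not match the configuration")
    training = mode == "TRAIN"

    h = Tensor(batch.features)
    for layer in params.gnn:
        if config.e_gnn == "GCN":
            h = _gcn_t(h, layer["W"], batch, "relu")
        elif config.e_gnn == "SAGE":
            h = _sage_t(h, layer["W"], batch, "relu")
        else:
            h = _gat_t(h, layer["W"], layer["a"], batch, "relu")

    x = _pool_t(h, batch, config.p_h)
    for i, layer in enumerate(params.fc):
        x = ad.add(ad.matmul(x, layer["W"]), layer["b"])
        if i < len(params.fc) - 1:
            x = ad.relu(x)
            x = ad.dropout(x, config.r_d, rng, training)
    return x


def forward(graph: DuplexGraph, params: ModelParameters, config: ClassifierConfig,
            mode: str = "EVAL", rng: np.random.Generator | None = None) -> np.ndarray:
    """Softmax probability pair for one duplex graph."""
    logits = forward_batch(collate([graph]), params, config, mode=mode, rng=rng)
    return ad.softmax_rows(logits.data)[0]


def predict_proba(graphs: list[DuplexGraph], params: ModelParameters,
                  config: ClassifierConfig, batch_size: int = 256) -> np.ndarray:
    """Softmax probabilities (n_graphs, 2), computed in EVAL mode."""
    chunks = []
    for start in range(0, len(graphs), batch_size):
        batch = collate(graphs[start:start + batch_size])
        logits = forward_batch(batch, params, config, mode="EVAL")
        chunks.append(ad.softmax_rows(logits.data))
    return np.vstack(chunks)


# ---------------------------------------------------------------------------
# functional single-layer API (NumPy in / NumPy out)
# ---------------------------------------------------------------------------

def _single_graph_batch(h: np.ndarray, edges: list[tuple[int, int]]) -> Batch:
    h = np.asarray(h, dtype=np.float64)
    src, dst = _directed_arcs(edges)
    if len(edges):
        top = int(max(src.max(), dst.max()))
        if top >= h.shape[0]:
            raise ValueError(f"edge references node {top} but only {h.shape[0]} nodes exist")
    return Batch(features=h, src=src, dst=dst,
                 graph_id=np.zeros(h.shape[0], dtype=np.intp), n_graphs=1)


def gcn_layer(h: np.ndarray, edges: list[tuple[int, int]], w: np.ndarray,
              activation: str = "relu") -> np.ndarray:
    """One spectral-convolution layer on a single graph."""
    batch = _single_graph_batch(h, edges)
    if np.asarray(w).shape[0] != batch.features.shape[1]:
        raise ValueError("weight matrix rows must equal the input feature dimension")
    return _gcn_t(Tensor(batch.features), Tensor(w), batch, activation).data


def sage_layer(h: np.ndarray, edges: list[tuple[int, int]], w: np.ndarray,
               aggregator: str = "MEAN", activation: str = "relu") -> np.ndarray:
    """One sample-and-aggregate layer (mean aggregator, unit-norm output)."""
    if aggregator != "MEAN":
        raise ValueError(f"only the MEAN aggregator is supported, got {aggregator!r}")
    batch = _single_graph_batch(h, edges)
    if np.asarray(w).shape[0] != 2 * batch.features.shape[1]:
        raise ValueError("weight matrix rows must equal twice the input feature dimension")
    return _sage_t(Tensor(batch.features), Tensor(w), batch, activation).data


def gat_layer(h: np.ndarray, edges: list[tuple[int, int]], w: np.ndarray,
              a: np.ndarray, activation: str = "relu") -> np.ndarray:
    """One single-head attention layer (self-loops added)."""
    batch = _single_graph_batch(h, edges)
    w = np.asarray(w)
    if w.shape[0] != batch.features.shape[1]:
        raise ValueError("weight matrix rows must equal the input feature dimension")
    if np.asarray(a).shape != (2 * w.shape[1],):
        raise ValueError("attention vector must have length 2 * output dimension")
    return _gat_t(Tensor(batch.features), Tensor(w), Tensor(a), batch, activation).data


def gat_attention(h: np.ndarray, edges: list[tuple[int, int]], w: np.ndarray,
                  a: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Attention coefficients for inspection: (alpha, src, dst), self-loops included."""
    batch = _single_graph_batch(h, edges)
    src, dst = batch.gat_arcs()
    hw = ad.matmul(Tensor(batch.features), Tensor(np.asarray(w, dtype=np.float64)))
    scores = ad.leaky_relu(
        ad.gat_edge_scores(hw, Tensor(np.asarray(a, dtype=np.float64)), src, dst),
        LEAKY_SLOPE)
    alpha = ad.segment_softmax(scores, dst, batch.n_nodes)
    return alpha.data, src, dst


def global_pool(node_embeddings: np.ndarray, p_h: str) -> np.ndarray:
    """Element-wise ADD / MEAN / MAX over the node axis."""
    h = np.asarray(node_embeddings, dtype=np.float64)
    if h.ndim != 2 or h.shape[0] == 0:
        raise ValueError("node embeddings must be a non-empty V x D matrix")
    if p_h == "ADD":
        return h.sum(axis=0)
    if p_h == "MEAN":
        return h.mean(axis=0)
    if p_h == "MAX":
        return h.max(axis=0)
    raise ValueError(f"unknown pooling operator {p_h!r}")
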
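"""The tiny graph-attention regressor and its readout strategies.

The network is a stack of (by default) 5 graph-attention layers with
tanh nonlinearities between them, mapping the N x 35 node-feature matrix
of a molecule to one raw scalar per node: 35 -> 28 -> 28 -> 28 -> 28 -> 1.
With single-head additive attention and a bias on every layer this comes
to 3699 trainable parameters — small enough to train full-batch on a
laptop CPU in seconds.

There is no pooling layer inside the network.  The per-node outputs are
turned into one molecular prediction by an explicit readout strategy:
either a positional readout that picks the node at a particular SMILES
position (first, second, penultimate, last, or the mean of the middle
nodes), a random-node control, or a classical mean/max/min pooling over
all nodes.  Because SMILES encoding places weakly connected, peripheral
atoms at the ends of the string, the positional readouts address
chemically meaningful atoms.

Layer registry: ``gat`` (single-head additive attention), ``gatv2``
(the dynamic-attention variant, where the attention vector is applied
after the nonlinearity), and ``gcn`` (symmetric-normalized graph
convolution).  Swapping layer types changes the parameter count per the
registry's closed forms but never the output arity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .graph_build import MolGraph

__all__ = [
    "ModelConfig",
    "ReadoutStrategy",
    "READOUT_KINDS",
    "LAYER_REGISTRY",
    "ReadoutError",
    "GraphBatch",
    "batch_graphs",
    "MolGATModel",
    "build_model",
    "readout",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
]

READOUT_KINDS = (
    "first_node", "second_node", "penultimate_node", "last_node",
    "middle_mean", "random_node", "random_mean_5",
    "mean_pool", "max_pool", "min_pool",
)


class ReadoutError(ValueError):
    """A readout strategy cannot be applied to the given prediction vector."""


@dataclass(frozen=True)
class ReadoutStrategy:
    """How per-node outputs become one molecular prediction."""

    kind: str = "last_node"
    seed: int = 0

    def __post_init__(self):
        if self.kind not in READOUT_KINDS:
            raise ValueError(
                f"unknown readout kind {self.kind!r}; one of {READOUT_KINDS}"
            )


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters of the regressor."""

    layer_type: str = "gat"
    n_layers: int = 5
    hidden: int = 28
    activation: str = "tanh"     # fixed; kept for checkpoint provenance
    attention_heads: int = 1
    readout: ReadoutStrategy = field(default_factory=ReadoutStrategy)
    seed: int = 0
    in_features: int = 35

    def __post_init__(self):
        if self.n_layers < 2:
            raise ValueError("n_layers must be >= 2")
        if self.hidden < 1:
            raise ValueError("hidden must be >= 1")
        if self.attention_heads != 1:
            raise ValueError("only single-head attention is supported")


# --- graph batching --------------------------------------------------------

class GraphBatch:
    """Disjoint union of molecular graphs for full-batch training.

    Node features are stacked, edge indices offset per graph, and each
    bond appears in both directions.  ``src_loop``/``dst_loop`` add one
    self-loop per node, the convention shared by attention (neighbors
    plus self) and GCN (renormalization trick) layers.
    """

    def __init__(self, graphs: list[MolGraph]):
        if not graphs:
            raise ValueError("cannot batch zero graphs")
        self.graphs = graphs
        self.n_graphs = len(graphs)
        feats, srcs, dsts, gids, slices = [], [], [], [], []
        offset = 0
        for g, graph in enumerate(graphs):
            feats.append(graph.node_features)
            ei = graph.edge_index() + offset
            srcs.append(ei[0])
            dsts.append(ei[1])
            gids.append(np.full(graph.n_nodes, g, dtype=np.int64))
            slices.append((offset, offset + graph.n_nodes))
            offset += graph.n_nodes
        self.n_nodes = offset
        self.x = np.concatenate(feats, axis=0)
        src = np.concatenate(srcs) if srcs else np.zeros(0, np.int64)
        dst = np.concatenate(dsts) if dsts else np.zeros(0, np.int64)
        loops = np.arange(self.n_nodes, dtype=np.int64)
        src = np.concatenate([src, loops])
        dst = np.concatenate([dst, loops])
        # store edges sorted by destination so per-node (dst-segment)
        # reductions hit the fast contiguous path every epoch
        by_dst = np.argsort(dst, kind="stable")
        self.src_loop = src[by_dst]
        self.dst_loop = dst[by_dst]
        self.graph_ids = np.concatenate(gids)
        self.node_slices = slices
        self.targets = np.array([g.target for g in graphs], dtype=np.float64)
        # in-degree including the self-loop, for GCN normalization
        deg = np.bincount(self.dst_loop, minlength=self.n_nodes).astype(float)
        self.gcn_norm = (1.0 / np.sqrt(deg[self.src_loop] * deg[self.dst_loop]))[:, None]
        # precomputed sort orders for fast per-epoch segment reductions
        self.seg_dst = ad.Segmentation(self.dst_loop, self.n_nodes)
        self.seg_src = ad.Segmentation(self.src_loop, self.n_nodes)


def batch_graphs(graphs: list[MolGraph]) -> GraphBatch:
    return GraphBatch(graphs)


# --- layer implementations -------------------------------------------------

def _glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


class _GATLayer:
    """Single-head additive graph attention.

    e_ij = LeakyReLU(a_src . W h_j + a_dst . W h_i) over incoming edges
    j -> i (self-loop included); attention weights are the per-node
    softmax of e; the output is the attention-weighted sum of W h_j plus
    a bias.  Parameters: W (in x out), a_src, a_dst, bias (out each).
    """

    name = "gat"

    @staticmethod
    def param_count(n_in: int, n_out: int) -> int:
        return n_in * n_out + 3 * n_out

    @staticmethod
    def init(rng, prefix: str, n_in: int, n_out: int) -> dict[str, Tensor]:
        return {
            f"{prefix}.W": Tensor(_glorot(rng, n_in, n_out), requires_grad=True),
            f"{prefix}.att_src": Tensor(_glorot(rng, n_out, 1), requires_grad=True),
            f"{prefix}.att_dst": Tensor(_glorot(rng, n_out, 1), requires_grad=True),
            f"{prefix}.b": Tensor(np.zeros((1, n_out)), requires_grad=True),
        }

    @staticmethod
    def forward(params, prefix: str, x: Tensor, batch: GraphBatch) -> Tensor:
        h = ad.matmul(x, params[f"{prefix}.W"])
        a_src = ad.matmul(h, params[f"{prefix}.att_src"])
        a_dst = ad.matmul(h, params[f"{prefix}.att_dst"])
        e = ad.leaky_relu(
            ad.add(ad.gather(a_src, batch.src_loop, batch.seg_src),
                   ad.gather(a_dst, batch.dst_loop, batch.seg_dst)),
            negative_slope=0.2,
        )
        alpha = ad.segment_softmax(e, batch.seg_dst, batch.n_nodes)
        msg = ad.mul(alpha, ad.gather(h, batch.src_loop, batch.seg_src))
        out = ad.segment_sum(msg, batch.seg_dst, batch.n_nodes)
        return ad.add(out, params[f"{prefix}.b"])


class _GATv2Layer:
    """Dynamic attention: a . LeakyReLU(W_l h_j + W_r h_i).

    Applying the attention vector after the nonlinearity removes the
    static-attention limitation of the original formulation.  Messages
    are W_l h_j.  Parameters: W_l, W_r (in x out each), a, bias (out).
    """

    name = "gatv2"

    @staticmethod
    def param_count(n_in: int, n_out: int) -> int:
        return 2 * n_in * n_out + 2 * n_out

    @staticmethod
    def init(rng, prefix, n_in, n_out):
        return {
            f"{prefix}.Wl": Tensor(_glorot(rng, n_in, n_out), requires_grad=True),
            f"{prefix}.Wr": Tensor(_glorot(rng, n_in, n_out), requires_grad=True),
            f"{prefix}.att": Tensor(_glorot(rng, n_out, 1), requires_grad=True),
            f"{prefix}.b": Tensor(np.zeros((1, n_out)), requires_grad=True),
        }

    @staticmethod
    def forward(params, prefix, x, batch):
        hl = ad.matmul(x, params[f"{prefix}.Wl"])
        hr = ad.matmul(x, params[f"{prefix}.Wr"])
        pre = ad.leaky_relu(
            ad.add(ad.gather(hl, batch.src_loop, batch.seg_src),
                   ad.gather(hr, batch.dst_loop, batch.seg_dst)),
            negative_slope=0.2,
        )
        e = ad.matmul(pre, params[f"{prefix}.att"])
        alpha = ad.segment_softmax(e, batch.seg_dst, batch.n_nodes)
        msg = ad.mul(alpha, ad.gather(hl, batch.src_loop, batch.seg_src))
        out = ad.segment_sum(msg, batch.seg_dst, batch.n_nodes)
        return ad.add(out, params[f"{prefix}.b"])


class _GCNLayer:
    """Graph convolution with symmetric degree normalization and self-loops."""

    name = "gcn"

    @staticmethod
    def param_count(n_in: int, n_out: int) -> int:
        return n_in * n_out + n_out

    @staticmethod
    def init(rng, prefix, n_in, n_out):
        return {
            f"{prefix}.W": Tensor(_glorot(rng, n_in, n_out), requires_grad=True),
            f"{prefix}.b": Tensor(np.zeros((1, n_out)), requires_grad=True),
        }

    @staticmethod
    def forward(params, prefix, x, batch):
        h = ad.matmul(x, params[f"{prefix}.W"])
        msg = ad.mul(ad.gather(h, batch.src_loop, batch.seg_src),
                     Tensor(batch.gcn_norm))
        out = ad.segment_sum(msg, batch.seg_dst, batch.n_nodes)
        return ad.add(out, params[f"{prefix}.b"])


LAYER_REGISTRY = {cls.name: cls for cls in (_GATLayer, _GATv2Layer, _GCNLayer)}


# --- the model -------------------------------------------------------------

class MolGATModel:
    """Stack of graph layers with tanh between them; raw per-node output."""

    def __init__(self, config: ModelConfig):
        if config.layer_type not in LAYER_REGISTRY:
            raise ValueError(
                f"unknown layer_type {config.layer_type!r}; "
                f"registry: {sorted(LAYER_REGISTRY)}"
            )
        self.config = config
        self.layer = LAYER_REGISTRY[config.layer_type]
        rng = np.random.default_rng(config.seed)
        self.params: dict[str, Tensor] = {}
        for i, (n_in, n_out) in enumerate(self._layer_dims()):
            self.params.update(self.layer.init(rng, f"layer{i}", n_in, n_out))

    def _layer_dims(self) -> list[tuple[int, int]]:
        c = self.config
        dims = [(c.in_features, c.hidden)]
        dims += [(c.hidden, c.hidden)] * (c.n_layers - 2)
        dims += [(c.hidden, 1)]
        return dims

    def forward_batch(self, batch: GraphBatch,
                      return_hidden: bool = False):
        """Per-node predictions for a batched graph, as a Tensor (N, 1)."""
        if batch.x.shape[1] != self.config.in_features:
            raise ValueError(
                f"feature width {batch.x.shape[1]} != "
                f"model input width {self.config.in_features}"
            )
        h = Tensor(batch.x)
        hidden: list[np.ndarray] = []
        n = self.config.n_layers
        for i in range(n):
            h = self.layer.forward(self.params, f"layer{i}", h, batch)
            if i < n - 1:
                h = ad.tanh(h)
                hidden.append(h.data)
        if return_hidden:
            return h, hidden
        return h

    def forward(self, graph: MolGraph) -> np.ndarray:
        """Per-node predictions for a single molecule, shape (n_nodes,)."""
        out = self.forward_batch(GraphBatch([graph]))
        return out.data[:, 0].copy()

    def predict(self, graph: MolGraph,
                strategy: ReadoutStrategy | None = None) -> float:
        """One molecular prediction: forward pass plus readout."""
        strategy = strategy or self.config.readout
        return readout(self.forward(graph), strategy)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.params.items():
            v.data = np.array(state[k], dtype=np.float64)


def build_model(config: ModelConfig) -> MolGATModel:
    """Build the network with deterministic seed-derived initial weights."""
    return MolGATModel(config)


def count_parameters(model: MolGATModel) -> int:
    """Exact count of trainable scalars."""
    return sum(p.data.size for p in model.params.values())


# --- readout ---------------------------------------------------------------

def readout(node_preds: np.ndarray, strategy: ReadoutStrategy) -> float:
    """Reduce a per-node prediction vector to one molecular prediction.

    ``middle_mean`` averages all nodes except the first two and the last
    two and therefore needs at least 5 nodes; smaller molecules raise
    ReadoutError so callers can exclude and count them.
    """
    v = np.asarray(node_preds, dtype=np.float64).ravel()
    if v.size == 0:
        raise ReadoutError("empty prediction vector")
    n = v.size
    kind = strategy.kind
    if kind == "first_node":
        return float(v[0])
    if kind == "second_node":
        return float(v[min(1, n - 1)])
    if kind == "penultimate_node":
        return float(v[max(n - 2, 0)])
    if kind == "last_node":
        return float(v[n - 1])
    if kind == "middle_mean":
        if n < 5:
            raise ReadoutError(
                f"middle_mean needs >= 5 nodes, molecule has {n}"
            )
        return float(v[2:n - 2].mean())
    if kind == "random_node":
        rng = np.random.default_rng(strategy.seed)
        return float(v[rng.integers(n)])
    if kind == "random_mean_5":
        rng = np.random.default_rng(strategy.seed)
        return float(v[rng.integers(n, size=5)].mean())
    if kind == "mean_pool":
        return float(v.mean())
    if kind == "max_pool":
        return float(v.max())
    if kind == "min_pool":
        return float(v.min())
    raise ReadoutError(f"unknown readout kind {kind!r}")


def _readout_plan(batch: GraphBatch, strategy: ReadoutStrategy):
    """(node_idx, weights, graph_ids) triples realizing a weighted readout.

    Supports every kind whose node selection does not depend on the
    current predictions (max/min pooling are handled dynamically in
    batch_readout).  Random kinds draw per molecule from a generator
    seeded by the strategy, in batch order.
    """
    idx, w, gid = [], [], []
    rng = np.random.default_rng(strategy.seed)
    for g, (start, end) in enumerate(batch.node_slices):
        n = end - start
        kind = strategy.kind
        if kind == "first_node":
            sel, wt = [start], [1.0]
        elif kind == "second_node":
            sel, wt = [start + min(1, n - 1)], [1.0]
        elif kind == "penultimate_node":
            sel, wt = [start + max(n - 2, 0)], [1.0]
        elif kind == "last_node":
            sel, wt = [end - 1], [1.0]
        elif kind == "middle_mean":
            if n < 5:
                raise ReadoutError(
                    f"middle_mean needs >= 5 nodes, graph {g} has {n}"
                )
            sel = list(range(start + 2, end - 2))
            wt = [1.0 / len(sel)] * len(sel)
        elif kind == "random_node":
            sel, wt = [start + int(rng.integers(n))], [1.0]
        elif kind == "random_mean_5":
            sel = (start + rng.integers(n, size=5)).tolist()
            wt = [0.2] * 5
        elif kind == "mean_pool":
            sel = list(range(start, end))
            wt = [1.0 / n] * n
        else:
            raise ReadoutError(f"kind {kind!r} has no static readout plan")
        idx.extend(sel)
        w.extend(wt)
        gid.extend([g] * len(sel))
    return (np.array(idx, dtype=np.int64), np.array(w)[:, None],
            np.array(gid, dtype=np.int64))


def batch_readout(node_preds: Tensor, batch: GraphBatch,
                  strategy: ReadoutStrategy) -> Tensor:
    """Differentiable readout over a batch: (N, 1) node preds -> (G, 1).

    For max/min pooling the extremal node is located from the current
    forward values and the gradient flows through that node only (the
    subgradient of the max).
    """
    if strategy.kind in ("max_pool", "min_pool"):
        pick = np.argmax if strategy.kind == "max_pool" else np.argmin
        idx = np.array(
            [start + pick(node_preds.data[start:end, 0])
             for start, end in batch.node_slices], dtype=np.int64,
        )
        return ad.gather(node_preds, idx)
    idx, w, gid = _readout_plan(batch, strategy)
    sel = ad.mul(ad.gather(node_preds, idx), Tensor(w))
    return ad.segment_sum(sel, gid, batch.n_graphs)


# --- checkpoints -----------------------------------------------------------

_CHECKPOINT_VERSION = 1


def save_checkpoint(model: MolGATModel, path: str | Path) -> None:
    """Save weights + config as a flat named-tensor .npz archive (v1)."""
    cfg = model.config
    meta = {
        "version": _CHECKPOINT_VERSION,
        "layer_type": cfg.layer_type, "n_layers": cfg.n_layers,
        "hidden": cfg.hidden, "activation": cfg.activation,
        "attention_heads": cfg.attention_heads,
        "readout_kind": cfg.readout.kind, "readout_seed": cfg.readout.seed,
        "seed": cfg.seed, "in_features": cfg.in_features,
    }
    np.savez(path, __config__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **model.state_dict())


def load_checkpoint(path: str | Path) -> MolGATModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__config__"]).decode())
        if meta["version"] != _CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        config = ModelConfig(
            layer_type=meta["layer_type"], n_layers=meta["n_layers"],
            hidden=meta["hidden"], activation=meta["activation"],
            attention_heads=meta["attention_heads"],
            readout=ReadoutStrategy(meta["readout_kind"], meta["readout_seed"]),
            seed=meta["seed"], in_features=meta["in_features"],
        )
        model = MolGATModel(config)
        model.load_state_dict({k: data[k] for k in data.files
                               if k != "__config__"})
    return model
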
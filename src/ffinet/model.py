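"""The force-field-inspired k-hop attention network.

Message passing aggregates from 1-, 2- and 3-hop neighbours; per-path
attention scores are

    e_p = a_k^T LeakyReLU( (sum_{r in p} W_r h'_r) * (W_k m_k[p]) )

with ``h'_r`` the node embedding multiplied elementwise by the hop-k
sinusoidal positional encoding, ``W_r`` a position-in-path-specific
projection and ``m_k[p]`` the path's spatial embedding basis.  Scores are
softmax-normalised over all hop-k paths sharing the target atom; the three
hop outputs are arbitrated per node by axial attention (dot product with the
node's input embedding), followed by residual + dropout + LayerNorm.  The
graph readout concatenates a gated weighted sum and a max-pool, feeding an
MLP head.

Implemented on NumPy via ``autograd`` with custom differentiable segment
reductions; no deep-learning framework is required.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import autograd.numpy as anp
import numpy as np
from autograd.extend import defvjp, primitive
from autograd.tracer import getval

from .errors import AlignmentError
from .geometry import BASIS_WIDTHS, BasisScaler, assemble_basis
from .khop import KHopIndex, build_khop_index
from .molio import MoleculeRecord

__all__ = [
    "ModelConfig",
    "GraphData",
    "AttentionRecord",
    "FFiNet",
    "positional_encoding",
    "khop_attention",
    "axial_combine",
    "ffinet_layer",
    "readout",
    "predict_head",
    "build_graph",
    "batch_graphs",
    "atom_contributions",
    "attention_map",
    "node_similarity",
]

EDGE_BONDED = 0
EDGE_NONBONDED_INTER = 1

# hop-1 basis rows are stored width-5: cols 0:2 bonded {r, r^2}, cols 2:5
# nonbonded {r^-1, r^-12, r^-6}; exactly one block is populated per row.
HOP1_WIDTH = 5


# ---------------------------------------------------------------------------
# differentiable segment reductions
# ---------------------------------------------------------------------------

@primitive
def segment_sum(x, seg, n):
    out = np.zeros((n,) + x.shape[1:])
    np.add.at(out, seg, x)
    return out


defvjp(segment_sum, lambda ans, x, seg, n: lambda g: g[seg], None, None)


@primitive
def segment_max(x, seg, n):
    out = np.full((n,) + x.shape[1:], -np.inf)
    np.maximum.at(out, seg, x)
    return out


def _segment_max_vjp(ans, x, seg, n):
    # split gradient evenly among exact ties (symmetric molecules produce
    # bitwise-equal embeddings, so ties are not a corner case here)
    mask = (x == ans[seg]).astype(float)
    counts = np.zeros((n,) + x.shape[1:])
    np.add.at(counts, seg, mask)
    mask = mask / counts[seg]
    return lambda g: g[seg] * mask


defvjp(segment_max, _segment_max_vjp, None, None)


def segment_softmax(e, seg, n):
    """Column-wise softmax of ``e`` within segments given by ``seg``."""
    shift = segment_max(getval(e), seg, n)  # constant shift; softmax-invariant
    z = anp.exp(e - shift[seg])
    denom = segment_sum(z, seg, n)
    return z / denom[seg]


def _leaky_relu(x, slope):
    return anp.where(x >= 0, x, slope * x)


def _layer_norm(x, g, b, eps=1e-5):
    mu = anp.mean(x, axis=-1, keepdims=True)
    var = anp.mean((x - mu) ** 2, axis=-1, keepdims=True)
    return g * (x - mu) / anp.sqrt(var + eps) + b


def _sigmoid(x):
    return 0.5 * (anp.tanh(0.5 * x) + 1.0)


# ---------------------------------------------------------------------------
# configuration and data containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelConfig:
    """Architecture switches; the ablations are realised by ``use_hops`` and
    ``use_axial`` (restricted hop sets / summed hop outputs)."""

    hidden_dim: int = 128
    n_heads: int = 4
    n_layers: int = 3
    dropout: float = 0.1
    leaky_slope: float = 0.2
    use_hops: tuple[int, ...] = (1, 2, 3)
    use_axial: bool = True
    task: str = "regression"
    n_tasks: int = 1
    dedupe_hops: bool = False
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "use_hops", tuple(sorted(set(self.use_hops))))
        if self.hidden_dim % self.n_heads != 0:
            raise ValueError("hidden_dim must be divisible by n_heads")
        if not self.use_hops or not set(self.use_hops) <= {1, 2, 3}:
            raise ValueError("use_hops must be a nonempty subset of {1, 2, 3}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.task not in ("regression", "classification"):
            raise ValueError(f"unknown task {self.task!r}")

    def to_dict(self) -> dict:
        return {
            "hidden_dim": self.hidden_dim,
            "n_heads": self.n_heads,
            "n_layers": self.n_layers,
            "dropout": self.dropout,
            "leaky_slope": self.leaky_slope,
            "use_hops": list(self.use_hops),
            "use_axial": self.use_axial,
            "task": self.task,
            "n_tasks": self.n_tasks,
            "dedupe_hops": self.dedupe_hops,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["use_hops"] = tuple(d.get("use_hops", (1, 2, 3)))
        return cls(**d)


@dataclass
class GraphData:
    """Model-ready (possibly batched) graph.

    ``paths[k]`` is the (P_k, k+1) path index; ``basis[k]`` the row-aligned
    standardised basis (hop 1 stored width-5, see ``HOP1_WIDTH``);
    ``edge_type`` types every hop-1 row; ``graph_seg`` maps atoms to graph
    ids for pooling.
    """

    x: np.ndarray
    paths: dict[int, np.ndarray]
    basis: dict[int, np.ndarray]
    edge_type: np.ndarray
    graph_seg: np.ndarray
    n_graphs: int

    @property
    def n_atoms(self) -> int:
        return int(self.x.shape[0])


@dataclass
class AttentionRecord:
    """Per-forward interpretation signals (plain NumPy, detached).

    ``alpha[layer][k]`` — (P_k, n_heads) normalised path weights;
    ``beta[layer]`` — (n_atoms, 3) axial weights (zero column for unused or
    pathless hops); ``gates`` — (n_atoms,) readout gate; ``h_final`` —
    final-layer node embeddings.
    """

    alpha: list[dict[int, np.ndarray]] = field(default_factory=list)
    beta: list[np.ndarray] = field(default_factory=list)
    gates: np.ndarray | None = None
    h_final: np.ndarray | None = None


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------

def build_graph(
    record: MoleculeRecord,
    dedupe_hops: bool = False,
    scaler: BasisScaler | None = None,
    index: KHopIndex | None = None,
) -> GraphData:
    """Turn a molecule record into a model-ready single graph."""
    if index is None:
        index = build_khop_index(record.bonds, record.n_atoms, dedupe_hops=dedupe_hops)
    sb = assemble_basis(record.positions, index)
    if scaler is not None:
        sb = scaler.transform(sb)
    p1 = index.hop1
    m1 = np.zeros((p1.shape[0], HOP1_WIDTH))
    m1[:, :2] = sb.m1
    return GraphData(
        x=record.atom_features,
        paths={1: p1, 2: index.hop2, 3: index.hop3},
        basis={1: m1, 2: sb.m2, 3: sb.m3},
        edge_type=np.zeros(p1.shape[0], dtype=np.int64),
        graph_seg=np.zeros(record.n_atoms, dtype=np.int64),
        n_graphs=1,
    )


def batch_graphs(graphs: Sequence[GraphData]) -> GraphData:
    """Disjoint-union batching with index offsets."""
    if not graphs:
        raise ValueError("empty batch")
    xs, etypes, segs = [], [], []
    paths = {k: [] for k in (1, 2, 3)}
    basis = {k: [] for k in (1, 2, 3)}
    offset = 0
    for gi, g in enumerate(graphs):
        xs.append(g.x)
        etypes.append(g.edge_type)
        segs.append(np.full(g.n_atoms, gi, dtype=np.int64))
        for k in (1, 2, 3):
            if g.paths[k].shape[0]:
                paths[k].append(g.paths[k] + offset)
                basis[k].append(g.basis[k])
        offset += g.n_atoms
    width = {1: HOP1_WIDTH, 2: BASIS_WIDTHS[2], 3: BASIS_WIDTHS[3]}
    return GraphData(
        x=np.concatenate(xs, axis=0),
        paths={
            k: (np.concatenate(paths[k]) if paths[k] else np.zeros((0, k + 1), dtype=np.int64))
            for k in (1, 2, 3)
        },
        basis={
            k: (np.concatenate(basis[k]) if basis[k] else np.zeros((0, width[k])))
            for k in (1, 2, 3)
        },
        edge_type=np.concatenate(etypes),
        graph_seg=np.concatenate(segs),
        n_graphs=len(graphs),
    )


# ---------------------------------------------------------------------------
# network pieces
# ---------------------------------------------------------------------------

def positional_encoding(k: int, dim: int) -> np.ndarray:
    """Transformer sinusoid at position ``k``: entry 2t = sin(k/10000^(2t/dim)),
    entry 2t+1 = cos(k/10000^(2t/dim))."""
    if k not in (1, 2, 3):
        raise ValueError(f"hop must be in {{1, 2, 3}}, got {k}")
    pe = np.zeros(dim)
    t = np.arange(0, dim, 2)
    freq = k / np.power(10000.0, t / dim)
    pe[0::2] = np.sin(freq)
    pe[1::2] = np.cos(freq)[: pe[1::2].shape[0]]
    return pe


def khop_attention(params_hop, h, paths, basis, k, cfg, edge_type=None, n_atoms=None):
    """Hop-k attention: returns ``(scores e, weights alpha, hop output o)``.

    ``o`` is the pre-mix per-head aggregate reshaped to (n, hidden): for a
    node with a single hop-k path it equals W_src h'_j exactly.  ``e`` and
    ``alpha`` have shape (P, n_heads).
    """
    n = n_atoms if n_atoms is not None else int(getval(h).shape[0])
    H, hid = cfg.n_heads, cfg.hidden_dim
    dh = hid // H
    P = paths.shape[0]
    if P == 0:
        zero = anp.zeros((n, hid))
        return np.zeros((0, H)), np.zeros((0, H)), zero
    if basis.shape[0] != P:
        raise AlignmentError(f"hop-{k} paths ({P}) and basis rows ({basis.shape[0]}) misaligned")

    pe = positional_encoding(k, hid)
    hp = anp.reshape(h * pe, (n, H, dh))

    # batched matmuls (BLAS) instead of einsum: (H,P,dh) @ (H,dh,dh)
    def _project(vecs, W):
        return anp.swapaxes(anp.matmul(anp.swapaxes(vecs, 0, 1), W), 0, 1)

    def _basis_proj(m, W_k):
        return anp.reshape(anp.dot(m, anp.reshape(W_k, (H * dh, -1)).T), (-1, H, dh))

    W_r = params_hop["W_r"]  # (k+1, H, dh, dh)
    sum_r = 0.0
    for pos in range(k + 1):
        sum_r = sum_r + _project(hp[paths[:, pos]], W_r[pos])

    if k == 1:
        mb = (edge_type == EDGE_BONDED).astype(float)[:, None, None]
        zb = _basis_proj(basis[:, :2], params_hop["W_k_b"])
        zn = _basis_proj(basis[:, 2:], params_hop["W_k_n"])
        z = mb * zb + (1.0 - mb) * zn
    else:
        z = _basis_proj(basis, params_hop["W_k"])

    gate = _leaky_relu(sum_r * z, cfg.leaky_slope)
    e = anp.sum(gate * params_hop["a"][None, :, :], axis=2)

    targets = paths[:, 0]
    alpha = segment_softmax(e, targets, n)

    src = _project(hp[paths[:, -1]], W_r[k])
    o = segment_sum(alpha[:, :, None] * src, targets, n)
    return e, alpha, anp.reshape(o, (n, hid))


def axial_combine(h_in, o_by_hop: dict, masks: dict, use_axial: bool, hidden_dim: int):
    """Arbitrate between hop outputs per node.

    ``o_by_hop[k]`` are the (mixed) hop outputs, ``masks[k]`` boolean
    (n,) flags for nodes with at least one hop-k path.  With axial attention
    on, scores are scaled dot products with the node's input embedding and
    softmax-normalised over the hops available to each node; off, the hop
    outputs are summed.  Returns ``(h_out, beta)`` with beta (n, 3)
    (zero columns for unavailable hops).
    """
    hops = sorted(o_by_hop)
    n = int(getval(h_in).shape[0])
    beta_full = np.zeros((n, 3))
    if not use_axial:
        h_out = 0.0
        for k in hops:
            h_out = h_out + o_by_hop[k]
        return h_out, beta_full

    scores, avail = [], []
    for k in hops:
        s = anp.sum(h_in * o_by_hop[k], axis=1) / np.sqrt(hidden_dim)
        scores.append(s)
        avail.append(masks[k].astype(float))
    S = anp.stack(scores, axis=1)  # (n, K)
    A = np.stack(avail, axis=1)
    # masked softmax over available hops; nodes with no paths at all get 0
    shift = np.max(np.where(A > 0, getval(S), -np.inf), axis=1, initial=-np.inf)
    shift = np.where(np.isfinite(shift), shift, 0.0)
    z = anp.exp(S - shift[:, None]) * A
    denom = anp.sum(z, axis=1, keepdims=True)
    beta = z / anp.where(denom > 0, denom, 1.0)
    h_out = 0.0
    for idx, k in enumerate(hops):
        h_out = h_out + beta[:, idx : idx + 1] * o_by_hop[k]
    beta_np = getval(beta)
    for idx, k in enumerate(hops):
        beta_full[:, k - 1] = beta_np[:, idx]
    return h_out, beta_full


def ffinet_layer(params_layer, h, graph: GraphData, cfg: ModelConfig, dropout_mask=None,
                 record: AttentionRecord | None = None):
    """One message-passing layer: k-hop attention, axial combination,
    residual + dropout + LayerNorm."""
    n = graph.n_atoms
    o_by_hop, masks, alphas = {}, {}, {}
    for k in cfg.use_hops:
        paths = graph.paths[k]
        _, alpha, o = khop_attention(
            params_layer["hops"][k], h, paths, graph.basis[k], k, cfg,
            edge_type=graph.edge_type if k == 1 else None, n_atoms=n,
        )
        o_by_hop[k] = anp.dot(o, params_layer["mix"][k])
        counts = np.zeros(n)
        if paths.shape[0]:
            np.add.at(counts, paths[:, 0], 1.0)
        masks[k] = counts > 0
        alphas[k] = getval(alpha)
    ax, beta = axial_combine(h, o_by_hop, masks, cfg.use_axial, cfg.hidden_dim)
    if dropout_mask is not None:
        ax = ax * dropout_mask
    h_new = _layer_norm(h + ax, params_layer["ln_g"], params_layer["ln_b"])
    if record is not None:
        record.alpha.append(alphas)
        record.beta.append(beta)
    return h_new


def readout(params_ro, h, graph_seg, n_graphs, record: AttentionRecord | None = None):
    """Gated weighted sum concatenated with max-pool: (G, 2*hidden)."""
    if getval(h).shape[0] == 0:
        raise ValueError("readout on an empty graph")
    gate = _sigmoid(anp.dot(h, params_ro["w"]) + params_ro["b"])
    wsum = segment_sum(gate[:, None] * h, graph_seg, n_graphs)
    mx = segment_max(h, graph_seg, n_graphs)
    if record is not None:
        record.gates = getval(gate)
    return anp.concatenate([wsum, mx], axis=1)


def predict_head(params_mlp, g):
    """Two-layer MLP from the graph vector to task outputs (raw / logits)."""
    z = anp.maximum(anp.dot(g, params_mlp["W1"]) + params_mlp["b1"], 0.0)
    return anp.dot(z, params_mlp["W2"]) + params_mlp["b2"]


def forward(params, graph: GraphData, cfg: ModelConfig, dropout_masks=None,
            record: AttentionRecord | None = None):
    """Full network pass; returns (G, n_tasks) raw outputs."""
    h = anp.dot(graph.x, params["embed_W"]) + params["embed_b"]
    for li in range(cfg.n_layers):
        mask = dropout_masks[li] if dropout_masks is not None else None
        h = ffinet_layer(params["layers"][li], h, graph, cfg, dropout_mask=mask, record=record)
    if record is not None:
        record.h_final = getval(h)
    g = readout(params["readout"], h, graph.graph_seg, graph.n_graphs, record=record)
    return predict_head(params["mlp"], g)


# ---------------------------------------------------------------------------
# parameter initialisation
# ---------------------------------------------------------------------------

def _glorot(rng, *shape):
    fan_in, fan_out = shape[-2], shape[-1]
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=shape)


def init_params(cfg: ModelConfig, n_features: int, rng: np.random.Generator) -> dict:
    H, hid = cfg.n_heads, cfg.hidden_dim
    dh = hid // H
    params = {
        "embed_W": _glorot(rng, n_features, hid),
        "embed_b": np.zeros(hid),
        "layers": [],
        "readout": {"w": rng.standard_normal(hid) / np.sqrt(hid), "b": np.float64(0.0)},
        "mlp": {
            "W1": _glorot(rng, 2 * hid, hid),
            "b1": np.zeros(hid),
            "W2": _glorot(rng, hid, cfg.n_tasks),
            "b2": np.zeros(cfg.n_tasks),
        },
    }
    for _ in range(cfg.n_layers):
        layer = {"hops": {}, "mix": {}, "ln_g": np.ones(hid), "ln_b": np.zeros(hid)}
        for k in cfg.use_hops:
            hop = {
                "W_r": _glorot(rng, k + 1, H, dh, dh),
                "a": rng.standard_normal((H, dh)) / np.sqrt(dh),
            }
            if k == 1:
                hop["W_k_b"] = _glorot(rng, H, dh, 2)
                hop["W_k_n"] = _glorot(rng, H, dh, 3)
            else:
                hop["W_k"] = _glorot(rng, H, dh, BASIS_WIDTHS[k])
            layer["hops"][k] = hop
            layer["mix"][k] = _glorot(rng, hid, hid)
        params["layers"].append(layer)
    return params


# ---------------------------------------------------------------------------
# model wrapper
# ---------------------------------------------------------------------------

CHECKPOINT_VERSION = 1


class FFiNet:
    """Stateful wrapper: parameters + config + frozen preprocessing stats."""

    def __init__(self, config: ModelConfig, n_features: int, seed: int | None = None):
        self.config = config
        self.n_features = n_features
        self.rng = np.random.default_rng(config.seed if seed is None else seed)
        self.params = init_params(config, n_features, self.rng)
        self.scaler: BasisScaler | None = None
        self.label_mean = np.zeros(config.n_tasks)
        self.label_std = np.ones(config.n_tasks)

    # -- data plumbing ------------------------------------------------------

    def graph_for(self, record) -> GraphData:
        from .complexes import ComplexGraph, graph_from_complex

        if isinstance(record, ComplexGraph):
            return graph_from_complex(record, scaler=self.scaler)
        return build_graph(record, dedupe_hops=self.config.dedupe_hops, scaler=self.scaler)

    # -- inference ----------------------------------------------------------

    def forward_graph(self, graph: GraphData, record_attention: bool = False):
        rec = AttentionRecord() if record_attention else None
        out = forward(self.params, graph, self.config, record=rec)
        return np.asarray(getval(out)), rec

    def predict(self, records: Iterable) -> np.ndarray:
        """Evaluation-mode predictions on label scale (regression
        de-standardised; classification probabilities)."""
        graphs = [self.graph_for(r) for r in records]
        out, _ = self.forward_graph(batch_graphs(graphs))
        if self.config.task == "regression":
            return out * self.label_std + self.label_mean
        return 1.0 / (1.0 + np.exp(-out))

    # -- persistence --------------------------------------------------------

    def save(self, path: str) -> None:
        flat = {}

        def walk(obj, prefix):
            if isinstance(obj, dict):
                for key, v in obj.items():
                    walk(v, f"{prefix}/{key}")
            elif isinstance(obj, list):
                for i, v in enumerate(obj):
                    walk(v, f"{prefix}/{i}")
            else:
                flat[prefix] = np.asarray(obj)

        walk(self.params, "p")
        meta = {
            "version": CHECKPOINT_VERSION,
            "config": self.config.to_dict(),
            "n_features": self.n_features,
            "scaler": self.scaler.to_dict() if self.scaler is not None else None,
            "label_mean": self.label_mean.tolist(),
            "label_std": self.label_std.tolist(),
        }
        np.savez(path, __meta__=json.dumps(meta), **flat)

    @classmethod
    def load(cls, path: str) -> "FFiNet":
        data = np.load(path if str(path).endswith(".npz") else str(path) + ".npz",
                       allow_pickle=False)
        meta = json.loads(str(data["__meta__"]))
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        model = cls(ModelConfig.from_dict(meta["config"]), meta["n_features"])
        for name in data.files:
            if name == "__meta__":
                continue
            parts = name.split("/")[1:]
            node = model.params
            for p in parts[:-1]:
                if isinstance(node, list):
                    node = node[int(p)]
                else:
                    node = node[p] if p in node else node[int(p)]
            leaf = parts[-1]
            if isinstance(node, list):
                node[int(leaf)] = data[name]
            else:
                key = leaf if leaf in node else int(leaf)
                node[key] = data[name]
        if meta["scaler"] is not None:
            model.scaler = BasisScaler.from_dict(meta["scaler"])
        model.label_mean = np.asarray(meta["label_mean"], dtype=float)
        model.label_std = np.asarray(meta["label_std"], dtype=float)
        return model


# ---------------------------------------------------------------------------
# interpretation
# ---------------------------------------------------------------------------

def atom_contributions(model: FFiNet, record) -> np.ndarray:
    """Readout gate per atom, normalised to sum 1."""
    _, rec = model.forward_graph(model.graph_for(record), record_attention=True)
    g = rec.gates
    total = g.sum()
    return g / total if total > 0 else np.full_like(g, 1.0 / len(g))


def attention_map(model: FFiNet, record, target_atom: int, layer: int, head: int):
    """Total path weights beta_k[target] * alpha_p for one layer and head.

    Returns ``{k: [(path_tuple, weight), ...]}`` over paths targeting
    ``target_atom``; across all hops the weights sum to the total axial mass
    of the available hops (1 when the atom has paths at every used hop).
    """
    graph = model.graph_for(record)
    _, rec = model.forward_graph(graph, record_attention=True)
    beta = rec.beta[layer]
    out: dict[int, list[tuple[tuple[int, ...], float]]] = {}
    for k in model.config.use_hops:
        paths = graph.paths[k]
        alpha = rec.alpha[layer][k]
        rows = np.nonzero(paths[:, 0] == target_atom)[0] if paths.shape[0] else []
        out[k] = [
            (tuple(int(a) for a in paths[r]), float(beta[target_atom, k - 1] * alpha[r, head]))
            for r in rows
        ]
    return out


def node_similarity(model: FFiNet, record) -> np.ndarray:
    """Pearson correlation between final-layer node embeddings."""
    _, rec = model.forward_graph(model.graph_for(record), record_attention=True)
    h = rec.h_final
    std = h.std(axis=1)
    safe = np.where(std > 0, std, 1.0)
    z = (h - h.mean(axis=1, keepdims=True)) / safe[:, None]
    corr = z @ z.T / h.shape[1]
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return corr
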
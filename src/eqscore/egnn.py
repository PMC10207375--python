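"""E(n)-equivariant graph network with shallow-MLP edge attention.

The network takes positions, 12-wide node features, edge indices, and
LL/LP/PP edge attributes.  Node features are first projected to the hidden
width, then passed through a stack of equivariant layers.  In each layer an
edge MLP builds a message m_ij from the endpoint embeddings, the squared
interatomic distance, and the edge type; a shallow attention MLP squashes
each message to a score e_ij in [0, 1]; the per-node aggregate is the
attention-weighted sum m_i = sum_j e_ij * m_ij; the node update is a
residual MLP on (h_i, m_i).  Position updates displace x_i along relative
position vectors with a scalar per-edge coefficient, also weighted by e_ij,
so that zeroing an edge's attention is exactly equivalent to deleting the
edge.  Predictions pool node features only (global average), so the scalar
output is invariant under rotations, translations, reflections, and atom
relabeling.

Two heads: ``pose`` ends in a sigmoid (y in [0, 1]); ``affinity`` ends in a
ReLU (nonnegative predicted -log-affinity), attached by head replacement
after pose pretraining.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .exceptions import EmptyInputError
from .graphs import ComplexGraph

__all__ = [
    "ModelConfig",
    "ModelParams",
    "init_params",
    "replace_head",
    "attention_scores",
    "egnn_layer",
    "predict",
    "PredictResult",
    "forward_tensors",
    "POSITION_SCALE",
]

#: Fixed scale (Angstrom) applied to the tanh-squashed per-edge position
#: coefficient; bounds each edge's displacement contribution for stability
#: without breaking rotation equivariance.
POSITION_SCALE = 0.1

#: Squared distances are divided by this (the ligand-protein cutoff squared,
#: Angstrom^2) before entering the edge MLP, keeping the input O(1).
DISTANCE_NORM = 100.0


@dataclass(frozen=True)
class ModelConfig:
    n_layers: int = 48
    hidden_width: int = 32
    attention_hidden: int = 16
    head: str = "pose"          # "pose" | "affinity"
    update_positions: bool = True
    seed: int = 0
    n_node_features: int = 12

    def __post_init__(self):
        if self.n_layers < 1 or self.hidden_width < 1:
            raise ValueError("n_layers and hidden_width must be >= 1")
        if self.head not in ("pose", "affinity"):
            raise ValueError(f"unknown head {self.head!r}")

    @classmethod
    def desk(cls, **overrides) -> "ModelConfig":
        """Small profile (4 layers, width 32) for CPU-scale experiments."""
        defaults = dict(n_layers=4, hidden_width=32, attention_hidden=16)
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class ModelParams:
    """Named parameter arrays plus the config that shaped them."""

    values: dict
    config: ModelConfig
    head_replaced: bool = False

    def copy(self) -> "ModelParams":
        return ModelParams({k: v.copy() for k, v in self.values.items()},
                           self.config, self.head_replaced)

    # -- flat (de)serialization ---------------------------------------
    def flatten(self) -> np.ndarray:
        return np.concatenate([self.values[k].ravel()
                               for k in sorted(self.values)])

    def unflatten(self, flat: np.ndarray) -> "ModelParams":
        out, offset = {}, 0
        for key in sorted(self.values):
            shape = self.values[key].shape
            size = self.values[key].size
            out[key] = flat[offset:offset + size].reshape(shape).copy()
            offset += size
        return ModelParams(out, self.config, self.head_replaced)

    def save(self, path) -> None:
        header = json.dumps({"config": asdict(self.config),
                             "head_replaced": self.head_replaced})
        np.savez(path, header=np.frombuffer(header.encode(), dtype=np.uint8),
                 **self.values)

    @classmethod
    def load(cls, path) -> "ModelParams":
        data = np.load(path)
        header = json.loads(bytes(data["header"]).decode())
        values = {k: data[k] for k in data.files if k != "header"}
        return cls(values, ModelConfig(**header["config"]),
                   header["head_replaced"])


def _glorot(rng, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _init_mlp(rng, values, prefix, sizes):
    for i, (fan_in, fan_out) in enumerate(zip(sizes[:-1], sizes[1:])):
        values[f"{prefix}.W{i}"] = _glorot(rng, fan_in, fan_out)
        values[f"{prefix}.b{i}"] = np.zeros(fan_out)


def init_params(config: ModelConfig) -> ModelParams:
    """Deterministic Glorot initialization from config.seed."""
    rng = np.random.default_rng(config.seed)
    h, a = config.hidden_width, config.attention_hidden
    values = {}
    values["embed.W"] = _glorot(rng, config.n_node_features, h)
    values["embed.b"] = np.zeros(h)
    for layer in range(config.n_layers):
        p = f"layer{layer}"
        _init_mlp(rng, values, f"{p}.edge", [2 * h + 1 + 3, h, h])
        # attention sees the message plus the scaled squared distance, so it
        # can resolve geometry directly rather than through the tanh-bounded
        # message alone
        _init_mlp(rng, values, f"{p}.att", [h + 1, a, 1])
        _init_mlp(rng, values, f"{p}.pos", [h, a, 1])
        _init_mlp(rng, values, f"{p}.node", [2 * h, h, h])
        # zero-init the residual branch's output so layers start as the
        # identity map and activations stay O(1) at any depth
        values[f"{p}.node.W1"] = np.zeros_like(values[f"{p}.node.W1"])
    values["head.W"] = _glorot(rng, h, 1)
    values["head.b"] = np.zeros(1)
    return ModelParams(values, config)


def replace_head(params: ModelParams, head: str = "affinity",
                 seed: int = 0) -> ModelParams:
    """Swap in a freshly initialized output head (used for finetuning)."""
    rng = np.random.default_rng(seed)
    out = params.copy()
    out.values["head.W"] = _glorot(rng, params.config.hidden_width, 1)
    # positive bias keeps the ReLU output head alive at the start of
    # finetuning (a zero or negative pre-activation would have no gradient)
    out.values["head.b"] = np.ones(1)
    out.config = replace(params.config, head=head)
    out.head_replaced = True
    return out


# -- forward pass ------------------------------------------------------

def _wrap(values) -> dict:
    return {k: Tensor(v) for k, v in values.items()}


def _mlp(tensors, prefix, x, hidden_act=ad.silu, final_act=None):
    x = hidden_act(x @ tensors[f"{prefix}.W0"] + tensors[f"{prefix}.b0"])
    x = x @ tensors[f"{prefix}.W1"] + tensors[f"{prefix}.b1"]
    return final_act(x) if final_act is not None else x


def _layer_tensors(tensors, prefix, h, x, edge_index, edge_attrs,
                   update_positions, edge_mask):
    """One equivariant layer on Tensors; returns (h', x', attention)."""
    src, dst = edge_index
    n = h.shape[0]
    h_src = ad.gather_rows(h, src)
    h_dst = ad.gather_rows(h, dst)
    x_src = ad.gather_rows(x, src)
    x_dst = ad.gather_rows(x, dst)
    rel = x_dst - x_src
    dist2 = (rel * rel).sum(axis=1, keepdims=True) * (1.0 / DISTANCE_NORM)
    # tanh-bounded messages: the attention score is then the only per-edge
    # gain control, so it cannot be bypassed by inflating message norms
    message = _mlp(tensors, f"{prefix}.edge",
                   ad.concat([h_dst, h_src, dist2, Tensor(edge_attrs)]),
                   final_act=ad.tanh)
    attention = _mlp(tensors, f"{prefix}.att", ad.concat([message, dist2]),
                     final_act=ad.sigmoid)
    if edge_mask is not None:
        attention = attention * Tensor(edge_mask.reshape(-1, 1))
    weighted = message * attention
    aggregate = ad.segment_sum(weighted, dst, n)
    update = _mlp(tensors, f"{prefix}.node", ad.concat([h, aggregate]))
    h_new = h + update
    if update_positions:
        coeff = _mlp(tensors, f"{prefix}.pos", message, final_act=ad.tanh)
        disp = ad.segment_sum(rel * (coeff * attention) * POSITION_SCALE,
                              dst, n)
        x_new = x + disp
    else:
        x_new = x
    return h_new, x_new, attention


def forward_tensors(tensors: dict, config: ModelConfig, graph: ComplexGraph,
                    edge_mask: np.ndarray | None = None):
    """Differentiable forward pass.

    Returns (raw head pre-activation as a 1x1 Tensor, list of per-layer
    attention Tensors, each m x 1).
    """
    if graph.n_nodes == 0:
        raise EmptyInputError("cannot score an empty graph")
    h = Tensor(graph.node_features.astype(float)) @ tensors["embed.W"] \
        + tensors["embed.b"]
    x = Tensor(graph.positions)
    attentions = []
    for layer in range(config.n_layers):
        h, x, att = _layer_tensors(tensors, f"layer{layer}", h, x,
                                   graph.edge_index, graph.edge_attrs,
                                   config.update_positions, edge_mask)
        attentions.append(att)
    pooled = h.mean(axis=0, keepdims=True)
    raw = pooled @ tensors["head.W"] + tensors["head.b"]
    return raw, attentions


@dataclass
class PredictResult:
    score: float                 # head output (pose: [0,1]; affinity: >= 0)
    raw: float                   # head pre-activation
    attention: np.ndarray        # final-layer e_ij per directed edge
    attention_layers: list       # all layers' e_ij arrays


def predict(graph: ComplexGraph, params: ModelParams,
            edge_mask: np.ndarray | None = None) -> PredictResult:
    """Score one complex graph; also exports edge attention for attribution.

    ``edge_mask`` (length m, 0/1) forces the attention score of flagged-0
    edges to zero in every layer, which is exactly equivalent to deleting
    those edges from the graph.
    """
    raw, attentions = forward_tensors(_wrap(params.values), params.config,
                                      graph, edge_mask)
    raw_value = float(raw.data.reshape(()))
    if params.config.head == "pose":
        score = float(1.0 / (1.0 + np.exp(-raw_value)))
    else:
        score = max(raw_value, 0.0)
    layers = [a.data.ravel().copy() for a in attentions]
    return PredictResult(score=score, raw=raw_value,
                         attention=layers[-1], attention_layers=layers)


def attention_scores(params: ModelParams, edge_embeddings: np.ndarray,
                     dist2: np.ndarray | None = None,
                     layer: int = -1) -> np.ndarray:
    """Apply one layer's shallow attention MLP to edge embeddings.

    Input is an m x hidden_width array of edge messages, optionally with the
    per-edge scaled squared distances (zeros when omitted); output is m
    scores in [0, 1].  Deterministic given parameters.
    """
    edge_embeddings = np.asarray(edge_embeddings, dtype=float)
    if not np.all(np.isfinite(edge_embeddings)):
        raise ValueError("edge embeddings contain non-finite values")
    if dist2 is None:
        dist2 = np.zeros((edge_embeddings.shape[0], 1))
    dist2 = np.asarray(dist2, dtype=float).reshape(-1, 1)
    index = layer % params.config.n_layers
    out = _mlp(_wrap(params.values), f"layer{index}.att",
               Tensor(np.concatenate([edge_embeddings, dist2], axis=1)),
               final_act=ad.sigmoid)
    return out.data.ravel().copy()


def egnn_layer(params: ModelParams, layer: int, node_features: np.ndarray,
               positions: np.ndarray, edge_index: np.ndarray,
               edge_attrs: np.ndarray,
               edge_mask: np.ndarray | None = None):
    """Run one equivariant layer on plain arrays (hidden-width features).

    Returns (updated node features, updated positions, attention scores).
    """
    edge_index = np.asarray(edge_index, dtype=np.intp)
    if edge_index.size and edge_index.max() >= node_features.shape[0]:
        raise IndexError("edge references a missing node")
    h, x, att = _layer_tensors(
        _wrap(params.values), f"layer{layer % params.config.n_layers}",
        Tensor(np.asarray(node_features, dtype=float)),
        Tensor(np.asarray(positions, dtype=float)),
        edge_index, np.asarray(edge_attrs, dtype=float),
        params.config.update_positions, edge_mask)
    return h.data.copy(), x.data.copy(), att.data.ravel().copy()
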
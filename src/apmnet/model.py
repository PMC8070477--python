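"""The cascade affinity-scoring network.

Pipeline: 75-dim one-hot atom features -> linear embedding (dense, no
activation — it exists to densify the sparse one-hot input) -> ARMA
graph-convolution stage (T recursion steps in K parallel stacks) ->
edge-conditioned message-passing stage (bond features drive per-edge
message matrices) -> global add pool -> dense head -> scalar pKa.

Pocket and ligand graphs are processed as one disjoint graph per
complex; batches are disjoint unions of complexes with a per-node graph
id, so the pooled readout separates cleanly and batched output equals
per-graph output. Ablation variants drop either stage via config.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._autodiff import Tensor, as_tensor, matmul, relu
from .gnn_layers import (ArmaConfig, ArmaWeights, EdgeNetwork,
                         edge_conv_forward, arma_forward, global_add_pool,
                         glorot_uniform, normalized_adjacency)
from .molgraph import ComplexGraph, N_ATOM_FEATURES

VARIANTS = ("full", "arma_only", "mpnn_only")


@dataclass
class ApmnetConfig:
    """Architecture knobs. Defaults follow the best grid-search cell:
    embedding width 128, 5 ARMA recursion steps, 1 MPNN layer."""

    input_dim: int = N_ATOM_FEATURES
    embed_dim: int = 128
    arma_layers: int = 5
    arma_stacks: int = 3
    mpnn_layers: int = 1
    head_dims: Optional[list[int]] = None
    edge_hidden: int = 32
    activation: str = "relu"
    variant: str = "full"

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.embed_dim < 1 or self.arma_layers < 1 or self.arma_stacks < 1:
            raise ValueError("embed_dim, arma_layers, arma_stacks must be >= 1")
        if self.mpnn_layers < 0:
            raise ValueError("mpnn_layers must be >= 0")
        if self.head_dims is None:
            self.head_dims = [max(self.embed_dim // 2, 1)]

    @property
    def n_mpnn(self) -> int:
        return 0 if self.variant == "arma_only" else self.mpnn_layers

    @property
    def use_arma(self) -> bool:
        return self.variant != "mpnn_only"

    def arma_config(self) -> ArmaConfig:
        return ArmaConfig(K=self.arma_stacks, T=self.arma_layers,
                          d_in=self.embed_dim, d_out=self.embed_dim,
                          activation=self.activation)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class ApmnetParams:
    """All trainable tensors, grouped by stage."""

    def __init__(self, embed_W: Tensor, embed_b: Tensor,
                 arma: Optional[ArmaWeights],
                 edge_nets: list[EdgeNetwork],
                 head: list[tuple[Tensor, Tensor]]):
        self.embed_W = embed_W
        self.embed_b = embed_b
        self.arma = arma
        self.edge_nets = edge_nets
        self.head = head

    def parameters(self) -> list[Tensor]:
        out = [self.embed_W, self.embed_b]
        if self.arma is not None:
            out += self.arma.parameters()
        for net in self.edge_nets:
            out += net.parameters()
        for W, b in self.head:
            out += [W, b]
        return out

    def copy_values(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.parameters()]

    def load_values(self, values: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        if len(values) != len(params):
            raise ValueError("parameter count mismatch")
        for p, v in zip(params, values):
            if p.value.shape != v.shape:
                raise ValueError("parameter shape mismatch")
            p.value = np.asarray(v, dtype=np.float64).copy()


def init_params(cfg: ApmnetConfig, seed: int) -> ApmnetParams:
    """Glorot-uniform weights, zero biases; reproducible from the seed."""
    rng = np.random.default_rng(seed)
    embed_W = Tensor(glorot_uniform(rng, cfg.input_dim, cfg.embed_dim),
                     requires_grad=True)
    embed_b = Tensor(np.zeros(cfg.embed_dim), requires_grad=True)
    arma = (ArmaWeights.init(cfg.arma_config(), rng)
            if cfg.use_arma else None)
    edge_nets = [EdgeNetwork(cfg.embed_dim, cfg.edge_hidden, rng)
                 for _ in range(cfg.n_mpnn)]
    head = []
    dims = [cfg.embed_dim, *cfg.head_dims, 1]
    for d_in, d_out in zip(dims[:-1], dims[1:]):
        head.append((Tensor(glorot_uniform(rng, d_in, d_out),
                            requires_grad=True),
                     Tensor(np.zeros(d_out), requires_grad=True)))
    return ApmnetParams(embed_W, embed_b, arma, edge_nets, head)


def _merge_batch(batch: Sequence[ComplexGraph]):
    """Disjoint union of complex graphs with a per-node graph id."""
    xs, eis, es, gids = [], [], [], []
    offset = 0
    for g, cg in enumerate(batch):
        xs.append(cg.graph.X)
        eis.append(cg.graph.edge_index + offset)
        es.append(cg.graph.E)
        gids.append(np.full(cg.graph.n, g, dtype=np.int64))
        offset += cg.graph.n
    return (np.vstack(xs), np.hstack(eis), np.vstack(es),
            np.concatenate(gids), offset)


def forward_tensor(batch: Sequence[ComplexGraph], params: ApmnetParams,
                   cfg: ApmnetConfig) -> Tensor:
    """Differentiable forward pass; returns a length-B prediction Tensor."""
    if not batch:
        raise ValueError("empty batch")
    X, edge_index, E, graph_id, n = _merge_batch(batch)
    if X.shape[1] != cfg.input_dim:
        raise ValueError(f"node features are {X.shape[1]}-dim, "
                         f"expected {cfg.input_dim}")
    h = matmul(Tensor(X), params.embed_W) + params.embed_b
    if cfg.use_arma:
        adj = normalized_adjacency(edge_index, n)
        h = arma_forward(h, adj, params.arma, cfg.arma_config())
    for i, net in enumerate(params.edge_nets):
        if i > 0:
            h = relu(h)
        h = edge_conv_forward(h, edge_index, E, net)
    pooled = global_add_pool(h, graph_id, len(batch))
    out = pooled
    for i, (W, b) in enumerate(params.head):
        if i > 0:
            out = relu(out)
        out = matmul(out, W) + b
    return out.reshape(len(batch))


def forward(batch: Sequence[ComplexGraph], params: ApmnetParams,
            cfg: ApmnetConfig) -> np.ndarray:
    """Predicted pKa per complex (plain numpy, no gradient tape)."""
    return forward_tensor(batch, params, cfg).value.copy()


def pooled_representation(cg: ComplexGraph, params: ApmnetParams,
                          cfg: ApmnetConfig) -> np.ndarray:
    """Graph-level vector after the add pool, before the dense head."""
    X, edge_index, E, graph_id, n = _merge_batch([cg])
    h = matmul(Tensor(X), params.embed_W) + params.embed_b
    if cfg.use_arma:
        adj = normalized_adjacency(edge_index, n)
        h = arma_forward(h, adj, params.arma, cfg.arma_config())
    for i, net in enumerate(params.edge_nets):
        if i > 0:
            h = relu(h)
        h = edge_conv_forward(h, edge_index, E, net)
    return global_add_pool(h, graph_id, 1).value[0].copy()


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(path: str, params: ApmnetParams,
                    cfg: ApmnetConfig) -> None:
    """Portable npz checkpoint keyed by the config hash."""
    arrays = {f"p{i:04d}": v for i, v in enumerate(params.copy_values())}
    arrays["config_json"] = np.array(json.dumps(asdict(cfg), sort_keys=True))
    arrays["config_hash"] = np.array(cfg.hash())
    np.savez_compressed(path, **arrays)


def load_checkpoint(path: str) -> tuple[ApmnetParams, ApmnetConfig]:
    with np.load(path) as z:
        cfg = ApmnetConfig(**json.loads(str(z["config_json"])))
        params = init_params(cfg, seed=0)
        values = [z[f"p{i:04d}"] for i in range(len(params.parameters()))]
    params.load_values(values)
    return params, cfg
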
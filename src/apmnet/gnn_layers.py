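"""Graph-convolution primitives: the ARMA filter and the
edge-conditioned message-passing layer.

Both layers come in two implementations with identical contracts:

* a vectorized forward (``arma_forward`` / ``edge_conv_forward``) built
  on the autodiff tape, used by the model and the training loop;
* a naive per-node, per-entry loop reference (``arma_reference`` /
  ``edge_conv_reference``) that shares no code path with the forward
  and serves as an independent oracle in tests.

The ARMA filter runs an auto-regressive moving-average recursion

    Xbar(t+1) = sigma( Ltilde Xbar(t) W_t + X V_t )

over the graph operator Ltilde = I - D^{-1/2} A D^{-1/2}, in K parallel
stacks whose final states are averaged (the average itself has no
activation). Xbar(0) = X, so T=0 would be the identity. The
edge-conditioned layer maps each 6-dim bond vector through a small
dense network to a d x d matrix that transforms the neighbouring node
vector before aggregation; the self term passes through untouched:

    x_i' = x_i + sum_{j in N(i)} Theta(e_ij) x_j
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Union

import numpy as np

from ._autodiff import Tensor, as_tensor, bmv, gather, matmul, relu, segment_sum

ArrayOrTensor = Union[np.ndarray, Tensor]

_ACTIVATIONS: dict[str, Callable[[Tensor], Tensor]] = {
    "relu": relu,
    "identity": lambda x: x,
}


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                   shape: tuple[int, ...] | None = None) -> np.ndarray:
    """Glorot/Xavier uniform draw: U(-a, a), a = sqrt(6 / (fan_in+fan_out))."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


@dataclass
class NormalizedAdjacency:
    """Symmetrically normalized adjacency L = D^{-1/2} A D^{-1/2} and its
    complement Ltilde = I - L. Zero-degree nodes get all-zero rows in L
    (0^{-1/2} is treated as 0)."""

    L: np.ndarray
    Ltilde: np.ndarray

    @property
    def n(self) -> int:
        return self.L.shape[0]


def normalized_adjacency(edge_index: np.ndarray, n: int) -> NormalizedAdjacency:
    edge_index = np.asarray(edge_index, dtype=np.int64).reshape(2, -1)
    if edge_index.size and edge_index.max() >= n:
        raise ValueError("edge index out of range")
    A = np.zeros((n, n))
    A[edge_index[0], edge_index[1]] = 1.0
    A[edge_index[1], edge_index[0]] = 1.0
    deg = A.sum(axis=1)
    with np.errstate(divide="ignore"):
        dinv = np.where(deg > 0, deg, 1.0) ** -0.5
    dinv = np.where(deg > 0, dinv, 0.0)
    L = dinv[:, None] * A * dinv[None, :]
    return NormalizedAdjacency(L=L, Ltilde=np.eye(n) - L)


@dataclass
class ArmaConfig:
    K: int = 3
    T: int = 5
    d_in: int = 75
    d_out: int = 75
    activation: str = "relu"

    def __post_init__(self):
        if self.K < 1 or self.T < 1:
            raise ValueError("K and T must be >= 1")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")


class ArmaWeights:
    """Per-stack, per-step trainable matrices W[k][t] and V[k][t].

    W[k][0] maps d_in -> d_out (it multiplies Xbar(0) = X); subsequent
    W[k][t] map d_out -> d_out. Every V[k][t] maps the skip input X,
    d_in -> d_out. No weight sharing across steps.
    """

    def __init__(self, W: list[list[Tensor]], V: list[list[Tensor]]):
        self.W = W
        self.V = V

    @classmethod
    def init(cls, cfg: ArmaConfig, rng: np.random.Generator) -> "ArmaWeights":
        W, V = [], []
        for _ in range(cfg.K):
            Wk, Vk = [], []
            for t in range(cfg.T):
                w_in = cfg.d_in if t == 0 else cfg.d_out
                Wk.append(Tensor(glorot_uniform(rng, w_in, cfg.d_out),
                                 requires_grad=True))
                Vk.append(Tensor(glorot_uniform(rng, cfg.d_in, cfg.d_out),
                                 requires_grad=True))
            W.append(Wk)
            V.append(Vk)
        return cls(W, V)

    def parameters(self) -> list[Tensor]:
        return [m for stack in (*self.W, *self.V) for m in stack]


def arma_forward(X: ArrayOrTensor, adj: NormalizedAdjacency,
                 weights: ArmaWeights, cfg: ArmaConfig) -> ArrayOrTensor:
    """Vectorized ARMA filter; returns the mean of the K stack outputs.

    Accepts a plain array (returns an array) or a Tensor (returns a
    Tensor participating in the autodiff tape).
    """
    as_array = not isinstance(X, Tensor)
    Xt = as_tensor(X)
    if Xt.shape != (adj.n, cfg.d_in):
        raise ValueError(f"X shape {Xt.shape} incompatible with "
                         f"n={adj.n}, d_in={cfg.d_in}")
    act = _ACTIVATIONS[cfg.activation]
    Lt = Tensor(adj.Ltilde)
    acc = None
    for k in range(cfg.K):
        xbar = Xt
        for t in range(cfg.T):
            xbar = act(matmul(matmul(Lt, xbar), weights.W[k][t])
                       + matmul(Xt, weights.V[k][t]))
        acc = xbar if acc is None else acc + xbar
    out = acc * (1.0 / cfg.K)
    return out.value if as_array else out


def arma_reference(X: np.ndarray, adj: NormalizedAdjacency,
                   weights: ArmaWeights, cfg: ArmaConfig) -> np.ndarray:
    """Per-node, per-entry loop implementation of the ARMA recursion.

    Deliberately unvectorized; independent oracle for arma_forward.
    """
    X = np.asarray(X, dtype=np.float64)
    n = adj.n
    if X.shape != (n, cfg.d_in):
        raise ValueError("shape mismatch")
    Lt = adj.Ltilde

    def act(v: float) -> float:
        if cfg.activation == "relu":
            return v if v > 0 else 0.0
        return v

    stack_outputs = []
    for k in range(cfg.K):
        xbar = X.copy()
        for t in range(cfg.T):
            W = weights.W[k][t].value
            V = weights.V[k][t].value
            nxt = np.zeros((n, cfg.d_out))
            for i in range(n):
                # propagated term: (Ltilde xbar)_i then times W
                prop = [sum(Lt[i, j] * xbar[j, d] for j in range(n))
                        for d in range(xbar.shape[1])]
                for c in range(cfg.d_out):
                    s = sum(prop[d] * W[d, c] for d in range(len(prop)))
                    s += sum(X[i, d] * V[d, c] for d in range(cfg.d_in))
                    nxt[i, c] = act(s)
            xbar = nxt
        stack_outputs.append(xbar)
    return sum(stack_outputs) / cfg.K


class EdgeNetwork:
    """Dense map from a 6-dim bond vector to a d x d message matrix.

    Single hidden layer with ReLU: 6 -> hidden -> d*d, reshaped per edge.
    """

    def __init__(self, d: int, hidden: int = 32,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.d = d
        self.hidden = hidden
        self.W1 = Tensor(glorot_uniform(rng, 6, hidden), requires_grad=True)
        self.b1 = Tensor(np.zeros(hidden), requires_grad=True)
        self.W2 = Tensor(glorot_uniform(rng, hidden, d * d), requires_grad=True)
        self.b2 = Tensor(np.zeros(d * d), requires_grad=True)

    def __call__(self, E: ArrayOrTensor) -> Tensor:
        Et = as_tensor(E)
        h = relu(matmul(Et, self.W1) + self.b1)
        flat = matmul(h, self.W2) + self.b2
        return flat.reshape(Et.shape[0], self.d, self.d)

    def parameters(self) -> list[Tensor]:
        return [self.W1, self.b1, self.W2, self.b2]


class ConstantEdgeNetwork:
    """Edge network that returns the same fixed matrix for every edge.

    Test utility for closed-form identities (identity or zero matrix)."""

    def __init__(self, matrix: np.ndarray):
        self.matrix = np.asarray(matrix, dtype=np.float64)
        self.d = self.matrix.shape[0]

    def __call__(self, E: ArrayOrTensor) -> Tensor:
        m = E.shape[0]
        return Tensor(np.broadcast_to(self.matrix, (m, self.d, self.d)).copy())

    def parameters(self) -> list[Tensor]:
        return []


def edge_conv_forward(X: ArrayOrTensor, edge_index: np.ndarray,
                      E: ArrayOrTensor, net) -> ArrayOrTensor:
    """Edge-conditioned convolution x_i' = x_i + sum_j Theta(e_ij) x_j
    over incoming directed edges (j -> i)."""
    as_array = not isinstance(X, Tensor)
    Xt, Et = as_tensor(X), as_tensor(E)
    edge_index = np.asarray(edge_index, dtype=np.int64).reshape(2, -1)
    m = edge_index.shape[1]
    if Et.shape[0] != m:
        raise ValueError(f"{m} edges but {Et.shape[0]} edge feature rows")
    n = Xt.shape[0]
    if m == 0:
        return Xt.value.copy() if as_array else Xt
    theta = net(Et)                      # (m, d, d)
    xj = gather(Xt, edge_index[0])       # source node states
    messages = bmv(theta, xj)
    out = Xt + segment_sum(messages, edge_index[1], n)
    return out.value if as_array else out


def edge_conv_reference(X: np.ndarray, edge_index: np.ndarray,
                        E: np.ndarray, net) -> np.ndarray:
    """Explicit-loop oracle for edge_conv_forward."""
    X = np.asarray(X, dtype=np.float64)
    edge_index = np.asarray(edge_index, dtype=np.int64).reshape(2, -1)
    E = np.asarray(E, dtype=np.float64)
    m = edge_index.shape[1]
    if E.shape[0] != m:
        raise ValueError("edge/feature count mismatch")
    n, d = X.shape
    theta = net(E).value if m else np.zeros((0, d, d))
    out = X.copy()
    for e in range(m):
        j, i = edge_index[0, e], edge_index[1, e]
        for r in range(d):
            out[i, r] += sum(theta[e, r, c] * X[j, c] for c in range(d))
    return out


def global_add_pool(X: ArrayOrTensor, graph_id: np.ndarray,
                    n_graphs: int | None = None) -> ArrayOrTensor:
    """Sum node rows per graph: the permutation-invariant readout."""
    graph_id = np.asarray(graph_id, dtype=np.int64)
    if n_graphs is None:
        n_graphs = int(graph_id.max()) + 1 if graph_id.size else 0
    as_array = not isinstance(X, Tensor)
    out = segment_sum(as_tensor(X), graph_id, n_graphs)
    return out.value if as_array else out
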
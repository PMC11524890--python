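"""Network building blocks: dense layers, MLPs and graph attention.

All layers hold their weights as :class:`~dualsyn.nn.autograd.Tensor`
objects with ``requires_grad=True`` and expose ``parameters()`` for the
optimizer. Initialization is Glorot-uniform from a caller-supplied
``numpy.random.Generator`` so whole-model construction is reproducible
from a single seed.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, gather_rows, segment_softmax, segment_sum


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    shape = shape if shape is not None else (fan_in, fan_out)
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class Module:
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state length does not match parameter count")
        for p, arr in zip(params, state):
            if p.data.shape != arr.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {arr.shape}")
            p.data = arr.astype(np.float64).copy()


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.weight = glorot(rng, in_dim, out_dim)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class MLP(Module):
    """Stack of Linear+ReLU layers; the final layer is also ReLU-activated.

    Matches the cell-line encoder and prediction-net equations, where
    every hidden layer applies ReLU and any task head is attached
    separately.
    """

    def __init__(self, dims: list[int], rng: np.random.Generator):
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x).relu()
        return x


class Dropout:
    """Inverted dropout; identity when ``training=False`` or rate 0."""

    def __init__(self, rate: float):
        self.rate = float(rate)

    def __call__(self, x: Tensor, rng: np.random.Generator, training: bool) -> Tensor:
        if not training or self.rate <= 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (rng.random(x.data.shape) < keep) / keep
        return x * Tensor(mask)


class GATConv(Module):
    """One multi-head graph-attention layer over a batched edge list.

    For directed edge ``j -> i`` (message from source j into target i)
    the unnormalized score is ``LeakyReLU(a^T [W h_i || W h_j])``,
    normalized by softmax over each target's in-neighborhood (self-loops
    are appended by the caller), and head outputs are concatenated.
    """

    def __init__(self, in_dim: int, out_dim: int, heads: int, rng: np.random.Generator,
                 negative_slope: float = 0.2):
        self.heads = heads
        self.out_dim = out_dim
        self.negative_slope = negative_slope
        self.weight = glorot(rng, in_dim, heads * out_dim)
        # attention vector a, split into target/source halves
        self.att_dst = glorot(rng, out_dim, 1, shape=(heads, out_dim))
        self.att_src = glorot(rng, out_dim, 1, shape=(heads, out_dim))
        self.bias = Tensor(np.zeros(heads * out_dim), requires_grad=True)

    def __call__(self, h: Tensor, edge_src: np.ndarray, edge_dst: np.ndarray,
                 n_nodes: int, return_alpha: bool = False):
        H, F = self.heads, self.out_dim
        wh = (h @ self.weight).reshape(n_nodes, H, F)
        # per-node attention logits, one scalar per head
        s_dst = (wh * self.att_dst).sum(axis=2)   # (N, H)
        s_src = (wh * self.att_src).sum(axis=2)   # (N, H)
        e = (gather_rows(s_dst, edge_dst) + gather_rows(s_src, edge_src)).leaky_relu(
            self.negative_slope
        )                                          # (E, H)
        alpha = segment_softmax(e, edge_dst, n_nodes)
        msg = gather_rows(wh, edge_src) * alpha.reshape(-1, H, 1)
        out = segment_sum(msg, edge_dst, n_nodes).reshape(n_nodes, H * F) + self.bias
        if return_alpha:
            return out, alpha
        return out


def relu_linear(x: Tensor, layer: Linear) -> Tensor:
    return layer(x).relu()


def log_softmax(x: Tensor) -> Tensor:
    """Row-wise log-softmax via the max-shift trick (shift is constant)."""
    shift = Tensor(x.data.max(axis=-1, keepdims=True))
    z = x - shift
    return z - z.exp().sum(axis=-1, keepdims=True).log()


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred - Tensor(np.asarray(target, dtype=np.float64))
    return (diff * diff).mean()


def cross_entropy_loss(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer ``labels`` under softmax."""
    labels = np.asarray(labels, dtype=np.intp)
    logp = log_softmax(logits)
    onehot = np.zeros(logits.data.shape)
    onehot[np.arange(labels.size), labels] = 1.0
    return (logp * Tensor(onehot)).sum() * (-1.0 / labels.size)
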
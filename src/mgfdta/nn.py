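"""Neural building blocks: linear layers, layer norm, multi-head self
attention, transformer encoder layers, dropout, Adam and a plateau
learning-rate scheduler.

All layers operate on :class:`~mgfdta._autodiff.Tensor` and use numpy
underneath. Padded positions are conventionally zeroed after every layer
so that downstream masked reductions stay exact.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from ._autodiff import Parameter, Tensor, concat

__all__ = [
    "Module", "Linear", "LayerNorm", "Dropout", "MultiheadSelfAttention",
    "TransformerEncoderLayer", "MLPHead", "masked_softmax", "Adam",
    "ReduceLROnPlateau",
]


def masked_softmax(scores: Tensor, mask: np.ndarray, axis: int = -1) -> Tensor:
    """Softmax over ``axis`` restricted to positions where ``mask`` is 1.

    Masked positions receive exactly zero weight; valid weights sum to 1.
    ``mask`` must broadcast against ``scores`` and contain at least one
    valid position along ``axis`` wherever a distribution is requested.
    """
    mask = np.asarray(mask, dtype=np.float64)
    if not np.all(mask.max(axis=axis) > 0):
        raise ValueError("masked_softmax: a row has no unmasked positions")
    shifted = scores + Tensor((1.0 - mask) * -1e9)
    # shift by a detached max for numerical stability (softmax-invariant)
    peak = Tensor(shifted.data.max(axis=axis, keepdims=True))
    weights = (shifted - peak).exp() * Tensor(mask)
    return weights / weights.sum(axis=axis, keepdims=True)


class Module:
    """Base class with recursive parameter discovery and state I/O."""

    training = True

    def named_parameters(self, prefix: str = ""):
        for name in sorted(vars(self)):
            attr = getattr(self, name)
            key = f"{prefix}{name}"
            if isinstance(attr, Parameter):
                yield key, attr
            elif isinstance(attr, Module):
                yield from attr.named_parameters(f"{key}.")
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{key}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{key}.{i}", item

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for name in sorted(vars(self)):
            attr = getattr(self, name)
            if isinstance(attr, Module):
                yield from attr.modules()
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = np.array(state[k], dtype=np.float64)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape: tuple[int, ...]) -> np.ndarray:
    bound = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=shape)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.weight = Parameter(_glorot(rng, in_dim, out_dim, (in_dim, out_dim)))
        self.bias = Parameter(np.zeros(out_dim))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered ** 2).mean(axis=-1, keepdims=True)
        return centered / (var + self.eps).sqrt() * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        keep = 1.0 - self.p
        mask = self.rng.random(x.shape) < keep
        return x * Tensor(mask / keep)


class MultiheadSelfAttention(Module):
    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads:
            raise ValueError(f"dim {dim} not divisible by n_heads {n_heads}")
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        B, L, D = x.shape
        h, dh = self.n_heads, self.head_dim

        def split(t: Tensor) -> Tensor:
            return t.reshape(B, L, h, dh).transpose((0, 2, 1, 3))

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.transpose((0, 1, 3, 2))) / math.sqrt(dh)
        key_mask = np.asarray(mask, dtype=np.float64).reshape(B, 1, 1, L)
        attn = masked_softmax(scores, key_mask)
        out = (attn @ v).transpose((0, 2, 1, 3)).reshape(B, L, D)
        return self.wo(out)


class TransformerEncoderLayer(Module):
    """Post-norm transformer encoder layer; padded positions are re-zeroed."""

    def __init__(self, dim: int, n_heads: int, ffn_dim: int,
                 rng: np.random.Generator, dropout: float = 0.1):
        self.attn = MultiheadSelfAttention(dim, n_heads, rng)
        self.norm1 = LayerNorm(dim)
        self.norm2 = LayerNorm(dim)
        self.ff1 = Linear(dim, ffn_dim, rng)
        self.ff2 = Linear(ffn_dim, dim, rng)
        self.drop = Dropout(dropout, rng)

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        m = Tensor(np.asarray(mask, dtype=np.float64)[..., None])
        x = self.norm1(x + self.drop(self.attn(x, mask))) * m
        x = self.norm2(x + self.drop(self.ff2(self.ff1(x).relu()))) * m
        return x


class MLPHead(Module):
    """Fully connected regression head: hidden ReLU layers then a scalar."""

    def __init__(self, in_dim: int, hidden: Sequence[int],
                 rng: np.random.Generator, dropout: float = 0.1):
        dims = [in_dim, *hidden]
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.out = Linear(dims[-1], 1, rng)
        self.drop = Dropout(dropout, rng)

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = self.drop(layer(x).relu())
        return self.out(x)


class Adam:
    def __init__(self, params: Sequence[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class ReduceLROnPlateau:
    """Halve (by ``factor``) the optimizer lr when the monitored loss stalls."""

    def __init__(self, optimizer: Adam, factor: float = 0.5, patience: int = 5,
                 min_lr: float = 1e-6, threshold: float = 1e-4):
        self.opt = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.threshold = threshold
        self.best = math.inf
        self.stale = 0

    def step(self, loss: float) -> None:
        if loss < self.best - self.threshold:
            self.best = loss
            self.stale = 0
        else:
            self.stale += 1
            if self.stale > self.patience:
                self.opt.lr = max(self.opt.lr * self.factor, self.min_lr)
                self.stale = 0
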
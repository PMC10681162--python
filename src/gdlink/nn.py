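"""A compact reverse-mode autodiff engine and neural layers over numpy.

Scope is deliberately small: exactly the operations the joint NER/RE model
needs (dense layers, embeddings, layer norm, multi-head self-attention, an
Elman-style bidirectional recurrent layer, elementwise max for span
pooling, softmax/cross-entropy) plus an AdamW optimizer with a linear
warmup/decay schedule. Everything runs single-threaded on CPU and is
bitwise deterministic given the same seed and platform.

Gradients are accumulated into ``Tensor.grad`` by :meth:`Tensor.backward`,
which does a topological sweep over the recorded graph. Elementwise max
routes gradient to the (first) argmax, matching the subgradient convention
used by mainstream frameworks.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np

Array = np.ndarray


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum out broadcast dimensions so grad matches the original shape."""
    if grad.shape == shape:
        return grad
    # Sum leading added axes.
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data: Array | float | list,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[Array], None] | None = None,
    ) -> None:
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Array | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward

    # -- plumbing ----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: Array) -> None:
        g = np.asarray(g, dtype=np.float64)
        self.grad = g if self.grad is None else self.grad + g

    def backward(self, grad: Array | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _lift(x: "Tensor | float | Array") -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g: Array) -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g: Array) -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._lift(other) ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self**-1.0

    def __pow__(self, p: float):
        out = Tensor(self.data**p, parents=(self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bw(g: Array) -> None:
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.shape))

        out._backward = bw
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))

        def bw(g: Array) -> None:
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        out._backward = bw
        return out

    # -- elementwise -------------------------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), parents=(self,))
        out._backward = lambda g: self._accum(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), parents=(self,))
        out._backward = lambda g: self._accum(g * (1.0 - out.data**2))
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))
        out._backward = lambda g: self._accum(g * (self.data > 0))
        return out

    # -- reductions / shape ------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bw(g: Array) -> None:
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def amax(self, axis: int):
        """Max along one axis; gradient flows to the first argmax (tie-break)."""
        out = Tensor(self.data.max(axis=axis), parents=(self,))
        idx = np.expand_dims(self.data.argmax(axis=axis), axis)

        def bw(g: Array) -> None:
            full = np.zeros_like(self.data)
            np.put_along_axis(full, idx, np.expand_dims(g, axis), axis=axis)
            self._accum(full)

        out._backward = bw
        return out

    def reshape(self, *shape: int):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.shape))
        return out

    def transpose(self, *axes: int):
        out = Tensor(self.data.transpose(*axes), parents=(self,))
        inv = np.argsort(axes)
        out._backward = lambda g: self._accum(g.transpose(*inv))
        return out


def maximum(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise max; gradient goes to the larger input (ties: first)."""
    out = Tensor(np.maximum(a.data, b.data), parents=(a, b))
    mask = a.data >= b.data

    def bw(g: Array) -> None:
        if a.requires_grad:
            a._accum(_unbroadcast(g * mask, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * ~mask, b.shape))

    out._backward = bw
    return out


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g: Array) -> None:
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    out._backward = bw
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), parents=tuple(tensors))

    def bw(g: Array) -> None:
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    out._backward = bw
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))  # detached shift
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def cross_entropy(logits: Tensor, labels: Array, reduction: str = "sum") -> Tensor:
    """Multiclass cross-entropy -sum_o sum_t y_{o,t} log p_{o,t}.

    ``labels`` are integer class indices of shape (n,). The default
    reduction is the plain sum over observations; "mean" is available for
    numerically gentler training. log-probabilities are computed via the
    shifted log-softmax, so no explicit epsilon clamp is needed; an exact
    zero probability cannot arise from finite logits.
    """
    lp = log_softmax(logits, axis=-1)
    n = logits.shape[0]
    if n == 0:
        return Tensor(0.0)
    picked = lp[np.arange(n), np.asarray(labels)]
    loss = -picked.sum()
    if reduction == "mean":
        loss = loss * (1.0 / n)
    return loss


# ---------------------------------------------------------------------------
# Modules

class Module:
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> list[Array]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: Iterable[Array]) -> None:
        for p, a in zip(self.parameters(), arrays, strict=True):
            p.data = np.asarray(a, dtype=np.float64)


def _init(rng: np.random.Generator, *shape: int, scale: float | None = None) -> Tensor:
    scale = scale if scale is not None else 1.0 / math.sqrt(shape[0])
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int) -> None:
        self.w = _init(rng, d_in, d_out)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Embedding(Module):
    def __init__(self, rng: np.random.Generator, n: int, d: int) -> None:
        self.table = Tensor(rng.normal(0.0, 0.1, size=(n, d)), requires_grad=True)

    def __call__(self, idx: Array) -> Tensor:
        return self.table[np.asarray(idx, dtype=np.intp)]


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5) -> None:
        self.gain = Tensor(np.ones(d), requires_grad=True)
        self.bias = Tensor(np.zeros(d), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2.0).mean(axis=-1, keepdims=True)
        return (x - mu) / ((var + self.eps) ** 0.5) * self.gain + self.bias


class MultiHeadSelfAttention(Module):
    def __init__(self, rng: np.random.Generator, d: int, heads: int) -> None:
        if d % heads:
            raise ValueError(f"hidden width {d} not divisible by {heads} heads")
        self.heads = heads
        self.dh = d // heads
        self.wq = Linear(rng, d, d)
        self.wk = Linear(rng, d, d)
        self.wv = Linear(rng, d, d)
        self.wo = Linear(rng, d, d)

    def __call__(self, x: Tensor) -> Tensor:
        n, d = x.shape
        def split(t: Tensor) -> Tensor:  # (n, d) -> (heads, n, dh)
            return t.reshape(n, self.heads, self.dh).transpose(1, 0, 2)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = q @ k.transpose(0, 2, 1) * (1.0 / math.sqrt(self.dh))
        ctx = softmax(scores, axis=-1) @ v  # (heads, n, dh)
        merged = ctx.transpose(1, 0, 2).reshape(n, d)
        return self.wo(merged)


class TransformerBlock(Module):
    """Pre-norm transformer block: x + MHSA(LN x); x + FFN(LN x)."""

    def __init__(self, rng: np.random.Generator, d: int, heads: int, d_ff: int | None = None) -> None:
        d_ff = d_ff or 2 * d
        self.ln1 = LayerNorm(d)
        self.attn = MultiHeadSelfAttention(rng, d, heads)
        self.ln2 = LayerNorm(d)
        self.ff1 = Linear(rng, d, d_ff)
        self.ff2 = Linear(rng, d_ff, d)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.ln1(x))
        return x + self.ff2(self.ff1(self.ln2(x)).relu())


class BiRecurrent(Module):
    """Single bidirectional Elman-style recurrent layer, tanh activation.

    Maps (n, d_in) -> (n, 2*d_h): forward and backward hidden states
    concatenated per position. Used as the sequence encoder producing the
    keys/values the relation head attends over.
    """

    def __init__(self, rng: np.random.Generator, d_in: int, d_h: int) -> None:
        self.d_h = d_h
        self.wx_f = _init(rng, d_in, d_h)
        self.wh_f = _init(rng, d_h, d_h)
        self.b_f = Tensor(np.zeros(d_h), requires_grad=True)
        self.wx_b = _init(rng, d_in, d_h)
        self.wh_b = _init(rng, d_h, d_h)
        self.b_b = Tensor(np.zeros(d_h), requires_grad=True)

    def _run(self, x: Tensor, wx: Tensor, wh: Tensor, b: Tensor, reverse: bool) -> list[Tensor]:
        n = x.shape[0]
        order = range(n - 1, -1, -1) if reverse else range(n)
        h = Tensor(np.zeros((1, self.d_h)))
        out: list[Tensor] = [None] * n  # type: ignore[list-item]
        proj = x @ wx + b  # (n, d_h), hoisted out of the loop
        for t in order:
            h = (proj[t : t + 1] + h @ wh).tanh()
            out[t] = h
        return out

    def __call__(self, x: Tensor) -> Tensor:
        fwd = self._run(x, self.wx_f, self.wh_f, self.b_f, reverse=False)
        bwd = self._run(x, self.wx_b, self.wh_b, self.b_b, reverse=True)
        rows = [concat([f, b], axis=-1) for f, b in zip(fwd, bwd)]
        return concat(rows, axis=0)


# ---------------------------------------------------------------------------
# Optimization

class AdamW:
    """AdamW with decoupled weight decay and a pluggable per-step LR."""

    def __init__(
        self,
        params: Sequence[Tensor],
        lr: float = 6e-5,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.01,
    ) -> None:
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * p.data)


def linear_warmup_decay(step: int, total_steps: int, base_lr: float, warmup: float = 0.1) -> float:
    """LR 0 at step 0, base_lr at the end of warmup, linear decay to 0 after."""
    warm = max(1, int(round(warmup * total_steps)))
    if step < warm:
        return base_lr * step / warm
    if total_steps <= warm:
        return base_lr
    return base_lr * max(0.0, (total_steps - step) / (total_steps - warm))
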
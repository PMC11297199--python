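"""A small reverse-mode automatic-differentiation core on NumPy arrays.

Supports exactly the operations the causal temporal networks and the
temporally-scaled focal loss need: dense linear maps, dilated causal
1-D convolutions, masked softmax attention, elementwise nonlinearities and
reductions.  Tensors wrap ``float32``/``float64`` arrays; ``backward()``
runs a topological sweep accumulating gradients into ``.grad``.

Causality note: the convolution pads on the left only and the attention
mask is additive (``-inf`` on forbidden positions), so an output at frame
``t`` is a function of inputs at frames ``<= t`` exactly — masked
positions contribute weight 0.0, leaving earlier outputs bit-identical
under perturbation of later frames.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=np.float64)
        self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # convenience operators ---------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __matmul__(self, other):
        return matmul(self, other)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data + b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.shape))

    out._backward = backward
    return out


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data * b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.shape))

    out._backward = backward
    return out


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data @ b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a._accum(g @ b.data.T)
        if b.requires_grad:
            b._accum(a.data.T @ g)

    out._backward = backward
    return out


def transpose(a: Tensor) -> Tensor:
    out = Tensor(a.data.T, parents=(a,))
    out._backward = lambda g: a._accum(g.T)
    return out


def relu(a: Tensor) -> Tensor:
    out = Tensor(np.maximum(a.data, 0), parents=(a,))
    out._backward = lambda g: a._accum(g * (a.data > 0))
    return out


def log(a: Tensor) -> Tensor:
    out = Tensor(np.log(a.data), parents=(a,))
    out._backward = lambda g: a._accum(g / a.data)
    return out


def clamp_min(a: Tensor, lo: float) -> Tensor:
    """max(a, lo); gradient passes only through unclamped entries."""
    out = Tensor(np.maximum(a.data, lo), parents=(a,))
    out._backward = lambda g: a._accum(g * (a.data >= lo))
    return out


def power(a: Tensor, exponent) -> Tensor:
    """Elementwise power with a constant (possibly per-element) exponent."""
    exponent = np.asarray(exponent)
    out = Tensor(a.data**exponent, parents=(a,))

    def backward(g):
        base = np.where(a.data == 0, 1.0, a.data)  # avoid 0^(e-1) blow-ups at exact zeros
        a._accum(g * exponent * base ** (exponent - 1) * (a.data != 0))

    out._backward = backward
    return out


def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), parents=(a,))

    def backward(g):
        if axis is None:
            a._accum(np.broadcast_to(g, a.shape).copy())
        else:
            g2 = g if keepdims else np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g2, a.shape).copy())

    out._backward = backward
    return out


def mean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    n = a.data.size if axis is None else a.data.shape[axis]
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets, offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    out._backward = backward
    return out


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax; tolerates ``-inf`` masked entries."""
    x = a.data
    m = np.max(x, axis=axis, keepdims=True)
    e = np.exp(x - m)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, parents=(a,))

    def backward(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        a._accum(y * (g - dot))

    out._backward = backward
    return out


def gather_rows(a: Tensor, index: np.ndarray) -> Tensor:
    """``a[arange(T), index]`` for a (T, C) tensor; returns shape (T,)."""
    index = np.asarray(index)
    rows = np.arange(a.data.shape[0])
    out = Tensor(a.data[rows, index], parents=(a,))

    def backward(g):
        ga = np.zeros_like(a.data, dtype=np.float64)
        np.add.at(ga, (rows, index), g)
        a._accum(ga)

    out._backward = backward
    return out


def causal_conv1d(x: Tensor, w: Tensor, b: Tensor, dilation: int = 1) -> Tensor:
    """Dilated causal convolution over a (T, Cin) sequence.

    ``w`` has shape (K, Cin, Cout); tap ``k`` reads ``x[t - k*dilation]``
    (implicit zero padding on the left), so output frame ``t`` never sees
    the future.
    """
    T = x.data.shape[0]
    K = w.data.shape[0]
    y = np.tile(b.data, (T, 1)).astype(np.result_type(x.data, w.data))
    for k in range(K):
        off = k * dilation
        if off < T:
            y[off:] += x.data[: T - off] @ w.data[k]
    out = Tensor(y, parents=(x, w, b))

    def backward(g):
        if b.requires_grad:
            b._accum(g.sum(axis=0))
        gw = np.zeros_like(w.data, dtype=np.float64) if w.requires_grad else None
        gx = np.zeros_like(x.data, dtype=np.float64) if x.requires_grad else None
        for k in range(K):
            off = k * dilation
            if off >= T:
                continue
            if gw is not None:
                gw[k] = x.data[: T - off].T @ g[off:]
            if gx is not None:
                gx[: T - off] += g[off:] @ w.data[k].T
        if gw is not None:
            w._accum(gw)
        if gx is not None:
            x._accum(gx)

    out._backward = backward
    return out


class Adam:
    """Adam with optional linear warm-up on the learning rate."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-3,
        betas=(0.9, 0.999),
        eps=1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data, dtype=np.float64) for p in params]
        self.v = [np.zeros_like(p.data, dtype=np.float64) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self, lr_scale: float = 1.0):
        self.t += 1
        lr = self.lr * lr_scale
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            update = mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay and p.data.ndim > 1:  # decoupled decay, weights only
                update = update + self.weight_decay * p.data
            p.data = (p.data - lr * update).astype(p.data.dtype, copy=False)
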
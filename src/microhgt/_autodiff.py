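"""Minimal reverse-mode automatic differentiation over numpy arrays.

The graph model and the autoencoders in this package are small (a few
thousand nodes, dense float64 arrays), so a compact tape-based autodiff
with exactly the primitives the model needs is sufficient: elementwise
arithmetic with broadcasting, matmul, relu/sigmoid/exp/log/power,
axis reductions, reshape, row gather, segment (scatter-add) sum, and
concatenation.  Gradients are checked against finite differences in the
unit tests.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "concat", "gather", "segment_sum", "segment_softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the tape entry needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        # parents: sequence of (parent Tensor, grad_fn: upstream -> parent grad)
        self._parents = tuple(p for p in parents if p[0].requires_grad)
        self.requires_grad = requires_grad or bool(self._parents)

    @property
    def shape(self):
        return self.data.shape

    # ---- graph construction helpers -------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents):
        return Tensor(data, parents=parents)

    # ---- arithmetic ------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        return self._make(
            self.data + other.data,
            [(self, lambda g: _unbroadcast(g, self.shape)),
             (other, lambda g: _unbroadcast(g, other.shape))],
        )

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, [(self, lambda g: -g)])

    def __sub__(self, other):
        other = self._lift(other)
        return self._make(
            self.data - other.data,
            [(self, lambda g: _unbroadcast(g, self.shape)),
             (other, lambda g: _unbroadcast(-g, other.shape))],
        )

    def __rsub__(self, other):
        return self._lift(other).__sub__(self)

    def __mul__(self, other):
        other = self._lift(other)
        return self._make(
            self.data * other.data,
            [(self, lambda g: _unbroadcast(g * other.data, self.shape)),
             (other, lambda g: _unbroadcast(g * self.data, other.shape))],
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return self._make(
            self.data / other.data,
            [(self, lambda g: _unbroadcast(g / other.data, self.shape)),
             (other, lambda g: _unbroadcast(-g * self.data / other.data ** 2, other.shape))],
        )

    def __rtruediv__(self, other):
        return self._lift(other).__truediv__(self)

    def __matmul__(self, other):
        other = self._lift(other)

        def grad_a(g):
            return _unbroadcast(np.matmul(g, np.swapaxes(other.data, -1, -2)), self.shape)

        def grad_b(g):
            return _unbroadcast(np.matmul(np.swapaxes(self.data, -1, -2), g), other.shape)

        return self._make(np.matmul(self.data, other.data), [(self, grad_a), (other, grad_b)])

    def power(self, p: float):
        """Elementwise x**p for a scalar exponent p."""
        out = self.data ** p

        def grad(g):
            with np.errstate(divide="ignore", invalid="ignore"):
                d = p * self.data ** (p - 1.0)
            return g * np.where(np.isfinite(d), d, 0.0)

        return self._make(out, [(self, grad)])

    # ---- nonlinearities --------------------------------------------------

    def relu(self):
        mask = self.data > 0
        return self._make(self.data * mask, [(self, lambda g: g * mask)])

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        return self._make(s, [(self, lambda g: g * s * (1.0 - s))])

    def exp(self):
        e = np.exp(self.data)
        return self._make(e, [(self, lambda g: g * e)])

    def log(self):
        return self._make(np.log(self.data), [(self, lambda g: g / self.data)])

    def clip_min(self, lo: float):
        """max(x, lo); gradient passes only through unclamped entries."""
        mask = self.data > lo
        return self._make(np.maximum(self.data, lo), [(self, lambda g: g * mask)])

    # ---- shape / reduction ----------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def grad(g):
            if axis is None:
                return np.broadcast_to(g, self.shape).copy()
            gg = g if keepdims else np.expand_dims(g, axis)
            return np.broadcast_to(gg, self.shape).copy()

        return self._make(out, [(self, grad)])

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        return self._make(self.data.reshape(shape), [(self, lambda g: g.reshape(old))])

    @property
    def T(self):
        return self._make(self.data.T, [(self, lambda g: g.T)])

    # ---- autodiff driver -------------------------------------------------

    def backward(self, seed: np.ndarray | None = None):
        if seed is None:
            if self.data.size != 1:
                raise ValueError("backward() without a seed requires a scalar output")
            seed = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p, _ in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(seed, dtype=np.float64)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if not t._parents:  # leaf
                t.grad = g if t.grad is None else t.grad + g
                continue
            for p, fn in t._parents:
                contrib = fn(g)
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + contrib
                else:
                    grads[id(p)] = contrib

    def item(self) -> float:
        return float(self.data)


# ---- structural primitives ----------------------------------------------


def _scatter_add(values: np.ndarray, idx: np.ndarray, n_rows: int) -> np.ndarray:
    """Row-wise scatter-add via bincount (much faster than np.add.at)."""
    inner = int(np.prod(values.shape[1:], dtype=np.intp)) if values.ndim > 1 else 1
    if inner == 1:
        flat = np.bincount(idx, weights=values.reshape(-1), minlength=n_rows)
        return flat.reshape((n_rows,) + values.shape[1:])
    comp = idx[:, None] * inner + np.arange(inner, dtype=np.intp)
    flat = np.bincount(comp.reshape(-1), weights=values.reshape(-1), minlength=n_rows * inner)
    return flat.reshape((n_rows,) + values.shape[1:])


def gather(t: Tensor, idx: np.ndarray) -> Tensor:
    """Select rows of `t` along axis 0 (duplicates allowed)."""
    idx = np.asarray(idx, dtype=np.intp)
    return Tensor(
        t.data[idx], parents=[(t, lambda g: _scatter_add(g, idx, t.data.shape[0]))]
    )


def segment_sum(t: Tensor, idx: np.ndarray, n_segments: int) -> Tensor:
    """Scatter-add rows of `t` into `n_segments` buckets along axis 0."""
    idx = np.asarray(idx, dtype=np.intp)
    return Tensor(_scatter_add(t.data, idx, n_segments), parents=[(t, lambda g: g[idx])])


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = list(tensors)
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def make_grad(i):
        sl = [slice(None)] * data.ndim
        sl[axis] = slice(offsets[i], offsets[i + 1])
        sl = tuple(sl)
        return lambda g: g[sl]

    return Tensor(data, parents=[(t, make_grad(i)) for i, t in enumerate(tensors)])


def segment_softmax(scores: Tensor, idx: np.ndarray, n_segments: int) -> Tensor:
    """Column-wise softmax of `scores` (E, h) within segments of axis 0.

    Rows sharing a segment id compete in the softmax, independently per
    column (attention head).  Numerically stabilised by subtracting the
    per-segment maximum (a constant w.r.t. the gradient).
    """
    idx = np.asarray(idx, dtype=np.intp)
    # per-segment, per-column max: a global shift would underflow whole
    # segments to 0/0 once the score spread exceeds ~log(float64 max)
    m = np.full((n_segments,) + scores.data.shape[1:], -np.inf)
    np.maximum.at(m, idx, scores.data)
    z = (scores - Tensor(m[idx])).exp()
    denom = segment_sum(z, idx, n_segments)
    return z / gather(denom, idx)


class Adam:
    """Standard Adam optimizer over a list of leaf Tensors."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = [p for p in params if p.requires_grad]
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad ** 2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
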
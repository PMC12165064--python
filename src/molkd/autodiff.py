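"""Minimal vectorized reverse-mode automatic differentiation.

Supports exactly the operations the reference encoder and the distillation
losses need: broadcasted arithmetic, matmul, sparse-dense products (for
neighbor gather/scatter and pooling), shifted softplus, reductions, and the
elementwise functions entering MAE/MSE/Huber losses and cosine similarity.
Gradients flow to parameters only; molecular geometry enters as constants.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

__all__ = [
    "Tensor",
    "constant",
    "parameter",
    "spmm",
    "ScatterPlan",
    "gather_rows",
    "segment_sum",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An ndarray node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray, own: bool = False) -> None:
        # `own=True` promises g is a freshly allocated array no one else holds
        if self.grad is None:
            self.grad = g if own else np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g * other.data, self.shape), own=True)
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(g * self.data, other.shape), own=True)

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad or other._parents:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accumulate(g @ other.data.T, own=True)
            if other.requires_grad or other._parents:
                other._accumulate(self.data.T @ g, own=True)

        out._backward = bw
        return out

    # -- elementwise -------------------------------------------------------
    def square(self):
        return self * self

    def sqrt(self):
        root = np.sqrt(self.data)
        out = Tensor(root, parents=(self,))
        out._backward = lambda g: self._accumulate(g * 0.5 / root)
        return out

    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, parents=(self,))
        out._backward = lambda g: self._accumulate(g * e)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def abs(self):
        sign = np.sign(self.data)
        out = Tensor(np.abs(self.data), parents=(self,))
        out._backward = lambda g: self._accumulate(g * sign)
        return out

    def ssp(self):
        """Shifted softplus: log(1 + e^x) - log 2."""
        x = self.data
        e = np.exp(-np.abs(x))          # stable; reused for the derivative
        fwd = np.maximum(x, 0.0) + np.log1p(e) - np.log(2.0)
        out = Tensor(fwd, parents=(self,))

        def bw(g):
            t = e / (1.0 + e)           # sigmoid(-|x|)
            sig = np.where(x >= 0, 1.0 - t, t)
            self._accumulate(g * sig, own=True)

        out._backward = bw
        return out

    # -- reductions & indexing ---------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def take_rows(self, idx: np.ndarray):
        """Row gather; backward scatter-adds into the source rows."""
        out = Tensor(self.data[idx], parents=(self,))

        def bw(g):
            acc = np.zeros_like(self.data)
            np.add.at(acc, idx, g)
            self._accumulate(acc)

        out._backward = bw
        return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def constant(x) -> Tensor:
    return Tensor(np.asarray(x, dtype=np.float64))


def parameter(x) -> Tensor:
    return Tensor(np.asarray(x, dtype=np.float64), requires_grad=True)


def spmm(mat: sparse.csr_matrix, x: Tensor) -> Tensor:
    """Sparse (constant) @ dense (tensor); used for gather/scatter/pooling."""
    out = Tensor(mat @ x.data, parents=(x,))
    mat_t = mat.T.tocsr()
    out._backward = lambda g: x._accumulate(mat_t @ g)
    return out


class ScatterPlan:
    """Precomputed scatter-add operator for a fixed index structure.

    Summing rows of a matrix into ``n_rows`` output rows grouped by ``idx``
    is a sparse one-hot matmul; building the CSR operator once and reusing
    it every training step is much faster than generic indexed accumulation.
    The forward *gather* along the same structure is plain fancy indexing.
    """

    def __init__(self, idx: np.ndarray, n_rows: int):
        self.idx = np.asarray(idx, dtype=np.int64)
        self.n_rows = n_rows
        n = len(self.idx)
        self._mat = sparse.csr_matrix(
            (np.ones(n), (self.idx, np.arange(n))), shape=(n_rows, n)
        )

    def apply(self, values: np.ndarray) -> np.ndarray:
        return self._mat @ values


def gather_rows(x: Tensor, idx: np.ndarray, plan: ScatterPlan) -> Tensor:
    """Row gather ``x[idx]``; backward scatter-adds along the same plan."""
    out = Tensor(x.data[idx], parents=(x,))
    out._backward = lambda g: x._accumulate(plan.apply(g), own=True)
    return out


def segment_sum(x: Tensor, plan: ScatterPlan) -> Tensor:
    """Sum rows of ``x`` into groups given by the plan's index vector."""
    out = Tensor(plan.apply(x.data), parents=(x,))
    out._backward = lambda g: x._accumulate(g[plan.idx], own=True)
    return out


class Adam:
    """Adaptive-moment optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad**2
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
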
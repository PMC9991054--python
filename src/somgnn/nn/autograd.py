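"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just the operations the SOM models need: dense and sparse matrix products,
scatter-style neighbor aggregation, elementwise arithmetic, ReLU, the
logistic function, row gathering/concatenation and binary cross-entropy.
Gradients are accumulated by a topological backward sweep.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            stack = [(t, iter(t._parents))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen and p.requires_grad:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operations --------------------------------------------------------

    def __add__(self, other: "Tensor") -> "Tensor":
        other = _as_tensor(other)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor(self.data + other.data, parents=(self, other), backward=bwd)

    def __mul__(self, other: "Tensor") -> "Tensor":
        other = _as_tensor(other)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(self.data * other.data, parents=(self, other), backward=bwd)

    def __matmul__(self, other: "Tensor") -> "Tensor":
        other = _as_tensor(other)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        return Tensor(self.data @ other.data, parents=(self, other), backward=bwd)

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor(self.data * mask, parents=(self,), backward=bwd)

    def sigmoid(self) -> "Tensor":
        out = _stable_sigmoid(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * out * (1.0 - out))

        return Tensor(out, parents=(self,), backward=bwd)

    def mean(self) -> "Tensor":
        n = self.data.size

        def bwd(g):
            if self.requires_grad:
                self._accumulate(np.full_like(self.data, float(g) / n))

        return Tensor(self.data.mean(), parents=(self,), backward=bwd)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Sum gradient over axes that numpy broadcasting expanded."""
    g = np.asarray(g)
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


def _stable_sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def scale_by_scalar(x: Tensor, s: Tensor) -> Tensor:
    """Multiply an (n, d) tensor by a learnable scalar tensor."""

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * float(s.data))
        if s.requires_grad:
            s._accumulate(np.array((g * x.data).sum()))

    return Tensor(x.data * float(s.data), parents=(x, s), backward=bwd)


def sparse_mm(A: sp.spmatrix, x: Tensor) -> Tensor:
    """Constant sparse matrix times variable dense matrix."""
    A = A.tocsr()

    def bwd(g):
        if x.requires_grad:
            x._accumulate(A.T @ g)

    return Tensor(A @ x.data, parents=(x,), backward=bwd)


def neighbor_sum(x: Tensor, src: np.ndarray, dst: np.ndarray) -> Tensor:
    """out[i] = sum over edges e with dst[e] == i of x[src[e]].

    ``src``/``dst`` form the directed expansion of an undirected edge list,
    so this realizes the neighbor-sum aggregation of message passing.
    """
    out = np.zeros_like(x.data)
    if len(src):
        np.add.at(out, dst, x.data[src])

    def bwd(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            if len(src):
                np.add.at(gx, src, g[dst])
            x._accumulate(gx)

    return Tensor(out, parents=(x,), backward=bwd)


def gather_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    def bwd(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            np.add.at(gx, idx, g)
            x._accumulate(gx)

    return Tensor(x.data[idx], parents=(x,), backward=bwd)


def mask_rows(x: Tensor, mask: np.ndarray) -> Tensor:
    """Multiply rows by a constant 0/1 column mask of shape (n, 1)."""
    mask = np.asarray(mask, dtype=np.float64).reshape(-1, 1)

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return Tensor(x.data * mask, parents=(x,), backward=bwd)


def concat_cols(a: Tensor, b: Tensor) -> Tensor:
    wa = a.data.shape[1]

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g[:, :wa])
        if b.requires_grad:
            b._accumulate(g[:, wa:])

    return Tensor(np.concatenate([a.data, b.data], axis=1), parents=(a, b), backward=bwd)


_EPS = 1e-7


def bce_loss(probs: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on probabilities (clipped away from 0/1)."""
    y = np.asarray(targets, dtype=np.float64).reshape(probs.data.shape)
    p = np.clip(probs.data, _EPS, 1.0 - _EPS)
    val = -(y * np.log(p) + (1.0 - y) * np.log1p(-p)).mean()
    n = p.size

    def bwd(g):
        if probs.requires_grad:
            inside = (probs.data > _EPS) & (probs.data < 1.0 - _EPS)
            probs._accumulate(float(g) / n * (p - y) / (p * (1.0 - p)) * inside)

    return Tensor(val, parents=(probs,), backward=bwd)


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
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
        for k, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
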
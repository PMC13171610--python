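"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for the dense graph encoder: broadcastable
arithmetic, matmul, ReLU/LeakyReLU, row-wise softmax, concatenation, row
gathering, dropout-by-mask and a numerically stable binary cross-entropy
on logits.  Gradients are accumulated by a topological backward sweep.
"""
from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "bce_with_logits", "gather_rows"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None, name: str = ""):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    # --- graph plumbing -------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: "Tensor") -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = np.zeros_like(t.data)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if self.requires_grad:
            if self.grad is None:
                self.grad = np.zeros_like(self.data)
            self.grad += _unbroadcast(grad, self.data.shape)

    # --- ops ------------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))
        out._backward = lambda g: (self._accum(g), other._accum(g))
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))
        out._backward = lambda g: (self._accum(g * other.data), other._accum(g * self.data))
        return out

    __rmul__ = __mul__

    def __truediv__(self, scalar: float):
        return self * (1.0 / scalar)

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data, parents=(self, other))
        out._backward = lambda g: (
            self._accum(g @ other.data.T),
            other._accum(self.data.T @ g),
        )
        return out

    __matmul__ = matmul

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))
        out._backward = lambda g: self._accum(g * mask)
        return out

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        factor = np.where(self.data > 0, 1.0, slope)
        out = Tensor(self.data * factor, parents=(self,))
        out._backward = lambda g: self._accum(g * factor)
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        out = Tensor(s, parents=(self,))
        out._backward = lambda g: self._accum(g * s * (1.0 - s))
        return out

    def sum(self) -> "Tensor":
        out = Tensor(self.data.sum(), parents=(self,))
        out._backward = lambda g: self._accum(np.broadcast_to(g, self.data.shape))
        return out

    def mean(self) -> "Tensor":
        return self.sum() / self.data.size

    def softmax_rows(self, mask: np.ndarray | None = None) -> "Tensor":
        """Row-wise softmax; entries where ``mask`` is False are excluded.

        A row with no unmasked entries comes out all-zero (no neighbors:
        nothing to attend to).
        """
        x = self.data
        if mask is not None:
            x = np.where(mask, x, -np.inf)
        xmax = np.max(x, axis=1, keepdims=True)
        xmax = np.where(np.isfinite(xmax), xmax, 0.0)
        e = np.exp(x - xmax)
        denom = e.sum(axis=1, keepdims=True)
        s = np.divide(e, denom, out=np.zeros_like(e), where=denom > 0)
        out = Tensor(s, parents=(self,))

        def back(g: np.ndarray) -> None:
            dot = (g * s).sum(axis=1, keepdims=True)
            self._accum(s * (g - dot))

        out._backward = back
        return out

    @property
    def T(self) -> "Tensor":
        out = Tensor(self.data.T, parents=(self,))
        out._backward = lambda g: self._accum(g.T)
        return out

    def rownormalize(self, eps: float = 1e-12) -> "Tensor":
        """L2-normalize each row."""
        n = np.sqrt((self.data * self.data).sum(axis=1, keepdims=True)) + eps
        y = self.data / n
        out = Tensor(y, parents=(self,))

        def back(g: np.ndarray) -> None:
            dot = (g * y).sum(axis=1, keepdims=True)
            self._accum((g - y * dot) / n)

        out._backward = back
        return out

    def reshape_col(self) -> "Tensor":
        """View as a column vector (n, 1)."""
        out = Tensor(self.data.reshape(-1, 1), parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def rowsum(self) -> "Tensor":
        """Sum over axis 1, returning a 1-D tensor."""
        out = Tensor(self.data.sum(axis=1), parents=(self,))
        out._backward = lambda g: self._accum(np.repeat(g[:, None], self.data.shape[1], axis=1))
        return out

    def dropout(self, rate: float, rng: np.random.Generator, training: bool) -> "Tensor":
        """Inverted dropout; identity when not training or rate == 0."""
        if not training or rate <= 0.0:
            return self
        keep = (rng.random(self.data.shape) >= rate) / (1.0 - rate)
        out = Tensor(self.data * keep, parents=(self,))
        out._backward = lambda g: self._accum(g * keep)
        return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def back(g: np.ndarray) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    out._backward = back
    return out


def gather_rows(t: Tensor, idx: np.ndarray) -> Tensor:
    idx = np.asarray(idx, dtype=int)
    out = Tensor(t.data[idx], parents=(t,))

    def back(g: np.ndarray) -> None:
        full = np.zeros_like(t.data)
        np.add.at(full, idx, g)
        t._accum(full)

    out._backward = back
    return out


def bce_with_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean binary cross-entropy, computed in the stable logits form.

    loss_i = max(x, 0) - x*y + log(1 + exp(-|x|))
    """
    y = np.asarray(labels, dtype=float)
    if y.size == 0:
        raise ValueError("bce_with_logits requires at least one pair")
    if logits.data.shape != y.shape:
        raise ValueError("logits and labels length mismatch")
    x = logits.data
    per = np.maximum(x, 0) - x * y + np.log1p(np.exp(-np.abs(x)))
    out = Tensor(per.mean(), parents=(logits,))
    sig = 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))
    out._backward = lambda g: logits._accum(g * (sig - y) / y.size)
    return out
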
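"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The pair classifier is small (a few dense layers plus attention over two
tokens), so rather than depending on a full deep-learning framework the
package carries its own scalar-loss reverse-mode engine.  A :class:`Tensor`
wraps an ``ndarray`` and records the operations applied to it; calling
:meth:`Tensor.backward` on a scalar result accumulates gradients into every
leaf.  All forward formulas used by the network live in this module twice
over: once as the Tensor op and once as the plain-NumPy branch of the
dispatch helpers, so inference code can run on raw arrays with zero graph
overhead while training reuses the identical arithmetic.

Gradient correctness is established by finite-difference checks in the test
suite, not assumed.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = [
    "Tensor",
    "relu",
    "sigmoid",
    "softmax_last",
    "swap_last",
    "concat_last",
    "stack_tokens",
    "flatten_tokens",
    "layer_norm",
    "bce_with_logits",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "_parents", "_backward")

    # make ndarray binary ops defer to our reflected operators
    __array_ufunc__ = None

    def __init__(self, data, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape})"

    # -- graph construction helpers ------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor | np.ndarray":
        """Non-Tensor operands are treated as constants (no gradient)."""
        return other

    def __add__(self, other):
        if isinstance(other, Tensor):
            out = Tensor(self.data + other.data, (self, other))

            def backward(g):
                return (_unbroadcast(g, self.data.shape),
                        _unbroadcast(g, other.data.shape))
        else:
            const = np.asarray(other, dtype=np.float64)
            out = Tensor(self.data + const, (self,))

            def backward(g):
                return (_unbroadcast(g, self.data.shape),)

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-other if isinstance(other, Tensor) else -np.asarray(other))

    def __rsub__(self, other):
        return (-self) + other

    def __mul__(self, other):
        if isinstance(other, Tensor):
            out = Tensor(self.data * other.data, (self, other))

            def backward(g):
                return (_unbroadcast(g * other.data, self.data.shape),
                        _unbroadcast(g * self.data, other.data.shape))
        else:
            const = np.asarray(other, dtype=np.float64)
            out = Tensor(self.data * const, (self,))

            def backward(g):
                return (_unbroadcast(g * const, self.data.shape),)

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise NotImplementedError("division by a Tensor is not supported")
        return self * (1.0 / np.asarray(other, dtype=np.float64))

    def __matmul__(self, other):
        other_data = other.data if isinstance(other, Tensor) else np.asarray(other)
        out_data = self.data @ other_data
        if isinstance(other, Tensor):
            out = Tensor(out_data, (self, other))

            def backward(g):
                ga = g @ np.swapaxes(other_data, -1, -2)
                if other_data.ndim == 2 and g.ndim > 2:
                    # batched input x 2-D weight: fold batch axes into one
                    # GEMM instead of materializing per-sample outer products
                    m, p = self.data.shape[-1], g.shape[-1]
                    gb = self.data.reshape(-1, m).T @ g.reshape(-1, p)
                else:
                    gb = _unbroadcast(np.swapaxes(self.data, -1, -2) @ g,
                                      other_data.shape)
                return (_unbroadcast(ga, self.data.shape), gb)
        else:
            out = Tensor(out_data, (self,))

            def backward(g):
                ga = g @ np.swapaxes(other_data, -1, -2)
                return (_unbroadcast(ga, self.data.shape),)

        out._backward = backward
        return out

    def __rmatmul__(self, other):
        const = np.asarray(other)
        out = Tensor(const @ self.data, (self,))

        def backward(g):
            gb = np.swapaxes(const, -1, -2) @ g
            return (_unbroadcast(gb, self.data.shape),)

        out._backward = backward
        return out

    def reshape(self, *shape):
        orig = self.data.shape
        out = Tensor(self.data.reshape(*shape), (self,))
        out._backward = lambda g: (g.reshape(orig),)
        return out

    def sum(self):
        out = Tensor(self.data.sum(), (self,))
        out._backward = lambda g: (np.broadcast_to(g, self.data.shape).copy(),)
        return out

    def mean(self):
        n = self.data.size
        out = Tensor(self.data.mean(), (self,))
        out._backward = lambda g: (np.broadcast_to(g / n, self.data.shape).copy(),)
        return out

    # -- backpropagation ------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
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
            if node._backward is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._backward(node.grad)):
                if parent.grad is None:
                    parent.grad = g.copy()
                else:
                    parent.grad += g

    def zero_grad(self):
        self.grad = None


# -- dispatch helpers: work on Tensor or plain ndarray ------------------

def _is_tensor(x) -> bool:
    return isinstance(x, Tensor)


def relu(x):
    """max(x, 0), thresholding negative values at zero."""
    if _is_tensor(x):
        mask = x.data > 0
        out = Tensor(np.where(mask, x.data, 0.0), (x,))
        out._backward = lambda g: (g * mask,)
        return out
    return np.maximum(x, 0.0)


def sigmoid(x):
    if _is_tensor(x):
        y = expit(x.data)
        out = Tensor(y, (x,))
        out._backward = lambda g: (g * y * (1.0 - y),)
        return out
    return expit(x)


def softmax_last(x):
    """Row-wise softmax over the last axis (numerically shifted)."""

    def _fwd(a):
        shifted = a - a.max(axis=-1, keepdims=True)
        e = np.exp(shifted)
        return e / e.sum(axis=-1, keepdims=True)

    if _is_tensor(x):
        y = _fwd(x.data)
        out = Tensor(y, (x,))

        def backward(g):
            dot = (g * y).sum(axis=-1, keepdims=True)
            return (y * (g - dot),)

        out._backward = backward
        return out
    return _fwd(x)


def swap_last(x):
    """Transpose the last two axes."""
    if _is_tensor(x):
        out = Tensor(np.swapaxes(x.data, -1, -2), (x,))
        out._backward = lambda g: (np.swapaxes(g, -1, -2),)
        return out
    return np.swapaxes(x, -1, -2)


def concat_last(parts):
    """Concatenate along the last axis."""
    if any(_is_tensor(p) for p in parts):
        tensors = [p if _is_tensor(p) else Tensor(p) for p in parts]
        widths = [t.data.shape[-1] for t in tensors]
        out = Tensor(np.concatenate([t.data for t in tensors], axis=-1), tensors)

        def backward(g):
            grads, start = [], 0
            for w in widths:
                grads.append(g[..., start:start + w])
                start += w
            return tuple(grads)

        out._backward = backward
        return out
    return np.concatenate(parts, axis=-1)


def stack_tokens(f1, f2):
    """Stack two feature vectors (or batches of them) as a 2-token axis."""
    if _is_tensor(f1) or _is_tensor(f2):
        t1 = f1 if _is_tensor(f1) else Tensor(f1)
        t2 = f2 if _is_tensor(f2) else Tensor(f2)
        out = Tensor(np.stack([t1.data, t2.data], axis=-2), (t1, t2))
        out._backward = lambda g: (g[..., 0, :], g[..., 1, :])
        return out
    return np.stack([f1, f2], axis=-2)


def flatten_tokens(x):
    """Merge the trailing (tokens, features) axes into one vector axis."""
    if _is_tensor(x):
        t, d = x.data.shape[-2], x.data.shape[-1]
        return x.reshape(*x.data.shape[:-2], t * d)
    return x.reshape(*x.shape[:-2], x.shape[-2] * x.shape[-1])


def layer_norm(x, eps: float = 1e-5):
    """Normalize the last axis to zero mean and unit variance."""

    def _stats(a):
        mu = a.mean(axis=-1, keepdims=True)
        xc = a - mu
        inv = 1.0 / np.sqrt((xc * xc).mean(axis=-1, keepdims=True) + eps)
        return xc, inv

    if _is_tensor(x):
        xc, inv = _stats(x.data)
        y = xc * inv
        out = Tensor(y, (x,))

        def backward(g):
            n = x.data.shape[-1]
            g_mean = g.mean(axis=-1, keepdims=True)
            gy_mean = (g * y).mean(axis=-1, keepdims=True)
            return (inv * (g - g_mean - y * gy_mean),)

        out._backward = backward
        return out
    xc, inv = _stats(np.asarray(x))
    return xc * inv


def bce_with_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean binary cross-entropy computed from logits (stable fused op)."""
    labels = np.asarray(labels, dtype=np.float64)
    z = logits.data
    loss = np.mean(np.logaddexp(0.0, z) - labels * z)
    out = Tensor(loss, (logits,))
    out._backward = lambda g: (g * (expit(z) - labels) / z.size,)
    return out
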
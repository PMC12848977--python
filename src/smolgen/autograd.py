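"""Minimal reverse-mode automatic differentiation over NumPy arrays.

A deliberately small tape-based engine — just the operations the decoder-only
transformer, its cross-entropy pretraining and the PPO objective need:
broadcasted arithmetic, batched matmul, gather, softmax/log-softmax, layer
normalization, GELU, clipping and reductions.  Gradients accumulate into
``Tensor.grad`` after ``backward()`` on a scalar loss.

Float32 throughout; determinism follows from NumPy's (no threading-dependent
reductions are used beyond BLAS matmul, which is reproducible on a fixed
platform).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum out broadcasted axes so grad matches the original operand shape."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers ------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        grad = grad.astype(np.float32, copy=False)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- arithmetic ----------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)

        def backward(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))
        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)
        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))
        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def backward(g):
            self._accum(_unbroadcast(g / other.data, self.data.shape))
            other._accum(_unbroadcast(-g * self.data / other.data ** 2,
                                      other.data.shape))
        return self._make(self.data / other.data, (self, other), backward)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        a, b = self.data, other.data

        def backward(g):
            ga = np.matmul(g, np.swapaxes(b, -1, -2))
            gb = np.matmul(np.swapaxes(a, -1, -2), g)
            self._accum(_unbroadcast(ga, a.shape))
            other._accum(_unbroadcast(gb, b.shape))
        return self._make(np.matmul(a, b), (self, other), backward)

    __matmul__ = matmul

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)
        return self._make(out_data, (self,), backward)

    def square(self) -> "Tensor":
        def backward(g):
            self._accum(2.0 * g * self.data)
        return self._make(self.data ** 2, (self,), backward)

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clamp values; gradient passes only through unclamped entries."""
        mask = ((self.data >= lo) & (self.data <= hi)).astype(np.float32)

        def backward(g):
            self._accum(g * mask)
        return self._make(np.clip(self.data, lo, hi), (self,), backward)

    def minimum(self, other: "Tensor") -> "Tensor":
        """Elementwise min; at ties the gradient goes to the left operand."""
        other = self._lift(other)
        take_left = (self.data <= other.data).astype(np.float32)

        def backward(g):
            self._accum(_unbroadcast(g * take_left, self.data.shape))
            other._accum(_unbroadcast(g * (1.0 - take_left), other.data.shape))
        return self._make(np.minimum(self.data, other.data), (self, other), backward)

    # -- shaping -------------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        old = self.data.shape

        def backward(g):
            self._accum(g.reshape(old))
        return self._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes) -> "Tensor":
        inv = np.argsort(axes)

        def backward(g):
            self._accum(g.transpose(*inv))
        return self._make(self.data.transpose(*axes), (self,), backward)

    def gather_rows(self, ids: np.ndarray) -> "Tensor":
        """Index rows of a 2-D table by an integer array (embedding lookup)."""
        ids = np.asarray(ids)

        def backward(g):
            acc = np.zeros_like(self.data)
            np.add.at(acc, ids.reshape(-1), g.reshape(-1, g.shape[-1]))
            self._accum(acc)
        return self._make(self.data[ids], (self,), backward)

    def take_last(self, ids: np.ndarray) -> "Tensor":
        """Gather along the last axis (per-position class selection)."""
        ids = np.asarray(ids)[..., None]

        def backward(g):
            acc = np.zeros_like(self.data)
            np.put_along_axis(acc, ids, g[..., None], axis=-1)
            self._accum(acc)
        return self._make(
            np.take_along_axis(self.data, ids, axis=-1)[..., 0], (self,), backward)

    # -- reductions ----------------------------------------------------------

    def sum(self, axis=None, keepdims=False) -> "Tensor":
        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())
        return self._make(self.data.sum(axis=axis, keepdims=keepdims),
                          (self,), backward)

    def mean(self, axis=None, keepdims=False) -> "Tensor":
        count = (self.data.size if axis is None
                 else self.data.shape[axis])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # -- neural-network primitives -------------------------------------------

    def gelu(self) -> "Tensor":
        """Gaussian Error Linear Unit, tanh approximation (GPT-2 convention)."""
        c = np.float32(np.sqrt(2.0 / np.pi))
        k = np.float32(0.044715)
        x = self.data
        x2 = x * x
        t = np.tanh(c * (x + k * x2 * x))

        def backward(g):
            dinner = c * (1.0 + np.float32(3) * k * x2)
            grad = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t * t) * dinner
            self._accum(g * grad)
        return self._make(0.5 * x * (1.0 + t), (self,), backward)

    def layer_norm(self, gain: "Tensor", bias: "Tensor",
                   eps: float = 1e-5) -> "Tensor":
        x = self.data
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x - mu) * inv

        def backward(g):
            gain._accum(_unbroadcast(g * xhat, gain.data.shape))
            bias._accum(_unbroadcast(g, bias.data.shape))
            gx = g * gain.data
            dx = inv * (gx - gx.mean(axis=-1, keepdims=True)
                        - xhat * (gx * xhat).mean(axis=-1, keepdims=True))
            self._accum(dx)
        return self._make(xhat * gain.data + bias.data,
                          (self, gain, bias), backward)

    def softmax(self, mask: np.ndarray | None = None) -> "Tensor":
        """Softmax over the last axis with an optional additive constant mask."""
        z = self.data if mask is None else self.data + mask
        z = z - np.max(z, axis=-1, keepdims=True)
        p = np.exp(z)
        p /= p.sum(axis=-1, keepdims=True)

        def backward(g):
            self._accum(p * (g - (g * p).sum(axis=-1, keepdims=True)))
        return self._make(p, (self,), backward)

    def log_softmax(self, mask: np.ndarray | None = None) -> "Tensor":
        """Log-softmax over the last axis with an optional additive mask.

        ``mask`` entries of ``-inf`` remove classes exactly (zero probability,
        zero gradient); the mask itself is a constant.
        """
        z = self.data if mask is None else self.data + mask
        zmax = np.max(z, axis=-1, keepdims=True)
        shifted = z - zmax
        logsumexp = np.log(np.sum(np.exp(shifted), axis=-1, keepdims=True))
        logp = shifted - logsumexp
        p = np.exp(logp)

        def backward(g):
            self._accum(g - p * g.sum(axis=-1, keepdims=True))
        return self._make(logp, (self,), backward)

    # -- autodiff driver -----------------------------------------------------

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar")
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
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def item(self) -> float:
        return float(self.data)


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Adam:
    """Adam optimizer with optional global-norm gradient clipping."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0,
                 grad_clip: float | None = 1.0):
        self.params = params
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.grad_clip = grad_clip
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data)
                 for p in self.params]
        if self.grad_clip is not None:
            total = np.sqrt(sum(float((g.astype(np.float64) ** 2).sum())
                                for g in grads))
            if total > self.grad_clip:
                scale = np.float32(self.grad_clip / (total + 1e-12))
                grads = [g * scale for g in grads]
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g ** 2
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
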
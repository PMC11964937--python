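"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ndarray and records the operations applied to
it; calling :meth:`Tensor.backward` on a scalar loss propagates gradients
to every parameter.  Broadcasting is handled by summing gradients over
broadcast axes.  The operation set is exactly what the gradient-trained
sequence models in :mod:`osmlab.nets` need (matmul, elementwise
arithmetic and nonlinearities, softmax cross-entropy, layer norm,
reductions, concatenation, slicing); it is deliberately small and has a
finite-difference test guarding it.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """Array node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")
    __array_priority__ = 100  # numpy defers binary ops to Tensor

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={'set' if self.grad is not None else 'none'})"

    # -------------------------------------------------------------- #
    # graph plumbing

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t: Tensor):
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

    # -------------------------------------------------------------- #
    # arithmetic

    def __add__(self, other):
        o = self._lift(other)

        def bwd(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g, self.data.shape)
            if o.requires_grad:
                o.grad += _unbroadcast(g, o.data.shape)
        return self._make(self.data + o.data, (self, o), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            if self.requires_grad:
                self.grad += -g
        return self._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        o = self._lift(other)

        def bwd(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g * o.data, self.data.shape)
            if o.requires_grad:
                o.grad += _unbroadcast(g * self.data, o.data.shape)
        return self._make(self.data * o.data, (self, o), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = self._lift(other)

        def bwd(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g / o.data, self.data.shape)
            if o.requires_grad:
                o.grad += _unbroadcast(-g * self.data / o.data ** 2, o.data.shape)
        return self._make(self.data / o.data, (self, o), bwd)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, k: float):
        def bwd(g):
            if self.requires_grad:
                self.grad += g * k * self.data ** (k - 1)
        return self._make(self.data ** k, (self,), bwd)

    def __matmul__(self, other):
        o = self._lift(other)

        def bwd(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g @ np.swapaxes(o.data, -1, -2),
                                          self.data.shape)
            if o.requires_grad:
                o.grad += _unbroadcast(np.swapaxes(self.data, -1, -2) @ g,
                                       o.data.shape)
        return self._make(self.data @ o.data, (self, o), bwd)

    def __getitem__(self, idx):
        def bwd(g):
            if self.requires_grad:
                np.add.at(self.grad, idx, g)
        return self._make(self.data[idx], (self,), bwd)

    # -------------------------------------------------------------- #
    # nonlinearities and reductions

    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            if self.requires_grad:
                self.grad += g * out_data
        return self._make(out_data, (self,), bwd)

    def log(self):
        def bwd(g):
            if self.requires_grad:
                self.grad += g / self.data
        return self._make(np.log(self.data), (self,), bwd)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bwd(g):
            if self.requires_grad:
                self.grad += g * (1 - out_data ** 2)
        return self._make(out_data, (self,), bwd)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            if self.requires_grad:
                self.grad += g * out_data * (1 - out_data)
        return self._make(out_data, (self,), bwd)

    def relu(self):
        mask = self.data > 0

        def bwd(g):
            if self.requires_grad:
                self.grad += g * mask
        return self._make(self.data * mask, (self,), bwd)

    def abs(self):
        sign = np.sign(self.data)

        def bwd(g):
            if self.requires_grad:
                self.grad += g * sign
        return self._make(np.abs(self.data), (self,), bwd)

    def sum(self, axis=None, keepdims=False):
        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self.grad += g
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self.grad += np.broadcast_to(gg, self.data.shape)
        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def bwd(g):
            if self.requires_grad:
                dot = (g * out_data).sum(axis=axis, keepdims=True)
                self.grad += out_data * (g - dot)
        return self._make(out_data, (self,), bwd)

    def transpose(self, *axes):
        axes = axes or None

        def bwd(g):
            if self.requires_grad:
                inv = np.argsort(axes) if axes else None
                self.grad += g.transpose(inv) if inv is not None else g.T
        return self._make(self.data.transpose(axes) if axes else self.data.T,
                          (self,), bwd)

    def reshape(self, *shape):
        old = self.data.shape

        def bwd(g):
            if self.requires_grad:
                self.grad += g.reshape(old)
        return self._make(self.data.reshape(*shape), (self,), bwd)


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    data = np.stack([t.data for t in tensors], axis=axis)
    out = Tensor(data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)

        def bwd(g):
            for i, t in enumerate(tensors):
                if t.requires_grad:
                    t.grad += np.take(g, i, axis=axis)
        out._backward = bwd
    return out


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        sizes = [t.data.shape[axis] for t in tensors]
        offs = np.cumsum([0] + sizes)

        def bwd(g):
            for i, t in enumerate(tensors):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(offs[i], offs[i + 1])
                    t.grad += g[tuple(sl)]
        out._backward = bwd
    return out


def cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy; ``targets`` are integer class ids with
    shape equal to the logits shape minus its last axis."""
    targets = np.asarray(targets)
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    logp = z - lse
    flat = logp.reshape(-1, logp.shape[-1])
    picked = flat[np.arange(flat.shape[0]), targets.ravel()]
    loss_val = -picked.mean()
    out = Tensor(loss_val)
    if logits.requires_grad:
        out.requires_grad = True
        out._parents = (logits,)
        probs = np.exp(logp)

        def bwd(g):
            grad = probs.copy().reshape(-1, probs.shape[-1])
            grad[np.arange(grad.shape[0]), targets.ravel()] -= 1.0
            logits.grad += g * grad.reshape(logits.data.shape) / flat.shape[0]
        out._backward = bwd
    return out


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalise the last axis to zero mean / unit variance, then scale
    and shift (built from primitive ops, so gradients come for free)."""
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc / (var + eps) ** 0.5 * gain + bias


def gelu(x: Tensor) -> Tensor:
    """Gaussian error linear unit (tanh approximation)."""
    c = float(np.sqrt(2.0 / np.pi))
    return 0.5 * x * (1.0 + (c * (x + 0.044715 * x * x * x)).tanh())


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
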
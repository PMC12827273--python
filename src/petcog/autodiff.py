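"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for a feature-attention + transformer-encoder
regressor: broadcast-aware add/mul, batched matmul, ReLU, softmax,
layer normalization, dropout, reductions and Huber loss.  Gradients are
accumulated by topological traversal of the recorded tape.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Tensor:
    """A node in the computation graph wrapping a numpy array."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    @property
    def shape(self):
        return self.data.shape

    def backward(self):
        order, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            order.append(t)

        visit(self)
        for t in order:
            # reuse persistent buffers (parameters keep theirs across steps)
            if t.grad is not None and t.grad.shape == t.data.shape:
                t.grad.fill(0)
            else:
                t.grad = np.zeros_like(t.data)
        self.grad = np.ones_like(self.data)
        for t in reversed(order):
            if t._backward is not None:
                t._backward(t.grad)

    # -- operators --------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __matmul__(self, other):
        return matmul(self, other)


def _unbroadcast(grad, shape):
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


def _wrap(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def add(a, b):
    a, b = _wrap(a), _wrap(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a.grad += _unbroadcast(g, a.data.shape)
        if b.requires_grad:
            b.grad += _unbroadcast(g, b.data.shape)

    return Tensor(out_data, parents=(a, b), backward=backward)


def mul(a, b):
    a, b = _wrap(a), _wrap(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a.grad += _unbroadcast(g * b.data, a.data.shape)
        if b.requires_grad:
            b.grad += _unbroadcast(g * a.data, b.data.shape)

    return Tensor(out_data, parents=(a, b), backward=backward)


def scale(a, k: float):
    a = _wrap(a)

    def backward(g):
        if a.requires_grad:
            a.grad += g * k

    return Tensor(a.data * k, parents=(a,), backward=backward)


def matmul(a, b):
    """Batched matrix product (numpy matmul semantics)."""
    a, b = _wrap(a), _wrap(b)
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a.grad += _unbroadcast(ga, a.data.shape)
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b.grad += _unbroadcast(gb, b.data.shape)

    return Tensor(out_data, parents=(a, b), backward=backward)


def relu(a):
    a = _wrap(a)
    mask = a.data > 0

    def backward(g):
        if a.requires_grad:
            a.grad += g * mask

    return Tensor(a.data * mask, parents=(a,), backward=backward)


def softmax(a, axis=-1):
    a = _wrap(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if a.requires_grad:
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            a.grad += out_data * (g - dot)

    return Tensor(out_data, parents=(a,), backward=backward)


def layer_norm(x, gain, bias, eps: float = 1e-5):
    """Normalization over the last axis with learnable gain and bias."""
    x, gain, bias = _wrap(x), _wrap(gain), _wrap(bias)
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out_data = gain.data * xhat + bias.data

    def backward(g):
        if gain.requires_grad:
            gain.grad += _unbroadcast(g * xhat, gain.data.shape)
        if bias.requires_grad:
            bias.grad += _unbroadcast(g, bias.data.shape)
        if x.requires_grad:
            gx = g * gain.data
            term1 = gx
            term2 = gx.mean(axis=-1, keepdims=True)
            term3 = xhat * (gx * xhat).mean(axis=-1, keepdims=True)
            x.grad += inv * (term1 - term2 - term3)

    return Tensor(out_data, parents=(x, gain, bias), backward=backward)


def dropout(a, p: float, rng: np.random.Generator, training: bool):
    if not training or p <= 0.0:
        return _wrap(a)
    a = _wrap(a)
    mask = (rng.random(a.data.shape) >= p).astype(DTYPE) / DTYPE(1.0 - p)

    def backward(g):
        if a.requires_grad:
            a.grad += g * mask

    return Tensor(a.data * mask, parents=(a,), backward=backward)


def reshape(a, shape):
    a = _wrap(a)
    old = a.data.shape

    def backward(g):
        if a.requires_grad:
            a.grad += g.reshape(old)

    return Tensor(a.data.reshape(shape), parents=(a,), backward=backward)


def transpose(a, axes):
    a = _wrap(a)
    inv = np.argsort(axes)

    def backward(g):
        if a.requires_grad:
            a.grad += g.transpose(inv)

    return Tensor(a.data.transpose(axes), parents=(a,), backward=backward)


def huber_loss(pred, target, delta: float = 1.0):
    """Mean Huber (SmoothL1) loss between predictions and a constant target."""
    pred = _wrap(pred)
    target = np.asarray(target, dtype=DTYPE)
    diff = pred.data - target
    absd = np.abs(diff)
    quad = absd <= delta
    elems = np.where(quad, 0.5 * diff * diff, delta * (absd - 0.5 * delta))
    n = diff.size

    def backward(g):
        if pred.requires_grad:
            grad_elem = np.where(quad, diff, delta * np.sign(diff))
            pred.grad += g * grad_elem / n

    return Tensor(elems.mean(), parents=(pred,), backward=backward)


class AdamW:
    """AdamW with decoupled weight decay and global-norm gradient clipping."""

    def __init__(self, params, lr=5e-5, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=1e-8, clip_norm=1.0):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay, self.clip_norm = weight_decay, clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        if self.clip_norm is not None:
            total = np.sqrt(
                sum(float(np.dot(p.grad.ravel(), p.grad.ravel())) for p in self.params)
            )
            if total > self.clip_norm:
                factor = DTYPE(self.clip_norm / (total + 1e-12))
                for p in self.params:
                    p.grad *= factor
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for i, p in enumerate(self.params):
            g = p.grad
            m, v = self.m[i], self.v[i]
            m *= b1
            m += DTYPE(1 - b1) * g
            np.multiply(g, g, out=g)  # grads are re-zeroed next backward
            v *= b2
            v += DTYPE(1 - b2) * g
            denom = np.sqrt(v)
            denom *= DTYPE(1.0 / np.sqrt(bc2))
            denom += DTYPE(self.eps)
            np.divide(m, denom, out=denom)
            denom *= DTYPE(self.lr / bc1)
            if self.weight_decay:
                denom += DTYPE(self.lr * self.weight_decay) * p.data
            p.data -= denom
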
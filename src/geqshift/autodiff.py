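"""Minimal vectorized reverse-mode automatic differentiation.

A :class:`Tensor` wraps a ``numpy`` array and records the operations applied
to it; ``backward()`` propagates gradients through the recorded graph in
reverse topological order.  The op set is exactly what the equivariant
network and its training loop need: broadcast arithmetic, matmul, a general
two-or-three-operand einsum, segment scatter/gather (for message passing),
and a handful of pointwise nonlinearities.  Everything is float64.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "parameter", "constant", "concatenate", "einsum",
           "gather", "segment_sum", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # keep numpy from hijacking reflected ops

    def __init__(self, data, requires_grad: bool = False,
                 parents=(), backward=None):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # -- construction helpers ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autograd ------------------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a "
                                 "scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep
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
        self.grad = np.asarray(grad, dtype=float)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray, own: bool = False) -> None:
        g = _unbroadcast(np.asarray(grad, dtype=float), self.data.shape)
        if g is not grad:
            own = True  # unbroadcast allocated a fresh array
        if self.grad is None:
            self.grad = g if own and g.flags.writeable and g.base is None \
                else g.copy()
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))
        def back(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)
        out._backward = back
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accum(-g, own=True)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))
        def back(g):
            if self.requires_grad:
                self._accum(g * other.data, own=True)
            if other.requires_grad:
                other._accum(g * self.data, own=True)
        out._backward = back
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))
        def back(g):
            if self.requires_grad:
                self._accum(g / other.data, own=True)
            if other.requires_grad:
                other._accum(-g * self.data / other.data ** 2, own=True)
        out._backward = back
        return out

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))
        def back(g):
            if self.requires_grad:
                self._accum(g @ other.data.swapaxes(-1, -2), own=True)
            if other.requires_grad:
                other._accum(self.data.swapaxes(-1, -2) @ g, own=True)
        out._backward = back
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, parents=(self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1), own=True)
        return out

    # -- pointwise -----------------------------------------------------------
    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, parents=(self,))
        out._backward = lambda g: self._accum(g * val, own=True)
        return out

    def sqrt(self):
        val = np.sqrt(self.data)
        out = Tensor(val, parents=(self,))
        out._backward = lambda g: self._accum(g * 0.5 / val, own=True)
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), parents=(self,))
        out._backward = lambda g: self._accum(g * np.sign(self.data), own=True)
        return out

    def sigmoid(self):
        val = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(val, parents=(self,))
        out._backward = lambda g: self._accum(g * val * (1.0 - val), own=True)
        return out

    def silu(self):
        sig = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(self.data * sig, parents=(self,))
        out._backward = lambda g: self._accum(
            g * sig * (1.0 + self.data * (1.0 - sig)), own=True)
        return out

    # -- reductions / shaping ------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     parents=(self,))
        def back(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape))
        out._backward = back
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], parents=(self,))
        basic = isinstance(key, slice) or (
            isinstance(key, tuple)
            and all(isinstance(k, (slice, int)) for k in key))
        def back(g):
            if self.grad is None:
                self.grad = np.zeros_like(self.data)
            if basic:
                self.grad[key] += g
            else:
                np.add.at(self.grad, key, g)
        out._backward = back
        return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(shape_or_data, rng: np.random.Generator | None = None,
              scale: float = 1.0) -> Tensor:
    """A trainable leaf tensor; with ``rng`` given, sampled ~N(0, scale^2)."""
    if rng is not None:
        data = rng.normal(0.0, scale, size=shape_or_data)
    else:
        data = shape_or_data
    return Tensor(data, requires_grad=True)


def constant(data) -> Tensor:
    return Tensor(data)


def concatenate(tensors, axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    def back(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)
    out._backward = back
    return out


def einsum(spec: str, *operands) -> Tensor:
    """Einstein summation with gradients for Tensor operands.

    Restricted to specs without repeated indices inside one operand and with
    an explicit ``->`` output; that covers every contraction in the network.
    """
    operands = [_as_tensor(t) for t in operands]
    inputs, out_sub = spec.replace(" ", "").split("->")
    subs = inputs.split(",")
    if len(subs) != len(operands):
        raise ValueError("einsum spec/operand mismatch")
    out = Tensor(np.einsum(spec, *[t.data for t in operands], optimize=True),
                 parents=tuple(operands))
    def back(g):
        for k, t in enumerate(operands):
            if not t.requires_grad:
                continue
            others = [operands[j].data for j in range(len(operands)) if j != k]
            other_subs = [subs[j] for j in range(len(operands)) if j != k]
            grad_spec = ",".join([out_sub] + other_subs) + "->" + subs[k]
            # indices of t summed out everywhere need broadcasting back
            known = set(out_sub) | set("".join(other_subs))
            lost = [i for i, c in enumerate(subs[k]) if c not in known]
            if lost:
                reduced_sub = "".join(c for c in subs[k] if c in known)
                grad_spec = ",".join([out_sub] + other_subs) + "->" + reduced_sub
                gk = np.einsum(grad_spec, g, *others, optimize=True)
                gk = np.expand_dims(gk, tuple(lost))
                t._accum(np.broadcast_to(gk, t.data.shape))
            else:
                t._accum(np.einsum(grad_spec, g, *others, optimize=True), own=True)
    out._backward = back
    return out


def gather(t: Tensor, index: np.ndarray) -> Tensor:
    """Row gather along axis 0 (``t[index]``) with scatter-add backward."""
    index = np.asarray(index, dtype=int)
    out = Tensor(t.data[index], parents=(t,))
    def back(g):
        if t.grad is None:
            t.grad = np.zeros_like(t.data)
        np.add.at(t.grad, index, g)
    out._backward = back
    return out


def segment_sum(t: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of ``t`` into ``num_segments`` buckets along axis 0."""
    segment_ids = np.asarray(segment_ids, dtype=int)
    shape = (num_segments,) + t.data.shape[1:]
    buf = np.zeros(shape, dtype=float)
    np.add.at(buf, segment_ids, t.data)
    out = Tensor(buf, parents=(t,))
    out._backward = lambda g: t._accum(g[segment_ids], own=True)
    return out


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 3e-4,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
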
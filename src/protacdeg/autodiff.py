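"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Every differentiable quantity is wrapped in a :class:`Tensor` holding a
float64 ``ndarray``.  Operations build a DAG; :meth:`Tensor.backward`
runs a topological sweep accumulating gradients.  The op set is exactly
what the graph network needs: broadcast arithmetic, matmul, elementwise
nonlinearities, row gather/scatter, per-graph segment reductions, and a
numerically stable (segment) softmax.

All computation is float64 and single-threaded NumPy, so repeated runs
with identical inputs are bit-identical — a property the training
pipeline relies on.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "concat",
    "segment_sum",
    "segment_softmax",
    "log_softmax",
    "tanh",
    "silu",
]


def _as_array(value) -> np.ndarray:
    return np.asarray(value, dtype=np.float64)


class Tensor:
    """A node in the autodiff graph.

    Parameters with ``requires_grad=True`` accumulate gradients in
    ``.grad`` after :meth:`backward`.  Intermediate nodes are created by
    the ops below and carry closures computing vector-Jacobian products.
    """

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(self, value, requires_grad: bool = False, parents=(), vjp=None):
        self.value = _as_array(value)
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self.grad = None
        self._parents = parents
        self._vjp = vjp

    # -- graph mechanics ------------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.value.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.value)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if id(node) in seen:
                continue
            if expanded:
                seen.add(id(node))
                topo.append(node)
            else:
                stack.append((node, True))
                for p in node._parents:
                    if id(p) not in seen and p.requires_grad:
                        stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): _as_array(grad)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._vjp is not None:
                for parent, pg in zip(node._parents, node._vjp(g)):
                    if not parent.requires_grad or pg is None:
                        continue
                    if id(parent) in grads:
                        grads[id(parent)] = grads[id(parent)] + pg
                    else:
                        grads[id(parent)] = pg
            else:
                if node.grad is None:
                    node.grad = np.zeros_like(node.value)
                node.grad = node.grad + g

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = _wrap(other)
        a, b = self, other

        def vjp(g):
            return _unbroadcast(g, a.shape), _unbroadcast(g, b.shape)

        return Tensor(a.value + b.value, parents=(a, b), vjp=vjp)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor(-a.value, parents=(a,), vjp=lambda g: (-g,))

    def __sub__(self, other):
        return self + (-_wrap(other))

    def __rsub__(self, other):
        return _wrap(other) + (-self)

    def __mul__(self, other):
        other = _wrap(other)
        a, b = self, other

        def vjp(g):
            return _unbroadcast(g * b.value, a.shape), _unbroadcast(g * a.value, b.shape)

        return Tensor(a.value * b.value, parents=(a, b), vjp=vjp)

    __rmul__ = __mul__

    def __pow__(self, p: float):
        a = self
        out = a.value ** p

        def vjp(g):
            return (g * p * a.value ** (p - 1.0),)

        return Tensor(out, parents=(a,), vjp=vjp)

    def __matmul__(self, other):
        other = _wrap(other)
        a, b = self, other
        a_vec, b_vec = a.value.ndim == 1, b.value.ndim == 1

        def vjp(g):
            g2 = g[:, None] if b_vec else (g[None, :] if a_vec else g)
            av = a.value[None, :] if a_vec else a.value
            bv = b.value[:, None] if b_vec else b.value
            ga = g2 @ bv.T if a.requires_grad else None
            gb = av.T @ g2 if b.requires_grad else None
            if ga is not None and a_vec:
                ga = ga[0]
            if gb is not None and b_vec:
                gb = gb[:, 0]
            return ga, gb

        return Tensor(a.value @ b.value, parents=(a, b), vjp=vjp)

    # -- reductions and reshaping --------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def vjp(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, a.shape).copy(),)

        return Tensor(a.value.sum(axis=axis, keepdims=keepdims), parents=(a,), vjp=vjp)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        a = self
        return Tensor(a.value.reshape(*shape), parents=(a,), vjp=lambda g: (g.reshape(a.shape),))

    def take(self, indices):
        """Row gather: ``out[i] = self[indices[i]]``."""
        a = self
        idx = np.asarray(indices)

        def vjp(g):
            out = np.zeros_like(a.value)
            np.add.at(out, idx, g)
            return (out,)

        return Tensor(a.value[idx], parents=(a,), vjp=vjp)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def tensor(value, requires_grad: bool = False) -> Tensor:
    return Tensor(value, requires_grad=requires_grad)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` to undo NumPy broadcasting."""
    grad = np.asarray(grad)
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


# -- elementwise nonlinearities ----------------------------------------

def tanh(a: Tensor) -> Tensor:
    a = _wrap(a)
    out = np.tanh(a.value)
    return Tensor(out, parents=(a,), vjp=lambda g: (g * (1.0 - out ** 2),))


def silu(a: Tensor) -> Tensor:
    """SiLU / swish: x * sigmoid(x)."""
    a = _wrap(a)
    sig = 1.0 / (1.0 + np.exp(-a.value))
    out = a.value * sig

    def vjp(g):
        return (g * (sig * (1.0 + a.value * (1.0 - sig))),)

    return Tensor(out, parents=(a,), vjp=vjp)


def exp(a: Tensor) -> Tensor:
    a = _wrap(a)
    out = np.exp(a.value)
    return Tensor(out, parents=(a,), vjp=lambda g: (g * out,))


# -- structural ops -----------------------------------------------------

def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    sizes = [t.value.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def vjp(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(np.concatenate([t.value for t in tensors], axis=axis),
                  parents=tuple(tensors), vjp=vjp)


def segment_sum(a: Tensor, segment_ids, num_segments: int) -> Tensor:
    """Sum rows of ``a`` into ``num_segments`` buckets: scatter-add."""
    a = _wrap(a)
    seg = np.asarray(segment_ids)
    out = np.zeros((num_segments,) + a.value.shape[1:], dtype=np.float64)
    np.add.at(out, seg, a.value)
    return Tensor(out, parents=(a,), vjp=lambda g: (g[seg],))


def segment_softmax(logits: Tensor, segment_ids, num_segments: int) -> Tensor:
    """Softmax of a 1-D logit vector within each segment (per-graph)."""
    a = _wrap(logits)
    seg = np.asarray(segment_ids)
    high = np.full(num_segments, -np.inf)
    np.maximum.at(high, seg, a.value)
    shifted = a.value - high[seg]
    e = np.exp(shifted)
    denom = np.zeros(num_segments)
    np.add.at(denom, seg, e)
    w = e / denom[seg]

    def vjp(g):
        wg = w * g
        s = np.zeros(num_segments)
        np.add.at(s, seg, wg)
        return (wg - w * s[seg],)

    return Tensor(w, parents=(a,), vjp=vjp)


def log_softmax(a: Tensor, axis: int = -1) -> Tensor:
    a = _wrap(a)
    shifted = a.value - a.value.max(axis=axis, keepdims=True)
    out = shifted - np.log(np.exp(shifted).sum(axis=axis, keepdims=True))

    def vjp(g):
        return (g - np.exp(out) * g.sum(axis=axis, keepdims=True),)

    return Tensor(out, parents=(a,), vjp=vjp)
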
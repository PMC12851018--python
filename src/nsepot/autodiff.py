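"""Minimal tape-based reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the potential needs: elementwise arithmetic
with broadcasting, a few smooth nonlinearities, dense matmul, reductions,
fancy-index gather and its transpose (segment sum), reshape and
concatenation.  The backward pass is itself composed of these operations,
so gradients are differentiable: forces (-dE/dR) can appear inside a
training loss and be differentiated again with respect to the parameters.

Everything is float64; there is no graph optimisation and no in-place
mutation of node values.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "tensor", "concat", "segment_sum", "gather", "grad"]


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_vjp")

    # make ndarray <op> Tensor defer to the reflected Tensor methods
    __array_ufunc__ = None
    __array_priority__ = 1000

    def __init__(self, value, requires_grad: bool = False, parents=(), vjp=None):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = None  # Tensor after backward()
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._vjp = vjp  # callable(grad: Tensor) -> tuple[Tensor | None, ...]

    # ---- graph traversal -------------------------------------------------
    def _toposort(self):
        topo, seen, stack = [], set(), [(self, False)]
        while stack:
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
        return topo  # parents before children; reverse for backprop

    def _compute_grads(self, seed) -> dict:
        grads = {id(self): tensor(seed if seed is not None else np.ones_like(self.value))}
        for node in reversed(self._toposort()):
            g = grads.get(id(node))
            if g is None or node._vjp is None:
                continue
            for parent, pg in zip(node._parents, node._vjp(g)):
                if pg is None or not parent.requires_grad:
                    continue
                acc = grads.get(id(parent))
                grads[id(parent)] = pg if acc is None else acc + pg
        return grads

    def backward(self, seed=None) -> None:
        """Populate `.grad` (a Tensor) on every reachable requires_grad node."""
        grads = self._compute_grads(seed)
        for node in self._toposort():
            if id(node) in grads:
                node.grad = grads[id(node)]

    def zero_grad(self) -> None:
        self.grad = None

    # ---- properties ------------------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    def item(self) -> float:
        return float(self.value)

    def __repr__(self):
        return f"Tensor(shape={self.value.shape}, requires_grad={self.requires_grad})"

    # ---- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = tensor(other)
        a_shape, b_shape = self.value.shape, other.value.shape

        def vjp(g):
            return (_unbroadcast(g, a_shape), _unbroadcast(g, b_shape))

        return Tensor(self.value + other.value, parents=(self, other), vjp=vjp)

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.value, parents=(self,), vjp=lambda g: (-g,))

    def __sub__(self, other):
        return self + (-tensor(other))

    def __rsub__(self, other):
        return tensor(other) + (-self)

    def __mul__(self, other):
        other = tensor(other)
        a_shape, b_shape = self.value.shape, other.value.shape

        def vjp(g):
            return (_unbroadcast(g * other, a_shape), _unbroadcast(g * self, b_shape))

        return Tensor(self.value * other.value, parents=(self, other), vjp=vjp)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = tensor(other)
        a_shape, b_shape = self.value.shape, other.value.shape

        def vjp(g):
            return (
                _unbroadcast(g / other, a_shape),
                _unbroadcast(-g * self / (other * other), b_shape),
            )

        return Tensor(self.value / other.value, parents=(self, other), vjp=vjp)

    def __rtruediv__(self, other):
        return tensor(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.value ** exponent, parents=(self,))
        out._vjp = lambda g: (g * (self ** (exponent - 1.0)) * exponent,)
        return out

    def __matmul__(self, other):
        other = tensor(other)

        def vjp(g):
            return (g @ other.T, self.T @ g)

        return Tensor(self.value @ other.value, parents=(self, other), vjp=vjp)

    @property
    def T(self):
        return Tensor(self.value.T, parents=(self,), vjp=lambda g: (g.T,))

    # ---- elementwise functions -------------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.value), parents=(self,))
        out._vjp = lambda g: (g * out,)
        return out

    def sqrt(self):
        out = Tensor(np.sqrt(self.value), parents=(self,))
        out._vjp = lambda g: (g * 0.5 / out,)
        return out

    def sin(self):
        return Tensor(np.sin(self.value), parents=(self,), vjp=lambda g: (g * self.cos(),))

    def cos(self):
        return Tensor(np.cos(self.value), parents=(self,), vjp=lambda g: (-g * self.sin(),))

    def tanh(self):
        out = Tensor(np.tanh(self.value), parents=(self,))
        out._vjp = lambda g: (g * (1.0 - out * out),)
        return out

    def sigmoid(self):
        out = Tensor(1.0 / (1.0 + np.exp(-np.clip(self.value, -500, 500))), parents=(self,))
        out._vjp = lambda g: (g * out * (1.0 - out),)
        return out

    def softplus(self):
        out = Tensor(np.logaddexp(0.0, self.value), parents=(self,))
        out._vjp = lambda g: (g * self.sigmoid(),)
        return out

    # ---- reductions & shaping --------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a_shape = self.value.shape

        def vjp(g):
            if axis is None:
                return (g.reshape(*([1] * len(a_shape))).broadcast_to(a_shape),)
            if not keepdims:
                kd_shape = list(a_shape)
                kd_shape[axis] = 1
                g = g.reshape(*kd_shape)
            return (g.broadcast_to(a_shape),)

        return Tensor(self.value.sum(axis=axis, keepdims=keepdims), parents=(self,), vjp=vjp)

    def mean(self, axis=None):
        n = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis) * (1.0 / n)

    def broadcast_to(self, shape):
        a_shape = self.value.shape
        return Tensor(
            np.broadcast_to(self.value, shape).copy(),
            parents=(self,),
            vjp=lambda g: (_unbroadcast(g, a_shape),),
        )

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a_shape = self.value.shape
        return Tensor(
            self.value.reshape(shape),
            parents=(self,),
            vjp=lambda g: (g.reshape(a_shape),),
        )

    def __getitem__(self, idx):
        a_shape = self.value.shape
        return Tensor(
            self.value[idx],
            parents=(self,),
            vjp=lambda g: (scatter_add(g, idx, a_shape),),
        )


def _unbroadcast(g: Tensor, shape: tuple) -> Tensor:
    """Sum Tensor `g` down to `shape`, inverting numpy broadcasting."""
    if g.value.shape == shape:
        return g
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.value.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


def tensor(x) -> Tensor:
    """Wrap `x` as a constant Tensor (no-op on Tensor input)."""
    return x if isinstance(x, Tensor) else Tensor(x)


def scatter_add(g: Tensor, idx, shape) -> Tensor:
    """Zeros of `shape` with `g` scatter-added at `idx` (adjoint of getitem)."""
    g = tensor(g)
    full = np.zeros(shape, dtype=np.float64)
    np.add.at(full, idx, g.value)
    return Tensor(full, parents=(g,), vjp=lambda gg: (gg[idx],))


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [tensor(t) for t in tensors]
    vals = [t.value for t in tensors]
    out = np.concatenate(vals, axis=axis)
    ax = axis % out.ndim
    sizes = [v.shape[ax] for v in vals]
    offsets = np.concatenate([[0], np.cumsum(sizes)])

    def vjp(g):
        pieces = []
        for k in range(len(vals)):
            sl = tuple(
                slice(offsets[k], offsets[k + 1]) if d == ax else slice(None)
                for d in range(out.ndim)
            )
            pieces.append(g[sl])
        return tuple(pieces)

    return Tensor(out, parents=tuple(tensors), vjp=vjp)


def segment_sum(t: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of `t` into `num_segments` buckets given by `segment_ids`."""
    t = tensor(t)
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    out = np.zeros((num_segments,) + t.value.shape[1:], dtype=np.float64)
    np.add.at(out, segment_ids, t.value)
    return Tensor(out, parents=(t,), vjp=lambda g: (g[segment_ids],))


def gather(t: Tensor, index: np.ndarray) -> Tensor:
    """Row gather t[index] with scatter-add backward."""
    return tensor(t)[np.asarray(index, dtype=np.intp)]


def grad(output: Tensor, inputs, seed=None):
    """Gradients of `output` w.r.t. `inputs` without touching `.grad` slots.

    Returns Tensors connected to the graph, so the result can be
    differentiated again (used for force-matching losses).  Inputs that the
    output does not depend on get a zero gradient.
    """
    single = isinstance(inputs, Tensor)
    inputs = [inputs] if single else list(inputs)
    grads = output._compute_grads(seed)
    out = [grads.get(id(x)) or Tensor(np.zeros_like(x.value)) for x in inputs]
    return out[0] if single else out
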
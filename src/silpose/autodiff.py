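"""Compact reverse-mode automatic differentiation on numpy arrays.

This is the package's differentiation engine: it backs the soft silhouette
rasterizer, the heatmap network, and the custom-gradient PnP layer.  It is a
define-by-run tape: every operation on a :class:`Tensor` records its parents
and a backward closure; :meth:`Tensor.backward` walks the tape in reverse
topological order accumulating gradients.

Only the operations the package needs are implemented (elementwise
arithmetic, matmul, conv2d via im2col, reductions, clipping, indexing,
sigmoid/exp/log, softmax helpers, nearest-neighbour upsampling).  All arrays
are float64 — the gradient checks in the test-suite rely on full double
precision.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "tensor", "concatenate", "stack", "minimum", "maximum", "where"]


def _as_array(x) -> np.ndarray:
    if isinstance(x, Tensor):
        raise TypeError("expected raw array, got Tensor")
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an attached gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100.0  # so ndarray.__mul__ defers to Tensor.__rmul__

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autograd ------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        else:
            grad = np.asarray(grad, dtype=np.float64).reshape(self.data.shape)

        # topological order over the tape
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        while stack:
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            unvisited = [p for p in node._parents
                         if p.requires_grad and id(p) not in seen]
            if unvisited:
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
                stack.pop()

        grads: dict[int, np.ndarray] = {id(self): grad}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.grad is None:
                node.grad = g.copy()
            else:
                node.grad = node.grad + g
            if node._backward is None:
                continue
            parent_grads = node._backward(g)
            for p, pg in zip(node._parents, parent_grads):
                if pg is None or not p.requires_grad:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg

    # -- elementwise arithmetic ----------------------------------------------
    def __add__(self, other):
        other = tensor(other)
        out = Tensor._make(self.data + other.data, (self, other),
                           lambda g: (_unbroadcast(g, self.shape),
                                      _unbroadcast(g, other.shape)))
        return out

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-tensor(other))

    def __rsub__(self, other):
        return tensor(other) + (-self)

    def __mul__(self, other):
        other = tensor(other)
        return Tensor._make(self.data * other.data, (self, other),
                            lambda g: (_unbroadcast(g * other.data, self.shape),
                                       _unbroadcast(g * self.data, other.shape)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = tensor(other)
        return Tensor._make(
            self.data / other.data, (self, other),
            lambda g: (_unbroadcast(g / other.data, self.shape),
                       _unbroadcast(-g * self.data / other.data ** 2, other.shape)))

    def __rtruediv__(self, other):
        return tensor(other) / self

    def __pow__(self, p: float):
        p = float(p)
        return Tensor._make(self.data ** p, (self,),
                            lambda g: (g * p * self.data ** (p - 1.0),))

    def __matmul__(self, other):
        other = tensor(other)

        def back(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return _unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape)

        return Tensor._make(self.data @ other.data, (self, other), back)

    # -- unary ---------------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return Tensor._make(np.log(self.data), (self,),
                            lambda g: (g / self.data,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return Tensor._make(out_data, (self,),
                            lambda g: (g * 0.5 / out_data,))

    def sigmoid(self):
        x = self.data
        e = np.exp(-np.abs(x))  # overflow-safe
        s = np.where(x >= 0, 1.0 / (1.0 + e), e / (1.0 + e))
        return Tensor._make(s, (self,), lambda g: (g * s * (1.0 - s),))

    def tanh(self):
        t = np.tanh(self.data)
        return Tensor._make(t, (self,), lambda g: (g * (1.0 - t * t),))

    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), lambda g: (g * mask,))

    def clip(self, lo: float, hi: float):
        mask = (self.data >= lo) & (self.data <= hi)
        return Tensor._make(np.clip(self.data, lo, hi), (self,),
                            lambda g: (g * mask,))

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def back(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)

        return Tensor._make(out_data, (self,), back)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis=None, keepdims=False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)

        def back(g):
            full = self.data.max(axis=axis, keepdims=True)
            mask = (self.data == full)
            mask = mask / mask.sum(axis=axis, keepdims=True)
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            return (mask * gg,)

        return Tensor._make(out_data, (self,), back)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        return Tensor._make(self.data.reshape(shape), (self,),
                            lambda g: (g.reshape(old),))

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        elif len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor._make(self.data.transpose(axes), (self,),
                            lambda g: (g.transpose(inv),))

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def back(g):
            gg = np.zeros(self.shape, dtype=np.float64)
            np.add.at(gg, idx, g)
            return (gg,)

        return Tensor._make(out_data, (self,), back)

    # -- composite helpers ---------------------------------------------------
    def softmax(self, axis=-1):
        shift = self.data.max(axis=axis, keepdims=True)  # constant shift
        e = (self - shift).exp()
        return e / e.sum(axis=axis, keepdims=True)

    def upsample_nearest(self, factor: int):
        """Nearest-neighbour upsampling of the last two axes by `factor`."""
        f = int(factor)
        rep = np.repeat(np.repeat(self.data, f, axis=-2), f, axis=-1)

        def back(g):
            *lead, h, w = g.shape
            g4 = g.reshape(*lead, h // f, f, w // f, f)
            return (g4.sum(axis=(-3, -1)),)

        return Tensor._make(rep, (self,), back)


def tensor(x, requires_grad: bool = False) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(x, requires_grad=requires_grad)


def concatenate(tensors, axis=0) -> Tensor:
    tensors = [tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(data, tensors, back)


def stack(tensors, axis=0) -> Tensor:
    tensors = [tensor(t) for t in tensors]
    data = np.stack([t.data for t in tensors], axis=axis)

    def back(g):
        return tuple(np.moveaxis(g, axis, 0))

    return Tensor._make(data, tensors, back)


def minimum(a, b) -> Tensor:
    """Elementwise min with the subgradient routed to the smaller branch."""
    a, b = tensor(a), tensor(b)
    take_a = a.data <= b.data
    data = np.where(take_a, a.data, b.data)

    def back(g):
        return (_unbroadcast(g * take_a, a.shape),
                _unbroadcast(g * ~take_a, b.shape))

    return Tensor._make(data, (a, b), back)


def maximum(a, b) -> Tensor:
    a, b = tensor(a), tensor(b)
    take_a = a.data >= b.data
    data = np.where(take_a, a.data, b.data)

    def back(g):
        return (_unbroadcast(g * take_a, a.shape),
                _unbroadcast(g * ~take_a, b.shape))

    return Tensor._make(data, (a, b), back)


def where(cond, a, b) -> Tensor:
    """Select with a non-differentiable boolean condition."""
    cond = np.asarray(cond, dtype=bool)
    a, b = tensor(a), tensor(b)
    data = np.where(cond, a.data, b.data)

    def back(g):
        return (_unbroadcast(g * cond, a.shape),
                _unbroadcast(g * ~cond, b.shape))

    return Tensor._make(data, (a, b), back)


# ---------------------------------------------------------------------------
# convolution (im2col)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    s = x.strides
    view = np.lib.stride_tricks.as_strided(
        x, shape=(n, c, oh, ow, kh, kw),
        strides=(s[0], s[1], s[2] * stride, s[3] * stride, s[2], s[3]),
        writeable=False)
    # (n, oh, ow, c*kh*kw)
    return view.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh, ow, c * kh * kw), oh, ow


def _col2im(cols: np.ndarray, x_shape, kh, kw, stride, pad):
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    xg = np.zeros((n, c, hp, wp), dtype=np.float64)
    cols6 = cols.reshape(n, oh, ow, c, kh, kw)
    for ki in range(kh):
        for kj in range(kw):
            xg[:, :, ki:ki + stride * oh:stride, kj:kj + stride * ow:stride] += \
                cols6[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
    if pad:
        xg = xg[:, :, pad:-pad, pad:-pad]
    return xg


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, pad: int = 1) -> Tensor:
    """2D convolution, NCHW layout, weight (out_c, in_c, kh, kw)."""
    x, weight = tensor(x), tensor(weight)
    oc, ic, kh, kw = weight.shape
    cols, oh, ow = _im2col(x.data, kh, kw, stride, pad)
    wmat = weight.data.reshape(oc, ic * kh * kw)
    out_data = cols @ wmat.T  # (n, oh, ow, oc)
    out_data = out_data.transpose(0, 3, 1, 2)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, oc, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def back(g):
        # g: (n, oc, oh, ow)
        gmat = g.transpose(0, 2, 3, 1)  # (n, oh, ow, oc)
        gw = np.einsum("nhwo,nhwk->ok", gmat, cols).reshape(weight.shape)
        gcols = gmat @ wmat  # (n, oh, ow, ic*kh*kw)
        gx = _col2im(gcols, x.shape, kh, kw, stride, pad)
        if bias is None:
            return gx, gw
        gb = g.sum(axis=(0, 2, 3))
        return gx, gw, gb

    return Tensor._make(out_data, parents, back)
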
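"""Minimal reverse-mode automatic differentiation over numpy arrays.

The enhancement networks are small stride-1 convolutional models, so the
primitive set is deliberately tiny: broadcast arithmetic, a handful of
element-wise nonlinearities, reductions, shape surgery, 2-D convolution
(with dilation), 2x2 max pooling, and separable linear resampling
expressed as per-axis matrix products.  Gradients flow through a taped
graph; ``Tensor.backward`` releases the tape after traversal so training
loops do not accumulate memory.

Every primitive is gradient-checked against central finite differences
in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concatenate",
    "conv2d",
    "maxpool2x2",
    "pad2d",
    "scale_axis",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # Collapse leading axes that were added by broadcasting.
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray plus an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph plumbing -------------------------------------------------

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=self.data.dtype, copy=True)
        else:
            self.grad += grad

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
                # Release the tape so intermediate buffers can be freed.
                node._parents = ()
                node._backward = None

    # -- convenience ----------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic ------------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor._from_op(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise TypeError("division by a Tensor is not supported; multiply by a constant reciprocal")
        return self * (1.0 / other)

    # -- element-wise ----------------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data)

        return Tensor._from_op(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._from_op(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0
        out_data = np.where(mask, self.data, 0.0)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor._from_op(out_data, (self,), backward)

    def abs(self):
        sign = np.sign(self.data)
        out_data = np.abs(self.data)

        def backward(g):
            if self.requires_grad:
                # Subgradient 0 at exactly zero.
                self._accumulate(g * sign)

        return Tensor._from_op(out_data, (self,), backward)

    # -- reductions ------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))

        return Tensor._from_op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape surgery ---------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old))

        return Tensor._from_op(out_data, (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        return Tensor._from_op(out_data, (self,), backward)

    def __getitem__(self, key):
        out_data = self.data[key]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, key, g)
                self._accumulate(full)

        return Tensor._from_op(out_data, (self,), backward)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concatenate(tensors: list[Tensor], axis: int) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._from_op(out_data, tuple(tensors), backward)


def pad2d(x: Tensor, pad: tuple[int, int, int, int]) -> Tensor:
    """Zero-pad the two trailing axes of an (N, C, H, W) tensor.

    ``pad`` is (top, bottom, left, right).
    """
    top, bottom, left, right = pad
    out_data = np.pad(x.data, ((0, 0), (0, 0), (top, bottom), (left, right)))

    def backward(g):
        if x.requires_grad:
            h, w = x.data.shape[-2:]
            x._accumulate(g[..., top:top + h, left:left + w])

    return Tensor._from_op(out_data, (x,), backward)


# -- convolution ---------------------------------------------------------


# The 'valid' convolution below never gathers patches.  The padded input
# is viewed as a flat spatial vector; each kernel tap (di, dj) is a
# contiguous slice of that vector at offset dilation * (di * Wp + dj), so
# the whole convolution is kh*kw GEMMs on views plus one strided crop.
# This is exact: for a valid output column j, the tap column
# j + dilation * dj never exceeds Wp - 1, so flat indexing never wraps
# into the next row.


def _strided_rows(flat: np.ndarray, ho: int, wo: int, wp: int, writeable: bool = False):
    """(N, C, Ho, Wo) view into (N, C, L) flat spatial storage of row pitch wp."""
    sn, sc, sl = flat.strides
    return np.lib.stride_tricks.as_strided(
        flat, shape=flat.shape[:2] + (ho, wo), strides=(sn, sc, wp * sl, sl),
        writeable=writeable)


def _conv_valid(x: np.ndarray, w: np.ndarray, dilation: int) -> np.ndarray:
    """'valid' stride-1 cross-correlation of (N,C,Hp,Wp) with (O,C,kh,kw)."""
    n, c, hp, wp = x.shape
    o, _, kh, kw = w.shape
    ho = hp - dilation * (kh - 1)
    wo = wp - dilation * (kw - 1)
    flat = np.ascontiguousarray(x).reshape(n, c, hp * wp)
    span = (ho - 1) * wp + wo
    acc = None
    for di in range(kh):
        for dj in range(kw):
            off = dilation * (di * wp + dj)
            term = np.matmul(w[:, :, di, dj], flat[:, :, off:off + span])
            acc = term if acc is None else np.add(acc, term, out=acc)
    return np.ascontiguousarray(_strided_rows(acc, ho, wo, wp))


def _conv_weight_grad(xp: np.ndarray, g: np.ndarray, kh: int, kw: int,
                      dilation: int) -> np.ndarray:
    """Gradient w.r.t. an (O,C,kh,kw) kernel given padded input and output grad."""
    n, c, hp, wp = xp.shape
    _, o, ho, wo = g.shape
    span = (ho - 1) * wp + wo
    gf = np.zeros((n, o, span), dtype=g.dtype)
    _strided_rows(gf, ho, wo, wp, writeable=True)[...] = g
    flat = np.ascontiguousarray(xp).reshape(n, c, hp * wp)
    dw = np.empty((kh, kw, o, c), dtype=g.dtype)
    for di in range(kh):
        for dj in range(kw):
            off = dilation * (di * wp + dj)
            dw[di, dj] = np.matmul(
                gf, flat[:, :, off:off + span].transpose(0, 2, 1)).sum(axis=0)
    return dw.transpose(2, 3, 0, 1)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, dilation: int = 1) -> Tensor:
    """Same-size stride-1 2-D convolution (cross-correlation convention).

    ``x``: (N, C, H, W); ``w``: (O, C, kh, kw) with odd kh, kw; ``b``: (O,)
    or None.  Zero padding of ``dilation * (k - 1) / 2`` keeps the spatial
    size; dilation spaces the kernel taps.
    """
    o, c, kh, kw = w.data.shape
    ph = dilation * (kh - 1) // 2
    pw = dilation * (kw - 1) // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    y = _conv_valid(xp, w.data, dilation)
    if b is not None:
        y = y + b.data[None, :, None, None]

    def backward(g):
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            w._accumulate(_conv_weight_grad(xp, g, kh, kw, dilation))
        if x.requires_grad:
            # Gradient w.r.t. the input is the transposed convolution:
            # pad the output gradient and correlate with the spatially
            # flipped kernel, swapping the channel axes.
            pg = dilation * (kh - 1)
            gp = np.pad(g, ((0, 0), (0, 0), (pg, pg), (pg, pg)))
            wt = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
            dxp = _conv_valid(gp, np.ascontiguousarray(wt), dilation)
            h, wdt = x.data.shape[-2:]
            x._accumulate(dxp[..., pg - ph:pg - ph + h, pg - pw:pg - pw + wdt])

    return Tensor._from_op(y, tuple(t for t in (x, w, b) if t is not None), backward)


def maxpool2x2(x: Tensor) -> Tensor:
    """2x2, stride-2 max pooling; odd trailing rows/columns are dropped."""
    n, c, h, w = x.data.shape
    h2, w2 = h // 2, w // 2
    crop = x.data[:, :, :2 * h2, :2 * w2]
    blocks = crop.reshape(n, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
    idx = blocks.argmax(axis=-1)
    out_data = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        db = np.zeros((n, c, h2, w2, 4), dtype=g.dtype)
        np.put_along_axis(db, idx[..., None], g[..., None], axis=-1)
        dcrop = db.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, 2 * h2, 2 * w2)
        full = np.zeros_like(x.data)
        full[:, :, :2 * h2, :2 * w2] = dcrop
        x._accumulate(full)

    return Tensor._from_op(out_data, (x,), backward)


def scale_axis(x: Tensor, m: np.ndarray, axis: int) -> Tensor:
    """Apply a fixed linear map ``m`` (n_out, n_in) along one axis of ``x``.

    Used for bilinear resampling and adaptive average pooling, whose
    per-axis weights are data-independent.
    """
    out_data = np.moveaxis(np.tensordot(m, x.data, axes=([1], [axis])), 0, axis)

    def backward(g):
        if x.requires_grad:
            x._accumulate(np.moveaxis(np.tensordot(m.T, g, axes=([1], [axis])), 0, axis))

    return Tensor._from_op(out_data, (x,), backward)
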
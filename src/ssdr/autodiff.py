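"""A minimal reverse-mode automatic differentiation engine.

The reconstruction network needs only a handful of operations (3D
convolution, ReLU, 2x max pooling, 2x nearest upsampling, channel
concatenation, linear resampling, and the maximum-intensity projection
with its subgradient). This module implements exactly those as fused
ops with hand-written backward passes on numpy arrays, which keeps the
whole training loop dependency-free and deterministic.

Feature maps are arrays of shape ``(C, X, Y, Z)``; the projector acts on
single-channel volumes ``(X, Y, Z)``. Gradients of ``max`` are routed to
the *first* maximal sample along the ray, a deterministic subgradient.
"""

from __future__ import annotations

import functools

import numpy as np

from . import geometry

__all__ = ["Tensor", "no_grad", "Adam"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager that disables graph building (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _result(data, parents, backward):
        out = Tensor.__new__(Tensor)
        out.data = data
        out.grad = None
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        else:
            out.requires_grad = False
            out._parents = ()
            out._backward = None
        return out

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            stack = [(t, iter(t._parents))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen and p.requires_grad:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # release graph memory as we go
                node._backward = None
                node._parents = ()

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    @property
    def shape(self):
        return self.data.shape

    # -- elementwise -------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._result(out_data, (self, other), backward)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data - other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g, other.data.shape))

        return Tensor._result(out_data, (self, other), backward)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._result(out_data, (self, other), backward)

    __radd__ = __add__
    __rmul__ = __mul__

    def square(self):
        out_data = self.data * self.data
        src = self.data

        def backward(g):
            if self.requires_grad:
                self._accum(2.0 * src * g)

        return Tensor._result(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0
        out_data = np.where(mask, self.data, 0.0).astype(np.float32)

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._result(out_data, (self,), backward)

    def sum(self):
        out_data = np.asarray(self.data.sum(dtype=np.float64), dtype=np.float32)
        shape = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accum(np.broadcast_to(g, shape).astype(np.float32))

        return Tensor._result(out_data, (self,), backward)

    def mean(self):
        n = self.data.size
        out_data = np.asarray(self.data.mean(dtype=np.float64), dtype=np.float32)
        shape = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accum(np.broadcast_to(g / n, shape).astype(np.float32))

        return Tensor._result(out_data, (self,), backward)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        old = self.data.shape
        out_data = self.data.reshape(*shape)

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return Tensor._result(out_data, (self,), backward)

    def slice3d(self, sl: tuple[slice, ...]):
        """Slice the trailing spatial axes (keeps the channel axis)."""
        full = (slice(None),) * (self.data.ndim - len(sl)) + tuple(sl)
        out_data = np.ascontiguousarray(self.data[full])
        shape = self.data.shape

        def backward(g):
            if self.requires_grad:
                gx = np.zeros(shape, dtype=np.float32)
                gx[full] = g
                self._accum(gx)

        return Tensor._result(out_data, (self,), backward)

    def pad_spatial(self, pads: tuple[tuple[int, int], ...]):
        """Zero-pad the trailing spatial axes; channel axis untouched."""
        nlead = self.data.ndim - len(pads)
        padding = ((0, 0),) * nlead + tuple(pads)
        out_data = np.pad(self.data, padding)
        crop = tuple(
            slice(p0, p0 + s)
            for (p0, _), s in zip(padding, self.data.shape)
        )

        def backward(g):
            if self.requires_grad:
                self._accum(np.ascontiguousarray(g[crop]))

        return Tensor._result(out_data, (self,), backward)


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    g = np.asarray(g)
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# network ops
# ---------------------------------------------------------------------------

def minimum(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise minimum; on ties the gradient goes to ``a``."""
    mask = a.data <= b.data
    out_data = np.where(mask, a.data, b.data)

    def backward(g):
        if a.requires_grad:
            a._accum(g * mask)
        if b.requires_grad:
            b._accum(g * ~mask)

    return Tensor._result(out_data.astype(np.float32), (a, b), backward)


def concat(tensors: list[Tensor]) -> Tensor:
    """Concatenate along the channel (first) axis."""
    out_data = np.concatenate([t.data for t in tensors], axis=0)
    sizes = [t.data.shape[0] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                t._accum(np.ascontiguousarray(g[a:b]))

    return Tensor._result(out_data, tuple(tensors), backward)


def _im2col(xp: np.ndarray, k: int, spatial: tuple[int, int, int]) -> np.ndarray:
    """(C, X+k-1, Y+k-1, Z+k-1) -> (C*k^3, n_vox) patch matrix.

    Row order is (cin, di, dj, dk), matching ``w.reshape(cout, -1)``.
    """
    X, Y, Z = spatial
    c = xp.shape[0]
    n = X * Y * Z
    k3 = k * k * k
    cols = np.empty((c * k3, n), dtype=xp.dtype)
    for di in range(k):
        for dj in range(k):
            for dk in range(k):
                off = (di * k + dj) * k + dk
                patch = xp[:, di:di + X, dj:dj + Y, dk:dk + Z]
                cols[off::k3] = patch.reshape(c, n)
    return cols


def conv3d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padded 3D convolution (cross-correlation).

    ``x``: (Cin, X, Y, Z); ``w``: (Cout, Cin, k, k, k); ``b``: (Cout,).
    """
    cin, X, Y, Z = x.data.shape
    cout, cin_w, k, _, _ = w.data.shape
    if cin != cin_w:
        raise ValueError(f"conv3d channel mismatch: input {cin}, weight {cin_w}")
    p = k // 2
    k3 = k * k * k
    if p:
        xp = np.pad(x.data, ((0, 0), (p, p), (p, p), (p, p)))
        cols = _im2col(xp, k, (X, Y, Z))
    else:
        cols = x.data.reshape(cin, -1)
    wmat = w.data.reshape(cout, -1)
    out_data = (wmat @ cols).reshape(cout, X, Y, Z) \
        + b.data[:, None, None, None]

    def backward(g):
        g2 = g.reshape(cout, -1)
        if w.requires_grad:
            w._accum((g2 @ cols.T).reshape(w.data.shape))
        if b.requires_grad:
            b._accum(g2.sum(axis=1))
        if x.requires_grad:
            dcols = wmat.T @ g2
            if p:
                gxp = np.zeros(
                    (cin, X + 2 * p, Y + 2 * p, Z + 2 * p), dtype=np.float32)
                for di in range(k):
                    for dj in range(k):
                        for dk in range(k):
                            off = (di * k + dj) * k + dk
                            gxp[:, di:di + X, dj:dj + Y, dk:dk + Z] += (
                                dcols[off::k3].reshape(cin, X, Y, Z))
                x._accum(gxp[:, p:p + X, p:p + Y, p:p + Z])
            else:
                x._accum(dcols.reshape(cin, X, Y, Z))

    return Tensor._result(out_data.astype(np.float32), (x, w, b), backward)


def maxpool2(x: Tensor) -> Tensor:
    """2x2x2 max pooling; spatial dims must be even."""
    c, X, Y, Z = x.data.shape
    if X % 2 or Y % 2 or Z % 2:
        raise ValueError(f"maxpool2 needs even spatial dims, got {x.data.shape}")
    r = x.data.reshape(c, X // 2, 2, Y // 2, 2, Z // 2, 2)
    r = np.ascontiguousarray(r.transpose(0, 1, 3, 5, 2, 4, 6)).reshape(
        c, X // 2, Y // 2, Z // 2, 8
    )
    arg = r.argmax(axis=-1)
    out_data = np.take_along_axis(r, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        if x.requires_grad:
            gr = np.zeros((c, X // 2, Y // 2, Z // 2, 8), dtype=np.float32)
            np.put_along_axis(gr, arg[..., None], g[..., None], axis=-1)
            gr = gr.reshape(c, X // 2, Y // 2, Z // 2, 2, 2, 2)
            gr = gr.transpose(0, 1, 4, 2, 5, 3, 6).reshape(c, X, Y, Z)
            x._accum(np.ascontiguousarray(gr))

    return Tensor._result(np.ascontiguousarray(out_data), (x,), backward)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling of the spatial axes."""
    out_data = (
        x.data.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)
    )
    c, X, Y, Z = x.data.shape

    def backward(g):
        if x.requires_grad:
            gr = g.reshape(c, X, 2, Y, 2, Z, 2).sum(axis=(2, 4, 6))
            x._accum(gr.astype(np.float32))

    return Tensor._result(np.ascontiguousarray(out_data), (x,), backward)


def mip(x: Tensor, angle_deg: float) -> Tensor:
    """Differentiable maximum intensity projection of a (X, Y, Z) tensor.

    Matches :func:`ssdr.geometry.forward_mip`; the gradient flows to the
    first maximal sample along each ray (deterministic subgradient) and
    back through the rotation's adjoint.
    """
    if x.data.ndim != 3:
        raise ValueError("mip expects a single-channel (X, Y, Z) tensor")
    alpha = 180.0 - float(angle_deg)
    rotated = geometry.apply_rotation(x.data, alpha)
    arg = rotated.argmax(axis=1)
    out_data = np.take_along_axis(rotated, arg[:, None, :], axis=1)[:, 0, :]
    shape = rotated.shape

    def backward(g):
        if x.requires_grad:
            grot = np.zeros(shape, dtype=np.float32)
            np.put_along_axis(grot, arg[:, None, :], g[:, None, :], axis=1)
            x._accum(geometry.apply_rotation_adjoint(grot, alpha))

    return Tensor._result(np.ascontiguousarray(out_data), (x,), backward)


@functools.lru_cache(maxsize=64)
def _resample_plan(in_shape: tuple[int, ...], out_shape: tuple[int, ...]):
    """Trilinear resampling plan (align-corners style endpoints)."""
    grids = []
    for n_in, n_out in zip(in_shape, out_shape):
        if n_out == 1:
            coords = np.zeros(1)
        elif n_in == 1:
            coords = np.zeros(n_out)
        else:
            coords = np.linspace(0.0, n_in - 1.0, n_out)
        grids.append(coords)
    mesh = np.meshgrid(*grids, indexing="ij")
    base = [np.floor(m).astype(np.int64) for m in mesh]
    frac = [m - b for m, b in zip(mesh, base)]
    base = [np.minimum(b, n - 2) if n > 1 else b
            for b, n in zip(base, in_shape)]
    frac = [m - b for m, b in zip(mesh, base)]
    strides = (in_shape[1] * in_shape[2], in_shape[2], 1)
    idx_list, w_list = [], []
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                xs = np.minimum(base[0] + dx, in_shape[0] - 1)
                ys = np.minimum(base[1] + dy, in_shape[1] - 1)
                zs = np.minimum(base[2] + dz, in_shape[2] - 1)
                w = (
                    (frac[0] if dx else 1 - frac[0])
                    * (frac[1] if dy else 1 - frac[1])
                    * (frac[2] if dz else 1 - frac[2])
                )
                idx_list.append(
                    (xs * strides[0] + ys * strides[1] + zs).ravel()
                )
                w_list.append(w.ravel())
    return np.stack(idx_list), np.stack(w_list)


def resample_linear(x: Tensor, out_shape: tuple[int, int, int]) -> Tensor:
    """Differentiable trilinear resampling of a (X, Y, Z) tensor."""
    if x.data.ndim != 3:
        raise ValueError("resample_linear expects a (X, Y, Z) tensor")
    in_shape = x.data.shape
    idx, w = _resample_plan(tuple(in_shape), tuple(out_shape))
    flat = x.data.ravel()
    out = np.zeros(idx.shape[1], dtype=np.float32)
    for k in range(idx.shape[0]):
        out += w[k].astype(np.float32) * flat[idx[k]]
    out_data = out.reshape(out_shape)

    def backward(g):
        if x.requires_grad:
            gx = np.zeros(flat.shape, dtype=np.float32)
            gflat = g.ravel()
            for k in range(idx.shape[0]):
                np.add.at(gx, idx[k], w[k].astype(np.float32) * gflat)
            x._accum(gx.reshape(in_shape))

    return Tensor._result(out_data, (x,), backward)


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2 = betas
        self.eps = float(eps)
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self, lr: float | None = None):
        lr = self.lr if lr is None else float(lr)
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p.data -= lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
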
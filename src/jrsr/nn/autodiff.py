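"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records its parents plus a
backward closure on a global tape-free graph; ``Tensor.backward`` runs a
topological sweep.  The op set is exactly what the reconstruction /
super-resolution generator, the discriminator and the loss stack need:
elementwise arithmetic, leaky ReLU, sigmoid/log, channel concatenation,
'same' 2D convolution (stride 1, im2col), 2x average pooling, nearest
upsampling and reductions.  Convolution inputs live in NCHW layout.

``GRAPH_NODE_COUNT`` counts graph-connected tensors created since the last
:func:`reset_node_count`; the deep-equilibrium training contract (memory
independent of forward iteration count) is asserted against it.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "avg_pool2x", "upsample_nearest",
           "reset_node_count", "node_count", "no_grad", "is_grad_enabled"]

_GRAPH_NODE_COUNT = 0
_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode).

    Inside the context no tensor records parents or backward closures, so
    fixed-point iterations cost no more memory than a single application.
    """

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def reset_node_count() -> None:
    global _GRAPH_NODE_COUNT
    _GRAPH_NODE_COUNT = 0


def node_count() -> int:
    return _GRAPH_NODE_COUNT


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=()):
        global _GRAPH_NODE_COUNT
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        track = _GRAD_ENABLED and (requires_grad or any(p.requires_grad for p in _parents))
        self.requires_grad = track
        self._parents = _parents if track else ()
        self._backward = None
        if self._parents:
            _GRAPH_NODE_COUNT += 1

    # -- graph plumbing -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that requires no grad")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("implicit gradient only for scalar outputs")
            grad = np.ones_like(self.data)
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic ---------------------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, _parents=(self, other))
        if out.requires_grad:
            def bwd(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g, self.data.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(g, other.data.shape))
            out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, _parents=(self, other))
        if out.requires_grad:
            def bwd(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g * other.data, self.data.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(g * self.data, other.data.shape))
            out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise NotImplementedError("division by a tensor is not supported")
        return self * (1.0 / other)

    def square(self):
        out = Tensor(self.data**2, _parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(2.0 * self.data * g)
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), _parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(np.sign(self.data) * g)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g / self.data)
        return out

    def sigmoid(self):
        sig = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(sig, _parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * sig * (1.0 - sig))
        return out

    def sqrt(self):
        root = np.sqrt(self.data)
        out = Tensor(root, _parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g / (2.0 * root + 1e-300))
        return out

    def clamp(self, lo: float | None = None, hi: float | None = None):
        clipped = np.clip(self.data, lo, hi)
        out = Tensor(clipped, _parents=(self,))
        if out.requires_grad:
            inside = np.ones_like(self.data)
            if lo is not None:
                inside = inside * (self.data >= lo)
            if hi is not None:
                inside = inside * (self.data <= hi)
            out._backward = lambda g: self._accum(g * inside)
        return out

    def narrow(self, start: int, length: int, axis: int = 1):
        """Slice ``[start, start+length)`` along ``axis``."""
        sl = [slice(None)] * self.data.ndim
        sl[axis] = slice(start, start + length)
        sl = tuple(sl)
        out = Tensor(self.data[sl], _parents=(self,))
        if out.requires_grad:
            def bwd(g):
                gx = np.zeros_like(self.data)
                gx[sl] = g
                self._accum(gx)
            out._backward = bwd
        return out

    def leaky_relu(self, slope: float = 0.2):
        factor = np.where(self.data > 0, 1.0, slope)
        out = Tensor(self.data * factor, _parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * factor)
        return out

    def sum(self):
        out = Tensor(self.data.sum(), _parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(np.broadcast_to(g, self.data.shape))
        return out

    def mean(self):
        n = self.data.size
        out = Tensor(self.data.mean(), _parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(np.broadcast_to(g / n, self.data.shape))
        return out

    def mean_spatial(self):
        """Mean over the H, W axes of an NCHW tensor, keeping dims."""
        n = self.data.shape[-2] * self.data.shape[-1]
        out = Tensor(self.data.mean(axis=(-2, -1), keepdims=True), _parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(
                np.broadcast_to(g / n, self.data.shape)
            )
        return out

    def reshape(self, *shape):
        orig = self.data.shape
        out = Tensor(self.data.reshape(*shape), _parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g.reshape(orig))
        return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), _parents=tuple(tensors))
    if out.requires_grad:
        sizes = [d.shape[axis] for d in datas]
        splits = np.cumsum(sizes)[:-1]

        def bwd(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accum(piece)
        out._backward = bwd
    return out


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """'Same' 2D convolution (cross-correlation), stride 1, NCHW layout.

    ``weight`` is (C_out, C_in, k, k) with odd k; im2col + BLAS matmul.
    """
    N, C, H, W = x.data.shape
    O, Ci, kh, kw = weight.data.shape
    if Ci != C:
        raise ValueError(f"channel mismatch: input {C}, weight expects {Ci}")
    ph, pw = kh // 2, kw // 2
    # one extra bottom pad row lets every kernel shift become a single
    # contiguous slice of the flattened padded image (fast im2col)
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph + 1), (pw, pw)))
    Wp = W + 2 * pw
    L = H * Wp
    xpf = xp.reshape(N, C, -1)
    kk = kh * kw
    cols = np.empty((N, C, kk, L))
    for idx in range(kk):
        ki, kj = divmod(idx, kw)
        off = ki * Wp + kj
        cols[:, :, idx] = xpf[:, :, off : off + L]
    cols = cols.reshape(N, C * kk, L)
    # weight layout (O, C, kh, kw) flattens to (O, C*kh*kw), matching cols;
    # output columns W..Wp-1 are junk corners inside the padding, dropped
    wmat = weight.data.reshape(O, C * kk)
    y = np.matmul(wmat, cols).reshape(N, O, H, Wp)[:, :, :, :W]
    if bias is not None:
        y = y + bias.data.reshape(1, O, 1, 1)
    else:
        y = np.ascontiguousarray(y)
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(y, _parents=parents)
    if out.requires_grad:
        def bwd(g):
            gfull = np.zeros((N, O, H, Wp))
            gfull[:, :, :, :W] = g
            gm = gfull.reshape(N, O, L)
            if weight.requires_grad:
                dw = np.matmul(gm, cols.transpose(0, 2, 1)).sum(axis=0)
                weight._accum(dw.reshape(weight.data.shape))
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                dcols = np.matmul(wmat.T, gm).reshape(N, C, kk, L)
                dxpf = np.zeros_like(xpf)
                for idx in range(kk):
                    ki, kj = divmod(idx, kw)
                    off = ki * Wp + kj
                    dxpf[:, :, off : off + L] += dcols[:, :, idx]
                dxp = dxpf.reshape(xp.shape)
                x._accum(dxp[:, :, ph : ph + H, pw : pw + W])
        out._backward = bwd
    return out


def avg_pool2x(x: Tensor) -> Tensor:
    """2x2 average pooling, stride 2 (even spatial dims required)."""
    N, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError("avg_pool2x needs even spatial dims")
    y = x.data.reshape(N, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))
    out = Tensor(y, _parents=(x,))
    if out.requires_grad:
        def bwd(g):
            gx = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) / 4.0
            x._accum(gx)
        out._backward = bwd
    return out


def upsample_nearest(x: Tensor, sh: int, sw: int | None = None) -> Tensor:
    """Nearest-neighbor upsampling by integer factors per spatial axis."""
    sw = sh if sw is None else sw
    y = np.repeat(np.repeat(x.data, sh, axis=-2), sw, axis=-1)
    out = Tensor(y, _parents=(x,))
    if out.requires_grad:
        N, C, H, W = x.data.shape

        def bwd(g):
            gx = g.reshape(N, C, H, sh, W, sw).sum(axis=(3, 5))
            x._accum(gx)
        out._backward = bwd
    return out
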
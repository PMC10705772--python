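"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides the small set of differentiable operations the segmentation model
needs: elementwise arithmetic with broadcasting, matrix products, 2-D
convolution (im2col), nearest-neighbour upsampling, max pooling, reductions,
reshapes, gathering, and fused loss primitives (softmax cross-entropy,
binary cross-entropy with logits, smooth-L1).  Gradients are accumulated by
a topological-order backward sweep, torch-style.

The default compute dtype is float32; finite-difference gradient checks
and other precision-sensitive work can switch to float64 with the
:class:`use_dtype` context manager.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32  # default compute dtype; see use_dtype for float64 work


class use_dtype:
    """Context manager switching the engine's compute dtype.

    Finite-difference gradient checks need float64; everything else runs
    float32 for speed.  Tensors created inside the context use the given
    dtype.
    """

    def __init__(self, dtype):
        self.dtype = dtype

    def __enter__(self):
        global DTYPE
        self._old = DTYPE
        DTYPE = self.dtype
        return self

    def __exit__(self, *exc):
        global DTYPE
        DTYPE = self._old
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None,
                 name: str | None = None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward
        self.name = name

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autograd core --------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=DTYPE)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, g):
        if not self.requires_grad and self._backward is None:
            return
        self.grad = g if self.grad is None else self.grad + g

    # -- elementwise ops ------------------------------------------------------
    def _binop(self, other, fwd, bwd_self, bwd_other):
        other = Tensor.as_tensor(other)
        out_data = fwd(self.data, other.data)
        req = self.requires_grad or other.requires_grad or \
            self._backward is not None or other._backward is not None

        def backward(g):
            self._accum(_unbroadcast(bwd_self(g, self.data, other.data), self.data.shape))
            other._accum(_unbroadcast(bwd_other(g, self.data, other.data), other.data.shape))

        return Tensor(out_data, req, (self, other), backward if req else None)

    def __add__(self, other):
        return self._binop(other, lambda a, b: a + b,
                           lambda g, a, b: g, lambda g, a, b: g)

    __radd__ = __add__

    def __sub__(self, other):
        return self._binop(other, lambda a, b: a - b,
                           lambda g, a, b: g, lambda g, a, b: -g)

    def __rsub__(self, other):
        return Tensor.as_tensor(other).__sub__(self)

    def __mul__(self, other):
        return self._binop(other, lambda a, b: a * b,
                           lambda g, a, b: g * b, lambda g, a, b: g * a)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self._binop(other, lambda a, b: a / b,
                           lambda g, a, b: g / b, lambda g, a, b: -g * a / (b * b))

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other).__truediv__(self)

    def __neg__(self):
        return self * (-1.0)

    def _unop(self, fwd, bwd):
        out_data = fwd(self.data)
        req = self.requires_grad or self._backward is not None

        def backward(g):
            self._accum(bwd(g, self.data, out_data))

        return Tensor(out_data, req, (self,), backward if req else None)

    def pow(self, p: float):
        return self._unop(lambda a: a ** p, lambda g, a, o: g * p * a ** (p - 1))

    def exp(self):
        return self._unop(np.exp, lambda g, a, o: g * o)

    def log(self):
        return self._unop(np.log, lambda g, a, o: g / a)

    def relu(self):
        return self._unop(lambda a: np.maximum(a, 0.0), lambda g, a, o: g * (a > 0))

    def sigmoid(self):
        return self._unop(_sigmoid, lambda g, a, o: g * o * (1.0 - o))

    def tanh(self):
        return self._unop(np.tanh, lambda g, a, o: g * (1.0 - o * o))

    # -- reductions / shape ops ----------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        req = self.requires_grad or self._backward is not None

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Tensor(out_data, req, (self,), backward if req else None)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        out_data = self.data.reshape(shape)
        req = self.requires_grad or self._backward is not None

        def backward(g):
            self._accum(g.reshape(old))

        return Tensor(out_data, req, (self,), backward if req else None)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)
        req = self.requires_grad or self._backward is not None

        def backward(g):
            self._accum(g.transpose(inv))

        return Tensor(out_data, req, (self,), backward if req else None)

    def __getitem__(self, key):
        out_data = self.data[key]
        req = self.requires_grad or self._backward is not None
        shape = self.data.shape

        def backward(g):
            full = np.zeros(shape, dtype=DTYPE)
            np.add.at(full, key, g)
            self._accum(full)

        return Tensor(out_data, req, (self,), backward if req else None)

    def take_rows(self, idx):
        """Gather rows along axis 0 by an integer index array."""
        idx = np.asarray(idx, dtype=np.intp)
        return self[idx]

    # -- linear algebra --------------------------------------------------------
    def matmul(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data @ other.data
        req = self.requires_grad or other.requires_grad or \
            self._backward is not None or other._backward is not None

        def backward(g):
            a, b = self.data, other.data
            if a.ndim == 1 and b.ndim == 1:           # dot -> scalar
                self._accum(g * b)
                other._accum(g * a)
                return
            a2 = a[None, :] if a.ndim == 1 else a
            b2 = b[:, None] if b.ndim == 1 else b
            g2 = np.asarray(g)
            if a.ndim == 1:
                g2 = g2[..., None, :]
            if b.ndim == 1:
                g2 = g2[..., :, None]
            ga = g2 @ np.swapaxes(b2, -1, -2)
            gb = np.swapaxes(a2, -1, -2) @ g2
            if a.ndim == 1:
                ga = ga.reshape(ga.shape[:-2] + (ga.shape[-1],))
                ga = _unbroadcast(ga, a.shape)
            else:
                ga = _unbroadcast(ga, a.shape)
            if b.ndim == 1:
                gb = gb.reshape(gb.shape[:-2] + (gb.shape[-2],))
                gb = _unbroadcast(gb, b.shape)
            else:
                gb = _unbroadcast(gb, b.shape)
            self._accum(ga)
            other._accum(gb)

        return Tensor(out_data, req, (self, other), backward if req else None)

    __matmul__ = matmul


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def concat(tensors, axis=0):
    tensors = [Tensor.as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad or t._backward is not None for t in tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    return Tensor(out_data, req, tuple(tensors), backward if req else None)


def softmax(x: Tensor, axis=-1) -> Tensor:
    shift = Tensor(x.data.max(axis=axis, keepdims=True))  # constant: no grad needed
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# Convolution / pooling / resampling
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh, kw, stride, pad):
    """x (N,C,H,W) -> patch matrix (N*Ho*Wo, C*kh*kw) plus output size."""
    n, c, h, w = x.shape
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (w + 2 * pad - kw) // stride + 1
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    s = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp, (n, ho, wo, c, kh, kw),
        (s[0], s[2] * stride, s[3] * stride, s[1], s[2], s[3]))
    return view.reshape(n * ho * wo, c * kh * kw), ho, wo


def _col2im(cols, xshape, kh, kw, stride, pad, ho, wo):
    """Scatter-add patch-matrix gradients back to input layout."""
    n, c, h, w = xshape
    xg = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    cols = cols.reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 4, 5, 1, 2)
    for i in range(kh):
        for j in range(kw):
            xg[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += cols[:, :, i, j]
    return xg[:, :, pad:pad + h, pad:pad + w] if pad else xg


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride=1, pad=0) -> Tensor:
    """2-D convolution (cross-correlation): x (N,C,H,W), w (Co,C,kh,kw)."""
    x, w = Tensor.as_tensor(x), Tensor.as_tensor(w)
    n, c, h, wdt = x.data.shape
    co, ci, kh, kw = w.data.shape
    if ci != c:
        raise ValueError(f"conv2d channel mismatch: input has {c}, kernel expects {ci}")
    cols, ho, wo = _im2col(x.data, kh, kw, stride, pad)       # (NHW, CKK)
    w2 = w.data.reshape(co, -1).T                             # (CKK, Co)
    out = (cols @ w2).reshape(n, ho, wo, co).transpose(0, 3, 1, 2)
    if b is not None:
        out = out + b.data.reshape(1, co, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    req = any(t.requires_grad or t._backward is not None for t in parents)

    def backward(g):
        g2 = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, co)  # (NHW, Co)
        gw = (cols.T @ g2).T.reshape(w.data.shape)
        w._accum(gw)
        gcols = g2 @ w2.T                                      # (NHW, CKK)
        x._accum(_col2im(gcols, x.data.shape, kh, kw, stride, pad, ho, wo))
        if b is not None:
            b._accum(g.sum(axis=(0, 2, 3)).reshape(b.data.shape))

    return Tensor(out, req, parents, backward if req else None)


def max_pool2d(x: Tensor, k=2, stride=2) -> Tensor:
    n, c, h, w = x.data.shape
    cols, ho, wo = _im2col(x.data, k, k, stride, 0)       # (NHW, C*k*k)
    flat = cols.reshape(n * ho * wo, c, k * k)
    arg = flat.argmax(axis=2)
    out = np.take_along_axis(flat, arg[..., None], axis=2)[..., 0]
    out = out.reshape(n, ho, wo, c).transpose(0, 3, 1, 2)
    req = x.requires_grad or x._backward is not None

    def backward(g):
        g2 = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, c)
        gcols = np.zeros_like(flat)
        np.put_along_axis(gcols, arg[..., None], g2[..., None], axis=2)
        x._accum(_col2im(gcols.reshape(n * ho * wo, c * k * k),
                         x.data.shape, k, k, stride, 0, ho, wo))

    return Tensor(out, req, (x,), backward if req else None)


def upsample_nearest2(x: Tensor) -> Tensor:
    """Nearest-neighbour x2 upsampling of (..., H, W)."""
    x = Tensor.as_tensor(x)
    out = x.data.repeat(2, axis=-2).repeat(2, axis=-1)
    req = x.requires_grad or x._backward is not None
    sh = x.data.shape

    def backward(g):
        g = g.reshape(sh[:-2] + (sh[-2], 2, sh[-1], 2))
        x._accum(g.sum(axis=(-3, -1)))

    return Tensor(out, req, (x,), backward if req else None)


# ---------------------------------------------------------------------------
# Fused loss primitives (numerically stable, closed-form backward)
# ---------------------------------------------------------------------------

def softmax_cross_entropy(logits: Tensor, labels) -> Tensor:
    """Per-row cross-entropy; logits (N,K), integer labels (N,)."""
    labels = np.asarray(labels, dtype=np.intp)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1))
    loss = logsumexp - z[np.arange(len(labels)), labels]
    req = logits.requires_grad or logits._backward is not None

    def backward(g):
        p = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
        p[np.arange(len(labels)), labels] -= 1.0
        logits._accum(p * g[:, None])

    return Tensor(loss, req, (logits,), backward if req else None)


def bce_with_logits(logits: Tensor, targets) -> Tensor:
    """Elementwise binary cross-entropy on logits (stable log1p form)."""
    t = np.asarray(targets, dtype=DTYPE)
    z = logits.data
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    req = logits.requires_grad or logits._backward is not None

    def backward(g):
        logits._accum(g * (_sigmoid(z) - t))

    return Tensor(loss, req, (logits,), backward if req else None)


def smooth_l1(pred: Tensor, target, beta: float = 1.0) -> Tensor:
    """Elementwise Huber/smooth-L1: 0.5 d^2/beta for |d|<beta else |d|-beta/2."""
    t = np.asarray(target, dtype=DTYPE)
    d = pred.data - t
    ad = np.abs(d)
    loss = np.where(ad < beta, 0.5 * d * d / beta, ad - 0.5 * beta)
    req = pred.requires_grad or pred._backward is not None

    def backward(g):
        pred._accum(g * np.where(ad < beta, d / beta, np.sign(d)))

    return Tensor(loss, req, (pred,), backward if req else None)


# ---------------------------------------------------------------------------
# Parameters and optimization
# ---------------------------------------------------------------------------

class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data, name=None):
        super().__init__(data, requires_grad=True, name=name)


def he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    """Zero-mean normal scaled by fan-in (Kaiming-style)."""
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class SGD:
    """SGD with classical momentum and decoupled-from-nothing L2 weight decay."""

    def __init__(self, params, lr=0.001, momentum=0.9, weight_decay=0.0005,
                 clip_norm: float | None = None):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.clip_norm = clip_norm
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data)
                 for p in self.params]
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g * g).sum()) for g in grads))
            if total > self.clip_norm and total > 0:
                scale = self.clip_norm / total
                grads = [g * scale for g in grads]
        for p, v, g in zip(self.params, self.velocity, grads):
            g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v


def numeric_grad(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite-difference gradient of scalar f at x (testing utility)."""
    g = np.zeros_like(x, dtype=DTYPE)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        old = x[i]
        x[i] = old + eps
        fp = f()
        x[i] = old - eps
        fm = f()
        x[i] = old
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g
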
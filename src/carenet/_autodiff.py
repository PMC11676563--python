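"""Minimal reverse-mode automatic differentiation on numpy arrays.

The network in :mod:`carenet.network` is small (tens of parameters tensors,
hundreds of tape nodes per batch) but recurrent, so the engine is a plain
dynamic tape: every op returns a :class:`Tensor` holding the forward value
and a closure that routes the upstream gradient to its parents.  Two
performance-critical pieces — the GRU layer and the masked softmax — are
fused ops with hand-derived backward passes; everything else is composed
from elementwise primitives.  All arithmetic is float64.
"""

from __future__ import annotations

import numpy as np
from scipy import special as _sp


class Tensor:
    """A node on the tape: a value, an accumulated gradient, and parents."""

    __slots__ = ("data", "grad", "_parents", "_bw", "requires_grad")

    def __init__(self, data, parents=(), bw=None, requires_grad=True):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._parents = parents
        self._bw = bw
        self.requires_grad = requires_grad

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- graph traversal ---------------------------------------------------

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._bw is not None and node.grad is not None:
                node._bw(node.grad)

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
        else:
            self.grad += g

    # -- operator sugar ----------------------------------------------------

    def __add__(self, other):
        return add(self, other)

    def __radd__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __rmul__(self, other):
        return mul(self, other)

    def __sub__(self, other):
        return add(self, mul(other, -1.0) if isinstance(other, Tensor) else -np.asarray(other))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __neg__(self):
        return mul(self, -1.0)

    def __truediv__(self, other):
        return div(self, other)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, key):
        return getitem(self, key)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 or isinstance(shape[0], int) else shape[0])


def astensor(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=np.float64), requires_grad=False)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


# -- elementwise primitives ------------------------------------------------


def add(a, b):
    a, b = astensor(a), astensor(b)
    out = Tensor(a.data + b.data, (a, b))

    def bw(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.data.shape))

    out._bw = bw
    return out


def mul(a, b):
    a, b = astensor(a), astensor(b)
    out = Tensor(a.data * b.data, (a, b))

    def bw(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.data.shape))

    out._bw = bw
    return out


def div(a, b):
    a, b = astensor(a), astensor(b)
    out = Tensor(a.data / b.data, (a, b))

    def bw(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g / b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

    out._bw = bw
    return out


def _unary(a, val, dval):
    a = astensor(a)
    y = val(a.data)
    out = Tensor(y, (a,))

    def bw(g):
        if a.requires_grad:
            a._accum(g * dval(a.data, y))

    out._bw = bw
    return out


def exp(a):
    return _unary(a, np.exp, lambda x, y: y)


def log(a):
    return _unary(a, np.log, lambda x, y: 1.0 / x)


def tanh(a):
    return _unary(a, np.tanh, lambda x, y: 1.0 - y * y)


def sigmoid(a):
    return _unary(a, _sp.expit, lambda x, y: y * (1.0 - y))


def square(a):
    return _unary(a, np.square, lambda x, y: 2.0 * x)


def softplus(a):
    """log(1 + e^x), overflow-safe; derivative sigmoid(x)."""

    def val(x):
        return np.logaddexp(0.0, x)

    return _unary(a, val, lambda x, y: _sp.expit(x))


def sum_(a, axis=None, keepdims=False):
    a = astensor(a)
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), (a,))

    def bw(g):
        if not a.requires_grad:
            return
        gg = g
        if axis is not None and not keepdims:
            gg = np.expand_dims(gg, axis)
        a._accum(np.broadcast_to(gg, a.data.shape).copy())

    out._bw = bw
    return out


def mean(a, axis=None, keepdims=False):
    a = astensor(a)
    n = a.data.size if axis is None else a.data.shape[axis]
    return mul(sum_(a, axis=axis, keepdims=keepdims), 1.0 / n)


def reshape(a, shape):
    a = astensor(a)
    out = Tensor(a.data.reshape(shape), (a,))

    def bw(g):
        if a.requires_grad:
            a._accum(g.reshape(a.data.shape))

    out._bw = bw
    return out


def getitem(a, key):
    a = astensor(a)
    out = Tensor(a.data[key], (a,))

    def bw(g):
        if a.requires_grad:
            full = np.zeros_like(a.data)
            full[key] = g
            a._accum(full)

    out._bw = bw
    return out


def concat(tensors, axis=-1):
    tensors = [astensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]

    def bw(g):
        offs = np.cumsum([0] + sizes)
        for t, lo, hi in zip(tensors, offs[:-1], offs[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    out._bw = bw
    return out


def matmul(a, b):
    """a @ b with a 2-D or 3-D left operand and a 2-D right operand."""
    a, b = astensor(a), astensor(b)
    if b.ndim != 2 or a.ndim not in (2, 3):
        raise ValueError("matmul supports (…,D)@(D,K) with 2-D weights only")
    out = Tensor(a.data @ b.data, (a, b))

    def bw(g):
        if a.requires_grad:
            a._accum(g @ b.data.T)
        if b.requires_grad:
            d = a.data.shape[-1]
            k = g.shape[-1]
            b._accum(a.data.reshape(-1, d).T @ g.reshape(-1, k))

    out._bw = bw
    return out


def embedding(weight: Tensor, idx: np.ndarray):
    """Row gather ``weight[idx]`` with scatter-add backward."""
    idx = np.asarray(idx)
    out = Tensor(weight.data[idx], (weight,))

    def bw(g):
        if weight.requires_grad:
            V, d = weight.data.shape
            flat_idx = idx.reshape(-1)
            flat_g = g.reshape(-1, d)
            # bincount per column beats np.add.at by an order of magnitude
            gw = np.stack([np.bincount(flat_idx, weights=flat_g[:, j], minlength=V)
                           for j in range(d)], axis=1)
            weight._accum(gw)

    out._bw = bw
    return out


# -- fused ops -------------------------------------------------------------


def masked_softmax(logits, mask: np.ndarray, axis: int = -1):
    """Softmax over ``axis`` restricted to positions where ``mask`` is 1.

    Rows whose mask is entirely zero produce an all-zero weight row (the
    caller substitutes its own representation for such groups).
    """
    logits = astensor(logits)
    m = np.asarray(mask, dtype=np.float64)
    x = logits.data
    neg = np.where(m > 0, x, -np.inf)
    mx = np.max(neg, axis=axis, keepdims=True)
    mx = np.where(np.isfinite(mx), mx, 0.0)
    e = np.exp(x - mx) * m
    s = e.sum(axis=axis, keepdims=True)
    a = e / np.maximum(s, 1e-300)
    out = Tensor(a, (logits,))

    def bw(g):
        if logits.requires_grad:
            inner = (g * a).sum(axis=axis, keepdims=True)
            logits._accum(a * (g - inner))

    out._bw = bw
    return out


try:
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba is a hard dependency
    def _njit(*a, **k):
        def deco(f):
            return f
        return deco(*a) if a and callable(a[0]) else deco


@_njit(cache=True)
def _gru_fwd_kernel(gx_all, mask, wh, reverse):
    B, T, H3 = gx_all.shape
    H = H3 // 3
    out = np.zeros((B, T, H))
    R = np.empty((B, T, H))
    Z = np.empty((B, T, H))
    Nn = np.empty((B, T, H))
    GHN = np.empty((B, T, H))
    h = np.zeros((B, H))
    for step in range(T):
        t = T - 1 - step if reverse else step
        gh = np.dot(h, wh)
        for i in range(B):
            m = mask[i, t]
            for j in range(H):
                r = 1.0 / (1.0 + np.exp(-(gx_all[i, t, j] + gh[i, j])))
                z = 1.0 / (1.0 + np.exp(-(gx_all[i, t, H + j] + gh[i, H + j])))
                ghn = gh[i, 2 * H + j]
                n = np.tanh(gx_all[i, t, 2 * H + j] + r * ghn)
                hnew = (1.0 - z) * n + z * h[i, j]
                hcur = m * hnew + (1.0 - m) * h[i, j]
                R[i, t, j] = r
                Z[i, t, j] = z
                Nn[i, t, j] = n
                GHN[i, t, j] = ghn
                out[i, t, j] = hcur
                h[i, j] = hcur
    return out, R, Z, Nn, GHN


@_njit(cache=True)
def _gru_bwd_kernel(gout, out, mask, R, Z, Nn, GHN, wh, reverse):
    B, T, H = gout.shape
    dG = np.zeros((B, T, 3 * H))
    dGh = np.empty((B, 3 * H))
    dWh = np.zeros_like(wh)
    dh = np.zeros((B, H))
    hprev = np.empty((B, H))
    for step in range(T - 1, -1, -1):
        t = T - 1 - step if reverse else step
        # hidden state entering step t (= output of the previous step)
        if step == 0:
            hprev[:] = 0.0
        else:
            tp = T - step if reverse else step - 1
            hprev[:] = out[:, tp]
        for i in range(B):
            m = mask[i, t]
            for j in range(H):
                dhij = dh[i, j] + gout[i, t, j]
                dhnew = m * dhij
                dhp = (1.0 - m) * dhij
                r = R[i, t, j]
                z = Z[i, t, j]
                n = Nn[i, t, j]
                ghn = GHN[i, t, j]
                dn = dhnew * (1.0 - z)
                dz = dhnew * (hprev[i, j] - n)
                dhp += dhnew * z
                dan = dn * (1.0 - n * n)
                dr = dan * ghn
                dghn = dan * r
                daz = dz * z * (1.0 - z)
                dar = dr * r * (1.0 - r)
                dG[i, t, j] = dar
                dG[i, t, H + j] = daz
                dG[i, t, 2 * H + j] = dan
                dGh[i, j] = dar
                dGh[i, H + j] = daz
                dGh[i, 2 * H + j] = dghn
                dh[i, j] = dhp
        dh += np.dot(dGh, wh.T)
        dWh += np.dot(hprev.T, dGh)
    return dG, dWh


def gru_layer(x: Tensor, mask: np.ndarray, wx: Tensor, wh: Tensor, b: Tensor,
              reverse: bool = False) -> Tensor:
    """One direction of a GRU over ``x`` of shape (B, T, D) -> (B, T, H).

    Gate order is [r | z | n]:

        r_t = sigmoid(x_t Wx_r + h_{t-1} Wh_r + b_r)
        z_t = sigmoid(x_t Wx_z + h_{t-1} Wh_z + b_z)
        n_t = tanh(x_t Wx_n + r_t * (h_{t-1} Wh_n) + b_n)
        h_t = (1 - z_t) * n_t + z_t * h_{t-1}

    Padded steps (mask 0) carry the hidden state through unchanged.  The
    layer is a single tape node: the recurrence runs in compiled kernels
    with a hand-derived BPTT backward; the large input/weight products go
    through BLAS outside the kernels.
    """
    B, T, D = x.data.shape
    Xd, Wxd, Whd, bd = x.data, wx.data, wh.data, b.data
    mask = np.ascontiguousarray(mask, dtype=np.float64)
    gx_all = (Xd.reshape(-1, D) @ Wxd + bd).reshape(B, T, -1)
    out, R, Z, Nn, GHN = _gru_fwd_kernel(gx_all, mask, Whd, reverse)
    result = Tensor(out, (x, wx, wh, b))

    def bw(gout):
        dG, dWh = _gru_bwd_kernel(np.ascontiguousarray(gout), out, mask,
                                  R, Z, Nn, GHN, Whd, reverse)
        flat = dG.reshape(-1, dG.shape[-1])
        if x.requires_grad:
            x._accum((flat @ Wxd.T).reshape(Xd.shape))
        if wx.requires_grad:
            wx._accum(Xd.reshape(-1, D).T @ flat)
        if wh.requires_grad:
            wh._accum(dWh)
        if b.requires_grad:
            b._accum(flat.sum(axis=0))

    result._bw = bw
    return result


def kl_beta_uniform(a, b):
    """KL( Beta(a, b) || Beta(1, 1) ), elementwise, with analytic gradient."""
    a, b = astensor(a), astensor(b)
    ad, bd = a.data, b.data
    s = ad + bd
    val = (_sp.gammaln(s) - _sp.gammaln(ad) - _sp.gammaln(bd)
           + (ad - 1.0) * _sp.digamma(ad) + (bd - 1.0) * _sp.digamma(bd)
           + (2.0 - s) * _sp.digamma(s))
    out = Tensor(val, (a, b))

    def bw(g):
        t1 = _sp.polygamma(1, s)
        if a.requires_grad:
            a._accum(_unbroadcast(g * ((ad - 1.0) * _sp.polygamma(1, ad) + (2.0 - s) * t1),
                                  ad.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * ((bd - 1.0) * _sp.polygamma(1, bd) + (2.0 - s) * t1),
                                  bd.shape))

    out._bw = bw
    return out


# -- parameters & optimiser ------------------------------------------------


class Adam:
    """Standard Adam on a dict of named parameter Tensors."""

    def __init__(self, params: dict, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def clip_global_norm(self, max_norm: float):
        total = 0.0
        for p in self.params.values():
            if p.grad is not None:
                total += float(np.sum(p.grad * p.grad))
        norm = np.sqrt(total)
        if norm > max_norm > 0:
            scale = max_norm / (norm + 1e-12)
            for p in self.params.values():
                if p.grad is not None:
                    p.grad *= scale
        return norm

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1.0 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1.0 - self.b2) * g * g
            p.data -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def numerical_gradient(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite differences of scalar-valued ``f`` — test oracle."""
    x = x.astype(np.float64)
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f(x)
        x[i] = orig - eps
        fm = f(x)
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g
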
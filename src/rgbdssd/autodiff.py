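"""Minimal reverse-mode automatic differentiation on numpy arrays.

This module is the numerical engine behind the detector and the
highlight-removal network: a tape-based autograd with exactly the
operations those models need — 2-D convolution (stride, padding,
dilation), max pooling, the usual pointwise nonlinearities, softmax
cross-entropy, smooth-L1 — plus Adam/SGD optimizers and a tiny
``Module`` container with ``state_dict`` serialization.

Arrays are kept in whatever float dtype they arrive in (float32 for
training speed, float64 in gradient-check tests).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "Module",
    "Conv2d",
    "Sequential",
    "Adam",
    "SGD",
    "clip_global_norm",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus a gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data)
        if self.data.dtype.kind != "f":
            self.data = self.data.astype(np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers ------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative topo sort: graphs can be deep (recurrent nets)
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
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic ----------------------------------------
    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._coerce(other)
        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))
        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)
        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        other = Tensor._coerce(other)
        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))
        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._coerce(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor._coerce(other) * self ** -1.0

    def __pow__(self, exponent: float):
        e = float(exponent)
        out_data = self.data ** e
        def backward(g):
            self._accum(g * e * self.data ** (e - 1.0))
        return Tensor._make(out_data, (self,), backward)

    # -- pointwise nonlinearities --------------------------------------
    def relu(self):
        mask = self.data > 0
        def backward(g):
            self._accum(g * mask)
        return Tensor._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        with np.errstate(over="ignore"):
            s = 1.0 / (1.0 + np.exp(-self.data))
        def backward(g):
            self._accum(g * s * (1.0 - s))
        return Tensor._make(s, (self,), backward)

    def tanh(self):
        t = np.tanh(self.data)
        def backward(g):
            self._accum(g * (1.0 - t * t))
        return Tensor._make(t, (self,), backward)

    def exp(self):
        e = np.exp(self.data)
        def backward(g):
            self._accum(g * e)
        return Tensor._make(e, (self,), backward)

    def log(self, eps: float = 0.0):
        d = self.data + eps if eps else self.data
        def backward(g):
            self._accum(g / d)
        return Tensor._make(np.log(d), (self,), backward)

    # -- shape ops ------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        def backward(g):
            self._accum(g.reshape(old))
        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        def backward(g):
            self._accum(g.transpose(inv))
        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)
        return Tensor._make(self.data[idx], (self,), backward)

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy()
                            if np.ndim(g) else np.full_like(self.data, g))
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.shape).astype(self.data.dtype))
        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims),
                            (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if np.isscalar(axis) else tuple(axis)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- matrix / convolution ops ---------------------------------------
    def matmul(self, other: "Tensor"):
        other = Tensor._coerce(other)
        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)
        return Tensor._make(self.data @ other.data, (self, other), backward)

    __matmul__ = matmul

    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0, dilation: int = 1):
        """2-D cross-correlation; x is NCHW, weight is (O, C, kh, kw)."""
        x, w = self, weight
        B, C, H, W = x.shape
        O, Cw, kh, kw = w.shape
        if C != Cw:
            raise ValueError(f"channel mismatch: input {C}, weight {Cw}")
        s, p, d = int(stride), int(padding), int(dilation)
        kh_eff = d * (kh - 1) + 1
        kw_eff = d * (kw - 1) + 1
        Ho = (H + 2 * p - kh_eff) // s + 1
        Wo = (W + 2 * p - kw_eff) // s + 1
        if Ho <= 0 or Wo <= 0:
            raise ValueError("convolution output would be empty")
        xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
        # channels-last tap loop: one small matmul per kernel tap keeps
        # memory traffic low at the narrow widths used on CPU
        xpl = np.ascontiguousarray(xp.transpose(0, 2, 3, 1))  # (B, Hp, Wp, C)
        wl = w.data.transpose(2, 3, 1, 0)                     # (kh, kw, C, O)
        acc = np.zeros((B, Ho, Wo, O), dtype=np.result_type(x.data, w.data))
        for i in range(kh):
            for j in range(kw):
                sl = xpl[:, i * d: i * d + Ho * s: s,
                         j * d: j * d + Wo * s: s, :]
                acc += sl @ wl[i, j]
        if bias is not None:
            acc += bias.data
        out = acc.transpose(0, 3, 1, 2)

        def backward(g):
            gl = np.ascontiguousarray(g.transpose(0, 2, 3, 1))
            gm = gl.reshape(B * Ho * Wo, O)
            if bias is not None and bias.requires_grad:
                bias._accum(gm.sum(axis=0))
            dw = np.empty_like(w.data) if w.requires_grad else None
            dxpl = np.zeros_like(xpl) if x.requires_grad else None
            for i in range(kh):
                for j in range(kw):
                    sl = xpl[:, i * d: i * d + Ho * s: s,
                             j * d: j * d + Wo * s: s, :]
                    if dw is not None:
                        dw[:, :, i, j] = (gm.T @ sl.reshape(-1, C))
                    if dxpl is not None:
                        dxpl[:, i * d: i * d + Ho * s: s,
                             j * d: j * d + Wo * s: s, :] += \
                            (gm @ wl[i, j].T).reshape(B, Ho, Wo, C)
            if dw is not None:
                w._accum(dw)
            if dxpl is not None:
                dxp = dxpl.transpose(0, 3, 1, 2)
                x._accum(dxp[:, :, p:p + H, p:p + W] if p else dxp)

        parents = (x, w) if bias is None else (x, w, bias)
        return Tensor._make(out, parents, backward)

    def max_pool2d(self, kernel: int = 2, stride: int | None = None,
                   padding: int = 0, ceil_mode: bool = False):
        x = self
        k, s = int(kernel), int(stride or kernel)
        B, C, H, W = x.shape
        p = int(padding)
        Hp, Wp = H + 2 * p, W + 2 * p
        if ceil_mode:
            Ho = -(-(Hp - k) // s) + 1
            Wo = -(-(Wp - k) // s) + 1
            pad_h = (Ho - 1) * s + k - Hp
            pad_w = (Wo - 1) * s + k - Wp
        else:
            Ho = (Hp - k) // s + 1
            Wo = (Wp - k) // s + 1
            pad_h = pad_w = 0
        neg = np.finfo(x.data.dtype).min
        xp = np.pad(x.data, ((0, 0), (0, 0), (p, p + pad_h), (p, p + pad_w)),
                    constant_values=neg) if (p or pad_h or pad_w) else x.data
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s].reshape(B, C, Ho, Wo, k * k)
        arg = win.argmax(axis=-1)
        out = np.take_along_axis(win, arg[..., None], axis=-1)[..., 0]

        def backward(g):
            dxp = np.zeros(xp.shape, dtype=x.data.dtype)
            ii = arg // k
            jj = arg % k
            bi, ci, oi, oj = np.indices(arg.shape)
            np.add.at(dxp, (bi, ci, oi * s + ii, oj * s + jj), g)
            x._accum(dxp[:, :, p:p + H, p:p + W])

        return Tensor._make(out, (x,), backward)

    # -- fused losses -----------------------------------------------------
    def softmax_cross_entropy(self, targets: np.ndarray):
        """Per-row cross-entropy of softmax(logits); logits (N, C), targets (N,)."""
        z = self.data
        t = np.asarray(targets, dtype=np.intp)
        zmax = z.max(axis=1, keepdims=True)
        ez = np.exp(z - zmax)
        sez = ez.sum(axis=1, keepdims=True)
        logp = (z - zmax) - np.log(sez)
        n = np.arange(z.shape[0])
        loss = -logp[n, t]

        def backward(g):
            soft = ez / sez
            soft[n, t] -= 1.0
            self._accum(soft * g[:, None])

        return Tensor._make(loss, (self,), backward)

    def smooth_l1(self, target) -> "Tensor":
        """Elementwise Huber: 0.5 x^2 for |x|<1, |x| - 0.5 otherwise."""
        tdata = target.data if isinstance(target, Tensor) else np.asarray(target)
        diff = self.data - tdata
        a = np.abs(diff)
        out = np.where(a < 1.0, 0.5 * diff * diff, a - 0.5)

        def backward(g):
            self._accum(g * np.where(a < 1.0, diff, np.sign(diff)))

        return Tensor._make(out, (self,), backward)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def concat(tensors: list, axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tensors, backward)


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------

class Module:
    """Container tracking parameter tensors and sub-modules by attribute."""

    def parameters(self) -> list[Tensor]:
        params, seen = [], set()
        for _, v in self._walk():
            if id(v) not in seen:
                seen.add(id(v))
                params.append(v)
        return params

    def _walk(self, prefix: str = ""):
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield key, value
            elif isinstance(value, Module):
                yield from value._walk(f"{key}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item._walk(f"{key}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{key}.{i}", item

    def state_dict(self) -> dict:
        return {k: v.data.copy() for k, v in self._walk()}

    def load_state_dict(self, state: dict) -> None:
        own = dict(self._walk())
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch: {sorted(missing)}")
        for k, v in own.items():
            arr = np.asarray(state[k], dtype=v.data.dtype)
            if arr.shape != v.data.shape:
                raise ValueError(f"shape mismatch for {k}")
            v.data = arr.copy()

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    def load(self, path) -> None:
        with np.load(path) as f:
            self.load_state_dict({k: f[k] for k in f.files})

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 stride: int = 1, padding: int = 0, dilation: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        rng = rng or np.random.default_rng()
        fan_in = in_ch * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)  # He init: ReLU-heavy stacks
        self.weight = Tensor(rng.normal(0.0, scale,
                                        (out_ch, in_ch, kernel, kernel)
                                        ).astype(dtype), requires_grad=True)
        self.bias = (Tensor(np.zeros(out_ch, dtype=dtype), requires_grad=True)
                     if bias else None)
        self.stride, self.padding, self.dilation = stride, padding, dilation

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride,
                        padding=self.padding, dilation=self.dilation)


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x) if isinstance(layer, Module) else layer(x)
        return x


# ---------------------------------------------------------------------------
# Optimizers
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            p.data = p.data - self.lr * (self.m[i] / bc1) / (
                np.sqrt(self.v[i] / bc2) + self.eps)


class SGD:
    def __init__(self, params: list[Tensor], lr: float = 1e-2,
                 momentum: float = 0.0):
        self.params = list(params)
        self.lr, self.momentum = lr, momentum
        self.buf = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.buf[i] = self.momentum * self.buf[i] + p.grad
            p.data = p.data - self.lr * self.buf[i]


def clip_global_norm(params: list[Tensor], max_norm: float) -> float:
    """Scale all gradients so their joint L2 norm is at most `max_norm`."""
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad ** 2).sum())
    norm = np.sqrt(total)
    if norm > max_norm and norm > 0:
        scale = max_norm / norm
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return float(norm)
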
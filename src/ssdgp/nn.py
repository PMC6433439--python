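"""Minimal reverse-mode autodiff and the layers the detector is built from.

A deliberately small tape: `Tensor` nodes record their parents and a
closure that routes the upstream gradient; `Tensor.backward()` walks the
graph in reverse topological order. Heavy lifting (convolution taps,
batch-norm statistics) is plain numpy; convolutions are computed one
kernel tap at a time as a GEMM, which keeps memory flat and is fast
enough for the desk-scale networks this package trains on a CPU.

Gradient contract of the order-statistic pooling layer: every output
cell routes its gradient to the input cell it was selected from; among
cells tied at the selected value, the first in row-major order receives
it (the usual argmax-pooling convention, extended to arbitrary rank).
"""

from __future__ import annotations

import contextlib

import numpy as np

from .pooling import PoolSpec, rank_pool_with_indices

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference / memory-light forward)."""
    global _grad_enabled
    prev, _grad_enabled = _grad_enabled, False
    try:
        yield
    finally:
        _grad_enabled = prev


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() expects a scalar loss")
        topo, seen = [], set()

        def dfs(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                dfs(p)
            topo.append(t)

        dfs(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)


def _node(data, parents, backward):
    """Result tensor; joins the tape only while gradients are enabled."""
    req = _grad_enabled and any(p.requires_grad for p in parents)
    if not req:
        return Tensor(data)
    return Tensor(data, requires_grad=True, parents=parents, backward=backward)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


# ---------------------------------------------------------------- ops


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride=1, padding=0, dilation=1) -> Tensor:
    """2-D convolution, NCHW; weights (out, in, kh, kw)."""
    n, c, h, wd = x.shape
    f, _, kh, kw = w.shape
    s, p, d = stride, padding, dilation
    oh = (h + 2 * p - d * (kh - 1) - 1) // s + 1
    ow = (wd + 2 * p - d * (kw - 1) - 1) // s + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data

    acc = np.zeros((n, oh, ow, f), dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            xt = xp[:, :, i * d : i * d + (oh - 1) * s + 1 : s, j * d : j * d + (ow - 1) * s + 1 : s]
            acc += np.tensordot(xt, w.data[:, :, i, j], axes=([1], [1]))
    if b is not None:
        acc += b.data
    y = np.ascontiguousarray(acc.transpose(0, 3, 1, 2))

    def backward(gy):
        gyt = np.ascontiguousarray(gy.transpose(0, 2, 3, 1))  # (n, oh, ow, f)
        if x.requires_grad:
            gxp = np.zeros_like(xp)
        gw = np.zeros_like(w.data) if w.requires_grad else None
        for i in range(kh):
            for j in range(kw):
                rs = slice(i * d, i * d + (oh - 1) * s + 1, s)
                cs = slice(j * d, j * d + (ow - 1) * s + 1, s)
                if gw is not None:
                    xt = xp[:, :, rs, cs]
                    gw[:, :, i, j] = np.tensordot(gyt, xt, axes=([0, 1, 2], [0, 2, 3]))
                if x.requires_grad:
                    gxp[:, :, rs, cs] += np.tensordot(gyt, w.data[:, :, i, j], axes=([3], [0])).transpose(0, 3, 1, 2)
        if x.requires_grad:
            x._accum(gxp[:, :, p : p + h, p : p + wd] if p else gxp)
        if gw is not None:
            w._accum(gw)
        if b is not None and b.requires_grad:
            b._accum(gy.sum(axis=(0, 2, 3)))

    parents = (x, w) + ((b,) if b is not None else ())
    return _node(y, parents, backward)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None, stride=2) -> Tensor:
    """Transposed (fractionally-strided) convolution; weights (in, out, kh, kw)."""
    n, c, h, wd = x.shape
    _, f, kh, kw = w.shape
    s = stride
    oh, ow = (h - 1) * s + kh, (wd - 1) * s + kw
    y = np.zeros((n, f, oh, ow), dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            contrib = np.tensordot(x.data, w.data[:, :, i, j], axes=([1], [0]))  # (n, h, w, f)
            y[:, :, i : i + (h - 1) * s + 1 : s, j : j + (wd - 1) * s + 1 : s] += contrib.transpose(0, 3, 1, 2)
    if b is not None:
        y += b.data[None, :, None, None]

    def backward(gy):
        gw = np.zeros_like(w.data) if w.requires_grad else None
        gx = np.zeros_like(x.data) if x.requires_grad else None
        for i in range(kh):
            for j in range(kw):
                gslice = gy[:, :, i : i + (h - 1) * s + 1 : s, j : j + (wd - 1) * s + 1 : s]
                gyt = gslice.transpose(0, 2, 3, 1)  # (n, h, w, f)
                if gx is not None:
                    gx += np.tensordot(gyt, w.data[:, :, i, j], axes=([3], [1])).transpose(0, 3, 1, 2)
                if gw is not None:
                    gw[:, :, i, j] = np.tensordot(x.data, gyt, axes=([0, 2, 3], [0, 1, 2]))
        if gx is not None:
            x._accum(gx)
        if gw is not None:
            w._accum(gw)
        if b is not None and b.requires_grad:
            b._accum(gy.sum(axis=(0, 2, 3)))

    parents = (x, w) + ((b,) if b is not None else ())
    return _node(y, parents, backward)


def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor, state: dict, training: bool,
                 momentum=0.1, eps=1e-5) -> Tensor:
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        state["mean"] = (1 - momentum) * state["mean"] + momentum * mean
        state["var"] = (1 - momentum) * state["var"] + momentum * var
    else:
        mean, var = state["mean"], state["var"]
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None, None]) * inv[None, :, None, None]
    y = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(gy):
        axes = (0, 2, 3)
        if gamma.requires_grad:
            gamma._accum((gy * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta._accum(gy.sum(axis=axes))
        if x.requires_grad:
            gxhat = gy * gamma.data[None, :, None, None]
            if training:
                m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                t1 = gxhat - gxhat.mean(axis=axes, keepdims=True)
                t2 = xhat * (gxhat * xhat).sum(axis=axes, keepdims=True) / m
                x._accum(inv[None, :, None, None] * (t1 - t2))
            else:
                x._accum(gxhat * inv[None, :, None, None])

    return _node(y, (x, gamma, beta), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    y = x.data * mask

    def backward(gy):
        if x.requires_grad:
            x._accum(gy * mask)

    return _node(y, (x,), backward)


def rank_pool2d(x: Tensor, spec: PoolSpec, rank: int) -> Tensor:
    out, idx = rank_pool_with_indices(x.data, spec, rank)
    n, c, h, w = x.shape

    def backward(gy):
        if not x.requires_grad:
            return
        gx = np.zeros((n * c, h * w), dtype=np.float32)
        flat_idx = (idx + (np.arange(n * c) * (h * w)).reshape(n, c, 1, 1)).ravel()
        np.add.at(gx.reshape(-1), flat_idx, gy.ravel())
        x._accum(gx.reshape(n, c, h, w))

    return _node(out, (x,), backward)


def max_pool2d(x: Tensor, kernel=2, stride=2, padding=0, mode="ceil") -> Tensor:
    return rank_pool2d(x, PoolSpec(kernel, stride, padding, mode), 1)


def concat_channels(ts: list[Tensor]) -> Tensor:
    y = np.concatenate([t.data for t in ts], axis=1)
    splits = np.cumsum([t.shape[1] for t in ts])[:-1]

    def backward(gy):
        for t, g in zip(ts, np.split(gy, splits, axis=1)):
            if t.requires_grad:
                t._accum(g)

    return _node(y, tuple(ts), backward)


def l2norm_scale(x: Tensor, gamma: Tensor, eps=1e-10) -> Tensor:
    """Channel-wise L2 normalization with a learned per-channel scale."""
    norm = np.sqrt((x.data ** 2).sum(axis=1, keepdims=True) + eps)
    xhat = x.data / norm
    y = gamma.data[None, :, None, None] * xhat

    def backward(gy):
        if gamma.requires_grad:
            gamma._accum((gy * xhat).sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxhat = gy * gamma.data[None, :, None, None]
            dot = (gxhat * xhat).sum(axis=1, keepdims=True)
            x._accum((gxhat - xhat * dot) / norm)

    return _node(y, (x, gamma), backward)


def _bilinear_matrix(n_in: int, n_out: int) -> np.ndarray:
    """(n_out, n_in) interpolation matrix, half-pixel-center convention."""
    a = np.zeros((n_out, n_in), dtype=np.float32)
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    lo = np.clip(np.floor(src).astype(int), 0, n_in - 1)
    hi = np.clip(lo + 1, 0, n_in - 1)
    frac = np.clip(src - lo, 0.0, 1.0)
    a[np.arange(n_out), lo] += 1 - frac
    a[np.arange(n_out), hi] += frac
    return a


def bilinear_resize(x: Tensor, out_h: int, out_w: int) -> Tensor:
    n, c, h, w = x.shape
    ah, aw = _bilinear_matrix(h, out_h), _bilinear_matrix(w, out_w)
    y = np.einsum("oh,nchw,pw->ncop", ah, x.data, aw, optimize=True)

    def backward(gy):
        if x.requires_grad:
            x._accum(np.einsum("oh,ncop,pw->nchw", ah, gy, aw, optimize=True))

    return _node(y, (x,), backward)


def center_crop(x: Tensor, out_h: int, out_w: int) -> Tensor:
    n, c, h, w = x.shape
    r0, c0 = (h - out_h) // 2, (w - out_w) // 2
    y = x.data[:, :, r0 : r0 + out_h, c0 : c0 + out_w]

    def backward(gy):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            gx[:, :, r0 : r0 + out_h, c0 : c0 + out_w] = gy
            x._accum(gx)

    return _node(np.ascontiguousarray(y), (x,), backward)


def to_box_layout(x: Tensor, d: int) -> Tensor:
    """Head output (N, A*d, H, W) -> (N, H*W*A, d), anchor-major channels."""
    n, ch, h, w = x.shape
    y = x.data.transpose(0, 2, 3, 1).reshape(n, h * w * (ch // d), d)

    def backward(gy):
        if x.requires_grad:
            x._accum(gy.reshape(n, h, w, ch).transpose(0, 3, 1, 2))

    return _node(np.ascontiguousarray(y), (x,), backward)


def concat_rows(ts: list[Tensor]) -> Tensor:
    """Concatenate (N, P_i, d) box layouts along the prior axis."""
    y = np.concatenate([t.data for t in ts], axis=1)
    splits = np.cumsum([t.shape[1] for t in ts])[:-1]

    def backward(gy):
        for t, g in zip(ts, np.split(gy, splits, axis=1)):
            if t.requires_grad:
                t._accum(g)

    return _node(y, tuple(ts), backward)


# ---------------------------------------------------------------- modules


class Module:
    """Tiny layer base: explicit parameter list, shared train/eval flag."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Parameter]:
        return [v for v in vars(self).values() if isinstance(v, Parameter)]

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for k, v in vars(self).items():
            if isinstance(v, Parameter):
                out[k] = v.data
            elif isinstance(v, dict) and k == "state":
                out.update({f"state.{sk}": sv for sk, sv in v.items()})
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for k, v in arrays.items():
            if k.startswith("state."):
                self.state[k[6:]] = v.astype(np.float32)
            else:
                p = getattr(self, k)
                if p.data.shape != v.shape:
                    raise ValueError(f"shape mismatch for {k}: {p.data.shape} vs {v.shape}")
                p.data = v.astype(np.float32)


def xavier_uniform(rng: np.random.Generator, shape, fan_in, fan_out) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, cin, cout, kernel, rng, stride=1, padding=0, dilation=1, bias=True):
        super().__init__()
        self.stride, self.padding, self.dilation = stride, padding, dilation
        k = kernel
        self.weight = Parameter(xavier_uniform(rng, (cout, cin, k, k), cin * k * k, cout * k * k))
        self.bias = Parameter(np.zeros(cout, dtype=np.float32)) if bias else None

    def parameters(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def state_arrays(self):
        out = {"weight": self.weight.data}
        if self.bias is not None:
            out["bias"] = self.bias.data
        return out

    def load_state_arrays(self, arrays):
        self.weight.data = arrays["weight"].astype(np.float32)
        if self.bias is not None:
            self.bias.data = arrays["bias"].astype(np.float32)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding, self.dilation)


class ConvTranspose2d(Module):
    def __init__(self, cin, cout, kernel, rng, stride=2, bias=True):
        super().__init__()
        self.stride = stride
        k = kernel
        self.weight = Parameter(xavier_uniform(rng, (cin, cout, k, k), cin * k * k, cout * k * k))
        self.bias = Parameter(np.zeros(cout, dtype=np.float32)) if bias else None

    def parameters(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def state_arrays(self):
        out = {"weight": self.weight.data}
        if self.bias is not None:
            out["bias"] = self.bias.data
        return out

    def load_state_arrays(self, arrays):
        self.weight.data = arrays["weight"].astype(np.float32)
        if self.bias is not None:
            self.bias.data = arrays["bias"].astype(np.float32)

    def __call__(self, x: Tensor) -> Tensor:
        return conv_transpose2d(x, self.weight, self.bias, self.stride)


class BatchNorm2d(Module):
    def __init__(self, c, momentum=0.1, eps=1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.gamma = Parameter(np.ones(c, dtype=np.float32))
        self.beta = Parameter(np.zeros(c, dtype=np.float32))
        self.state = {"mean": np.zeros(c, dtype=np.float32), "var": np.ones(c, dtype=np.float32)}

    def __call__(self, x: Tensor) -> Tensor:
        return batch_norm2d(x, self.gamma, self.beta, self.state, self.training,
                            self.momentum, self.eps)


class L2NormScale(Module):
    def __init__(self, c, init_scale=20.0):
        super().__init__()
        self.gamma = Parameter(np.full(c, init_scale, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        return l2norm_scale(x, self.gamma)


class SGD:
    """Stochastic gradient descent with momentum and weight decay."""

    def __init__(self, params: list[Parameter], lr: float, momentum=0.9, weight_decay=0.0):
        self.params = params
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self.velocity = [np.zeros_like(p.data) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v
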
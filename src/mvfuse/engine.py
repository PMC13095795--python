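"""Minimal reverse-mode automatic differentiation engine on NumPy arrays.

The package trains small CNNs and differentiates class scores with respect to
intermediate convolutional activations (for Grad-CAM), so the engine keeps the
full computation graph and accumulates gradients on every node, not only on
leaves.  All arithmetic is float32; graphs are built eagerly and freed when the
root :class:`Tensor` goes out of scope.

Only the operations the model zoo needs are implemented: broadcasting
elementwise arithmetic, matmul, 2-D convolution (grouped), max pooling,
reductions, a few activations, dropout, concatenation and row gather/scatter
(used to route incomplete view triplets through a shared encoder).
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

# Global RNG used for parameter init and dropout unless a layer is handed its
# own generator.  trainer.set_global_seed replaces it.
_GLOBAL_RNG = np.random.default_rng(0)


def get_rng() -> np.random.Generator:
    return _GLOBAL_RNG


def set_rng(rng: np.random.Generator) -> None:
    global _GLOBAL_RNG
    _GLOBAL_RNG = rng


def _needs_grad(t: "Tensor") -> bool:
    """Whether a backward closure must produce a gradient for `t`."""
    return t.requires_grad or bool(t._prev)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = _prev

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None, free_graph: bool = True) -> None:
        """Backpropagate from this node through the whole graph.

        With `free_graph` (default) the graph edges and closures are released
        afterwards, breaking the reference cycles between nodes and their
        backward closures; gradients stay available, but a second backward
        pass through the same graph is not possible.
        """
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=np.float32).copy()
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()
        if free_graph:
            for node in topo:
                node._backward = None
                node._prev = ()

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def _bwd():
            if _needs_grad(self):
                self._accumulate(_unbroadcast(out.grad, self.data.shape))
            if _needs_grad(other):
                other._accumulate(_unbroadcast(out.grad, other.data.shape))

        out._backward = _bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _prev=(self,))
        out._backward = lambda: self._accumulate(-out.grad)
        return out

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def _bwd():
            if _needs_grad(self):
                self._accumulate(_unbroadcast(out.grad * other.data, self.data.shape))
            if _needs_grad(other):
                other._accumulate(_unbroadcast(out.grad * self.data, other.data.shape))

        out._backward = _bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def _bwd():
            if _needs_grad(self):
                self._accumulate(_unbroadcast(out.grad / other.data, self.data.shape))
            if _needs_grad(other):
                other._accumulate(
                    _unbroadcast(-out.grad * self.data / (other.data**2),
                                 other.data.shape))

        out._backward = _bwd
        return out

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, _prev=(self,))

        def _bwd():
            self._accumulate(out.grad * exponent * self.data ** (exponent - 1))

        out._backward = _bwd
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def _bwd():
            self._accumulate(out.grad @ other.data.T)
            other._accumulate(self.data.T @ out.grad)

        out._backward = _bwd
        return out

    __matmul__ = matmul

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _prev=(self,))
        out._backward = lambda: self._accumulate(out.grad.reshape(self.data.shape))
        return out

    def transpose(self, axes: Sequence[int]) -> "Tensor":
        out = Tensor(self.data.transpose(axes), _prev=(self,))
        inv = np.argsort(axes)
        out._backward = lambda: self._accumulate(out.grad.transpose(inv))
        return out

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def _bwd():
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))

        out._backward = _bwd
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- activations -------------------------------------------------------
    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))
        out._backward = lambda: self._accumulate(out.grad * (self.data > 0))
        return out

    def relu6(self) -> "Tensor":
        out = Tensor(np.clip(self.data, 0.0, 6.0), _prev=(self,))
        out._backward = lambda: self._accumulate(
            out.grad * ((self.data > 0) & (self.data < 6))
        )
        return out

    def tanh(self) -> "Tensor":
        y = np.tanh(self.data)
        out = Tensor(y, _prev=(self,))
        out._backward = lambda: self._accumulate(out.grad * (1.0 - y * y))
        return out

    def sigmoid(self) -> "Tensor":
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, _prev=(self,))
        out._backward = lambda: self._accumulate(out.grad * y * (1.0 - y))
        return out

    def exp(self) -> "Tensor":
        y = np.exp(self.data)
        out = Tensor(y, _prev=(self,))
        out._backward = lambda: self._accumulate(out.grad * y)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), _prev=(self,))
        out._backward = lambda: self._accumulate(out.grad / self.data)
        return out


# ---------------------------------------------------------------------------
# Functional operations
# ---------------------------------------------------------------------------


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bwd():
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * out.grad.ndim
            sl[axis] = slice(a, b)
            t._accumulate(out.grad[tuple(sl)])

    out._backward = _bwd
    return out


def gather_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    """Select rows `idx` along axis 0."""
    out = Tensor(x.data[idx], _prev=(x,))

    def _bwd():
        g = np.zeros_like(x.data)
        np.add.at(g, idx, out.grad)
        x._accumulate(g)

    out._backward = _bwd
    return out


def scatter_rows(x: Tensor, idx: np.ndarray, n: int) -> Tensor:
    """Place rows of `x` at positions `idx` in a zero tensor with `n` rows."""
    data = np.zeros((n,) + x.data.shape[1:], dtype=np.float32)
    data[idx] = x.data
    out = Tensor(data, _prev=(x,))
    out._backward = lambda: x._accumulate(out.grad[idx])
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding: int = 0, groups: int = 1) -> Tensor:
    """2-D convolution, NCHW layout, square stride/padding."""
    N, C, H, W = x.data.shape
    O, Cg, kh, kw = w.data.shape
    s, p = int(stride), int(padding)
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    Ho = (H + 2 * p - kh) // s + 1
    Wo = (W + 2 * p - kw) // s + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::s, ::s]  # (N, C, Ho, Wo, kh, kw)

    if groups == 1:
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            N * Ho * Wo, C * kh * kw
        )
        wmat = w.data.reshape(O, Cg * kh * kw)
        out_d = (cols @ wmat.T).reshape(N, Ho, Wo, O).transpose(0, 3, 1, 2)
    else:
        wing = win.reshape(N, groups, C // groups, Ho, Wo, kh, kw)
        wg = w.data.reshape(groups, O // groups, Cg, kh, kw)
        out_d = np.einsum("ngchwij,gocij->ngohw", wing, wg, optimize=True)
        out_d = out_d.reshape(N, O, Ho, Wo)
    if b is not None:
        out_d = out_d + b.data.reshape(1, -1, 1, 1)

    prev = (x, w) if b is None else (x, w, b)
    out = Tensor(out_d, _prev=prev)

    def _bwd():
        dout = out.grad
        need_x = _needs_grad(x)
        if b is not None:
            b._accumulate(dout.sum(axis=(0, 2, 3)))
        if groups == 1:
            dout2 = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(-1, O)
            w._accumulate((dout2.T @ cols).reshape(w.data.shape))
            if not need_x:
                return
            dcols = (dout2 @ wmat).reshape(N, Ho, Wo, C, kh, kw).transpose(0, 3, 1, 2, 4, 5)
        else:
            dg = dout.reshape(N, groups, O // groups, Ho, Wo)
            w._accumulate(
                np.einsum("ngohw,ngchwij->gocij", dg, wing, optimize=True).reshape(w.data.shape)
            )
            if not need_x:
                return
            dcols = np.einsum("ngohw,gocij->ngchwij", dg, wg, optimize=True).reshape(
                N, C, Ho, Wo, kh, kw
            )
        dxp = np.zeros((N, C, H + 2 * p, W + 2 * p), dtype=np.float32)
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i : i + s * Ho : s, j : j + s * Wo : s] += dcols[:, :, :, :, i, j]
        x._accumulate(dxp[:, :, p : p + H, p : p + W] if p else dxp)

    out._backward = _bwd
    return out


def max_pool2d(x: Tensor, kernel: int = 2, stride: int | None = None,
               padding: int = 0) -> Tensor:
    s = stride or kernel
    k, p = int(kernel), int(padding)
    N, C, H, W = x.data.shape
    if k == 2 and s == 2 and p == 0 and H % 2 == 0 and W % 2 == 0:
        return _max_pool2x2(x)
    if p:
        xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
    else:
        xp = x.data
    Ho = (H + 2 * p - k) // s + 1
    Wo = (W + 2 * p - k) // s + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
    flat = win.reshape(N, C, Ho, Wo, k * k)
    idx = flat.argmax(axis=-1)
    out = Tensor(np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0], _prev=(x,))

    def _bwd():
        if not _needs_grad(x):
            return
        dxp = np.zeros((N, C, H + 2 * p, W + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                sel = idx == (i * k + j)
                dxp[:, :, i : i + s * Ho : s, j : j + s * Wo : s] += out.grad * sel
        x._accumulate(dxp[:, :, p : p + H, p : p + W] if p else dxp)

    out._backward = _bwd
    return out


def _max_pool2x2(x: Tensor) -> Tensor:
    """Fast non-overlapping 2x2 pooling; ties resolve to the first window
    position, matching the generic path."""
    cand = [x.data[:, :, i::2, j::2] for i in (0, 1) for j in (0, 1)]
    stacked = np.stack(cand)
    idx = stacked.argmax(axis=0)
    out = Tensor(np.take_along_axis(stacked, idx[None], axis=0)[0], _prev=(x,))

    def _bwd():
        if not _needs_grad(x):
            return
        dx = np.zeros_like(x.data)
        for pos, (i, j) in enumerate(((0, 0), (0, 1), (1, 0), (1, 1))):
            dx[:, :, i::2, j::2] += out.grad * (idx == pos)
        x._accumulate(dx)

    out._backward = _bwd
    return out


def global_avg_pool(x: Tensor) -> Tensor:
    """Spatial mean of an NCHW feature map -> (N, C)."""
    return x.mean(axis=(2, 3))


def dropout(x: Tensor, p: float, training: bool, rng: np.random.Generator | None = None) -> Tensor:
    if not training or p <= 0.0:
        return x
    rng = rng or _GLOBAL_RNG
    mask = (rng.random(x.data.shape) >= p).astype(np.float32) / (1.0 - p)
    return x * Tensor(mask)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy over a batch; fused stable softmax."""
    z = logits.data
    zmax = z.max(axis=1, keepdims=True)
    ez = np.exp(z - zmax)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = z.shape[0]
    nll = -np.log(np.maximum(probs[np.arange(n), labels], 1e-12)).mean()
    out = Tensor(nll, _prev=(logits,))

    def _bwd():
        g = probs.copy()
        g[np.arange(n), labels] -= 1.0
        logits._accumulate(out.grad * g / n)

    out._backward = _bwd
    return out


# ---------------------------------------------------------------------------
# Module system
# ---------------------------------------------------------------------------


class Parameter(Tensor):
    """Learnable tensor; `trainable=False` marks it frozen for the optimizer."""

    __slots__ = ("trainable",)

    def __init__(self, data, trainable: bool = True):
        super().__init__(data, requires_grad=True)
        self.trainable = trainable


class Module:
    def __init__(self):
        self.training = True

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def modules(self) -> list:
        out = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                out.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.modules())
        return out

    def named_parameters(self, prefix: str = "") -> list:
        out = []
        for name, v in self.__dict__.items():
            full = f"{prefix}{name}"
            if isinstance(v, Parameter):
                out.append((full, v))
            elif isinstance(v, Module):
                out.extend(v.named_parameters(full + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(f"{full}.{i}."))
                    elif isinstance(item, Parameter):
                        out.append((f"{full}.{i}", item))
        return out

    def parameters(self) -> list:
        return [p for _, p in self.named_parameters()]

    def named_modules(self, prefix: str = "") -> list:
        out = [(prefix.rstrip("."), self)]
        for name, v in self.__dict__.items():
            if isinstance(v, Module):
                out.extend(v.named_modules(f"{prefix}{name}."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.extend(item.named_modules(f"{prefix}{name}.{i}."))
        return out

    def named_buffers(self) -> list:
        """Non-learnable state (e.g. batch-norm running statistics)."""
        out = []
        for mname, m in self.named_modules():
            for bname in getattr(m, "_buffer_names", ()):
                full = f"{mname}.{bname}" if mname else bname
                out.append((full, m, bname))
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        out = {name: p.data.copy() for name, p in self.named_parameters()}
        for full, m, bname in self.named_buffers():
            out[full] = getattr(m, bname).copy()
        return out

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        buffers = {full: (m, bname) for full, m, bname in self.named_buffers()}
        missing = (set(own) | set(buffers)) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for name, p in own.items():
            p.data = np.asarray(state[name], dtype=np.float32).copy()
        for full, (m, bname) in buffers.items():
            setattr(m, bname, np.asarray(state[full], dtype=np.float32).copy())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or _GLOBAL_RNG
        bound = 1.0 / math.sqrt(in_features)
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(rng.uniform(-bound, bound, (out_features, in_features)))
        self.bias = Parameter(rng.uniform(-bound, bound, out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return _linear(x, self.weight, self.bias)


def _linear(x: Tensor, w: Parameter, b: Parameter | None) -> Tensor:
    out_d = x.data @ w.data.T
    if b is not None:
        out_d = out_d + b.data
    prev = (x, w) if b is None else (x, w, b)
    out = Tensor(out_d, _prev=prev)

    def _bwd():
        if _needs_grad(x):
            x._accumulate(out.grad @ w.data)
        w._accumulate(out.grad.T @ x.data)
        if b is not None:
            b._accumulate(out.grad.sum(axis=0))

    out._backward = _bwd
    return out


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, groups: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or _GLOBAL_RNG
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kernel_size, self.stride, self.padding, self.groups = (
            kernel_size, stride, padding, groups,
        )
        fan_in = (in_channels // groups) * kernel_size * kernel_size
        std = math.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.weight = Parameter(
            rng.normal(0.0, std, (out_channels, in_channels // groups, kernel_size, kernel_size))
        )
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding, self.groups)

    def out_shape(self, in_shape: tuple) -> tuple:
        c, h, w = in_shape
        ho = (h + 2 * self.padding - self.kernel_size) // self.stride + 1
        wo = (w + 2 * self.padding - self.kernel_size) // self.stride + 1
        return (self.out_channels, ho, wo)

    def macs(self, in_shape: tuple) -> int:
        _, ho, wo = self.out_shape(in_shape)
        per_pos = (self.in_channels // self.groups) * self.kernel_size**2
        return self.out_channels * ho * wo * per_pos


class BatchNorm2d(Module):
    _buffer_names = ("running_mean", "running_var")

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_features = num_features
        self.eps, self.momentum = eps, momentum
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        # fused forward/backward (closed-form BN gradient)
        w, b = self.weight, self.bias
        if self.training:
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        inv_sd = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        xhat = (x.data - mu.reshape(1, -1, 1, 1)) * inv_sd.reshape(1, -1, 1, 1)
        out = Tensor(xhat * w.data.reshape(1, -1, 1, 1) + b.data.reshape(1, -1, 1, 1),
                     _prev=(x, w, b))
        batch_stats = self.training

        def _bwd():
            dout = out.grad
            dbeta = dout.sum(axis=(0, 2, 3))
            dgamma = (dout * xhat).sum(axis=(0, 2, 3))
            w._accumulate(dgamma)
            b._accumulate(dbeta)
            if not _needs_grad(x):
                return
            scale = (w.data * inv_sd).reshape(1, -1, 1, 1)
            if batch_stats:
                m = dout.shape[0] * dout.shape[2] * dout.shape[3]
                dx = scale * (dout - (dbeta / m).reshape(1, -1, 1, 1)
                              - xhat * (dgamma / m).reshape(1, -1, 1, 1))
            else:
                dx = scale * dout
            x._accumulate(dx)

        out._backward = _bwd
        return out


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class ReLU6(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu6()


class MaxPool2d(Module):
    def __init__(self, kernel_size: int, stride: int | None = None, padding: int = 0):
        super().__init__()
        self.kernel_size = kernel_size
        self.stride = stride or kernel_size
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return max_pool2d(x, self.kernel_size, self.stride, self.padding)

    def out_shape(self, in_shape: tuple) -> tuple:
        c, h, w = in_shape
        ho = (h + 2 * self.padding - self.kernel_size) // self.stride + 1
        wo = (w + 2 * self.padding - self.kernel_size) // self.stride + 1
        return (c, ho, wo)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x

    def __iter__(self):
        return iter(self.layers)

    def __getitem__(self, i):
        return self.layers[i]


class Dropout(Module):
    def __init__(self, p: float = 0.5):
        super().__init__()
        self.p = p

    def forward(self, x: Tensor) -> Tensor:
        return dropout(x, self.p, self.training)
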
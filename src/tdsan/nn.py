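"""Minimal reverse-mode autodiff on numpy arrays, with the handful of neural
layers the sleep-staging network needs.

The engine is tape-based: every op returns a :class:`Tensor` holding the
result, its parents and a closure that accumulates gradients into them.
``Tensor.backward()`` topologically sorts the tape and runs the closures.
Only the operations the model actually uses are implemented (batched matmul,
1-D convolution, batch norm, max pooling, softmax, elementwise arithmetic);
this is not a general framework.

All arithmetic is float32; randomness is always injected through an explicit
``numpy.random.Generator`` so training is bit-reproducible single-threaded.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Conv1d",
    "BatchNorm1d",
    "Linear",
    "MaxPool1d",
    "LeakyReLU",
    "Adam",
    "leaky_relu",
    "softmax",
    "log_softmax",
    "log",
    "clip",
]

_DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
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
    """A numpy array plus the tape bookkeeping needed for backprop."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(
        self,
        data,
        parents: Sequence["Tensor"] = (),
        backward: Callable[[np.ndarray], None] | None = None,
        requires_grad: bool = False,
    ):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad: np.ndarray | None = None
        self._parents = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    # -- graph -------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if id(node) in seen:
                continue
            if expanded:
                seen.add(id(node))
                topo.append(node)
                continue
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = grad.astype(_DTYPE, copy=True)
        else:
            self.grad += grad

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)

        def bwd(g):
            self._accum(_unbroadcast(g, self.shape))
            other._accum(_unbroadcast(g, other.shape))

        return Tensor(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accum(-g)

        return Tensor(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def bwd(g):
            self._accum(_unbroadcast(g * other.data, self.shape))
            other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def matmul(self, other: "Tensor") -> "Tensor":
        """Batched matrix product (numpy @ semantics, equal batch dims)."""
        other = as_tensor(other)

        def bwd(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            self._accum(_unbroadcast(ga, self.shape))
            other._accum(_unbroadcast(gb, other.shape))

        return Tensor(self.data @ other.data, (self, other), bwd)

    __matmul__ = matmul

    def transpose(self, *axes: int) -> "Tensor":
        inv = np.argsort(axes)

        def bwd(g):
            self._accum(g.transpose(inv))

        return Tensor(self.data.transpose(axes), (self,), bwd)

    def reshape(self, *shape: int) -> "Tensor":
        def bwd(g):
            self._accum(g.reshape(self.shape))

        return Tensor(self.data.reshape(shape), (self,), bwd)

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def bwd(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).astype(_DTYPE))

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def abs(self) -> "Tensor":
        sign = np.sign(self.data)

        def bwd(g):
            self._accum(g * sign)

        return Tensor(np.abs(self.data), (self,), bwd)

    def item(self) -> float:
        return float(self.data)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


class Parameter(Tensor):
    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


# ---------------------------------------------------------------------------
# Functional ops
# ---------------------------------------------------------------------------

def log(x: Tensor) -> Tensor:
    def bwd(g):
        x._accum(g / x.data)

    return Tensor(np.log(x.data), (x,), bwd)


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient passes only through the un-clamped interior."""
    mask = ((x.data >= lo) & (x.data <= hi)).astype(_DTYPE)

    def bwd(g):
        x._accum(g * mask)

    return Tensor(np.clip(x.data, lo, hi), (x,), bwd)


def leaky_relu(x: Tensor, slope: float = 0.1) -> Tensor:
    scale = np.where(x.data > 0, _DTYPE(1.0), _DTYPE(slope))

    def bwd(g):
        x._accum(g * scale)

    return Tensor(x.data * scale, (x,), bwd)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        x._accum(y * (g - dot))

    return Tensor(y, (x,), bwd)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable log-softmax; safe where softmax saturates."""
    z = x.data - x.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out = z - lse
    p = np.exp(out)

    def bwd(g):
        x._accum(g - p * g.sum(axis=axis, keepdims=True))

    return Tensor(out, (x,), bwd)


def _conv1d_forward(x: np.ndarray, w: np.ndarray, pad: int):
    """'same'-padded stride-1 cross-correlation via a strided column view.

    x: (B, Cin, L); w: (Cout, Cin, k) -> (B, Cout, L), plus the column view
    (B, Cin, k, L) cached for the backward pass.
    """
    k = w.shape[2]
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    cols = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)  # (B,Cin,L,k)
    cols = np.ascontiguousarray(cols.transpose(0, 2, 1, 3))  # (B,L,Cin,k)
    B, L = cols.shape[0], cols.shape[1]
    out = cols.reshape(B * L, -1) @ w.reshape(w.shape[0], -1).T
    return out.reshape(B, L, -1).transpose(0, 2, 1), cols


def conv1d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """1-D convolution, stride 1, zero 'same' padding (odd or even kernel)."""
    k = w.data.shape[2]
    pad_l = (k - 1) // 2
    pad_r = k - 1 - pad_l
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad_l, pad_r)))
    cols = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)  # (B,Cin,L,k)
    B, Cin, L, _ = cols.shape
    cols2 = np.ascontiguousarray(cols.transpose(0, 2, 1, 3)).reshape(B * L, Cin * k)
    Cout = w.data.shape[0]
    out = cols2 @ w.data.reshape(Cout, -1).T  # (B*L, Cout)
    out = out.reshape(B, L, Cout).transpose(0, 2, 1) + b.data[None, :, None]

    def bwd(g):
        # g: (B, Cout, L)
        g2 = g.transpose(0, 2, 1).reshape(B * L, Cout)
        if w.requires_grad:
            w._accum((g2.T @ cols2).reshape(w.shape))
        if b.requires_grad:
            b._accum(g.sum(axis=(0, 2)))
        if x.requires_grad:
            dcols = (g2 @ w.data.reshape(Cout, -1)).reshape(B, L, Cin, k)
            dxp = np.zeros_like(xp)
            for j in range(k):  # k <= 25, cheap fold
                dxp[:, :, j : j + L] += dcols[:, :, :, j].transpose(0, 2, 1)
            x._accum(dxp[:, :, pad_l : pad_l + x.data.shape[2]])

    return Tensor(out, (x, w, b), bwd)


def max_pool1d(x: Tensor, k: int) -> Tensor:
    """Non-overlapping max pooling, kernel == stride == k, floor division."""
    B, C, L = x.data.shape
    Lo = L // k
    xv = x.data[:, :, : Lo * k].reshape(B, C, Lo, k)
    arg = xv.argmax(axis=3)
    out = np.take_along_axis(xv, arg[..., None], axis=3)[..., 0]

    def bwd(g):
        dxv = np.zeros((B, C, Lo, k), dtype=_DTYPE)
        np.put_along_axis(dxv, arg[..., None], g[..., None], axis=3)
        dx = np.zeros_like(x.data)
        dx[:, :, : Lo * k] = dxv.reshape(B, C, Lo * k)
        x._accum(dx)

    return Tensor(out, (x,), bwd)


def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Batch normalization over all axes but the channel axis (axis 1)."""
    axes = (0,) + tuple(range(2, x.data.ndim))
    bshape = (1, -1) + (1,) * (x.data.ndim - 2)
    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        n = x.data.size // x.data.shape[1]
        running_mean *= 1 - momentum
        running_mean += momentum * mu
        running_var *= 1 - momentum
        running_var += momentum * var * (n / max(n - 1, 1))
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(bshape)) * inv.reshape(bshape)
    out = gamma.data.reshape(bshape) * xhat + beta.data.reshape(bshape)

    def bwd(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta._accum(g.sum(axis=axes))
        if x.requires_grad:
            gs = g * gamma.data.reshape(bshape)
            if training:
                n = x.data.size // x.data.shape[1]
                t1 = gs.sum(axis=axes, keepdims=True)
                t2 = (gs * xhat).sum(axis=axes, keepdims=True)
                dx = (gs - t1 / n - xhat * t2 / n) * inv.reshape(bshape)
            else:
                dx = gs * inv.reshape(bshape)
            x._accum(dx.astype(_DTYPE))

    return Tensor(out, (x, gamma, beta), bwd)


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

def _fan_in_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(_DTYPE)


class Module:
    """Base container: recursive parameter collection and train/eval mode."""

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        for v in vars(self).values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def set_training(self, flag: bool) -> None:
        for v in vars(self).values():
            if isinstance(v, Module):
                v.set_training(flag)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.set_training(flag)
        if hasattr(self, "training"):
            self.training = flag

    def state_arrays(self, prefix: str = "") -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for name, v in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(v, Parameter):
                out[key] = v.data
            elif isinstance(v, np.ndarray):
                out[key] = v
            elif isinstance(v, Module):
                out.update(v.state_arrays(f"{key}."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.update(item.state_arrays(f"{key}.{i}."))
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, v in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(v, Parameter):
                v.data = state[key].astype(_DTYPE).reshape(v.data.shape)
            elif isinstance(v, np.ndarray):
                v[...] = state[key]
            elif isinstance(v, Module):
                v.load_state_arrays(state, f"{key}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item.load_state_arrays(state, f"{key}.{i}.")


class Conv1d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        fan_in = cin * k
        self.weight = Parameter(_fan_in_uniform(rng, (cout, cin, k), fan_in))
        self.bias = Parameter(_fan_in_uniform(rng, (cout,), fan_in))

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias)


class BatchNorm1d(Module):
    def __init__(self, c: int):
        self.gamma = Parameter(np.ones(c, dtype=_DTYPE))
        self.beta = Parameter(np.zeros(c, dtype=_DTYPE))
        self.running_mean = np.zeros(c, dtype=_DTYPE)
        self.running_var = np.ones(c, dtype=_DTYPE)
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        return batch_norm(
            x, self.gamma, self.beta, self.running_mean, self.running_var, self.training
        )


class Linear(Module):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator):
        self.weight = Parameter(_fan_in_uniform(rng, (nin, nout), nin))
        self.bias = Parameter(_fan_in_uniform(rng, (nout,), nin))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class MaxPool1d(Module):
    def __init__(self, k: int):
        self.k = k

    def __call__(self, x: Tensor) -> Tensor:
        return max_pool1d(x, self.k)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.1):
        self.slope = slope

    def __call__(self, x: Tensor) -> Tensor:
        return leaky_relu(x, self.slope)


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with the standard defaults (beta1 .9, beta2 .999, eps 1e-8)."""

    def __init__(self, params: Sequence[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
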
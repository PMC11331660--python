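"""Neural-network building blocks over :mod:`clms.autodiff`.

Modules follow the familiar container pattern: a :class:`Module` owns named
:class:`Parameter` leaves and sub-modules, exposes ``parameters()`` /
``state_dict()`` and a train/eval switch (batch-norm is the only layer that
cares).  The :class:`Adam` optimizer updates parameter arrays in place from
gradients returned by :func:`clms.autodiff.grad`.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float64), requires_grad=True)


class Module:
    def __init__(self):
        self._modules: dict[str, "Module"] = {}
        self._params: dict[str, Parameter] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for mname, mod in self._modules.items():
            yield from mod.named_parameters(prefix + mname + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    # -- (de)serialization -------------------------------------------------
    def state_dict(self) -> dict:
        out = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            out[name] = buf.copy()
        return out

    def load_state_dict(self, state: dict):
        for name, p in self.named_parameters():
            p.data[...] = state[name]
        for name, _ in self.named_buffers():
            self._set_buffer(name, state[name])

    def named_buffers(self, prefix: str = ""):
        for name in getattr(self, "_buffer_names", ()):
            yield prefix + name, getattr(self, name)
        for mname, mod in self._modules.items():
            yield from mod.named_buffers(prefix + mname + ".")

    def _set_buffer(self, dotted: str, value):
        obj = self
        parts = dotted.split(".")
        for part in parts[:-1]:
            obj = obj._modules[part]
        getattr(obj, parts[-1])[...] = value

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


# ---------------------------------------------------------------------------
# parameter vector view — the θ index space of the quadratic penalties
# ---------------------------------------------------------------------------

def flatten_params(model: Module) -> np.ndarray:
    """Stable flat view of all trainable scalars (order = named_parameters)."""
    return np.concatenate([p.data.ravel() for p in model.parameters()]) \
        if model.parameters() else np.zeros(0)


def load_flat_params(model: Module, flat: np.ndarray):
    i = 0
    for p in model.parameters():
        n = p.data.size
        p.data[...] = flat[i:i + n].reshape(p.data.shape)
        i += n
    if i != flat.size:
        raise ValueError(f"flat vector has {flat.size} entries, model needs {i}")


def count_parameters(model: Module) -> int:
    """Exact count of trainable scalars (independent of any layer bookkeeping)."""
    return int(sum(p.data.size for p in model.parameters()))


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

def _kaiming(rng, fan_in, shape):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng=None, bias: bool = True):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(_kaiming(rng, in_features, (out_features, in_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = ad.einsum("ni,oi->no", x, self.weight)
        if self.bias is not None:
            y = y + self.bias
        return y


class Conv1d(Module):
    def __init__(self, in_channels, out_channels, kernel_size, stride=1,
                 padding="same", rng=None, bias: bool = True):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.kernel_size = kernel_size
        # "same"-style padding keeps out_len == ceil(in_len / stride)
        self.padding = (kernel_size - 1) // 2 if padding == "same" else int(padding)
        fan_in = in_channels * kernel_size
        self.weight = Parameter(_kaiming(rng, fan_in, (out_channels, in_channels, kernel_size)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        p = self.padding
        k, s = self.kernel_size, self.stride
        pad_r = p + (s - 1)  # guarantee coverage of the tail for any stride
        xp = ad.pad_last(x, p, pad_r)
        target = -(-x.shape[-1] // s)
        u = ad.unfold1d(xp, k, s)
        if u.shape[2] > target:
            u = ad.slice_axis(u, 0, target, axis=2)
        y = ad.einsum("nclk,ock->nol", u, self.weight)
        if self.bias is not None:
            y = y + ad.reshape(self.bias, (1, -1, 1))
        return y


class BatchNorm(Module):
    """Batch normalization for (N, F) or (N, C, L) inputs (axis 1 = feature)."""

    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self._buffer_names = ("running_mean", "running_var")

    def forward(self, x: Tensor) -> Tensor:
        axes = (0,) if x.ndim == 2 else (0, 2)
        shape = (1, -1) if x.ndim == 2 else (1, -1, 1)
        if self.training:
            mu = ad.mean_(x, axis=axes, keepdims=True)
            var = ad.mean_((x - mu) ** 2, axis=axes, keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.ravel())
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.ravel())
        else:
            mu = Tensor(self.running_mean.reshape(shape))
            var = Tensor(self.running_var.reshape(shape))
        xhat = (x - mu) / ad.sqrt(var + Tensor(self.eps))
        return xhat * ad.reshape(self.gamma, shape) + ad.reshape(self.beta, shape)


class ReLU(Module):
    def forward(self, x):
        return ad.relu(x)


class LeakyReLU(Module):
    def __init__(self, alpha: float = 0.2):
        super().__init__()
        self.alpha = alpha

    def forward(self, x):
        return ad.leaky_relu(x, self.alpha)


class Tanh(Module):
    def forward(self, x):
        return ad.tanh(x)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"l{i}", layer)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, grads):
        """Apply one update from a list of gradient arrays (same order as params)."""
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            g = g.data if isinstance(g, Tensor) else g
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
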
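"""Neural-network modules: parameter containers, conv/BN/linear layers.

Mirrors the familiar Module/Parameter idiom: attributes that are Parameters or
Modules are auto-registered, ``train()``/``eval()`` toggle batch-norm
behaviour, and ``state_dict`` round-trips weights plus batch-norm running
statistics as plain NumPy arrays.
"""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor

__all__ = [
    "Parameter",
    "Module",
    "Sequential",
    "ModuleList",
    "Conv2d",
    "BatchNorm2d",
    "BatchNorm1d",
    "Linear",
    "ReLU",
    "Identity",
    "MaxPool2d",
    "seed_all",
]

_RNG = np.random.default_rng(0)


def seed_all(seed: int) -> None:
    """Reset the RNG used for parameter initialization."""
    global _RNG
    _RNG = np.random.default_rng(seed)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name, value):
        self._buffers[name] = np.asarray(value, dtype=np.float32)
        object.__setattr__(self, name, self._buffers[name])

    def _set_buffer(self, name, value):
        self._buffers[name] = np.asarray(value, dtype=np.float32)
        object.__setattr__(self, name, self._buffers[name])

    # -- traversal ------------------------------------------------------------
    def named_modules(self, prefix=""):
        yield prefix, self
        for name, mod in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from mod.named_modules(sub)

    def named_parameters(self, prefix=""):
        for name, p in self._params.items():
            yield (f"{prefix}.{name}" if prefix else name), p
        for name, mod in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from mod.named_parameters(sub)

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix=""):
        for name in self._buffers:
            yield (f"{prefix}.{name}" if prefix else name), self._buffers[name]
        for name, mod in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from mod.named_buffers(sub)

    # -- modes ----------------------------------------------------------------
    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # -- serialization --------------------------------------------------------
    def state_dict(self):
        state = {f"param:{k}": np.array(p.data) for k, p in self.named_parameters()}
        state.update(
            {f"buffer:{k}": np.array(b) for k, b in self.named_buffers()}
        )
        return state

    def load_state_dict(self, state):
        for k, p in self.named_parameters():
            p.data = np.asarray(state[f"param:{k}"], dtype=np.float32).reshape(p.shape)
        modules = dict(self.named_modules())
        for key, value in state.items():
            if not key.startswith("buffer:"):
                continue
            path = key[len("buffer:"):]
            mod_path, _, name = path.rpartition(".")
            modules[mod_path]._set_buffer(name, value)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        for i, m in enumerate(mods):
            setattr(self, str(i), m)
        self._order = [str(i) for i in range(len(mods))]

    def __iter__(self):
        return (self._modules[k] for k in self._order)

    def __getitem__(self, i):
        return self._modules[self._order[i]]

    def forward(self, x):
        for m in self:
            x = m(x)
        return x


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._order = []
        for m in mods:
            self.append(m)

    def append(self, m):
        name = str(len(self._order))
        setattr(self, name, m)
        self._order.append(name)

    def __iter__(self):
        return (self._modules[k] for k in self._order)

    def __len__(self):
        return len(self._order)

    def __getitem__(self, i):
        return self._modules[self._order[i]]

    def forward(self, x):  # pragma: no cover - containers are iterated
        raise NotImplementedError


class Conv2d(Module):
    def __init__(
        self,
        in_channels,
        out_channels,
        kernel_size,
        stride=1,
        padding=0,
        dilation=1,
        groups=1,
        bias=False,
    ):
        super().__init__()
        kh, kw = (kernel_size, kernel_size) if isinstance(kernel_size, int) else kernel_size
        self.stride, self.padding, self.dilation, self.groups = (
            stride,
            padding,
            dilation,
            groups,
        )
        fan_out = out_channels * kh * kw // groups
        std = float(np.sqrt(2.0 / fan_out))
        self.weight = Parameter(
            _RNG.normal(0.0, std, size=(out_channels, in_channels // groups, kh, kw))
        )
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x):
        return F.conv2d(
            x,
            self.weight,
            self.bias,
            stride=self.stride,
            padding=self.padding,
            dilation=self.dilation,
            groups=self.groups,
        )


class _BatchNorm(Module):
    """Batch standardization with trainable per-feature scale and shift.

    Training mode uses batch statistics and updates exponential running
    estimates; eval mode uses the running estimates.
    """

    def __init__(self, num_features, eps=1e-5, momentum=0.1, affine=True):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.affine = affine
        if affine:
            self.weight = Parameter(np.ones(num_features))
            self.bias = Parameter(np.zeros(num_features))
        self.register_buffer("running_mean", np.zeros(num_features))
        self.register_buffer("running_var", np.ones(num_features))

    def _stats_axes(self, x):
        raise NotImplementedError

    def _shape(self, x):
        raise NotImplementedError

    def forward(self, x):
        axes = self._stats_axes(x)
        shape = self._shape(x)
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean *= 1 - m
            self.running_mean += m * mu.data.reshape(-1)
            self.running_var *= 1 - m
            self.running_var += m * var.data.reshape(-1)
        else:
            mu = Tensor(self.running_mean.reshape(shape))
            var = Tensor(self.running_var.reshape(shape))
        xhat = (x - mu) / (var + self.eps).sqrt()
        if self.affine:
            xhat = xhat * self.weight.reshape(shape) + self.bias.reshape(shape)
        return xhat


class BatchNorm2d(_BatchNorm):
    def _stats_axes(self, x):
        return (0, 2, 3)

    def _shape(self, x):
        return (1, self.num_features, 1, 1)


class BatchNorm1d(_BatchNorm):
    def _stats_axes(self, x):
        return (0,)

    def _shape(self, x):
        return (1, self.num_features)


class Linear(Module):
    def __init__(self, in_features, out_features, bias=True):
        super().__init__()
        bound = float(np.sqrt(1.0 / in_features))
        self.weight = Parameter(
            _RNG.uniform(-bound, bound, size=(out_features, in_features))
        )
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x):
        out = x @ self.weight.transpose(1, 0)
        if self.bias is not None:
            out = out + self.bias
        return out


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Identity(Module):
    def forward(self, x):
        return x


class MaxPool2d(Module):
    def __init__(self, kernel_size=3, stride=2, padding=1):
        super().__init__()
        self.kernel_size, self.stride, self.padding = kernel_size, stride, padding

    def forward(self, x):
        return F.max_pool2d(x, self.kernel_size, self.stride, self.padding)
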
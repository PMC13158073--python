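"""Layer containers, parameter registry and the Adam optimizer.

Modules hold :class:`~dgfinet.autodiff.Tensor` parameters in insertion order;
``named_parameters`` walks the module tree and yields dotted names, which is
the stable registry used for parameter counting and checkpointing.

Weight initialization is Kaiming-uniform (fan-in, ReLU gain) drawn from an
explicit ``numpy.random.Generator`` passed to each constructor, so a model
built twice from the same seed is bit-identical.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

DTYPE = np.float32


def kaiming_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(DTYPE)


class Module:
    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    # registration happens through attribute assignment, torch-style
    def __setattr__(self, name, value):
        if isinstance(value, Tensor):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def named_buffers(self, prefix: str = ""):
        for name, b in self._buffers.items():
            yield prefix + name, b
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Identity(Module):
    def forward(self, x):
        return x


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            self._modules[str(i)] = layer

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Conv2d(Module):
    """Stride-1 same-padded 2-D convolution layer (odd square kernel)."""

    def __init__(self, rng, in_channels, out_channels, kernel_size, *,
                 dilation=1, groups=1, bias=True):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError("groups must divide both channel counts")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.dilation = dilation
        self.groups = groups
        cg = in_channels // groups
        fan_in = cg * kernel_size * kernel_size
        self.weight = Tensor(
            kaiming_uniform(rng, (out_channels, cg, kernel_size, kernel_size), fan_in),
            requires_grad=True,
        )
        self.bias = (
            Tensor(np.zeros(out_channels, dtype=DTYPE), requires_grad=True)
            if bias
            else None
        )

    def forward(self, x):
        return ad.conv2d(
            x, self.weight, self.bias, dilation=self.dilation, groups=self.groups
        )


class ConvTranspose2d2x(Module):
    """2x2 stride-2 transposed convolution (learned 2x upsampling)."""

    def __init__(self, rng, in_channels, out_channels, *, bias=True):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        fan_in = in_channels * 4
        self.weight = Tensor(
            kaiming_uniform(rng, (in_channels, out_channels, 2, 2), fan_in),
            requires_grad=True,
        )
        self.bias = (
            Tensor(np.zeros(out_channels, dtype=DTYPE), requires_grad=True)
            if bias
            else None
        )

    def forward(self, x):
        return ad.conv_transpose2d_2x(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, channels, *, momentum=0.1, eps=1e-5):
        super().__init__()
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.weight = Tensor(np.ones(channels, dtype=DTYPE), requires_grad=True)
        self.bias = Tensor(np.zeros(channels, dtype=DTYPE), requires_grad=True)
        self.register_buffer("running_mean", np.zeros(channels, dtype=np.float64))
        self.register_buffer("running_var", np.ones(channels, dtype=np.float64))

    def forward(self, x):
        return ad.batch_norm(
            x, self.weight, self.bias, self.running_mean, self.running_var,
            training=self.training, momentum=self.momentum, eps=self.eps,
        )


class ReLU(Module):
    def forward(self, x):
        return ad.relu(x)


class ConvBNReLU(Module):
    """conv -> batch norm -> ReLU; the conv is bias-free (BN absorbs shifts)."""

    def __init__(self, rng, in_channels, out_channels, kernel_size, *,
                 dilation=1, groups=1):
        super().__init__()
        self.conv = Conv2d(rng, in_channels, out_channels, kernel_size,
                           dilation=dilation, groups=groups, bias=False)
        self.bn = BatchNorm2d(out_channels)

    def forward(self, x):
        return ad.relu(self.bn(self.conv(x)))


class Adam:
    """Adam over a named-parameter dict (defaults: betas 0.9/0.999, eps 1e-8)."""

    def __init__(self, params: dict[str, Tensor], lr=1e-3,
                 betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.params = dict(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        self._v = {k: np.zeros_like(p.data) for k, p in self.params.items()}

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m = self._m[k]
            v = self._v[k]
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
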
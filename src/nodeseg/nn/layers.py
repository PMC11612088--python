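"""Layer modules built on the autodiff tensor engine.

Layout is channels-first with N spatial dimensions: (batch, channels, *spatial),
with ndim=2 for axial slices / 2.5D stacks and ndim=3 for volume patches.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, batchnorm, conv_nd, conv_transpose2x, matmul, maxpool2

__all__ = ["Module", "Conv", "ConvTranspose2x", "BatchNorm", "Linear",
           "ConvBlock", "Sequential", "MaxPool2"]


class Module:
    """Minimal module: parameter discovery by attribute recursion."""

    training = True

    @staticmethod
    def _children(obj, prefix):
        """Yield (name, value) over attributes, recursing through lists/tuples."""
        if isinstance(obj, Module):
            items = vars(obj).items()
        else:
            items = ((str(i), v) for i, v in enumerate(obj))
        for name, val in items:
            if isinstance(val, (list, tuple)):
                yield from Module._children(val, f"{prefix}{name}.")
            else:
                yield f"{prefix}{name}", val

    def named_parameters(self, prefix: str = ""):
        for name, val in Module._children(self, prefix):
            if isinstance(val, Tensor) and val.requires_grad:
                yield name, val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{name}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, val in Module._children(self, prefix):
            if isinstance(val, np.ndarray):
                yield name, val
            elif isinstance(val, Module):
                yield from val.named_buffers(f"{name}.")

    def modules(self):
        yield self
        for _, val in Module._children(self, ""):
            if isinstance(val, Module):
                yield from val.modules()

    def train(self, flag: bool = True):
        for m in self.modules():
            m.training = flag
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        state = {f"param:{k}": v.data for k, v in self.named_parameters()}
        state.update({f"buffer:{k}": v for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict, strict: bool = True):
        for k, p in self.named_parameters():
            key = f"param:{k}"
            if key in state:
                p.data = np.asarray(state[key], dtype=p.data.dtype)
            elif strict:
                raise KeyError(f"missing parameter {k} in state dict")
        for k, b in self.named_buffers():
            key = f"buffer:{k}"
            if key in state:
                b[...] = state[key]
            elif strict:
                raise KeyError(f"missing buffer {k} in state dict")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)
    return Tensor(w, requires_grad=True)


class Conv(Module):
    """Stride-1 N-D convolution with 'same' padding for odd kernels."""

    def __init__(self, ndim: int, cin: int, cout: int, k: int = 3,
                 dilation: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        if dilation < 1:
            raise ValueError("dilation must be a positive integer")
        self.ndim, self.dilation = ndim, dilation
        self.weight = _he_init(rng, (cout, cin) + (k,) * ndim, cin * k ** ndim)
        self.bias = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True) \
            if bias else None

    def forward(self, x):
        if x.shape[1] != self.weight.shape[1]:
            raise ValueError(
                f"expected {self.weight.shape[1]} input channels, got {x.shape[1]}")
        return conv_nd(x, self.weight, self.bias, dilation=self.dilation)


class ConvTranspose2x(Module):
    """Kernel-2 stride-2 transposed convolution: 2x spatial upsampling."""

    def __init__(self, ndim: int, cin: int, cout: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.weight = _he_init(rng, (cin, cout) + (2,) * ndim, cin * 2 ** ndim)
        self.bias = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)

    def forward(self, x):
        return conv_transpose2x(x, self.weight, self.bias)


class BatchNorm(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x):
        return batchnorm(x, self.gamma, self.beta, self.running_mean,
                         self.running_var, self.training, self.momentum, self.eps)


class Linear(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.weight = _he_init(rng, (cin, cout), cin)
        self.bias = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)

    def forward(self, x):
        return matmul(x, self.weight) + self.bias


class MaxPool2(Module):
    def forward(self, x):
        return maxpool2(x)


class ConvBlock(Module):
    """Convolution + batch normalisation + ReLU.

    The convolution carries no bias: batch normalisation's mean subtraction
    would cancel it exactly, leaving a dead parameter.
    """

    def __init__(self, ndim: int, cin: int, cout: int, k: int = 3,
                 dilation: int = 1, rng: np.random.Generator | None = None):
        self.conv = Conv(ndim, cin, cout, k=k, dilation=dilation, bias=False, rng=rng)
        self.bn = BatchNorm(cout)

    def forward(self, x):
        return self.bn(self.conv(x)).relu()


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x
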
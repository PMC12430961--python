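"""Neural-network building blocks on top of the autodiff engine.

Blocks follow the conventions of modern one-stage detectors: Conv means
convolution + batch norm + SiLU, C2f is the split/bottleneck feature-mixing
block, and all parameters are float32 tensors initialised from an explicit
numpy Generator so model construction is fully seeded.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, concat

__all__ = [
    "Module", "Conv2d", "BatchNorm2d", "ConvBNSiLU", "Bottleneck", "C2f",
    "Linear", "LayerNorm", "SGD", "count_parameters",
]


class Module:
    """Base class: recursively collects Tensor parameters and submodules."""

    def parameters(self):
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def modules(self):
        mods = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                mods.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train_mode(self, flag: bool = True):
        for m in self.modules():
            m.training = flag
        return self

    training = True

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self):
        """Parameters plus persistent buffers (batch-norm running stats)."""
        out = {i: p.data.copy() for i, p in enumerate(self.parameters())}
        for j, m in enumerate(self.modules()):
            if hasattr(m, "running_mean"):
                out[f"b{j}_mean"] = m.running_mean.copy()
                out[f"b{j}_var"] = m.running_var.copy()
        return out

    def load_state_dict(self, state):
        for i, p in enumerate(self.parameters()):
            p.data[...] = state[i]
        for j, m in enumerate(self.modules()):
            if hasattr(m, "running_mean") and f"b{j}_mean" in state:
                m.running_mean[...] = state[f"b{j}_mean"]
                m.running_var[...] = state[f"b{j}_var"]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def count_parameters(module: Module) -> int:
    return int(sum(p.data.size for p in module.parameters()))


class Conv2d(Module):
    """Bare convolution (He-normal init), optional bias."""

    def __init__(self, c_in, c_out, k=1, stride=1, bias=True, rng=None,
                 padding=None):
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * k * k
        self.weight = Tensor(
            rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k)),
            requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True) if bias else None
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride,
                        padding=self.padding)


class BatchNorm2d(Module):
    def __init__(self, c, eps=1e-5, momentum=0.1):
        self.gamma = Tensor(np.ones(c), requires_grad=True)
        self.beta = Tensor(np.zeros(c), requires_grad=True)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.eps = eps
        self.momentum = momentum

    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(c)
            self.running_var = (1 - m) * self.running_var + m * var.data.reshape(c)
        else:
            mu = Tensor(self.running_mean.reshape(1, c, 1, 1))
            var = Tensor(self.running_var.reshape(1, c, 1, 1))
        xhat = (x - mu) / ((var + self.eps) ** 0.5)
        return xhat * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class ConvBNSiLU(Module):
    """k×k convolution + batch norm + SiLU — the detector's basic block."""

    def __init__(self, c_in, c_out, k=3, stride=1, rng=None):
        self.conv = Conv2d(c_in, c_out, k, stride, bias=False, rng=rng)
        self.bn = BatchNorm2d(c_out)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).silu()


class Bottleneck(Module):
    def __init__(self, c, shortcut=True, rng=None):
        self.cv1 = ConvBNSiLU(c, c, 3, rng=rng)
        self.cv2 = ConvBNSiLU(c, c, 3, rng=rng)
        self.shortcut = shortcut

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv2(self.cv1(x))
        return x + y if self.shortcut else y


class C2f(Module):
    """Split-transform-concat block with n bottlenecks on half the channels."""

    def __init__(self, c_in, c_out, n=1, shortcut=True, rng=None):
        self.c_hidden = c_out // 2
        self.cv1 = ConvBNSiLU(c_in, 2 * self.c_hidden, 1, rng=rng)
        self.blocks = [Bottleneck(self.c_hidden, shortcut, rng=rng) for _ in range(n)]
        self.cv2 = ConvBNSiLU((2 + n) * self.c_hidden, c_out, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv1(x)
        c = self.c_hidden
        a = _slice_channels(y, 0, c)
        b = _slice_channels(y, c, 2 * c)
        outs = [a, b]
        for blk in self.blocks:
            outs.append(blk(outs[-1]))
        return self.cv2(concat(outs, axis=1))


def _slice_channels(x: Tensor, lo: int, hi: int) -> Tensor:
    def bw(g):
        full = np.zeros_like(x.data)
        full[:, lo:hi] = g
        x._accum(full)

    return Tensor._make(x.data[:, lo:hi], (x,), bw)


class Linear(Module):
    def __init__(self, d_in, d_out, rng=None, bias=True):
        rng = rng or np.random.default_rng(0)
        self.weight = Tensor(
            rng.normal(0.0, np.sqrt(1.0 / d_in), size=(d_in, d_out)),
            requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x.matmul(self.weight)
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    def __init__(self, d, eps=1e-5):
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) / ((var + self.eps) ** 0.5) * self.gamma + self.beta


class SGD:
    """SGD with momentum and optional weight decay."""

    def __init__(self, params, lr=0.01, momentum=0.9, weight_decay=0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.grad = None
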
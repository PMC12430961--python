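"""Hierarchical feature extractor for strip images.

The backbone follows the familiar one-stage-detector stage layout
(stride-2 convolution then C2f feature mixing per stage) with two
task-specific modifications:

* **S-5 pooling** — five parallel stride-1 max-pool branches with kernels
  1/4/7/10/13 at the deepest stage, channel-concatenated and reduced by a
  1x1 convolution.  The large kernels widen the receptive field while
  stride 1 preserves the fine spatial detail that the narrow chromogenic
  bands require.
* **SimAM attention** — a parameter-free elementwise gate derived from a
  neuron-energy criterion, applied after every C2f block (and after S-5)
  to emphasise locally distinctive activations such as the colour bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Tensor, Module, ConvBNSiLU, C2f, concat

__all__ = [
    "FeatureMap", "S5Config", "SimAMConfig", "S5", "Backbone",
    "simam", "simam_forward", "s5_forward", "multi_kernel_maxpool",
    "backbone_forward",
]

_VALID_STRIDES = (4, 8, 16, 32)


@dataclass
class FeatureMap:
    """An activation array tagged with its pyramid stride.

    `values` may be a raw (C, H, W) / (N, C, H, W) numpy array or an
    autodiff Tensor; `stride` is the downsampling factor vs. the input
    image.
    """

    values: object
    stride: int

    def __post_init__(self):
        if self.stride not in _VALID_STRIDES:
            raise ValueError(f"stride must be one of {_VALID_STRIDES}")

    @property
    def array(self) -> np.ndarray:
        return self.values.data if isinstance(self.values, Tensor) else self.values


@dataclass
class S5Config:
    kernel_sizes: tuple = (1, 4, 7, 10, 13)
    out_channels: int = 128

    def __post_init__(self):
        ks = tuple(self.kernel_sizes)
        if len(ks) != 5 or list(ks) != sorted(ks):
            raise ValueError("S-5 requires exactly five ascending kernel sizes")
        self.kernel_sizes = ks


@dataclass
class SimAMConfig:
    lambda_reg: float = 1e-4

    def __post_init__(self):
        if self.lambda_reg <= 0:
            raise ValueError("lambda_reg must be positive")


def _maxpool_same_np(x: np.ndarray, k: int) -> np.ndarray:
    """Stride-1 max pool with size-preserving padding on an (..., H, W) array.

    Even kernels pad floor((k-1)/2) before and ceil((k-1)/2) after.
    """
    if k == 1:
        return x.copy()
    pa, pb = (k - 1) // 2, k - 1 - (k - 1) // 2
    pad = [(0, 0)] * (x.ndim - 2) + [(pa, pb), (pa, pb)]
    xp = np.pad(x, pad, constant_values=-np.inf)
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(-2, -1))
    return win.max(axis=(-2, -1))


def multi_kernel_maxpool(x: np.ndarray, kernels=(1, 4, 7, 10, 13)) -> np.ndarray:
    """Pre-reduction S-5 stage: concatenate stride-1 max pools of `x`
    (channel axis is -3), giving len(kernels)*C channels."""
    return np.concatenate([_maxpool_same_np(x, k) for k in kernels], axis=-3)


class S5(Module):
    """Five-kernel stride-1 pyramid pooling with 1x1 reduction."""

    def __init__(self, c_in: int, cfg: S5Config, rng=None):
        self.cfg = cfg
        self.reduce = ConvBNSiLU(5 * c_in, cfg.out_channels, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        branches = [x if k == 1 else x.maxpool2d_s1(k)
                    for k in self.cfg.kernel_sizes]
        return self.reduce(concat(branches, axis=1))


def s5_forward(x: FeatureMap, cfg: S5Config, rng=None) -> FeatureMap:
    """Functional S-5: pool, concatenate, reduce.  Spatial size unchanged."""
    v = x.values if isinstance(x.values, Tensor) else Tensor(np.asarray(x.values))
    if v.ndim == 3:
        v = v.reshape((1,) + v.shape)
    block = S5(v.shape[1], cfg, rng=rng)
    return FeatureMap(block(v), x.stride)


def simam(x, lambda_reg: float = 1e-4):
    """Parameter-free SimAM gate.

    Per channel, with spatial mean mu and (population) variance s2, each
    activation t is gated by sigmoid(1/e*) where the minimal neuron energy
    is e* = 4(s2+lambda)/((t-mu)^2 + 2 s2 + 2 lambda).  A constant channel
    therefore receives the uniform gate sigmoid(0.5).  Works on numpy
    arrays and autodiff Tensors; shape (N, C, H, W) or (C, H, W).
    """
    tensor_in = isinstance(x, Tensor)
    v = x if tensor_in else np.asarray(x, dtype=np.float32)
    squeeze = v.ndim == 3
    if squeeze:
        v = v.reshape((1,) + tuple(v.shape))
    if v.shape[2] * v.shape[3] < 2:
        raise ValueError("SimAM needs at least 2 spatial positions per channel")
    if tensor_in:
        mu = v.mean(axis=(2, 3), keepdims=True)
        d = (v - mu) ** 2
        s2 = d.mean(axis=(2, 3), keepdims=True)
        inv_energy = (d + 2.0 * s2 + 2.0 * lambda_reg) / (4.0 * (s2 + lambda_reg))
        out = v * inv_energy.sigmoid()
    else:
        mu = v.mean(axis=(2, 3), keepdims=True)
        d = (v - mu) ** 2
        s2 = d.mean(axis=(2, 3), keepdims=True)
        inv_energy = (d + 2.0 * s2 + 2.0 * lambda_reg) / (4.0 * (s2 + lambda_reg))
        out = v * (1.0 / (1.0 + np.exp(-inv_energy)))
    if squeeze:
        out = out.reshape(tuple(out.shape[1:]))
    return out


def simam_forward(x: FeatureMap, cfg: SimAMConfig) -> FeatureMap:
    return FeatureMap(simam(x.values, cfg.lambda_reg), x.stride)


class SimAM(Module):
    """Module wrapper so the gate slots into sequential stacks (no params)."""

    def __init__(self, cfg: SimAMConfig | None = None):
        self.cfg = cfg or SimAMConfig()

    def forward(self, x: Tensor) -> Tensor:
        return simam(x, self.cfg.lambda_reg)


class Backbone(Module):
    """Stage stack producing pyramid features at strides 4/8/16/32.

    Stage widths and per-stage C2f depths are configurable; the default is
    a nano scale (width multiplier 0.25, depth multiplier 0.33 of the
    common base) so desk-scale CPU training is feasible.
    """

    def __init__(self, widths=(16, 32, 64, 128, 128), depths=(1, 2, 2, 1),
                 s5: S5Config | None = None, simam_cfg: SimAMConfig | None = None,
                 rng=None):
        rng = rng or np.random.default_rng(0)
        w0, w1, w2, w3, w4 = widths
        d1, d2, d3, d4 = depths
        s5 = s5 or S5Config(out_channels=w4)
        self.widths = tuple(widths)
        self.stem = ConvBNSiLU(3, w0, 3, stride=2, rng=rng)          # stride 2
        self.down1 = ConvBNSiLU(w0, w1, 3, stride=2, rng=rng)        # stride 4
        self.c2f1 = C2f(w1, w1, d1, rng=rng)
        self.down2 = ConvBNSiLU(w1, w2, 3, stride=2, rng=rng)        # stride 8
        self.c2f2 = C2f(w2, w2, d2, rng=rng)
        self.down3 = ConvBNSiLU(w2, w3, 3, stride=2, rng=rng)        # stride 16
        self.c2f3 = C2f(w3, w3, d3, rng=rng)
        self.down4 = ConvBNSiLU(w3, w4, 3, stride=2, rng=rng)        # stride 32
        self.c2f4 = C2f(w4, w4, d4, rng=rng)
        self.s5 = S5(w4, s5, rng=rng)
        self.attn = SimAM(simam_cfg)

    def forward(self, x: Tensor) -> dict:
        if x.shape[-1] % 32 or x.shape[-2] % 32:
            raise ValueError("input spatial dims must be divisible by 32")
        t = self.stem(x)
        p2 = self.attn(self.c2f1(self.down1(t)))
        c3 = self.attn(self.c2f2(self.down2(p2)))
        c4 = self.attn(self.c2f3(self.down3(c3)))
        c5 = self.attn(self.c2f4(self.down4(c4)))
        s5 = self.attn(self.s5(c5))
        return {
            4: FeatureMap(p2, 4),
            8: FeatureMap(c3, 8),
            16: FeatureMap(c4, 16),
            32: FeatureMap(s5, 32),
        }


def backbone_forward(image: np.ndarray, model: Backbone) -> dict:
    """Run the backbone on an (H, W, 3) uint8 raster or (N, 3, H, W) float."""
    arr = np.asarray(image)
    if arr.ndim == 3 and arr.shape[-1] == 3:
        arr = arr.astype(np.float32).transpose(2, 0, 1)[None] / 255.0
    return model(Tensor(arr))
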
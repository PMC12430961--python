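"""Bidirectional cross-scale feature fusion neck.

Two departures from a plain FPN/PAN:

* **Normalized weighted fusion.**  Each three-input fusion node carries
  nonnegative learnable scalars (w1, w2, w3).  Every input is scaled by its
  weight, passed through its own 1x1 convolution, the three are summed and
  divided by (w1+w2+w3+eps), and a final convolution mixes the result:

      out = Conv( [Conv(w1*a) + Conv(w2*b) + Conv(w3*c)] / (w1+w2+w3+eps) )

  The stride-16 node fuses the backbone C4 map, the upsampled deepest map
  and the downsampled C3 map; the dedicated stride-8 small-object node
  fuses the upsampled stride-16 node, the top-down stride-8 node and the
  downsampled stride-4 backbone map, so very shallow detail reaches the
  detection head.

* **LIVT** — a lightweight transformer encoder replacing the usual C2f at
  the deepest neck position: grid tokens (one per spatial cell), a reduced
  embedding width, multi-head self-attention and a depthwise-separable
  feed-forward, all residual, reprojected to the input shape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor, Module, Conv2d, ConvBNSiLU, Linear, LayerNorm, concat
from .backbone import FeatureMap

__all__ = ["FusionWeights", "LIVTConfig", "WeightedFuse", "LIVT", "Neck",
           "weighted_fuse", "livt_forward", "neck_forward"]


@dataclass
class FusionWeights:
    """Raw fusion parameters for one node; nonnegativity is enforced by a
    rectifier on the raw values."""

    omega: tuple = (1.0, 1.0, 1.0)
    epsilon: float = 1e-4

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if len(self.omega) != 3:
            raise ValueError("each fusion node has exactly three weights")

    def constrained(self) -> np.ndarray:
        return np.maximum(np.asarray(self.omega, dtype=np.float64), 0.0)

    def coefficients(self) -> np.ndarray:
        """Normalized coefficients w_i / (sum w + eps)."""
        w = self.constrained()
        return w / (w.sum() + self.epsilon)


@dataclass
class LIVTConfig:
    token_dim: int = 128
    n_heads: int = 4
    n_layers: int = 1
    grid: int = 400          # maximum token count
    positional: bool = True

    def __post_init__(self):
        if self.token_dim % self.n_heads:
            raise ValueError("token_dim must be divisible by n_heads")
        if self.grid > 1024:
            raise ValueError("token grid capped at 1024")


class WeightedFuse(Module):
    """One normalized weighted fusion node over three aligned inputs."""

    def __init__(self, c_ins, c_out, epsilon: float = 1e-4, rng=None):
        self.raw = Tensor(np.ones(3, dtype=np.float32), requires_grad=True)
        self.epsilon = float(epsilon)
        self.branch = [ConvBNSiLU(c, c_out, 1, rng=rng) for c in c_ins]
        self.out = ConvBNSiLU(c_out, c_out, 3, rng=rng)

    def forward(self, inputs) -> Tensor:
        shapes = {tuple(t.shape[-2:]) for t in inputs}
        if len(shapes) != 1:
            raise ValueError(f"fusion inputs not spatially aligned: {shapes}")
        w = self.raw.relu()
        denom = w.sum() + self.epsilon
        total = None
        for i, (x, conv) in enumerate(zip(inputs, self.branch)):
            wi = w.gather_rows([i]).reshape(1, 1, 1, 1)
            term = conv(x * wi)
            total = term if total is None else total + term
        return self.out(total / denom.reshape(1, 1, 1, 1))


def weighted_fuse(inputs, w: FusionWeights, branch_convs=None, out_conv=None):
    """Functional fusion on numpy arrays with convolutions stubbed to
    identity unless supplied — the arithmetic core of the fusion node."""
    arrs = [np.asarray(x, dtype=np.float64) for x in inputs]
    if len({a.shape[-2:] for a in arrs}) != 1:
        raise ValueError("fusion inputs not spatially aligned")
    ws = w.constrained()
    convs = branch_convs or [lambda a: a] * 3
    total = sum(conv(wi * a) for wi, a, conv in zip(ws, arrs, convs))
    fused = total / (ws.sum() + w.epsilon)
    return (out_conv or (lambda a: a))(fused)


class _EncoderLayer(Module):
    def __init__(self, dim, heads, rng=None):
        self.heads = heads
        self.qkv = Linear(dim, 3 * dim, rng=rng)
        self.proj = Linear(dim, dim, rng=rng)
        self.norm1 = LayerNorm(dim)
        self.norm2 = LayerNorm(dim)
        # depthwise-separable feed-forward: a per-channel (1x1 depthwise)
        # stage followed by pointwise expansion/contraction.  Kernel size 1
        # keeps the encoder token-permutation equivariant; spatial mixing
        # is left entirely to attention.
        self.dw = Tensor(np.zeros((dim, 1, 1), dtype=np.float32), requires_grad=True)
        self.pw1 = Linear(dim, 2 * dim, rng=rng)
        self.pw2 = Linear(2 * dim, dim, rng=rng)

    def _attend(self, x: Tensor) -> Tensor:
        n, t, d = x.shape
        h, dh = self.heads, d // self.heads
        qkv = self.qkv(x)                                   # (n, t, 3d)
        qkv = qkv.reshape(n, t, 3, h, dh).transpose(2, 0, 3, 1, 4)
        q = _index0(qkv, 0)
        k = _index0(qkv, 1)
        v = _index0(qkv, 2)                                  # (n, h, t, dh)
        att = q.matmul(k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        att = att.softmax(axis=-1)
        out = att.matmul(v).transpose(0, 2, 1, 3).reshape(n, t, d)
        return self.proj(out)

    def forward(self, x: Tensor, hw) -> Tensor:
        x = self.norm1(x + self._attend(x))
        n, t, d = x.shape
        grid = x.transpose(0, 2, 1).reshape(n, d, hw[0], hw[1])
        grid = grid.depthwise_conv2d(self.dw) + grid
        y = grid.reshape(n, d, t).transpose(0, 2, 1)
        y = self.pw2(self.pw1(y).silu())
        return self.norm2(x + y)


def _index0(x: Tensor, i: int) -> Tensor:
    def bw(g):
        full = np.zeros_like(x.data)
        full[i] = g
        x._accum(full)

    return Tensor._make(x.data[i], (x,), bw)


class LIVT(Module):
    """Lightweight transformer encoder over the spatial grid of a map.

    Shape-preserving: tokens are projected to `token_dim`, encoded, then
    reprojected to the input channel count and added to the input.
    """

    def __init__(self, c_in: int, cfg: LIVTConfig | None = None, rng=None):
        self.cfg = cfg or LIVTConfig()
        self.embed = Linear(c_in, self.cfg.token_dim, rng=rng)
        self.layers = [_EncoderLayer(self.cfg.token_dim, self.cfg.n_heads, rng=rng)
                       for _ in range(self.cfg.n_layers)]
        self.unembed = Linear(self.cfg.token_dim, c_in, rng=rng)
        self.pos = None
        self._rng = rng or np.random.default_rng(0)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        t = h * w
        if t > self.cfg.grid:
            raise ValueError(f"token count {t} exceeds grid cap {self.cfg.grid}")
        tokens = x.reshape(n, c, t).transpose(0, 2, 1)       # (n, t, c)
        z = self.embed(tokens)
        if self.cfg.positional:
            if self.pos is None or self.pos.shape[1] != t:
                self.pos = Tensor(
                    self._rng.normal(0, 0.02, size=(1, t, self.cfg.token_dim)),
                    requires_grad=True)
            z = z + self.pos
        for layer in self.layers:
            z = layer(z, (h, w))
        y = self.unembed(z).transpose(0, 2, 1).reshape(n, c, h, w)
        return x + y


def livt_forward(x: FeatureMap, cfg: LIVTConfig, rng=None) -> FeatureMap:
    v = x.values if isinstance(x.values, Tensor) else Tensor(np.asarray(x.values))
    squeeze = v.ndim == 3
    if squeeze:
        v = v.reshape((1,) + tuple(v.shape))
    out = LIVT(v.shape[1], cfg, rng=rng)(v)
    if squeeze:
        out = out.reshape(tuple(out.shape[1:]))
    return FeatureMap(out, x.stride)


class Neck(Module):
    """Cross-scale fusion producing detection maps at strides 8/16/32.

    Topology (strides in parentheses): the deepest backbone output (32)
    passes through LIVT to become N5; N4 (16) fuses C4, up(N5) and
    down(C3); N3 (8) is a plain top-down node from C3 and up(N4); the
    dedicated small-object node P3 (8) fuses up(N4), N3 and down(P2);
    bottom-up nodes then rebuild strides 16 and 32 for the remaining heads.
    """

    def __init__(self, in_widths, width: int = 64, epsilon: float = 1e-4,
                 livt: LIVTConfig | None = None, use_livt: bool = True, rng=None):
        w_p2, w_c3, w_c4, w_c5 = in_widths
        w = width
        self.width = w
        self.lat5 = ConvBNSiLU(w_c5, w, 1, rng=rng)
        self.livt = LIVT(w, livt, rng=rng) if use_livt else None
        self.lat4 = ConvBNSiLU(w_c4, w, 1, rng=rng)
        self.lat3 = ConvBNSiLU(w_c3, w, 1, rng=rng)
        self.down_c3 = ConvBNSiLU(w_c3, w, 3, stride=2, rng=rng)
        self.down_p2 = ConvBNSiLU(w_p2, w, 3, stride=2, rng=rng)
        self.fuse_n4 = WeightedFuse([w, w, w], w, epsilon, rng=rng)   # C4, N5, C3
        self.n3_conv = ConvBNSiLU(2 * w, w, 3, rng=rng)
        self.fuse_p3 = WeightedFuse([w, w, w], w, epsilon, rng=rng)   # N4, N3, P2
        self.down_p3 = ConvBNSiLU(w, w, 3, stride=2, rng=rng)
        self.d4_conv = ConvBNSiLU(2 * w, w, 3, rng=rng)
        self.down_d4 = ConvBNSiLU(w, w, 3, stride=2, rng=rng)
        self.d5_conv = ConvBNSiLU(2 * w, w, 3, rng=rng)

    def forward(self, feats: dict) -> dict:
        for s in (4, 8, 16, 32):
            if s not in feats:
                raise ValueError(f"missing backbone level at stride {s}")
        p2, c3, c4, c5 = (feats[4].values, feats[8].values,
                          feats[16].values, feats[32].values)
        n5 = self.lat5(c5)
        if self.livt is not None:
            n5 = self.livt(n5)
        n4 = self.fuse_n4([self.lat4(c4), n5.upsample2x(), self.down_c3(c3)])
        n3 = self.n3_conv(concat([self.lat3(c3), n4.upsample2x()], axis=1))
        p3 = self.fuse_p3([n4.upsample2x(), n3, self.down_p2(p2)])
        d4 = self.d4_conv(concat([self.down_p3(p3), n4], axis=1))
        d5 = self.d5_conv(concat([self.down_d4(d4), n5], axis=1))
        return {8: FeatureMap(p3, 8), 16: FeatureMap(d4, 16),
                32: FeatureMap(d5, 32)}


def neck_forward(feats: dict, neck: Neck) -> dict:
    return neck(feats)
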
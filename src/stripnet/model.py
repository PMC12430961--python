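"""Full detector assembly with ablation toggles.

The full model = backbone (S-5 + SimAM) + cross-FPN neck (normalized
weighted fusion, dedicated stride-8 small-object node, LIVT) + decoupled
anchor-free head.  Each architectural contribution can be toggled off to
recover the plain baseline (SPPF bottom block, no attention, plain
FPN/PAN, no transformer), which is what the ablation harness exercises.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .nn import Tensor, Module, ConvBNSiLU, concat, count_parameters
from .backbone import Backbone, FeatureMap, S5, S5Config, SimAM, SimAMConfig
from .neck import Neck, LIVTConfig
from .head_loss import Head, REG_MAX

__all__ = ["ModelConfig", "Detector", "SPPF"]


@dataclass
class ModelConfig:
    n_classes: int = 5
    image_size: int = 160
    widths: tuple = (16, 32, 64, 128, 128)
    depths: tuple = (1, 2, 2, 1)
    neck_width: int = 64
    epsilon: float = 1e-4
    simam_lambda: float = 1e-4
    s5_kernels: tuple = (1, 4, 7, 10, 13)
    livt: dict = field(default_factory=lambda: dict(
        token_dim=128, n_heads=4, n_layers=1, grid=400, positional=True))
    reg_max: int = REG_MAX
    use_s5: bool = True
    use_simam: bool = True
    use_cfpn: bool = True
    use_livt: bool = True
    seed: int = 0

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("widths", "depths", "s5_kernels"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


class SPPF(Module):
    """Baseline fast pyramid pooling: three chained k=5 stride-1 max pools."""

    def __init__(self, c_in, c_out, rng=None):
        self.reduce = ConvBNSiLU(4 * c_in, c_out, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        p1 = x.maxpool2d_s1(5)
        p2 = p1.maxpool2d_s1(5)
        p3 = p2.maxpool2d_s1(5)
        return self.reduce(concat([x, p1, p2, p3], axis=1))


class _Identity(Module):
    def forward(self, x):
        return x


class Detector(Module):
    def __init__(self, cfg: ModelConfig | None = None):
        cfg = cfg or ModelConfig()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.backbone = Backbone(cfg.widths, cfg.depths,
                                 S5Config(cfg.s5_kernels, cfg.widths[-1]),
                                 SimAMConfig(cfg.simam_lambda), rng=rng)
        if not cfg.use_s5:
            self.backbone.s5 = SPPF(cfg.widths[-1], cfg.widths[-1], rng=rng)
        if not cfg.use_simam:
            self.backbone.attn = _Identity()
        livt_cfg = LIVTConfig(**cfg.livt)
        self.neck = Neck(cfg.widths[1:], cfg.neck_width, cfg.epsilon,
                         livt_cfg, use_livt=cfg.use_livt, rng=rng)
        self.use_cfpn = cfg.use_cfpn
        if not cfg.use_cfpn:
            w = cfg.neck_width
            self.n4_plain = ConvBNSiLU(2 * w, w, 3, rng=rng)
        self.head = Head(cfg.neck_width, cfg.n_classes, cfg.reg_max, rng=rng)

    def features(self, x: Tensor) -> dict:
        feats = self.backbone(x)
        if self.use_cfpn:
            return self.neck(feats)
        # plain FPN/PAN: top-down concat nodes only, no P2 connection,
        # no weighted fusion
        nk = self.neck
        c3, c4, c5 = feats[8].values, feats[16].values, feats[32].values
        n5 = nk.lat5(c5)
        if nk.livt is not None:
            n5 = nk.livt(n5)
        n4 = self.n4_plain(concat([nk.lat4(c4), n5.upsample2x()], axis=1))
        p3 = nk.n3_conv(concat([nk.lat3(c3), n4.upsample2x()], axis=1))
        d4 = nk.d4_conv(concat([nk.down_p3(p3), n4], axis=1))
        d5 = nk.d5_conv(concat([nk.down_d4(d4), n5], axis=1))
        return {8: FeatureMap(p3, 8), 16: FeatureMap(d4, 16),
                32: FeatureMap(d5, 32)}

    def forward(self, x) -> dict:
        """x: (N, 3, H, W) float in [0,1] (array or Tensor).
        Returns {stride: (cls_logits, reg_logits)}."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        return self.head(self.features(x))

    def materialize(self):
        """Run a dummy forward so lazily-created parameters (the LIVT
        positional embedding) exist before an optimizer snapshots them."""
        s = self.cfg.image_size
        was_training = self.training
        self.train_mode(True)
        self.forward(np.zeros((1, 3, s, s), dtype=np.float32))
        self.train_mode(was_training)
        return self

    @property
    def n_parameters(self) -> int:
        return count_parameters(self)
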
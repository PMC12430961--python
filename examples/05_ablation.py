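"""Cumulative architecture ablation at reduced scale.

Trains the baseline detector and then adds C-FPN (weighted cross-scale
fusion), LIVT (transformer neck block), S-5 (five-kernel pooling) and
SimAM (parameter-free attention) one at a time on the same seeded data,
printing a markdown mAP table.  Reduced sizes keep this to about ten minutes on one core;
row ordering at this scale is noisy and is reported, not asserted.
"""

from stripnet.model import ModelConfig
from stripnet.pipeline import TrainConfig
from stripnet.synthetic import generate_dataset
from stripnet.evaluation import run_ablation

generate_dataset(100, "example_ablation", seed=19, image_size=128,
                 val_fraction=0.2)

base = ModelConfig(n_classes=4, image_size=128, widths=(8, 16, 32, 64, 64),
                   neck_width=48,
                   livt=dict(token_dim=64, n_heads=4, n_layers=1, grid=64,
                             positional=True), seed=2)
cfg = TrainConfig(epochs=15, warmup_epochs=3, batch=8, mosaic_off_last=3,
                  patience=15, seed=4)
result = run_ablation(base, "example_ablation", cfg)
print(result["markdown"])
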
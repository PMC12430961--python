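# Methods

## Problem and model

`stripnet` quantifies colloidal-gold lateral-flow test strips (HCG as the
motivating analyte) from ordinary photographs.  The assay presents two
narrow chromogenic bands on a membrane: a control line (C-line) that
validates the run, and a test line (T-line) whose red-purple darkness
increases with analyte concentration.  The task is posed as anchor-free
object detection: the detector localizes the bands and classifies the
T-line into a concentration bin; a readout stage maps detections to a
concentration in IU/L and a validity verdict.

The detector is a conventional one-stage pyramid architecture with four
task-specific modifications:

* **S-5 pooling.**  At the deepest backbone stage, five parallel stride-1
  max-pool branches (kernels 1/4/7/10/13) are channel-concatenated and
  reduced by a 1×1 convolution.  Large kernels widen the receptive field;
  stride 1 with size-preserving padding keeps the fine detail the very
  thin bands need.  Even kernels (4, 10) pad floor((k−1)/2) before and
  ceil((k−1)/2) after on each axis.
* **SimAM attention.**  After every C2f block (and after S-5), each
  activation t in a channel with spatial mean μ and population variance σ²
  is gated by sigmoid(1/e*) with minimal neuron energy
  e* = 4(σ²+λ)/((t−μ)² + 2σ² + 2λ), λ = 1e-4.  The gate has no learnable
  parameters; a constant channel receives the uniform gate sigmoid(0.5).
* **Cross-FPN with normalized weighted fusion.**  Fusion nodes carry three
  nonnegative learnable scalars (raw parameters through a rectifier,
  initialized at 1.0).  Each input is scaled by its weight, passed through
  its own 1×1 convolution, summed, divided by (Σω + ε) with ε = 1e-4, and
  mixed by a final 3×3 convolution.  The stride-16 node fuses the backbone
  C4 map, the upsampled deepest map, and the downsampled C3 map; a
  dedicated stride-8 small-object node fuses the upsampled stride-16 node,
  the top-down stride-8 node, and the downsampled stride-4 backbone map,
  so shallow high-resolution detail reaches the head that detects the
  bands.  Resampling is ×2 nearest-neighbour upsampling top-down and
  stride-2 convolution bottom-up.  The cross-connection topology is held
  in the model configuration, not hard-coded.
* **LIVT.**  The deepest neck position runs a lightweight transformer
  encoder instead of a feature-mixing convolution block: one token per
  spatial cell, linear projection to a reduced embedding (default 128,
  4 heads, 1 layer, learned positional embedding, token budget capped),
  multi-head self-attention, and a depthwise-separable feed-forward.  The
  depthwise stage uses a 1×1 (per-channel) kernel: with positional
  encoding disabled the encoder is then exactly token-permutation
  equivariant, which keeps "global context" the job of attention rather
  than of an implicit grid convolution; the pointwise linears carry the
  capacity.  The capacity caps (embedding width, single layer, token
  budget) are the pruning story: they bound cost a priori instead of
  pruning weights post hoc.

The decoupled head emits, per location and level (strides 8/16/32), class
logits and four discrete side-offset distributions over Reg_max = 16 bins
(bin width one stride unit).  Boxes decode by per-side expectation.

## Loss

L = 1.5·l_dfl + 0.5·l_cls + 0.5·l_box.

* l_dfl (distribution focal loss), per matched anchor and side, with
  target offset p, i = floor(p): −[(i+1−p)·ln S_i + (p−i)·ln S_{i+1}].
  It is minimized exactly at the linear-interpolation distribution
  (S_i, S_{i+1}) = (i+1−p, p−i), verified by simplex grid search in the
  tests.  Side targets are clipped to [0, 15−1e-3] stride units.
* l_cls: binary cross-entropy of sigmoid confidences against one-hot
  targets, summed over classes, averaged over all anchors.  Confidences
  are clamped to [1e-7, 1−1e-7] before logs.
* l_box: complete IoU, 1 − IoU + ρ²/c² + αv, with
  v = (4/π²)(arctan(w_g/h_g) − arctan(w_p/h_p))² and α = v/((1−IoU)+v)
  treated as a constant with respect to gradients.

Assignment is task-aligned: candidates are anchors whose center lies
inside a ground-truth box, ranked by score^0.5 · IoU^6, top-10 per ground
truth, ties broken by higher IoU then lower anchor index; an anchor
claimed twice keeps the higher-alignment claim.  Two accommodations
matter for bands only a few pixels tall.  First, the inside-test expands
each box to at least one anchor stride per axis around its centre —
otherwise a 5-px band can contain no stride-8 anchor centre at all and
would never be assigned.  Second, objects are gated to the pyramid level
matching their scale (larger side in (4s, 8s] for stride s; the finest
level has no lower bound, the coarsest no upper bound), so thin bands
train only the stride-8 head; without this the coarse heads learn sloppy
high-confidence duplicates that survive NMS.

Two further numerical choices shape training.  The per-side regression
logits are initialized with a decaying bias (−0.5 per bin index) so the
initial expected offset is ≈1.6 stride units rather than the uniform
distribution's 7.5 — for objects a fraction of a stride tall, starting
near the right scale removes most of the localization burn-in.  And the
classification BCE, though computed over every anchor, is normalized by
the number of matched anchors rather than all anchors, so the positive
gradient is not diluted by the ~500-to-20 background majority.

At inference each anchor commits to its argmax class before per-class
NMS; emitting every class above threshold floods the evaluation with
adjacent-bin duplicates of the same physical band.  A class-agnostic
suppression mode exists but is off by default: when a wrong-class box
outranks the right one it deletes the correct detection entirely.

## Training protocol

SGD (momentum 0.9, weight decay 5e-4), lr₀ = 0.01, batch 8, linear warmup
over the first 3 epochs to lr₀ then constant, mosaic augmentation (2×2
collage, probability 0.5) disabled for the final 10 epochs of a 50-epoch
schedule, per-sample augmentation of rotation ±10°, translation ±10 px and
brightness ±20% (boxes transformed by rotating corners and taking the
enclosing box, reclipped; a draw that removes every box is redrawn, at
most 10 times), early stopping on validation mAP@0.5 with patience 10, and
a global gradient-norm clip at 10 (a stability guard for small-batch
training; it does not alter the loss).  All randomness flows from explicit
seeds; two runs with the same seed reproduce losses bit for bit.

The network, its gradients and the optimizer run on a small reverse-mode
autodiff engine over numpy arrays built into the package (`stripnet.nn`);
convolution is im2col + BLAS matmul, and every operation's gradient is
checked against central finite differences in the test suite.

## Exposure normalization

Strip housings carry two white reference patches flanking the membrane
window.  The mean gray over the patches is compared with the standard
value recorded at generation time (250); within ±10 gray levels the image
passes unchanged (verdict "normal"), otherwise a single multiplicative
gain standard/measured is applied and the verdict is "overexposed" or
"underexposed".  The correction is idempotent by construction.

## Synthetic data

The generator emulates a smartphone-acquired strip dataset: a white
housing with a lighter membrane window on one of six background colours
with mild sensor noise; a fixed-darkness C-line; a T-line whose darkness
follows a saturating Langmuir-type law i(c) = i_max·c/(k_half+c) with
defaults i_max = 0.8, k_half = 50 IU/L (colloidal-gold colour response
saturates; the half-saturation point sits at the clinical decision range);
concentrations drawn from a discrete dilution ladder per bin
(10–50, 60–100, 120–200 IU/L) as a laboratory would prepare them, with
zero-concentration negatives; bin edges {0, 50, 100, 200} IU/L (width 50
below 100, doubling above), representatives at bin midpoints; geometry
jitter (position, scale, ±4° rotation); and seven illumination conditions
realized as simple parametric transfers (gains 0.5/1.4 for low/strong,
R/B channel ratios for warm 3000 K / cool 6500 K, an additive specular
ellipse for glare, a multiplicative horizontal gradient for shadow).
Classes balance to within one sample per strip class.  Everything is a
pure function of configuration and seed; labels are YOLO-format text
files and the manifest is YAML.

What the generator does **not** emulate: perspective distortion, focus
blur, shot noise correlated with exposure, membrane texture, bleed or
smear of the bands, multiple strips per frame, and real phone colour
pipelines.  Tests passing on this data therefore demonstrate that the
architecture, losses, training loop and metrics are implemented correctly
and that the method solves a structurally faithful miniature of the task —
not that the reported clinical-grade accuracies transfer to real strips.

## Concentration readout

A strip with no C-line detection is invalid (no estimate).  A C-line
without a T-line is a valid negative (0 IU/L).  Otherwise the readout is
the representative (midpoint) concentration of the highest-confidence
T-line class, so the error of a correctly-binned strip is bounded by half
the bin width.  An optional refinement inverts the chromogenic law from
the measured T/C darkness ratio (the C-line's known fixed darkness serves
as the per-image photometric scale), giving sub-bin estimates; it is off
by default because it assumes the generator's law, and how a continuous
readout should be obtained from binned detections on real data is an open
modelling choice.

## Study sizing

The package's end-to-end study trains the nano-scale detector (stage
widths 8/16/32/64/64, neck width 48, LIVT embedding 64) at 160×160 input
on 200 training strips and evaluates on 50 held-out strips, 30 epochs.
These sizes were chosen so the full study runs in minutes on a single CPU
core with the numpy engine while leaving the bands several stride-8 cells
tall; the same code scales to 320×320 and wider stages by configuration.

## Known limitations

* The numpy engine is single-threaded BLAS-bound; wall-clock cost, not
  method, limits image size and epochs.
* mAP on the synthetic study uses greedy all-point-interpolated AP; small
  validation sets quantize the PR curve visibly.
* The strip-level confusion matrix derives from the readout, so a missed
  C-line lands in an explicit "invalid" column rather than being coerced
  into a bin.
* Illumination transfers are linear per-pixel maps; they do not model
  saturation-induced hue shifts, and under 'strong'/'glare' the white
  reference spots clip at 255, which bounds how much the exposure
  correction can recover.
* With midpoint bin representatives, the lowest bin's representative
  (25 IU/L) coincides with the 25 IU/L clinical threshold, so every
  correctly-binned low-positive strip counts as threshold-positive under
  the stated "positive = ≥ t" rule.  Specificity at that threshold is
  therefore pessimistic for the bin-representative readout; the
  sub-bin refinement mode does not have this atom.
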
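"""Seeded synthetic lateral-flow strip photographs with YOLO-format labels.

Real colloidal-gold strip datasets are rarely shareable, so every stage of
the package is testable against this generator.  It emulates the
statistical structure of a smartphone-acquired HCG strip dataset:

* a vertical strip (white plastic housing, lighter membrane window) on a
  varied background;
* a fixed-darkness C-line and, for positive samples, a T-line whose
  red-purple darkness follows a saturating (Langmuir-type) chromogenic
  law  i(c) = i_max * c / (k_half + c)  — colloidal-gold colour response
  saturates at high analyte concentration;
* concentrations drawn from a discrete dilution series, binned into
  detection classes (bin width 50 IU/L below 100, wider above);
* illumination conditions (normal / low / strong / warm 3000 K /
  cool 6500 K / glare / shadow) applied as simple parametric transfer
  functions;
* two white reference spots on the housing for exposure normalization.

Everything is a pure function of (configuration, seed).
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from PIL import Image

__all__ = [
    "ChromogenicLaw", "ConcentrationBinning", "SceneConfig", "StripImage",
    "BoxLabel", "NEGATIVE_CLASS", "C_LINE_CLASS",
    "intensity_from_concentration", "assign_bin", "render_strip",
    "apply_illumination", "generate_dataset", "read_labels", "write_labels",
    "ILLUMINATIONS", "DEFAULT_LEVELS",
]

ILLUMINATIONS = ("normal", "low", "strong", "warm3000K", "cool6500K",
                 "glare", "shadow")

#: strip-level class id for a valid negative (no T-line) result
NEGATIVE_CLASS = -1
#: detection class id of the control line; T-line bin b maps to 1 + b
C_LINE_CLASS = 0

# membrane base colour and the full-darkness band colour (red-purple)
_MEMBRANE = np.array([232.0, 226.0, 220.0])
_BAND_FULL = np.array([122.0, 32.0, 62.0])

#: default dilution series per positive bin (IU/L), emulating a lab
#: dilution ladder rather than a continuum
DEFAULT_LEVELS = {
    0: (10.0, 20.0, 30.0, 40.0, 50.0),
    1: (60.0, 75.0, 90.0, 100.0),
    2: (120.0, 150.0, 180.0, 200.0),
}


@dataclass
class ChromogenicLaw:
    """Saturating concentration -> T-line darkness law."""

    i_max: float = 0.8
    k_half: float = 50.0
    c_line_intensity: float = 0.8

    def __post_init__(self):
        if not 0 < self.i_max <= 1:
            raise ValueError("i_max must lie in (0, 1]")
        if self.k_half <= 0:
            raise ValueError("k_half must be positive")
        if not 0 < self.c_line_intensity <= 1:
            raise ValueError("c_line_intensity must lie in (0, 1]")


@dataclass
class ConcentrationBinning:
    """Ascending concentration cut-points with one representative per bin."""

    edges: tuple = (0.0, 50.0, 100.0, 200.0)
    representative: tuple = None
    negative_class: bool = True

    def __post_init__(self):
        e = tuple(float(x) for x in self.edges)
        if list(e) != sorted(set(e)):
            raise ValueError("edges must be strictly ascending")
        widths = np.diff(e)
        low = widths[np.array(e[:-1]) < 100.0]
        if low.size and not np.allclose(low, 50.0):
            raise ValueError("low-range (<100) bin widths must equal 50")
        above = widths[np.array(e[:-1]) >= 100.0]
        seq = np.concatenate([low, above])
        if np.any(np.diff(seq) < 0):
            raise ValueError("bin widths must be nondecreasing above 100")
        self.edges = e
        if self.representative is None:
            self.representative = tuple((a + b) / 2 for a, b in zip(e, e[1:]))
        else:
            self.representative = tuple(float(x) for x in self.representative)
        for r, lo, hi in zip(self.representative, e, e[1:]):
            if not lo < r <= hi:
                raise ValueError(f"representative {r} outside bin ({lo}, {hi}]")

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    @property
    def n_detection_classes(self) -> int:
        """C-line plus one class per positive bin."""
        return 1 + self.n_bins

    def class_names(self) -> list:
        names = ["C_line"]
        for lo, hi in zip(self.edges, self.edges[1:]):
            names.append(f"T_line_{lo:g}_{hi:g}")
        return names


@dataclass
class SceneConfig:
    illumination: str = "normal"
    background_id: int = 0
    geometry: dict = field(default_factory=lambda: dict(
        cx=0.5, cy=0.5, scale=0.85, rotation_deg=0.0))
    image_size: int = 160
    seed: int = 0

    def __post_init__(self):
        if self.illumination not in ILLUMINATIONS:
            raise ValueError(f"unknown illumination {self.illumination!r}")


@dataclass
class StripImage:
    pixels: np.ndarray          # (H, W, 3) uint8
    meta: dict


@dataclass
class BoxLabel:
    """YOLO-convention box: class id and center/size normalized to [0,1]."""

    class_id: int
    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self):
        if not (0 <= self.cx <= 1 and 0 <= self.cy <= 1):
            raise ValueError("box center outside [0,1]")
        if not (0 < self.w <= 1 and 0 < self.h <= 1):
            raise ValueError("box size outside (0,1]")

    def to_xyxy(self, width: int, height: int) -> tuple:
        """Pixel corner box (0-based, half-open)."""
        x1 = (self.cx - self.w / 2) * width
        y1 = (self.cy - self.h / 2) * height
        return (x1, y1, x1 + self.w * width, y1 + self.h * height)

    @classmethod
    def from_xyxy(cls, class_id, x1, y1, x2, y2, width, height):
        return cls(class_id, (x1 + x2) / 2 / width, (y1 + y2) / 2 / height,
                   (x2 - x1) / width, (y2 - y1) / height)


def intensity_from_concentration(c: float, law: ChromogenicLaw) -> float:
    """Saturating chromogenic response i_max * c / (k_half + c); zero at zero,
    nondecreasing, bounded by i_max."""
    if c < 0:
        raise ValueError("concentration must be nonnegative")
    return law.i_max * c / (law.k_half + c)


def assign_bin(c: float, binning: ConcentrationBinning) -> int:
    """Bin index of concentration c under half-open (lo, hi] intervals;
    c == 0 maps to the negative class (NEGATIVE_CLASS)."""
    if c == 0:
        return NEGATIVE_CLASS
    if not 0 <= c <= binning.edges[-1]:
        raise ValueError(f"concentration {c} outside [0, {binning.edges[-1]}]")
    for b, (lo, hi) in enumerate(zip(binning.edges, binning.edges[1:])):
        if lo < c <= hi:
            return b
    raise ValueError(f"no bin for concentration {c}")  # pragma: no cover


def _band_color(darkness: float) -> np.ndarray:
    return _MEMBRANE + darkness * (_BAND_FULL - _MEMBRANE)


def render_strip(c: float, law: ChromogenicLaw, binning: ConcentrationBinning,
                 scene: SceneConfig):
    """Render one strip photograph.  Returns (StripImage, [BoxLabel]).

    The image always contains the C-line (class 0); iff c > 0 it also
    contains a T-line labelled 1 + assign_bin(c).  Boxes tightly enclose
    the rendered bands.  Bit-identical output per (inputs, seed).
    """
    rng = np.random.default_rng(scene.seed)
    s = scene.image_size
    geo = scene.geometry

    # background: palette colour by background_id plus low-amplitude noise
    palette = np.array([[70, 85, 100], [150, 140, 120], [60, 60, 60],
                        [120, 150, 130], [170, 120, 110], [100, 100, 140]])
    base = palette[scene.background_id % len(palette)].astype(np.float64)
    img = np.tile(base, (s, s, 1))
    img += rng.normal(0, 4.0, size=img.shape)

    # strip geometry (axis-aligned; small rotation applied at the end)
    strip_h = geo["scale"] * s
    strip_w = 0.28 * strip_h
    cx, cy = geo["cx"] * s, geo["cy"] * s
    sx1, sy1 = cx - strip_w / 2, cy - strip_h / 2
    sx2, sy2 = cx + strip_w / 2, cy + strip_h / 2
    if sx1 < 0 or sy1 < 0 or sx2 > s or sy2 > s:
        raise ValueError("geometry places the strip outside the frame")

    def fill(x1, y1, x2, y2, color):
        img[int(round(y1)):int(round(y2)), int(round(x1)):int(round(x2))] = color

    housing = np.array([245.0, 245.0, 243.0])
    fill(sx1, sy1, sx2, sy2, housing)

    # membrane window: central 45% of the strip height
    wx1, wx2 = sx1 + 0.12 * strip_w, sx2 - 0.12 * strip_w
    wy1 = cy - 0.225 * strip_h
    wy2 = cy + 0.225 * strip_h
    fill(wx1, wy1, wx2, wy2, _MEMBRANE)

    # reference spots: white patches on the housing above and below window
    spot_h = 0.05 * strip_h
    spots = []
    for syc in (wy1 - 0.1 * strip_h, wy2 + 0.1 * strip_h):
        r = (int(round(wx1)), int(round(syc - spot_h / 2)),
             int(round(wx2)), int(round(syc + spot_h / 2)))
        fill(*r, np.array([250.0, 250.0, 250.0]))
        spots.append(r)

    # bands: C-line at 25% of window height, T-line at 65%.  Band height
    # is 8% of the window — the physical ratio of a ~1 mm test line on a
    # ~12 mm visible membrane.
    band_h = max(3.0, 0.08 * (wy2 - wy1))
    labels_px = []
    c_yc = wy1 + 0.25 * (wy2 - wy1)
    fill(wx1, c_yc - band_h / 2, wx2, c_yc + band_h / 2,
         _band_color(law.c_line_intensity))
    labels_px.append((C_LINE_CLASS,
                      wx1, c_yc - band_h / 2, wx2, c_yc + band_h / 2))
    if c > 0:
        t_yc = wy1 + 0.65 * (wy2 - wy1)
        darkness = intensity_from_concentration(c, law)
        fill(wx1, t_yc - band_h / 2, wx2, t_yc + band_h / 2,
             _band_color(darkness))
        labels_px.append((1 + assign_bin(c, binning),
                          wx1, t_yc - band_h / 2, wx2, t_yc + band_h / 2))

    # sensor noise
    img += rng.normal(0, 2.0, size=img.shape)

    rot = float(geo.get("rotation_deg", 0.0))
    if abs(rot) > 1e-9:
        from scipy.ndimage import rotate as nd_rotate
        img = nd_rotate(img, -rot, axes=(0, 1), reshape=False, order=1,
                        mode="nearest")
        labels_px = [_rotate_box(lbl, rot, s) for lbl in labels_px]
        spots = [tuple(int(round(v)) for v in _rotate_box((0,) + r, rot, s)[1:])
                 for r in spots]

    pixels = np.clip(img, 0, 255).astype(np.uint8)
    meta = dict(asdict(scene), concentration=float(c),
                strip_class=assign_bin(c, binning) if c > 0 else NEGATIVE_CLASS,
                reference_spots=[list(r) for r in spots])
    out = StripImage(pixels, meta)
    out = apply_illumination(out, scene.illumination, rng=rng)
    boxes = [BoxLabel.from_xyxy(cid, x1, y1, x2, y2, s, s)
             for cid, x1, y1, x2, y2 in labels_px]
    return out, boxes


def _rotate_box(lbl, rot_deg, size):
    cid, x1, y1, x2, y2 = lbl
    th = np.deg2rad(rot_deg)
    cx0 = cy0 = (size - 1) / 2
    corners = np.array([[x1, y1], [x2, y1], [x1, y2], [x2, y2]]) - (cx0, cy0)
    rotm = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    rc = corners @ rotm.T + (cx0, cy0)
    return (cid, rc[:, 0].min(), rc[:, 1].min(), rc[:, 0].max(), rc[:, 1].max())


def apply_illumination(image: StripImage, condition: str, rng=None) -> StripImage:
    """Apply a named illumination transfer function.

    normal: identity; low/strong: gain 0.5 / 1.4; warm/cool: opposite R/B
    channel gains; glare: additive specular ellipse; shadow: multiplicative
    horizontal gradient down to 0.55.
    """
    if condition not in ILLUMINATIONS:
        raise ValueError(f"unknown illumination {condition!r}")
    px = image.pixels.astype(np.float64)
    h, w = px.shape[:2]
    if condition == "normal":
        out = px
    elif condition == "low":
        out = px * 0.5
    elif condition == "strong":
        out = px * 1.4
    elif condition == "warm3000K":
        out = px * np.array([1.15, 1.0, 0.82])
    elif condition == "cool6500K":
        out = px * np.array([0.82, 1.0, 1.15])
    elif condition == "glare":
        rng = rng or np.random.default_rng(0)
        gx, gy = rng.uniform(0.25, 0.75, 2) * (w, h)
        ax, ay = rng.uniform(0.12, 0.2, 2) * (w, h)
        ys, xs = np.mgrid[0:h, 0:w]
        blob = np.exp(-(((xs - gx) / ax) ** 2 + ((ys - gy) / ay) ** 2))
        out = px + 130.0 * blob[..., None]
    elif condition == "shadow":
        grad = np.linspace(1.0, 0.55, w)[None, :, None]
        out = px * grad
    meta = dict(image.meta)
    meta["illumination_applied"] = condition
    return StripImage(np.clip(out, 0, 255).astype(np.uint8), meta)


def write_labels(path, labels) -> None:
    with open(path, "w") as fh:
        for b in labels:
            fh.write(f"{b.class_id} {b.cx:.6f} {b.cy:.6f} "
                     f"{b.w:.6f} {b.h:.6f}\n")


def read_labels(path) -> list:
    out = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            out.append(BoxLabel(int(parts[0]), *map(float, parts[1:5])))
    return out


def generate_dataset(n: int, out_dir, binning: ConcentrationBinning = None,
                     law: ChromogenicLaw = None, conditions=ILLUMINATIONS,
                     levels: dict = None, image_size: int = 160,
                     val_fraction: float = 0.0, seed: int = 0) -> dict:
    """Write n strip images + YOLO label files + a YAML manifest.

    Strip-level classes (negative plus each positive bin) are balanced to
    within one sample; conditions cycle through `conditions`; geometry is
    jittered per image.  Pure function of the arguments and `seed`.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    binning = binning or ConcentrationBinning()
    law = law or ChromogenicLaw()
    levels = levels or DEFAULT_LEVELS
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(seed)

    strip_classes = [NEGATIVE_CLASS] + list(range(binning.n_bins))
    counts = [n // len(strip_classes)] * len(strip_classes)
    for i in range(n - sum(counts)):
        counts[i] += 1
    class_seq = [c for c, k in zip(strip_classes, counts) for _ in range(k)]
    rng.shuffle(class_seq)

    entries = []
    for i, strip_cls in enumerate(class_seq):
        if strip_cls == NEGATIVE_CLASS:
            c = 0.0
        else:
            opts = levels[strip_cls]
            c = float(opts[rng.integers(len(opts))])
        cond = conditions[i % len(conditions)]
        geo = dict(cx=float(rng.uniform(0.44, 0.56)),
                   cy=float(rng.uniform(0.46, 0.54)),
                   scale=float(rng.uniform(0.78, 0.92)),
                   rotation_deg=float(rng.uniform(-4.0, 4.0)))
        scene = SceneConfig(illumination=cond, background_id=int(rng.integers(6)),
                            geometry=geo, image_size=image_size,
                            seed=int(rng.integers(2 ** 31 - 1)))
        img, labels = render_strip(c, law, binning, scene)
        stem = f"strip_{i:05d}"
        Image.fromarray(img.pixels).save(os.path.join(out_dir, stem + ".png"))
        write_labels(os.path.join(out_dir, stem + ".txt"), labels)
        entries.append(dict(image=stem + ".png", label=stem + ".txt",
                            concentration=c, strip_class=int(strip_cls),
                            condition=cond,
                            reference_spots=img.meta["reference_spots"]))

    # stratified split by strip class
    train, val = [], []
    by_class = {}
    for e in entries:
        by_class.setdefault(e["strip_class"], []).append(e)
    for cls_entries in by_class.values():
        n_val = int(round(val_fraction * len(cls_entries)))
        val.extend(e["image"] for e in cls_entries[:n_val])
        train.extend(e["image"] for e in cls_entries[n_val:])

    manifest = dict(
        n=n, seed=seed, image_size=image_size,
        class_names=binning.class_names(),
        binning=dict(edges=list(binning.edges),
                     representative=list(binning.representative)),
        law=asdict(law),
        conditions=list(conditions),
        entries=entries,
        splits=dict(train=sorted(train), val=sorted(val)),
    )
    path = os.path.join(out_dir, "manifest.yaml")
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    with open(path, "rb") as fh:
        manifest["manifest_sha1"] = hashlib.sha1(fh.read()).hexdigest()
    return manifest
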
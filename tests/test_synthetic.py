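"""Synthetic strip generator: chromogenic law, binning, rendering,
illumination transfer functions, dataset balance and determinism."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stripnet.synthetic import (
    ChromogenicLaw, ConcentrationBinning, SceneConfig, BoxLabel,
    intensity_from_concentration, assign_bin, render_strip,
    apply_illumination, generate_dataset, read_labels, write_labels,
    StripImage, NEGATIVE_CLASS, C_LINE_CLASS,
)


class TestChromogenicLaw:
    def test_zero_concentration_gives_zero_intensity(self):
        assert intensity_from_concentration(0.0, ChromogenicLaw()) == 0.0

    def test_half_maximum_at_k_half(self):
        law = ChromogenicLaw(i_max=0.8, k_half=50.0)
        assert intensity_from_concentration(50.0, law) == pytest.approx(0.40)

    def test_saturating_value_at_200(self):
        law = ChromogenicLaw(i_max=0.8, k_half=50.0)
        assert intensity_from_concentration(200.0, law) == pytest.approx(0.64)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            intensity_from_concentration(-1.0, ChromogenicLaw())

    @given(st.floats(0, 1000), st.floats(0, 1000))
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_bounded(self, c1, c2):
        law = ChromogenicLaw(i_max=0.8, k_half=50.0)
        lo, hi = sorted([c1, c2])
        i_lo = intensity_from_concentration(lo, law)
        i_hi = intensity_from_concentration(hi, law)
        assert i_lo <= i_hi < law.i_max

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ChromogenicLaw(i_max=1.5)
        with pytest.raises(ValueError):
            ChromogenicLaw(k_half=0.0)


class TestBinning:
    def test_zero_is_negative_class(self):
        assert assign_bin(0.0, ConcentrationBinning()) == NEGATIVE_CLASS

    def test_low_bin_membership(self):
        assert assign_bin(25.0, ConcentrationBinning()) == 0

    def test_high_bin_membership(self):
        assert assign_bin(150.0, ConcentrationBinning()) == 2

    def test_half_open_edges(self):
        b = ConcentrationBinning()
        assert assign_bin(50.0, b) == 0
        assert assign_bin(50.0001, b) == 1

    def test_above_range_rejected(self):
        with pytest.raises(ValueError):
            assign_bin(250.0, ConcentrationBinning())

    def test_representatives_default_to_midpoints(self):
        b = ConcentrationBinning()
        assert b.representative == (25.0, 75.0, 150.0)

    def test_bad_edges_rejected(self):
        with pytest.raises(ValueError):
            ConcentrationBinning(edges=(0, 60, 100, 200))  # low width != 50
        with pytest.raises(ValueError):
            ConcentrationBinning(edges=(0, 50, 100, 200, 250))  # shrinking


class TestRender:
    def setup_method(self):
        self.law = ChromogenicLaw()
        self.binning = ConcentrationBinning()

    def test_negative_strip_has_only_c_line(self):
        _, labels = render_strip(0.0, self.law, self.binning, SceneConfig(seed=1))
        assert [b.class_id for b in labels] == [C_LINE_CLASS]

    def test_positive_strip_has_t_line_with_bin_class(self):
        _, labels = render_strip(75.0, self.law, self.binning, SceneConfig(seed=1))
        assert len(labels) == 2
        assert labels[1].class_id == 1 + assign_bin(75.0, self.binning)

    def test_bit_identical_per_seed(self):
        a, la = render_strip(75.0, self.law, self.binning, SceneConfig(seed=9))
        b, lb = render_strip(75.0, self.law, self.binning, SceneConfig(seed=9))
        assert np.array_equal(a.pixels, b.pixels)
        assert la == lb

    def test_out_of_frame_geometry_rejected(self):
        scene = SceneConfig(geometry=dict(cx=0.95, cy=0.5, scale=0.8,
                                          rotation_deg=0.0))
        with pytest.raises(ValueError):
            render_strip(0.0, self.law, self.binning, scene)

    def test_band_contrast_against_adjacent_membrane(self):
        """Cropping at each box yields a region darker than the membrane
        just above it by a clear margin (contrast threshold 10 gray
        levels in the green channel)."""
        img, labels = render_strip(75.0, self.law, self.binning,
                                   SceneConfig(seed=2))
        s = img.pixels.shape[0]
        for b in labels:
            x1, y1, x2, y2 = [int(round(v)) for v in b.to_xyxy(s, s)]
            band_g = img.pixels[y1:y2, x1:x2, 1].mean()
            above_g = img.pixels[max(0, y1 - 8):y1 - 4, x1:x2, 1].mean()
            assert above_g - band_g > 10

    def test_rendered_darkness_monotone_in_concentration(self):
        """Under a fixed scene, the mean T-line darkness never decreases
        with concentration."""
        scene = SceneConfig(seed=5)
        means = []
        for c in (10.0, 40.0, 75.0, 150.0, 200.0):
            img, labels = render_strip(c, self.law, self.binning, scene)
            s = img.pixels.shape[0]
            x1, y1, x2, y2 = [int(round(v)) for v in labels[1].to_xyxy(s, s)]
            means.append(img.pixels[y1:y2, x1:x2].mean())
        assert all(a >= b - 1e-9 for a, b in zip(means, means[1:]))


class TestIllumination:
    def _const(self, value):
        return StripImage(np.full((8, 8, 3), value, dtype=np.uint8), {})

    def test_normal_is_identity(self):
        img = self._const(128)
        out = apply_illumination(img, "normal")
        assert np.array_equal(out.pixels, img.pixels)

    def test_low_light_halves_constant_image(self):
        out = apply_illumination(self._const(128), "low")
        assert np.all(out.pixels == 64)

    def test_warm_raises_red_blue_ratio(self):
        rng = np.random.default_rng(0)
        img = StripImage(rng.integers(50, 200, (8, 8, 3)).astype(np.uint8), {})
        out = apply_illumination(img, "warm3000K")
        before = img.pixels[..., 0].mean() / img.pixels[..., 2].mean()
        after = out.pixels[..., 0].mean() / out.pixels[..., 2].mean()
        assert after > before

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError):
            apply_illumination(self._const(1), "candlelight")

    def test_pixel_range_preserved(self):
        for cond in ("low", "strong", "warm3000K", "cool6500K", "glare",
                     "shadow"):
            out = apply_illumination(self._const(200), cond,
                                     rng=np.random.default_rng(0))
            assert out.pixels.min() >= 0 and out.pixels.max() <= 255


class TestLabelsIO:
    def test_roundtrip_precision(self, tmp_path):
        labels = [BoxLabel(0, 0.5, 0.41, 0.2, 0.02),
                  BoxLabel(3, 0.123456, 0.654321, 0.111111, 0.033333)]
        p = tmp_path / "x.txt"
        write_labels(p, labels)
        back = read_labels(p)
        for a, b in zip(labels, back):
            assert a.class_id == b.class_id
            for f in ("cx", "cy", "w", "h"):
                assert abs(getattr(a, f) - getattr(b, f)) <= 1e-6

    def test_invalid_boxes_rejected(self):
        with pytest.raises(ValueError):
            BoxLabel(0, 1.5, 0.5, 0.1, 0.1)
        with pytest.raises(ValueError):
            BoxLabel(0, 0.5, 0.5, 0.0, 0.1)


class TestGenerateDataset:
    def test_exact_balance_when_divisible(self, tmp_path):
        m = generate_dataset(12, tmp_path / "d1", seed=3, image_size=96)
        counts = {}
        for e in m["entries"]:
            counts[e["strip_class"]] = counts.get(e["strip_class"], 0) + 1
        assert sorted(counts.values()) == [3, 3, 3, 3]

    def test_near_balance_otherwise(self, tmp_path):
        m = generate_dataset(10, tmp_path / "d2", seed=3, image_size=96)
        counts = {}
        for e in m["entries"]:
            counts[e["strip_class"]] = counts.get(e["strip_class"], 0) + 1
        assert max(counts.values()) - min(counts.values()) <= 1

    def test_manifest_hash_deterministic(self, tmp_path):
        m1 = generate_dataset(6, tmp_path / "a", seed=7, image_size=96)
        m2 = generate_dataset(6, tmp_path / "b", seed=7, image_size=96)
        assert m1["manifest_sha1"] == m2["manifest_sha1"]

    def test_files_written_and_labels_match_class(self, tmp_path):
        out = tmp_path / "d3"
        m = generate_dataset(12, out, seed=1, image_size=96, val_fraction=0.25)
        assert (out / "manifest.yaml").exists()
        for e in m["entries"]:
            assert (out / e["image"]).exists()
            labels = read_labels(out / e["label"])
            ids = sorted(b.class_id for b in labels)
            if e["strip_class"] == NEGATIVE_CLASS:
                assert ids == [C_LINE_CLASS]
            else:
                assert ids == [C_LINE_CLASS, 1 + e["strip_class"]]
        n_val = len(m["splits"]["val"])
        assert n_val == 4  # one of the three per class, stratified
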
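"""Reference-spot exposure normalization on a deliberately underexposed
strip photograph.

Renders one strip, darkens it with the low-light illumination transfer,
then corrects it using the white reference spots on the housing and prints
the verdicts and spot gray levels.
"""

import numpy as np

from stripnet.synthetic import (ChromogenicLaw, ConcentrationBinning,
                                SceneConfig, render_strip, apply_illumination)
from stripnet.pipeline import ReferenceSpot, normalize_exposure

law, binning = ChromogenicLaw(), ConcentrationBinning()
img, _ = render_strip(75.0, law, binning, SceneConfig(seed=21))

spots = [ReferenceSpot(tuple(r), standard_gray=250.0, tolerance=10.0)
         for r in img.meta["reference_spots"]]


def spot_gray(pixels):
    return np.mean([pixels[y1:y2, x1:x2].mean()
                    for (x1, y1, x2, y2) in (s.region for s in spots)])


print(f"as rendered: spot gray = {spot_gray(img.pixels):.1f}")
over = apply_illumination(img, "low")
print(f"after low-light: spot gray = {spot_gray(over.pixels):.1f}")

corrected, verdict = normalize_exposure(over.pixels, spots)
print(f"verdict = {verdict}; corrected spot gray = "
      f"{spot_gray(corrected):.1f} (back at the 250 standard)")
again, verdict2 = normalize_exposure(corrected, spots)
print(f"second pass verdict = {verdict2} (idempotent: nothing to fix)")
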
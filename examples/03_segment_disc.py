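"""Segment the optic disc end to end and score the result.

The pipeline: locate the disc, clean the ROI, fit the elliptical prior
with the adaptive threshold, then evolve the four-term level set.
"""

import warnings

from odseg import RunConfig, iou, render, segment_image
from odseg.synthetic import standard_suite

suite = standard_suite(6, seed=42)
print(f"{'condition':<14} {'IoU':>6} {'iters':>6} {'prior a,b (px)':>16}")
for (image, gt, spec), name in zip(
    suite, ("clean", "vessels", "ppa", "bright_blob", "low_contrast", "wide_angle")
):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mask, report = segment_image(image, RunConfig(style=spec.style))
    a, b = report["prior"]["semi_axes"]
    print(f"{name:<14} {iou(mask, gt):>6.3f} {report['iterations']:>6} "
          f"{a:>8.1f},{b:>6.1f}")
# IoU is the mask overlap with the known ground-truth ellipse; the
# fitted prior axes track the true disc within a couple of pixels, and
# the shape-guarded evolution keeps the final contour elliptical.
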
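"""Generate a synthetic fundus image and inspect its ground truth.

Renders a posterior-style retina: a bright elliptical optic disc on a
darker background, three dark vessels crossing it, and sensor noise.
"""

import numpy as np

from odseg import SynthSpec, render

spec = SynthSpec(
    od_center=(160.0, 150.0),
    od_axes=(52.0, 44.0),
    od_rotation=0.4,
    vessels=[([(40.0, 150.0), (160.0, 150.0), (290.0, 160.0)], 4.0, 0.1)],
    seed=42,
)
image, gt = render(spec)
value = image.as_float().max(axis=-1)

print(f"image grid:            {image.grid_shape}")
print(f"ground-truth disc area {gt.sum()} px "
      f"(ellipse pi*a*b = {np.pi * 52 * 44:.0f} px)")
print(f"value channel inside disc:  {value[gt].mean():.3f}")
print(f"value channel outside disc: {value[image.fov_mask & ~gt].mean():.3f}")
# The disc is the brightest structure, which is what both the localizer
# (step 4) and the adaptive threshold rely on.
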
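"""Four-side (sector) evaluation of a segmentation result.

Splits the disc into superior / nasal / inferior / temporal quadrants,
computes per-sector agreement with the ground truth, and aggregates
clinician-style scores.
"""

import numpy as np

from odseg import FseRecord, fse_aggregate, sector_agreement, sector_masks

yy, xx = np.mgrid[0:200, 0:200]
gt = np.hypot(yy - 100, xx - 100) <= 50
result = gt.copy()
result[(yy < 100 - np.abs(xx - 100))] = False  # fail the superior sector

sectors = sector_masks((100.0, 100.0), "right", gt.shape)
agreement = sector_agreement(result, gt, sectors)
print("per-sector IoU:", {k: None if v is None else round(v, 3)
                          for k, v in agreement.items()})

# a rater marks sectors with IoU >= 0.8 as "accurate enough"
flags = tuple(agreement[s] is not None and agreement[s] >= 0.8
              for s in ("superior", "nasal", "inferior", "temporal"))
record = FseRecord("demo-case", score=sum(flags) + 1 if any(flags) else 1,
                   flags=flags)
summary = fse_aggregate([record])
print(f"accurate sectors: {sum(flags)}/4 -> score {record.score}/5")
print("aggregate:", summary)
# Three accurate sectors map to score 4; with many cases the summary
# mirrors a score-distribution table (counts per level 0-5 plus mean).
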
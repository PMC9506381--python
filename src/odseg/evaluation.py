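"""Segmentation evaluation: IoU and four-side evaluation (FSE) geometry.

IoU is the usual intersection-over-union of result and ground-truth
masks.  FSE is a clinician-facing score: the disc is split into four
90-degree sectors (superior, nasal, inferior, temporal) about its
center, a point is given per sector judged accurate, and the score maps
to 0-5 (0/1 both mean no accurate sector, 1 being the milder failure;
2..5 mean 1..4 accurate sectors).  The clinician's judgment itself is
not automated here - only the sector geometry, per-sector objective
agreement proxies, score entry and aggregation.

Nasal/temporal depend on eye laterality: nasal faces the nose, which is
image-left for a right eye in standard fundus orientation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SectorSet",
    "FseRecord",
    "iou",
    "sector_masks",
    "sector_agreement",
    "score_from_flags",
    "fse_aggregate",
]

SECTOR_NAMES = ("superior", "nasal", "inferior", "temporal")


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two binary masks on one grid.

    Returns 0.0 (by convention) when both masks are empty.
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("masks must share one grid")
    union = np.count_nonzero(a | b)
    if union == 0:
        return 0.0
    return float(np.count_nonzero(a & b) / union)


@dataclass
class SectorSet:
    """Four disjoint 90-degree sector masks partitioning the plane."""

    superior: np.ndarray
    nasal: np.ndarray
    inferior: np.ndarray
    temporal: np.ndarray
    center: tuple[float, float]
    laterality: str

    def as_dict(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in SECTOR_NAMES}


def sector_masks(
    center: tuple[float, float],
    laterality: str,
    grid_shape: tuple[int, int],
) -> SectorSet:
    """Partition the grid into the four diagonal 90-degree sectors.

    Angles are measured from image-right, counterclockwise, with rows
    growing downward; sector boundaries sit on the +-45-degree
    diagonals, half-open [theta, theta + 90).  Superior is the up-facing
    sector.  Unknown laterality defaults to right-eye orientation.
    """
    h, w = grid_shape
    if not (0 <= center[0] < h and 0 <= center[1] < w):
        raise ValueError("center must lie inside the grid")
    if laterality not in ("left", "right"):
        import warnings

        warnings.warn("unknown laterality; assuming right eye")
        laterality = "right"
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    theta = np.degrees(np.arctan2(-(rr - center[0]), cc - center[1]))
    theta = np.mod(theta, 360.0)
    superior = (45.0 <= theta) & (theta < 135.0)
    image_left = (135.0 <= theta) & (theta < 225.0)
    inferior = (225.0 <= theta) & (theta < 315.0)
    image_right = ~(superior | image_left | inferior)
    if laterality == "right":
        nasal, temporal = image_left, image_right
    else:
        nasal, temporal = image_right, image_left
    return SectorSet(
        superior=superior,
        nasal=nasal,
        inferior=inferior,
        temporal=temporal,
        center=center,
        laterality=laterality,
    )


def sector_agreement(
    result: np.ndarray, gt: np.ndarray, sectors: SectorSet
) -> dict[str, float | None]:
    """Per-sector IoU between result and ground truth.

    An objective proxy for the clinician's per-sector judgment.  A
    sector with no ground-truth pixels is reported as None (missing).
    """
    result = np.asarray(result).astype(bool)
    gt = np.asarray(gt).astype(bool)
    out: dict[str, float | None] = {}
    for name, sector in sectors.as_dict().items():
        if not (gt & sector).any():
            out[name] = None
            continue
        out[name] = iou(result & sector, gt & sector)
    return out


def score_from_flags(flags: tuple[bool, bool, bool, bool], zero_vs_one: int = 1) -> int:
    """FSE score from four per-sector accuracy flags.

    1..4 accurate sectors map to scores 2..5.  With no accurate sector
    the score is 0 or 1 at the rater's discretion (``zero_vs_one``);
    it is never auto-assigned by the objective proxies.
    """
    n = sum(bool(f) for f in flags)
    if n == 0:
        if zero_vs_one not in (0, 1):
            raise ValueError("zero_vs_one must be 0 or 1")
        return zero_vs_one
    return n + 1


@dataclass
class FseRecord:
    """One rater's score of one case."""

    case_id: str
    score: int
    flags: tuple[bool, bool, bool, bool]  # superior, nasal, inferior, temporal
    rater_id: str = "rater"

    def __post_init__(self) -> None:
        if not 0 <= self.score <= 5:
            raise ValueError("FSE score must be in 0..5")
        n = sum(bool(f) for f in self.flags)
        expected = None if n == 0 else n + 1
        if expected is not None and self.score != expected:
            raise ValueError(
                f"score {self.score} inconsistent with {n} accurate sectors"
            )
        if n == 0 and self.score not in (0, 1):
            raise ValueError("score with no accurate sector must be 0 or 1")


def fse_aggregate(records: list[FseRecord]) -> dict:
    """Mean score and per-level counts over a batch of FSE records."""
    if not records:
        raise ValueError("no FSE records supplied")
    scores = [r.score for r in records]
    counts = Counter(scores)
    return {
        "mean": float(np.mean(scores)),
        "counts": {level: counts.get(level, 0) for level in range(6)},
        "n": len(records),
    }
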
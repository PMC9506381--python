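"""Optic-disc localization and ROI extraction.

The optic disc is found by combining its three salient properties in a
fundus photograph: high vascular density (vessels converge on the disc),
high brightness, and an oval shape.  The six steps are

1. extract and invert the green channel (vessels are dark in green);
2. morphological top-hat to get a rough vessel map;
3. rank circular windows (radius = the assumed mean OD radius) by
   integrated vessel density, keep the top 20;
4. among those candidates keep the one containing the most of the
   brightest 2% of value-channel pixels;
5. cut a rough crop of side 4 OD diameters around it;
6. refine the center with a circular Hough transform and cut the final
   ROI of side 3 OD diameters.

The assumed mean OD radius is tied to the visible circular area: one
third of its radius for posterior images, one eighth for wide-angle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve
from skimage import feature, morphology, transform

__all__ = [
    "FundusImage",
    "RoiResult",
    "LocalizationError",
    "average_od_radius",
    "vessel_map",
    "top_density_circles",
    "select_bright_circle",
    "hough_correct",
    "detect_roi",
    "value_channel",
]


class LocalizationError(RuntimeError):
    """Raised when no plausible optic-disc location can be found."""


@dataclass
class FundusImage:
    """An RGB fundus photograph with optional field-of-view mask.

    ``rgb`` is an (H, W, 3) uint8 array.  ``fov_mask`` marks the visible
    circular area (wide-angle cameras image through a circular aperture);
    when absent it is derived from the image.  ``laterality`` is
    'left', 'right' or 'unknown' and is only consulted by the sector
    evaluation geometry.
    """

    rgb: np.ndarray
    fov_mask: Optional[np.ndarray] = None
    laterality: str = "unknown"

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb)
        if self.rgb.ndim != 3 or self.rgb.shape[-1] != 3:
            raise ValueError("rgb must be an (H, W, 3) array")
        if self.fov_mask is not None:
            self.fov_mask = np.asarray(self.fov_mask).astype(bool)
            if self.fov_mask.shape != self.rgb.shape[:2]:
                raise ValueError("fov_mask grid must match the rgb grid")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.rgb.shape[:2]

    def as_float(self) -> np.ndarray:
        if self.rgb.dtype == np.uint8:
            return self.rgb.astype(float) / 255.0
        return np.clip(self.rgb.astype(float), 0.0, 1.0)


@dataclass
class RoiResult:
    """Square ROI crop around the detected disc, in source coordinates."""

    crop: np.ndarray
    center: tuple[int, int]
    side_px: int
    od_radius_px: float
    low_confidence: bool = False

    def to_source(self, mask: np.ndarray, source_shape: tuple[int, int]) -> np.ndarray:
        """Paste an ROI-coordinate mask back onto the source grid."""
        mask = np.asarray(mask).astype(bool)
        out = np.zeros(source_shape, dtype=bool)
        half = self.side_px // 2
        r0, c0 = self.center[0] - half, self.center[1] - half
        rs, re = max(r0, 0), min(r0 + self.side_px, source_shape[0])
        cs, ce = max(c0, 0), min(c0 + self.side_px, source_shape[1])
        if rs < re and cs < ce:
            out[rs:re, cs:ce] = mask[rs - r0 : re - r0, cs - c0 : ce - c0]
        return out


def value_channel(image: FundusImage) -> np.ndarray:
    """HSV value channel (max over RGB), float in [0, 1]."""
    return image.as_float().max(axis=-1)


def _fov_mask_and_radius(image: FundusImage) -> tuple[np.ndarray, float]:
    if image.fov_mask is not None:
        mask = image.fov_mask
    else:
        v = value_channel(image)
        mask = v > 0.02
        if mask.any():
            lbl, n = ndimage.label(mask)
            if n > 1:
                sizes = ndimage.sum(mask, lbl, index=np.arange(1, n + 1))
                mask = lbl == (1 + int(np.argmax(sizes)))
            mask = ndimage.binary_fill_holes(mask)
    if not mask.any():
        raise LocalizationError("no visible circular area detected")
    area = float(mask.sum())
    radius = float(np.sqrt(area / np.pi))
    h, w = mask.shape
    radius = min(radius, min(h, w) / 2.0)
    return mask, radius


def average_od_radius(image: FundusImage, style: str = "posterior") -> float:
    """Assumed mean OD radius from the visible-area radius.

    One third of the field-of-view radius for posterior images, one
    eighth for wide-angle images.
    """
    _, r_fov = _fov_mask_and_radius(image)
    if style == "posterior":
        return r_fov / 3.0
    if style == "wide_angle":
        return r_fov / 8.0
    raise ValueError(f"unknown style {style!r}")


def vessel_map(image: FundusImage, od_radius: Optional[float] = None) -> np.ndarray:
    """Rough vessel-density map: top-hat of the inverted green channel.

    Vessels are dark thin curves with best contrast in green; inverting
    makes them bright ridges that a white top-hat (image minus opening)
    extracts.  The structuring disc radius is od_radius/10 so structures
    much wider than vessels are suppressed.  Zero outside the FOV.
    """
    fov, r_fov = _fov_mask_and_radius(image)
    if od_radius is None:
        od_radius = r_fov / 3.0
    green = image.as_float()[..., 1]
    inverted = 1.0 - green
    selem = morphology.disk(max(int(np.ceil(od_radius / 10.0)), 1))
    vmap = morphology.white_tophat(inverted, footprint=selem)
    vmap = np.where(fov, vmap, 0.0)
    # the aperture rim itself is a strong edge; suppress a thin margin
    eroded = ndimage.binary_erosion(fov, iterations=3, border_value=0)
    return np.where(eroded, vmap, 0.0)


def _disk_kernel(radius: int) -> np.ndarray:
    return morphology.disk(radius).astype(float)


def top_density_circles(
    vmap: np.ndarray, radius: float, k: int = 20
) -> list[tuple[int, int]]:
    """Centers of the k highest vessel-density circular windows.

    Density is the sum of the map inside a disc of the given radius;
    candidates are chosen greedily with non-maximum suppression so
    centers are at least ``radius`` apart.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if k < 1:
        raise ValueError("k must be >= 1")
    r = int(round(radius))
    kernel = _disk_kernel(r)
    score = fftconvolve(np.asarray(vmap, dtype=float), kernel, mode="same")
    score = np.ascontiguousarray(score)
    centers: list[tuple[int, int]] = []
    rr, cc = np.mgrid[0 : score.shape[0], 0 : score.shape[1]]
    for _ in range(k):
        idx = int(np.argmax(score))
        pr, pc = np.unravel_index(idx, score.shape)
        centers.append((int(pr), int(pc)))
        suppress = (rr - pr) ** 2 + (cc - pc) ** 2 < r * r
        score[suppress] = -np.inf
        if not np.isfinite(score).any():
            break
    if len(centers) < k:
        warnings.warn(f"only {len(centers)} candidate circles found (wanted {k})")
    return centers


def select_bright_circle(
    centers: list[tuple[int, int]],
    value: np.ndarray,
    radius: float,
    fov_mask: Optional[np.ndarray] = None,
) -> tuple[int, int]:
    """Candidate disc containing the most of the brightest 2% of pixels.

    The bright-pixel population is taken over the FOV; ties (including a
    uniform image where every pixel ties) fall back to the candidates'
    vessel-density rank.
    """
    if not centers:
        raise ValueError("no candidate centers supplied")
    value = np.asarray(value, dtype=float)
    pop = value[fov_mask] if fov_mask is not None else value.ravel()
    thr = np.quantile(pop, 0.98)
    bright = value >= thr
    if fov_mask is not None:
        bright &= fov_mask
    pop_size = pop.size if fov_mask is not None else value.size
    if bright.sum() > 0.05 * pop_size:
        # massive ties at the threshold value: restrict to strictly
        # brighter pixels so "the brightest 2%" keeps its meaning
        strict = value > thr
        if fov_mask is not None:
            strict &= fov_mask
        if not strict.any():
            return centers[0]  # uniform image: fall back to vessel rank
        bright = strict
    if not bright.any():
        return centers[0]
    rr, cc = np.mgrid[0 : value.shape[0], 0 : value.shape[1]]
    best, best_count = centers[0], -1
    for center in centers:  # iteration order = vessel rank, ties keep first
        pr, pc = center
        disc = (rr - pr) ** 2 + (cc - pc) ** 2 <= radius * radius
        count = int(np.count_nonzero(bright & disc))
        if count > best_count:
            best, best_count = center, count
    return best


def _crop_with_pad(arr: np.ndarray, center: tuple[int, int], side: int) -> np.ndarray:
    """Square crop centered at `center`, zero-padded where it leaves the grid."""
    h, w = arr.shape[:2]
    half = side // 2
    r0, c0 = center[0] - half, center[1] - half
    out_shape = (side, side) + arr.shape[2:]
    out = np.zeros(out_shape, dtype=arr.dtype)
    rs, re = max(r0, 0), min(r0 + side, h)
    cs, ce = max(c0, 0), min(c0 + side, w)
    if rs < re and cs < ce:
        out[rs - r0 : re - r0, cs - c0 : ce - c0] = arr[rs:re, cs:ce]
    return out


def hough_correct(
    rough_crop: np.ndarray, od_radius: float
) -> tuple[float, float, bool]:
    """Refine the disc center inside the rough crop via Hough circles.

    Searches radii in [0.5, 1.5] x od_radius on a Canny edge map and
    returns (row_offset, col_offset) of the strongest circle relative to
    the crop center, plus a found flag.  Falls back to (0, 0) when no
    circle is supported.
    """
    crop = np.asarray(rough_crop, dtype=float)
    if crop.ndim == 3:
        crop = crop.max(axis=-1)
    if crop.max() > crop.min():
        crop = (crop - crop.min()) / (crop.max() - crop.min())
    edges = feature.canny(crop, sigma=2.0)
    if not edges.any():
        return 0.0, 0.0, False
    radii = np.unique(
        np.round(np.linspace(0.5 * od_radius, 1.5 * od_radius, 15)).astype(int)
    )
    radii = radii[radii >= 3]
    if radii.size == 0:
        return 0.0, 0.0, False
    accum = transform.hough_circle(edges, radii)
    _, ccs, crs, _ = transform.hough_circle_peaks(accum, radii, total_num_peaks=1)
    if len(ccs) == 0:
        return 0.0, 0.0, False
    center = (crop.shape[0] - 1) / 2.0
    return float(crs[0] - center), float(ccs[0] - center), True


def detect_roi(image: FundusImage, style: str = "posterior") -> RoiResult:
    """Full six-step localization; returns the corrected square ROI.

    The crop side is three OD diameters, clamped to the source grid and
    zero-padded where the window exceeds it.  A low-confidence flag is
    set when the Hough refinement finds no circle.
    """
    fov, r_fov = _fov_mask_and_radius(image)
    od_radius = average_od_radius(image, style)
    vmap = vessel_map(image, od_radius)
    centers = top_density_circles(vmap, od_radius, k=20)
    value = value_channel(image)
    center = select_bright_circle(centers, value, od_radius, fov)

    rough_side = int(round(4 * 2 * od_radius))
    rough = _crop_with_pad(value, center, rough_side)
    dr, dc, found = hough_correct(rough, od_radius)
    if found:
        center = (int(round(center[0] + dr)), int(round(center[1] + dc)))
    else:
        warnings.warn("Hough refinement found no circle; keeping rough center")

    h, w = image.grid_shape
    center = (int(np.clip(center[0], 0, h - 1)), int(np.clip(center[1], 0, w - 1)))
    side = int(round(3 * 2 * od_radius))
    crop = _crop_with_pad(image.as_float(), center, side)
    return RoiResult(
        crop=crop,
        center=center,
        side_px=side,
        od_radius_px=od_radius,
        low_confidence=not found,
    )
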
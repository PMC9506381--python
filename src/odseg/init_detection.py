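"""Adaptive-threshold ellipse fitting: the level-set initial value.

The shape prior that stabilizes the evolution is an ellipse fitted to
the disc candidate extracted from the preprocessed ROI:

    adaptive threshold -> binary opening -> largest 4-connected
    component -> boundary trace -> direct least-squares ellipse fit

The adaptive threshold marks pixels at least as bright as their local
mean over a half-ROI window (offset C, default 0).  Because a
parapapillary-atrophy crescent is dimmer than the disc it usually
thresholds into a separate (or opened-away) component, so the fitted
ellipse - and with it the shape prior - excludes it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage import measure

from .ls_numerics import LevelSetField, sdf_from_mask

__all__ = [
    "EllipsePrior",
    "EllipseFitError",
    "adaptive_threshold",
    "largest_4cc",
    "morph_open_binary",
    "fit_ellipse",
    "detect_initial",
]

#: 4-connectivity structuring element for component labeling
_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


class EllipseFitError(RuntimeError):
    """Raised when boundary points do not determine an ellipse."""


@dataclass
class EllipsePrior:
    """A fitted ellipse and its signed-distance field (the shape model).

    ``semi_axes`` is ordered (a, b) with a >= b > 0; ``rotation`` is the
    angle of the a-axis in radians, measured from the column axis.
    """

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    rotation: float
    grid_shape: Optional[tuple[int, int]] = None
    _phi: Optional[LevelSetField] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        a, b = self.semi_axes
        if not (a >= b > 0):
            raise ValueError("semi-axes must satisfy a >= b > 0")

    def mask(self, grid_shape: Optional[tuple[int, int]] = None) -> np.ndarray:
        """Rasterized ellipse interior on a grid."""
        shape = grid_shape or self.grid_shape
        if shape is None:
            raise ValueError("no grid shape supplied")
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
        dr = rr - self.center[0]
        dc = cc - self.center[1]
        ca, sa = np.cos(self.rotation), np.sin(self.rotation)
        u = dc * ca + dr * sa
        v = -dc * sa + dr * ca
        a, b = self.semi_axes
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0

    @property
    def phi_initial(self) -> LevelSetField:
        """SDF of the ellipse (negative inside) on the attached grid."""
        if self._phi is None:
            self._phi = sdf_from_mask(self.mask())
        return self._phi

    def to_dict(self) -> dict:
        return {
            "center": [float(x) for x in self.center],
            "semi_axes": [float(x) for x in self.semi_axes],
            "rotation": float(self.rotation),
        }


def adaptive_threshold(
    img: np.ndarray,
    w: Optional[int] = None,
    h: Optional[int] = None,
    C: float = 0.0,
    valid: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Mean adaptive threshold: 1 where local mean - C <= pixel value.

    The local mean is taken over a w x h window centered at each pixel
    (reflect padding).  Defaults: w, h = half the ROI width/height.
    When a ``valid`` mask is given (e.g. the field of view inside an ROI
    that includes out-of-aperture black), the mean is normalized over
    valid pixels only and invalid pixels are never selected.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel image")
    if h is None:
        h = max(img.shape[0] // 2, 1)
    if w is None:
        w = max(img.shape[1] // 2, 1)
    if w < 1 or h < 1:
        raise ValueError("window dimensions must be >= 1")
    if w > 2 * img.shape[1] or h > 2 * img.shape[0]:
        raise ValueError("threshold window larger than twice the image")
    if valid is None:
        local_mean = ndimage.uniform_filter(img, size=(h, w), mode="reflect")
        return (local_mean - C) <= img
    valid = np.asarray(valid).astype(bool)
    num = ndimage.uniform_filter(np.where(valid, img, 0.0), size=(h, w), mode="reflect")
    den = ndimage.uniform_filter(valid.astype(float), size=(h, w), mode="reflect")
    local_mean = num / np.maximum(den, 1e-9)
    return ((local_mean - C) <= img) & valid


def morph_open_binary(mask: np.ndarray, element: int = 5) -> np.ndarray:
    """Binary opening with a small elliptical element (default 5x5).

    Breaks thin links between blobs so the disc separates from attached
    crescents and speckle before component selection.
    """
    mask = np.asarray(mask).astype(bool)
    if element < 3:
        return mask
    r = element // 2
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    footprint = yy * yy + xx * xx <= r * r
    return ndimage.binary_opening(mask, structure=footprint)


def largest_4cc(mask: np.ndarray) -> np.ndarray:
    """Largest 4-connected component; ties go to the topmost-leftmost blob."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("degenerate mask: no foreground pixels")
    labels, n = ndimage.label(mask, structure=_FOUR_CONN)
    if n == 1:
        return mask
    sizes = ndimage.sum(mask, labels, index=np.arange(1, n + 1))
    best_size = sizes.max()
    # scan labels in raster order of their first pixel: topmost-leftmost wins
    candidates = [i + 1 for i, s in enumerate(sizes) if s == best_size]
    if len(candidates) == 1:
        return labels == candidates[0]
    flat = labels.ravel()
    for lbl in flat:
        if lbl in candidates:
            return labels == lbl
    return labels == candidates[0]  # unreachable


def boundary_points(mask: np.ndarray) -> np.ndarray:
    """Outer boundary of a connected binary blob as (row, col) points."""
    contours = measure.find_contours(np.asarray(mask).astype(float), 0.5)
    if not contours:
        raise ValueError("degenerate mask: no boundary found")
    return max(contours, key=len)


def fit_ellipse(
    boundary: np.ndarray, grid_shape: Optional[tuple[int, int]] = None
) -> EllipsePrior:
    """Direct least-squares ellipse fit to boundary points.

    Needs at least 5 points in general position.  Returns geometric
    parameters normalized to a >= b with the rotation of the major axis.
    """
    pts = np.asarray(boundary, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 5:
        raise EllipseFitError("ellipse fit needs at least 5 boundary points")
    # EllipseModel works in (x, y) = (col, row)
    xy = np.column_stack([pts[:, 1], pts[:, 0]])
    model = measure.EllipseModel.from_estimate(xy)
    if not model:
        raise EllipseFitError("degenerate boundary configuration")
    xc, yc = model.center
    a, b = model.axis_lengths
    theta = model.theta
    if not (np.isfinite([xc, yc, a, b, theta]).all() and a > 0 and b > 0):
        raise EllipseFitError("ellipse fit did not converge")
    if b > a:
        a, b = b, a
        theta += np.pi / 2.0
    theta = float(np.mod(theta, np.pi))
    return EllipsePrior(
        center=(float(yc), float(xc)),
        semi_axes=(float(a), float(b)),
        rotation=theta,
        grid_shape=grid_shape,
    )


def detect_initial(
    roi_preprocessed: np.ndarray,
    C: float = 0.0,
    open_element: int = 5,
    valid: Optional[np.ndarray] = None,
) -> EllipsePrior:
    """Initial-value detection on a preprocessed ROI.

    Runs the adaptive threshold, opens away thin links, keeps the
    largest 4-connected blob, traces its boundary and fits the ellipse.
    A PPA crescent dimmer than the disc is excluded whenever these steps
    leave it disconnected from the disc blob.  ``valid`` restricts the
    analysis to the field of view when the ROI contains black padding.
    """
    roi = np.asarray(roi_preprocessed, dtype=float)
    mask = adaptive_threshold(roi, C=C, valid=valid)
    if not mask.any() or mask.all():
        raise ValueError(
            "degenerate mask: adaptive threshold selected nothing or everything"
        )
    mask = morph_open_binary(mask, element=open_element)
    if not mask.any():
        raise ValueError("degenerate mask: opening removed all foreground")
    blob = largest_4cc(mask)
    pts = boundary_points(blob)
    return fit_ellipse(pts, grid_shape=roi.shape)
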
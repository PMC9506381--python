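"""Scalar primitives of the level-set machinery.

A contour is represented implicitly as the zero level set of a scalar
field phi.  Throughout this package phi follows the convention

    phi < 0  inside the object,   phi > 0  outside.

The regularized Heaviside/Dirac pair smears the region indicator over a
band of half-width ``eps`` (pixels) so that region and length energies
can be written as integrals over the whole grid.  The double-well
derivative is the restoring force that keeps ``|grad phi|`` near 1, which
is what makes reinitialization of phi unnecessary during evolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "LevelSetField",
    "DEFAULT_EPS",
    "GRAD_FLOOR",
    "heaviside_eps",
    "dirac_eps",
    "dw_deriv",
    "sdf_from_mask",
    "gradient",
    "curvature",
]

#: default half-width of the regularized Heaviside/Dirac band (pixels)
DEFAULT_EPS = 1.5

#: floor applied to |grad phi| before any division
GRAD_FLOOR = 1e-8


@dataclass
class LevelSetField:
    """Scalar field phi on a pixel grid; the zero level set is the contour.

    When built as a signed distance function (SDF) from a mask, values are
    negative inside the mask, positive outside, and |value| is the
    Euclidean distance to the mask boundary.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("level-set field must be a 2-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("level-set field must be finite everywhere")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.values.shape

    def inside_mask(self) -> np.ndarray:
        """Boolean mask of the region enclosed by the contour ({phi < 0})."""
        return self.values < 0


def _check_eps(eps: float) -> float:
    eps = float(eps)
    if not eps > 0:
        raise ValueError(f"eps must be positive, got {eps}")
    return eps


def heaviside_eps(x, eps: float = DEFAULT_EPS):
    """Regularized Heaviside step H_eps(x) in [0, 1].

    1 for x > eps, 0 for x < -eps, and the smooth sine blend
    (1/2)(1 + x/eps + sin(pi x/eps)/pi) inside the band.  Satisfies
    H(x) + H(-x) = 1 exactly.
    """
    eps = _check_eps(eps)
    x = np.asarray(x, dtype=float)
    band = 0.5 * (1.0 + x / eps + np.sin(np.pi * x / eps) / np.pi)
    out = np.where(x > eps, 1.0, np.where(x < -eps, 0.0, band))
    out = np.clip(out, 0.0, 1.0)  # guard float round-off at +-eps
    return out if out.ndim else float(out)


def dirac_eps(x, eps: float = DEFAULT_EPS):
    """Regularized Dirac delta, the derivative of :func:`heaviside_eps`.

    (1/2eps)(1 + cos(pi x/eps)) for |x| <= eps, zero outside; integrates
    to 1 over the band.
    """
    eps = _check_eps(eps)
    x = np.asarray(x, dtype=float)
    band = (1.0 + np.cos(np.pi * x / eps)) / (2.0 * eps)
    out = np.where(np.abs(x) > eps, 0.0, band)
    return out if out.ndim else float(out)


def dw_deriv(s):
    """Derivative p'(s) of the double-well potential of the distance regularizer.

    sin(2 pi s)/(2 pi) for s <= 1 and s - 1 for s > 1; vanishes at s = 0
    and s = 1 so the flow it drives restores |grad phi| toward 1 (away
    from 0).  Both branches meet continuously at s = 1.
    """
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("dw_deriv expects s = |grad phi| >= 0")
    out = np.where(s <= 1.0, np.sin(2.0 * np.pi * s) / (2.0 * np.pi), s - 1.0)
    return out if out.ndim else float(out)


def sdf_from_mask(mask: np.ndarray) -> LevelSetField:
    """Signed Euclidean distance field of a binary mask (negative inside).

    The zero crossing lies on the mask boundary and the mask is recovered
    as ``{phi < 0}``.  Raises on an empty or full mask, for which no
    boundary exists.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any() or mask.all():
        raise ValueError("degenerate mask: empty or full grid has no boundary")
    d_out = ndimage.distance_transform_edt(~mask)
    d_in = ndimage.distance_transform_edt(mask)
    # subtract half a pixel from each side so the zero set sits on the
    # boundary between inside and outside samples
    phi = np.where(mask, -(d_in - 0.5), d_out - 0.5)
    return LevelSetField(phi)


def gradient(phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference gradient (d/drow, d/dcol)."""
    return np.gradient(np.asarray(phi, dtype=float))


def curvature(phi: np.ndarray) -> np.ndarray:
    """Mean curvature div(grad phi / |grad phi|) by central differences.

    |grad phi| is floored at a small constant so critical points do not
    blow up; zero for planar fields.  On an SDF of a circle of radius r
    the value on the zero set is approximately 1/r.
    """
    phi = np.asarray(phi, dtype=float)
    if not np.all(np.isfinite(phi)):
        raise ValueError("curvature requires a finite field")
    gr, gc = np.gradient(phi)
    norm = np.sqrt(gr * gr + gc * gc)
    norm = np.maximum(norm, GRAD_FLOOR)
    nr = gr / norm
    nc = gc / norm
    return np.gradient(nr, axis=0) + np.gradient(nc, axis=1)
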
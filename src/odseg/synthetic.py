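"""Seeded generator of fundus-like test images with known ground truth.

Real fundus photographs show a bright, roughly elliptical optic disc (OD)
on a darker orange retina, dark blood vessels converging on and crossing
the disc, and - in the difficult cases - a parapapillary-atrophy (PPA)
crescent hugging the disc boundary, bright noise blobs nearby, and (for
wide-angle cameras) a circular aperture with a dark surround and almost
no blue-channel signal.  The generator renders exactly these confounds
with controllable geometry so every downstream stage can be tested
against an analytically known ground-truth mask.

Rendering is a pure function of (spec, seed): the same spec renders to
bit-identical images.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .roi_detection import FundusImage

__all__ = ["SynthSpec", "render", "standard_suite", "STRATA"]

#: the six stress conditions covered by :func:`standard_suite`
STRATA = (
    "clean",
    "vessels",
    "ppa",
    "bright_blob",
    "low_contrast",
    "wide_angle",
)


@dataclass
class SynthSpec:
    """Declarative description of one synthetic fundus image.

    Intensities are in [0, 1] and refer to the value (max-RGB) channel;
    the RGB rendering keeps red >= green >= blue as in real fundus
    photographs.  ``od_axes`` are semi-axes in pixels.
    """

    grid_shape: tuple[int, int] = (320, 320)
    od_center: tuple[float, float] = (160.0, 160.0)
    od_axes: tuple[float, float] = (52.0, 44.0)
    od_rotation: float = 0.3
    od_intensity: float = 0.88
    background_intensity: float = 0.42
    radial_gradient: float = 0.08
    vessels: Sequence[tuple] = field(default_factory=list)
    # vessel entries: (control_points [(r,c)...], width_px, intensity)
    ppa: Optional[tuple[float, float, float, float]] = None
    # (angle_center_rad, angular_span_rad, radial_thickness_px, intensity)
    bright_blobs: Sequence[tuple[tuple[float, float], float, float]] = field(
        default_factory=list
    )
    style: str = "posterior"
    noise_sigma: float = 0.01
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def _ellipse_field(shape, center, axes, rotation):
    """Normalized radius field: < 1 inside the ellipse, 1 on it."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    dr = rr - center[0]
    dc = cc - center[1]
    ca, sa = np.cos(rotation), np.sin(rotation)
    u = dc * ca + dr * sa
    v = -dc * sa + dr * ca
    a, b = axes
    return np.sqrt((u / a) ** 2 + (v / b) ** 2)


def _soft_edge(field, width):
    """1 inside (field < 1), 0 outside, smooth ramp of ~width in field units."""
    return np.clip((1.0 - field) / max(width, 1e-9) + 0.5, 0.0, 1.0)


def _polyline_distance(shape, points):
    """Per-pixel distance to a polyline given by control points."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    dist = np.full(shape, np.inf)
    pts = np.asarray(points, dtype=float)
    for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
        dr, dc = r1 - r0, c1 - c0
        denom = dr * dr + dc * dc
        if denom < 1e-12:
            d = np.hypot(rr - r0, cc - c0)
        else:
            t = ((rr - r0) * dr + (cc - c0) * dc) / denom
            t = np.clip(t, 0.0, 1.0)
            d = np.hypot(rr - (r0 + t * dr), cc - (c0 + t * dc))
        dist = np.minimum(dist, d)
    return dist


def render(spec: SynthSpec) -> tuple[FundusImage, np.ndarray]:
    """Render a spec to an (image, ground-truth OD mask) pair.

    The ground truth is the rasterized OD ellipse.  Raises if the OD
    does not fit inside the field of view.
    """
    shape = tuple(spec.grid_shape)
    h, w = shape
    rng = np.random.default_rng(spec.seed)

    fov_radius = min(h, w) / 2.0 - 2.0
    fov_center = (h / 2.0, w / 2.0)
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    r_from_center = np.hypot(rr - fov_center[0], cc - fov_center[1])
    fov_mask = r_from_center <= fov_radius

    od_extent = max(spec.od_axes)
    od_offset = np.hypot(
        spec.od_center[0] - fov_center[0], spec.od_center[1] - fov_center[1]
    )
    if od_offset + od_extent > fov_radius:
        raise ValueError("invalid spec: OD ellipse extends outside the field of view")

    # value-channel composition -------------------------------------------
    value = np.full(shape, spec.background_intensity)
    value -= spec.radial_gradient * (r_from_center / max(fov_radius, 1.0)) ** 2

    od_field = _ellipse_field(shape, spec.od_center, spec.od_axes, spec.od_rotation)
    edge_w = 2.0 / min(spec.od_axes)  # ~2 px soft edge in normalized units
    od_alpha = _soft_edge(od_field, edge_w)

    if spec.ppa is not None:
        ang0, span, thickness, inten = spec.ppa
        a, b = spec.od_axes
        outer = _ellipse_field(
            shape, spec.od_center, (a + thickness, b + thickness), spec.od_rotation
        )
        ring = _soft_edge(outer, 2.0 / (min(spec.od_axes) + thickness)) * (1 - od_alpha)
        theta = np.arctan2(-(rr - spec.od_center[0]), cc - spec.od_center[1])
        dang = np.angle(np.exp(1j * (theta - ang0)))
        angular = np.clip((span / 2 - np.abs(dang)) / 0.15 + 0.5, 0.0, 1.0)
        value = value + ring * angular * (inten - value)

    value = value + od_alpha * (spec.od_intensity - value)

    for center, radius, inten in spec.bright_blobs:
        blob_field = _ellipse_field(shape, center, (radius, radius), 0.0)
        blob_alpha = _soft_edge(blob_field, 2.0 / max(radius, 1.0))
        value = value + blob_alpha * (inten - value)

    for points, width, inten in spec.vessels:
        d = _polyline_distance(shape, points)
        profile = np.exp(-0.5 * (d / (width / 2.0)) ** 2)
        value = value + profile * (inten - value) * 0.9

    value = np.clip(value, 0.0, 1.0)

    # RGB: fundus-like warm palette; V channel (max of RGB) equals `value`
    red = value
    green = np.clip(value * 0.62, 0.0, 1.0)
    blue = np.clip(value * 0.18, 0.0, 1.0)
    if spec.style == "wide_angle":
        blue = np.zeros_like(value)  # red/green light sources only
    rgb = np.stack([red, green, blue], axis=-1)
    if spec.noise_sigma > 0:
        rgb = rgb + rng.normal(0.0, spec.noise_sigma, rgb.shape)  # sensor noise
        rgb = np.clip(rgb, 0.0, 1.0)
    rgb[~fov_mask] = 0.0
    rgb8 = np.round(rgb * 255.0).astype(np.uint8)

    gt = _ellipse_field(shape, spec.od_center, spec.od_axes, spec.od_rotation) <= 1.0
    image = FundusImage(rgb=rgb8, fov_mask=fov_mask, laterality="right")
    return image, gt


def _case_spec(stratum: str, rng: np.random.Generator, seed: int) -> SynthSpec:
    # wide-angle frames are larger so the disc stays well above the fixed
    # preprocessing kernel scale despite being a smaller FOV fraction
    shape = (320, 320) if stratum != "wide_angle" else (640, 640)
    fov_r = min(shape) / 2.0 - 2.0
    # posterior convention: mean OD radius is one third of the FOV radius
    base_r = fov_r / 3.0
    if stratum == "wide_angle":
        base_r = fov_r / 8.0
    r = base_r * rng.uniform(0.85, 1.1)
    ecc = rng.uniform(0.78, 0.95)
    axes = (r, r * ecc)
    max_off = (fov_r - r) * 0.35
    ang = rng.uniform(0, 2 * np.pi)
    off = rng.uniform(0.0, max_off)
    center = (shape[0] / 2.0 + off * np.sin(ang), shape[1] / 2.0 + off * np.cos(ang))

    od_int, bg_int = 0.88, 0.42
    noise = 0.01
    if stratum == "low_contrast":
        od_int, bg_int = 0.66, 0.46
        noise = 0.02
    if stratum == "wide_angle":
        od_int, bg_int = 0.78, 0.40

    vessels = []
    if stratum not in ("clean",):
        n_v = 3 if stratum != "vessels" else 4
        for _ in range(n_v):
            a0 = rng.uniform(0, 2 * np.pi)
            pts = []
            for t in np.linspace(-1.3, 1.3, 5):
                rad = t * fov_r * 0.85
                wob = rng.normal(0, 6.0)
                pr = center[0] + rad * np.sin(a0) + wob
                pc = center[1] + rad * np.cos(a0) - wob
                pts.append((pr, pc))
            width = rng.uniform(3.0, 5.0)
            vessels.append((pts, width, 0.10))

    ppa = None
    if stratum == "ppa":
        # atrophy crescent: clearly brighter than retina (misleads the
        # region term) but dimmer than the disc, as in real PPA-beta
        ppa = (
            rng.uniform(0, 2 * np.pi),
            rng.uniform(1.2, 2.2),
            r * rng.uniform(0.25, 0.4),
            bg_int + rng.uniform(0.15, 0.25) * (od_int - bg_int),
        )

    blobs = []
    if stratum == "bright_blob":
        bang = rng.uniform(0, 2 * np.pi)
        brad = r * rng.uniform(0.20, 0.30)
        # gap wider than the closing reach so the adaptive threshold
        # separates blob and disc; a blob fused to the disc (gap below
        # the closing reach) corrupts the prior and is the method's
        # documented failure mode, exercised by the dedicated ablation
        # fixture rather than the standard suite
        dist = max(axes) + brad + rng.uniform(14.0, 20.0)
        bc = (center[0] + dist * np.sin(bang), center[1] + dist * np.cos(bang))
        # keep the blob inside the FOV
        d_fov = np.hypot(bc[0] - shape[0] / 2, bc[1] - shape[1] / 2)
        if d_fov + brad > fov_r - 2:
            bc = (
                center[0] - dist * np.sin(bang),
                center[1] - dist * np.cos(bang),
            )
        blobs.append((bc, brad, od_int * 0.97))

    return SynthSpec(
        grid_shape=shape,
        od_center=center,
        od_axes=axes,
        od_rotation=rng.uniform(0, np.pi),
        od_intensity=od_int,
        background_intensity=bg_int,
        vessels=vessels,
        ppa=ppa,
        bright_blobs=blobs,
        style="wide_angle" if stratum == "wide_angle" else "posterior",
        noise_sigma=noise,
        seed=seed,
    )


def standard_suite(
    n: int = 40, seed: int = 7
) -> list[tuple[FundusImage, np.ndarray, SynthSpec]]:
    """Generate ``n`` cases stratified over the six stress conditions.

    Strata cycle (clean, vessel-occluded, +PPA, +bright blob,
    low-contrast, wide-angle) so any n >= 6k gives at least k cases per
    stratum.  Fully reproducible from ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        stratum = STRATA[i % len(STRATA)]
        case_seed = int(rng.integers(0, 2**31 - 1))
        spec = _case_spec(stratum, rng, case_seed)
        image, gt = render(spec)
        out.append((image, gt, spec))
    return out
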
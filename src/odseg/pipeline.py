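"""End-to-end orchestration: localize, preprocess, initialize, evolve.

``segment_case`` chains the stages on one image and returns the mask in
source coordinates with a per-stage report; ``evaluate_batch`` pairs
result and ground-truth masks by filename and produces the IoU summary
(max/min/mean/variance plus the three IoU bands).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import ndimage

from . import io as odseg_io
from .evaluation import iou
from .hlsm import HlsmParams, evolve
from .init_detection import detect_initial
from .preprocessing import PreprocParams, remove_vessels_noise
from .roi_detection import FundusImage, detect_roi

__all__ = ["RunConfig", "segment_case", "segment_image", "evaluate_batch"]


@dataclass
class RunConfig:
    """Everything a segmentation run depends on; YAML round-trippable."""

    style: str = "posterior"
    laterality: str = "right"
    hlsm: HlsmParams = field(default_factory=HlsmParams)
    preproc: PreprocParams = field(default_factory=PreprocParams)
    threshold_C: float = 0.0
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "style": self.style,
            "laterality": self.laterality,
            "hlsm": self.hlsm.to_dict(),
            "preproc": {
                "gauss_kernel": self.preproc.gauss_kernel,
                "gauss_sigma": self.preproc.gauss_sigma,
                "morph_ellipse": self.preproc.morph_ellipse,
                "morph_iters": self.preproc.morph_iters,
                "lowpass_side": self.preproc.lowpass_side,
            },
            "threshold_C": self.threshold_C,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            style=d.get("style", "posterior"),
            laterality=d.get("laterality", "right"),
            hlsm=HlsmParams(**d.get("hlsm", {})),
            preproc=PreprocParams(**d.get("preproc", {})),
            threshold_C=d.get("threshold_C", 0.0),
            seed=d.get("seed", 0),
        )


def segment_image(
    image: FundusImage, config: Optional[RunConfig] = None
) -> tuple[np.ndarray, dict]:
    """Segment the optic disc of an in-memory image.

    Returns (mask in source coordinates, report).  The report records
    ROI geometry, the ellipse prior, iteration count, convergence flag
    and per-stage timings.
    """
    if config is None:
        config = RunConfig()
    report: dict = {"stages": {}}

    def timed(name, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except Exception as exc:  # keep partial outputs for debugging
            report["failed_stage"] = name
            report["error"] = f"{type(exc).__name__}: {exc}"
            raise
        report["stages"][name] = round(time.perf_counter() - t0, 4)
        return out

    roi = timed("roi_detection", detect_roi, image, config.style)
    report["roi"] = {
        "center": list(roi.center),
        "side_px": roi.side_px,
        "od_radius_px": roi.od_radius_px,
        "low_confidence": roi.low_confidence,
    }

    value = roi.crop.max(axis=-1) if roi.crop.ndim == 3 else roi.crop
    preproc = config.preproc.scaled_for(roi.side_px)
    clean = timed("vessel_noise_removal", remove_vessels_noise, value, preproc)
    # restrict thresholding to the field of view: the square ROI can
    # include out-of-aperture black, eroded past the low-pass rim halo
    valid = ndimage.binary_erosion(value > 0.02, iterations=10, border_value=0)
    if not valid.any():
        valid = None
    prior = timed("initial_value", detect_initial, clean, config.threshold_C,
                  valid=valid)
    report["prior"] = prior.to_dict()

    result = timed("evolution", evolve, clean, prior, config.hlsm)
    report["iterations"] = result.iterations
    report["converged"] = result.converged
    report["energy_trace"] = result.energy_trace

    mask = roi.to_source(result.mask, image.grid_shape)
    return mask, report


def segment_case(
    image_path: str | Path, config: Optional[RunConfig] = None
) -> tuple[np.ndarray, dict]:
    """Segment the optic disc of an image file (PNG/TIFF/JPEG)."""
    path = Path(image_path)
    if not path.exists():
        raise FileNotFoundError(path)
    if config is None:
        config = RunConfig()
    image = odseg_io.read_image(path, laterality=config.laterality)
    mask, report = segment_image(image, config)
    report["image"] = str(path)
    return mask, report


def evaluate_batch(mask_dir: str | Path, gt_dir: str | Path) -> dict:
    """Per-case IoU and the seven-row summary over paired mask files.

    Masks are paired by filename; unpaired files are listed and excluded
    from the statistics.
    """
    mask_dir, gt_dir = Path(mask_dir), Path(gt_dir)
    masks = {p.name: p for p in sorted(mask_dir.glob("*.png"))}
    gts = {p.name: p for p in sorted(gt_dir.glob("*.png"))}
    paired = sorted(set(masks) & set(gts))
    unpaired = sorted(set(masks) ^ set(gts))
    per_case = {}
    for name in paired:
        a = odseg_io.read_mask(masks[name])
        b = odseg_io.read_mask(gts[name])
        per_case[name] = iou(a, b)
    values = np.array(list(per_case.values()), dtype=float)
    if values.size:
        summary = {
            "max_iou": float(values.max()),
            "min_iou": float(values.min()),
            "mean_iou": float(values.mean()),
            "var_iou": float(values.var()),
            "n_iou_ge_0.9": int(np.count_nonzero(values >= 0.9)),
            "n_iou_0.8_0.9": int(
                np.count_nonzero((values >= 0.8) & (values < 0.9))
            ),
            "n_iou_lt_0.8": int(np.count_nonzero(values < 0.8)),
        }
    else:
        summary = {}
    return {"per_case": per_case, "summary": summary, "unpaired": unpaired}


def save_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=float))
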
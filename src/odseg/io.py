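"""Raster and config I/O helpers (PNG/TIFF/JPEG via imageio, YAML configs)."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .roi_detection import FundusImage

__all__ = ["read_image", "write_image", "read_mask", "write_mask",
           "load_config", "save_config"]


def read_image(path: str | Path, laterality: str = "unknown") -> FundusImage:
    """Read an RGB fundus raster; grayscale inputs are replicated to RGB."""
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    return FundusImage(rgb=arr, laterality=laterality)


def write_image(path: str | Path, rgb: np.ndarray) -> None:
    rgb = np.asarray(rgb)
    if rgb.dtype != np.uint8:
        rgb = np.round(np.clip(rgb, 0.0, 1.0) * 255).astype(np.uint8)
    iio.imwrite(path, rgb)


def read_mask(path: str | Path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 127


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(path, (np.asarray(mask).astype(np.uint8) * 255))


def load_config(path: str | Path):
    from .pipeline import RunConfig

    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


def save_config(config, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
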
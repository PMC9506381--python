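"""Channel selection and vessel/noise removal.

Which color channel to segment is decided quantitatively with the
contrast-to-noise ratio

    CNR = (mean_fg - mean_bg) / std_bg

computed over nine channels (R, G, B, H, S, V, L, A, B*) with the disc
as foreground.  On fundus data the HSV value channel wins, which is why
the rest of the pipeline operates on it.

Vessels and high-frequency noise are then removed from the ROI by a
fixed three-stage chain: Gaussian blur (17x17, sigma 1), grayscale
morphological closing then opening (15x15 elliptical element, 3
iterations each - the product of element size and iterations must exceed
the vessel thickness), and a hard FFT low-pass keeping a 40x40 square
around DC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import color, morphology

from .roi_detection import FundusImage

__all__ = [
    "CHANNELS",
    "CnrReport",
    "PreprocParams",
    "cnr",
    "channel_stack",
    "rank_channels",
    "remove_vessels_noise",
]

#: channel order used everywhere (also the tie-break order)
CHANNELS = ("red", "green", "blue", "hue", "saturation", "value",
            "lightness", "a", "b")


@dataclass
class PreprocParams:
    """Vessel/noise-removal parameters.

    Defaults are stated for a ~600 px reference ROI.  The spatial
    kernels (Gaussian, morphological element) are physical sizes and
    must shrink with the ROI to keep the chain scale-covariant;
    :meth:`scaled_for` does this against ``reference_roi``.  The
    low-pass mask lives in frequency space, where a fixed side already
    selects the same relative cutoff at any ROI size, so it never
    scales.
    """

    gauss_kernel: int = 17
    gauss_sigma: float = 1.0
    morph_ellipse: int = 15
    morph_iters: int = 3
    lowpass_side: int = 40
    reference_roi: int = 600

    def __post_init__(self) -> None:
        if self.gauss_kernel % 2 == 0 or self.morph_ellipse % 2 == 0:
            raise ValueError("kernel sizes must be odd")
        if self.morph_iters < 1 or self.lowpass_side < 1:
            raise ValueError("morph_iters and lowpass_side must be >= 1")

    def scaled_for(self, roi_side: int) -> "PreprocParams":
        """Parameters with spatial kernels rescaled to an ROI side."""
        s = roi_side / self.reference_roi

        def odd(x: float, lo: int = 3) -> int:
            k = max(int(round(x)), lo)
            return k if k % 2 == 1 else k + 1

        return PreprocParams(
            gauss_kernel=odd(self.gauss_kernel * s),
            gauss_sigma=max(self.gauss_sigma * s, 0.5),
            morph_ellipse=odd(self.morph_ellipse * s),
            morph_iters=self.morph_iters,
            lowpass_side=self.lowpass_side,
            reference_roi=roi_side,
        )


@dataclass
class CnrReport:
    """Per-channel CNR means/variances across a set of images."""

    mean: dict[str, float]
    variance: dict[str, float]
    chosen_channel: str = field(init=False)

    def __post_init__(self) -> None:
        best = max(self.mean, key=lambda ch: (self.mean[ch], -CHANNELS.index(ch)))
        # deterministic tie-break: earliest channel in CHANNELS order
        top = self.mean[best]
        for ch in CHANNELS:
            if ch in self.mean and self.mean[ch] == top:
                best = ch
                break
        self.chosen_channel = best

    def as_rows(self) -> list[tuple[str, float, float]]:
        return [(ch, self.mean[ch], self.variance[ch]) for ch in CHANNELS]


def cnr(img: np.ndarray, fg: np.ndarray, bg: np.ndarray) -> float:
    """Contrast-to-noise ratio of a single channel.

    (mean over foreground - mean over background) / population std over
    background.  Masks must be non-empty and disjoint; a constant
    background makes the ratio undefined.
    """
    img = np.asarray(img, dtype=float)
    fg = np.asarray(fg).astype(bool)
    bg = np.asarray(bg).astype(bool)
    if not fg.any() or not bg.any():
        raise ValueError("foreground and background masks must be non-empty")
    if (fg & bg).any():
        raise ValueError("foreground and background masks overlap")
    sd = float(img[bg].std())
    if sd == 0.0:
        raise ZeroDivisionError("undefined CNR: constant background")
    return float((img[fg].mean() - img[bg].mean()) / sd)


def channel_stack(image: FundusImage) -> dict[str, np.ndarray]:
    """The nine analysis channels of an image as float arrays."""
    rgb = image.as_float()
    hsv = color.rgb2hsv(rgb)
    lab = color.rgb2lab(rgb)
    return {
        "red": rgb[..., 0],
        "green": rgb[..., 1],
        "blue": rgb[..., 2],
        "hue": hsv[..., 0],
        "saturation": hsv[..., 1],
        "value": hsv[..., 2],
        "lightness": lab[..., 0],
        "a": lab[..., 1],
        "b": lab[..., 2],
    }


def rank_channels(
    images: list[FundusImage], gts: list[np.ndarray]
) -> CnrReport:
    """CNR of every channel across paired (image, OD ground truth) lists.

    Foreground is the disc; background is everything else inside the
    FOV.  The chosen channel maximizes mean CNR (ties resolved in fixed
    R, G, B, H, S, V, L, A, B* order).
    """
    if not images or len(images) != len(gts):
        raise ValueError("need non-empty paired image/ground-truth lists")
    per_channel: dict[str, list[float]] = {ch: [] for ch in CHANNELS}
    for image, gt in zip(images, gts):
        gt = np.asarray(gt).astype(bool)
        fov = image.fov_mask if image.fov_mask is not None else np.ones_like(gt)
        bg = fov.astype(bool) & ~gt
        for ch, arr in channel_stack(image).items():
            per_channel[ch].append(cnr(arr, gt, bg))
    mean = {ch: float(np.mean(v)) for ch, v in per_channel.items()}
    var = {ch: float(np.var(v)) for ch, v in per_channel.items()}
    return CnrReport(mean=mean, variance=var)


def _elliptical_footprint(size: int) -> np.ndarray:
    return morphology.disk(size // 2)


def lowpass_fft(img: np.ndarray, side: int) -> np.ndarray:
    """Hard FFT low-pass: keep a side x side square centered at DC.

    The pass region is realized symmetrically about DC (|k| < side/2 in
    each axis) so the kept spectrum stays Hermitian and the output is
    exactly real and band-limited.
    """
    spec = np.fft.fftshift(np.fft.fft2(img))
    h, w = img.shape
    kr = np.arange(h) - h // 2
    kc = np.arange(w) - w // 2
    mask = (np.abs(kr)[:, None] < side / 2) & (np.abs(kc)[None, :] < side / 2)
    return np.real(np.fft.ifft2(np.fft.ifftshift(spec * mask)))


def remove_vessels_noise(
    roi: np.ndarray, params: PreprocParams | None = None
) -> np.ndarray:
    """Remove dark vessels and high-frequency noise from a single-channel ROI.

    Gaussian blur -> grayscale closing then opening (closing fills the
    dark vessel troughs, opening shaves residual bright specks) -> hard
    FFT low-pass.  Input and output are in [0, 1].
    """
    if params is None:
        params = PreprocParams()
    roi = np.asarray(roi, dtype=float)
    if roi.ndim != 2:
        raise ValueError("ROI must be single-channel")
    if min(roi.shape) < max(params.gauss_kernel, params.morph_ellipse):
        raise ValueError("ROI smaller than the processing kernels")

    # truncated Gaussian matching a gauss_kernel x gauss_kernel stencil
    radius = params.gauss_kernel // 2
    out = ndimage.gaussian_filter(
        roi, params.gauss_sigma, mode="reflect", radius=radius
    )

    # "iterations" compose the elementary dilations/erosions (so closing
    # with k iterations reaches ~k times the element radius); the product
    # of element size and iterations must exceed the vessel thickness
    footprint = _elliptical_footprint(params.morph_ellipse)
    for _ in range(params.morph_iters):  # closing: fills dark vessel troughs
        out = ndimage.grey_dilation(out, footprint=footprint, mode="reflect")
    for _ in range(params.morph_iters):
        out = ndimage.grey_erosion(out, footprint=footprint, mode="reflect")
    for _ in range(params.morph_iters):  # opening: shaves bright specks
        out = ndimage.grey_erosion(out, footprint=footprint, mode="reflect")
    for _ in range(params.morph_iters):
        out = ndimage.grey_dilation(out, footprint=footprint, mode="reflect")

    out = lowpass_fft(out, params.lowpass_side)
    return np.clip(out, 0.0, 1.0)
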
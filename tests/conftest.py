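"""Shared fixtures: all test inputs are generated programmatically."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from odseg.init_detection import EllipsePrior
from odseg.preprocessing import PreprocParams, remove_vessels_noise
from odseg.synthetic import SynthSpec, render, standard_suite


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def small_suite():
    """Twelve stratified synthetic cases (two per stress condition)."""
    return standard_suite(12, seed=7)


@pytest.fixture(scope="session")
def disc_sdf_101():
    """SDF of a centered radius-20 disc on a 101x101 grid."""
    from odseg.ls_numerics import sdf_from_mask

    yy, xx = np.mgrid[-50:51, -50:51]
    mask = np.hypot(yy, xx) <= 20
    return mask, sdf_from_mask(mask)


@pytest.fixture(scope="session")
def blob_roi_fixture():
    """ROI-level scene: disc plus a connected dimmer bright blob.

    Returns (preprocessed image, gt mask, true-ellipse prior, blob mask).
    The blob sits one closing-reach away from the disc so preprocessing
    bridges the gap - the leak path an unconstrained contour follows.
    """
    from odseg.synthetic import _ellipse_field

    shape = (240, 240)
    ctr, axes, rot = (120, 120), (48, 42), 0.3
    brad, gap, bint = 14, 6, 0.75
    spec = SynthSpec(
        grid_shape=shape,
        od_center=ctr,
        od_axes=axes,
        od_rotation=rot,
        bright_blobs=[((120, 120 + 48 + brad + gap), brad, bint)],
        seed=11,
    )
    img, gt = render(spec)
    clean = remove_vessels_noise(
        img.as_float().max(axis=-1), PreprocParams().scaled_for(shape[0])
    )
    prior = EllipsePrior(center=ctr, semi_axes=axes, rotation=rot, grid_shape=shape)
    blob = _ellipse_field(shape, spec.bright_blobs[0][0], (brad, brad), 0.0) <= 1.0
    return clean, gt, prior, blob


@pytest.fixture(scope="session")
def two_level_disc():
    """Two-level piecewise-constant disc image with its SDF ground truth."""
    from odseg.synthetic import _ellipse_field

    shape = (200, 200)
    gt = _ellipse_field(shape, (100, 100), (50, 42), 0.4) <= 1.0
    img = np.where(gt, 0.9, 0.1)
    return img, gt
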
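"""Adaptive-threshold ellipse fitting (the level-set initial value)."""

import numpy as np
import pytest

from odseg.evaluation import iou
from odseg.init_detection import (
    EllipseFitError,
    EllipsePrior,
    adaptive_threshold,
    boundary_points,
    detect_initial,
    fit_ellipse,
    largest_4cc,
    morph_open_binary,
)
from odseg.preprocessing import PreprocParams, remove_vessels_noise
from odseg.synthetic import SynthSpec, _ellipse_field, render


def _ellipse_samples(a, b, theta, n=100, center=(100.0, 100.0)):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    x, y = a * np.cos(t), b * np.sin(t)
    xr = x * np.cos(theta) - y * np.sin(theta)
    yr = x * np.sin(theta) + y * np.cos(theta)
    return np.column_stack([yr + center[0], xr + center[1]])


class TestAdaptiveThreshold:
    def test_constant_image_all_selected(self):
        assert adaptive_threshold(np.full((50, 50), 0.3)).all()

    def test_blob_core_in_far_background_out(self):
        yy, xx = np.mgrid[0:120, 0:120]
        img = np.exp(-((yy - 60) ** 2 + (xx - 60) ** 2) / (2 * 15**2))
        mask = adaptive_threshold(img)
        assert mask[60, 60]
        assert not mask[3, 3]

    def test_extreme_offsets(self):
        # the offset C is subtracted from the local mean, so C -> +inf
        # lowers the threshold (all selected) and C -> -inf raises it
        # beyond reach (none selected)
        img = np.random.default_rng(0).random((40, 40))
        assert adaptive_threshold(img, C=np.inf).all()
        assert not adaptive_threshold(img, C=-np.inf).any()

    def test_oversized_window_rejected(self):
        with pytest.raises(ValueError):
            adaptive_threshold(np.zeros((20, 20)), w=100, h=10)

    def test_valid_mask_excludes_black_padding(self):
        img = np.zeros((100, 100))
        yy, xx = np.mgrid[0:100, 0:100]
        fov = np.hypot(yy - 50, xx - 50) <= 40
        img[fov] = 0.5
        img[np.hypot(yy - 50, xx - 50) <= 12] = 0.9
        mask = adaptive_threshold(img, valid=fov)
        assert not mask[~fov].any()
        assert mask[50, 50]


class TestLargest4cc:
    def test_bigger_blob_wins(self):
        m = np.zeros((50, 50), bool)
        m[5:15, 5:15] = True   # 100 px
        m[30:40, 30:35] = True  # 50 px
        out = largest_4cc(m)
        assert out[10, 10] and not out[32, 32]

    def test_diagonal_touch_is_two_components(self):
        m = np.zeros((10, 10), bool)
        m[2:4, 2:4] = True
        m[4:7, 4:7] = True  # touches only diagonally at (3,3)/(4,4)
        out = largest_4cc(m)
        assert out.sum() == 9

    def test_single_blob_identity(self):
        m = np.zeros((20, 20), bool)
        m[5:12, 5:12] = True
        assert np.array_equal(largest_4cc(m), m)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            largest_4cc(np.zeros((5, 5), bool))


class TestMorphOpenBinary:
    def test_bridge_removed(self):
        from scipy import ndimage

        m = np.zeros((40, 80), bool)
        m[10:30, 5:30] = True
        m[10:30, 50:75] = True
        m[19:20, 30:50] = True  # 1-px bridge
        out = morph_open_binary(m)
        _, n = ndimage.label(out)
        assert n == 2

    def test_large_square_mostly_preserved(self):
        m = np.zeros((80, 80), bool)
        m[10:60, 10:60] = True
        out = morph_open_binary(m)
        assert iou(out, m) > 0.98

    def test_empty_stays_empty(self):
        assert not morph_open_binary(np.zeros((10, 10), bool)).any()


class TestFitEllipse:
    def test_noiseless_recovery_within_tolerance(self):
        pts = _ellipse_samples(60, 40, np.deg2rad(30))
        fit = fit_ellipse(pts)
        assert fit.semi_axes[0] == pytest.approx(60, rel=0.01)
        assert fit.semi_axes[1] == pytest.approx(40, rel=0.01)
        assert np.rad2deg(fit.rotation) == pytest.approx(30, abs=1.0)

    def test_circle_accepted_with_equal_axes(self):
        pts = _ellipse_samples(35, 35, 0.0)
        fit = fit_ellipse(pts)
        assert fit.semi_axes[0] == pytest.approx(fit.semi_axes[1], rel=1e-3)
        assert fit.semi_axes[0] >= fit.semi_axes[1]

    def test_too_few_points_rejected(self):
        with pytest.raises(EllipseFitError):
            fit_ellipse(np.array([[0, 0], [1, 1], [2, 2], [3, 3]]))

    def test_residual_below_half_pixel(self):
        pts = _ellipse_samples(47, 33, 1.1)
        fit = fit_ellipse(pts)
        # orthogonal distance proxy: normalized radius error times local scale
        field = _ellipse_field(
            (200, 200), fit.center, fit.semi_axes, fit.rotation
        )
        idx = np.round(pts).astype(int)
        vals = field[idx[:, 0], idx[:, 1]]
        assert np.abs(vals - 1.0).mean() * min(fit.semi_axes) <= 0.5


class TestDetectInitial:
    def test_clean_disc_recovered(self):
        spec = SynthSpec(seed=21)
        img, gt = render(spec)
        clean = remove_vessels_noise(
            img.as_float().max(axis=-1), PreprocParams().scaled_for(320)
        )
        prior = detect_initial(clean, valid=img.fov_mask)
        assert iou(prior.mask(), gt) >= 0.85

    def test_ppa_crescent_excluded(self):
        spec = SynthSpec(
            od_center=(160.0, 160.0),
            od_axes=(50.0, 44.0),
            ppa=(0.8, 1.8, 16.0, 0.51),
            seed=22,
        )
        img, gt = render(spec)
        clean = remove_vessels_noise(
            img.as_float().max(axis=-1), PreprocParams().scaled_for(320)
        )
        prior = detect_initial(clean, valid=img.fov_mask)
        d = np.hypot(prior.center[0] - 160, prior.center[1] - 160)
        assert d <= 0.1 * 2 * 50  # within 10% of the OD diameter
        assert prior.mask().sum() == pytest.approx(gt.sum(), rel=0.25)

    def test_all_dark_roi_rejected(self):
        with pytest.raises(ValueError):
            detect_initial(np.zeros((60, 60)), C=0.5)

    def test_deterministic(self):
        spec = SynthSpec(seed=23)
        img, _ = render(spec)
        clean = remove_vessels_noise(
            img.as_float().max(axis=-1), PreprocParams().scaled_for(320)
        )
        p1 = detect_initial(clean, valid=img.fov_mask)
        p2 = detect_initial(clean, valid=img.fov_mask)
        assert p1.to_dict() == p2.to_dict()

    def test_phi_initial_satisfies_sdf_round_trip(self):
        prior = EllipsePrior(
            center=(60.0, 60.0), semi_axes=(30.0, 22.0), rotation=0.5,
            grid_shape=(120, 120),
        )
        assert iou(prior.phi_initial.inside_mask(), prior.mask()) >= 0.99


def test_boundary_points_requires_content():
    with pytest.raises(ValueError):
        boundary_points(np.zeros((10, 10), bool))
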
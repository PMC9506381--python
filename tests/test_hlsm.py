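"""The four-term hybrid level-set evolution."""

import numpy as np
import pytest

from odseg.evaluation import iou
from odseg.hlsm import HlsmParams, evolve, hlsm_energy, hlsm_step, region_means
from odseg.ls_numerics import sdf_from_mask
from odseg.synthetic import _ellipse_field


def _disc_sdf(shape=(121, 121), r=25):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    c = (shape[0] - 1) / 2
    return sdf_from_mask(np.hypot(yy - c, xx - c) <= r).values


class TestRegionMeans:
    def test_constant_image(self):
        phi = _disc_sdf()
        st = region_means(np.full(phi.shape, 0.7), phi)
        assert st.c1 == pytest.approx(0.7) and st.c2 == pytest.approx(0.7)

    def test_two_level_disc(self, two_level_disc):
        img, gt = two_level_disc
        phi = sdf_from_mask(gt).values
        st = region_means(img, phi)
        assert st.c1 == pytest.approx(0.9, abs=0.02)
        assert st.c2 == pytest.approx(0.1, abs=0.02)

    def test_empty_inside_falls_back_to_global_mean(self):
        img = np.random.default_rng(0).random((50, 50))
        phi = np.full((50, 50), 10.0)  # everything outside
        st = region_means(img, phi)
        assert st.c1 == pytest.approx(img.mean())


class TestHlsmStep:
    def test_sdf_near_stationary_under_regularizer_only(self):
        phi = _disc_sdf()
        p = HlsmParams(alpha=0, beta=0, lambda_in=0, lambda_out=0, lambda_shape=0)
        phi2 = hlsm_step(phi, np.zeros_like(phi), phi, p).values
        assert np.abs(phi2 - phi).max() <= p.dt * 1e-2

    def test_shape_term_vanishes_at_prior(self):
        phi = _disc_sdf()
        p = HlsmParams(mu=0, alpha=0, beta=0, lambda_in=0, lambda_out=0,
                       lambda_shape=50.0)
        phi2 = hlsm_step(phi, np.zeros_like(phi), phi, p).values
        assert np.abs(phi2 - phi).max() < 1e-12

    def test_region_force_moves_toward_true_boundary(self, two_level_disc):
        img, gt = two_level_disc
        shifted = _ellipse_field(img.shape, (100, 100), (54, 46), 0.4) <= 1.0
        phi = sdf_from_mask(shifted).values
        p = HlsmParams(mu=0.1, alpha=0, beta=0, lambda_shape=0)
        gt_sdf = sdf_from_mask(gt).values
        before = np.abs(gt_sdf[np.abs(phi) <= 1.5]).mean()
        for _ in range(10):
            phi = hlsm_step(phi, img, gt_sdf * 0 + 10, p).values
        after = np.abs(gt_sdf[np.abs(phi) <= 1.5]).mean()
        assert after < before

    def test_nonfinite_input_raises(self):
        phi = _disc_sdf()
        img = np.zeros_like(phi)
        img[0, 0] = np.nan
        with pytest.raises(FloatingPointError):
            hlsm_step(phi, img, phi, HlsmParams())


class TestEvolve:
    def test_region_terms_converge_on_two_level_disc(self, two_level_disc):
        img, gt = two_level_disc
        prior = _ellipse_field(img.shape, (100, 100), (52, 44), 0.4) <= 1.0
        p = HlsmParams(alpha=0, beta=0, lambda_shape=0, tol=0, max_iters=1000)
        res = evolve(img, sdf_from_mask(prior).values, p)
        assert iou(res.mask, gt) >= 0.99

    def test_huge_shape_weight_returns_prior(self, blob_roi_fixture):
        clean, _, prior, _ = blob_roi_fixture
        res = evolve(clean, prior, HlsmParams(lambda_shape=1e3, max_iters=300))
        assert iou(res.mask, prior.mask()) >= 0.99

    def test_shape_prior_blocks_blob_ablation_admits_it(self, blob_roi_fixture):
        clean, gt, prior, blob = blob_roi_fixture
        guarded = evolve(clean, prior, HlsmParams(
            lambda_shape=1.1, region_mode="full", tol=0, max_iters=600))
        naked = evolve(clean, prior, HlsmParams(
            lambda_shape=0.0, region_mode="full", tol=0, max_iters=600))
        ov_guarded = (guarded.mask & blob).sum() / blob.sum()
        ov_naked = (naked.mask & blob).sum() / blob.sum()
        assert iou(guarded.mask, gt) >= 0.90
        assert ov_guarded <= 0.10
        assert ov_naked > ov_guarded

    def test_beta_sign_sets_balloon_direction(self):
        phi0 = _disc_sdf((101, 101), 20)
        img = np.full((101, 101), 0.5)
        for sign in (+1, -1):
            p = HlsmParams(mu=0.1, alpha=0, beta=sign * 0.5,
                           lambda_in=0, lambda_out=0, lambda_shape=0,
                           tol=0, max_iters=60)
            res = evolve(img, phi0, p)
            areas = [np.count_nonzero(phi0 < 0), np.count_nonzero(res.mask)]
            if sign > 0:
                assert areas[1] > areas[0]  # beta>0 grows {phi<0}
            else:
                assert areas[1] < areas[0]

    def test_curvature_term_smooths_notched_contour(self, two_level_disc):
        img, gt = two_level_disc
        img = img.copy()
        yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
        notch = (np.abs(yy - 100) <= 3) & (xx > 140)
        img[notch] = 0.1  # vessel-like dark notch through the disc edge
        prior = sdf_from_mask(gt).values
        perims = {}
        for alpha in (3.0, 0.0):
            p = HlsmParams(alpha=alpha, beta=0, lambda_shape=0, tol=0,
                           max_iters=200)
            res = evolve(img, prior, p)
            m = res.mask
            perims[alpha] = np.count_nonzero(m ^ np.roll(m, 1, 0)) + np.count_nonzero(
                m ^ np.roll(m, 1, 1)
            )
        assert perims[3.0] <= perims[0.0]

    def test_energy_nonincreasing_and_band_gradient_bounded(self, two_level_disc):
        img, gt = two_level_disc
        prior = _ellipse_field(img.shape, (100, 100), (52, 44), 0.4) <= 1.0
        phi0 = sdf_from_mask(prior).values
        p = HlsmParams(tol=0, max_iters=400)
        res = evolve(img, phi0, p)
        energies = [e for _, e in res.energy_trace]
        for a, b in zip(energies, energies[1:]):
            assert b <= a * 1.01
        gr, gc = np.gradient(res.phi.values)
        band = np.abs(res.phi.values) <= 3.0
        assert 0.7 <= np.hypot(gr, gc)[band].mean() <= 1.3

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evolve(np.zeros((10, 10)), np.zeros((12, 12)), HlsmParams())


class TestEnergy:
    def test_energy_decreases_along_descent(self, two_level_disc):
        img, gt = two_level_disc
        prior = _ellipse_field(img.shape, (100, 100), (54, 46), 0.4) <= 1.0
        phi = sdf_from_mask(prior).values
        p = HlsmParams(lambda_shape=0)
        e0 = hlsm_energy(phi, img, phi, p)
        for _ in range(30):
            phi = hlsm_step(phi, img, phi * 0 + 10, p).values
        assert hlsm_energy(phi, img, phi * 0 + 10, p) <= e0


def test_params_validation():
    with pytest.raises(ValueError):
        HlsmParams(dt=0)
    with pytest.raises(ValueError):
        HlsmParams(u0_mode="nope")
    with pytest.raises(ValueError):
        HlsmParams(region_mode="nope")
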
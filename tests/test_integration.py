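"""Measurement boxes, background planes, summation and profile fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ptccd.cascade import NoiseBudget
from ptccd.integration import (BoxError, CovarianceModel,
                               build_measurement_box, build_reference_profile,
                               empirical_pixel_covariance, extract_box,
                               fit_background_plane, profile_fit,
                               summation_integrate, variance_cascade,
                               variance_poisson_mosflm)


def plane_image(nx, ny, a, b, c):
    dx = np.arange(nx) - nx // 2
    dy = np.arange(ny) - ny // 2
    gx, gy = np.meshgrid(dx, dy)
    return a * gx + b * gy + c


class TestMeasurementBox:
    def test_minimal_box(self):
        box = build_measurement_box((5, 5), 3, 3, 1, 1, 99)
        assert box.m_peak == 1
        assert box.n_bg == 8
        assert box.peak_mask[1, 1]

    def test_reference_box_counts(self):
        # NX=NY=23, NRX=5, NRY=4, NC=11: peak |dx|<=6, |dy|<=7 minus the
        # taxicab corner cut |dx|+|dy| >= 11 (cut pixels join the
        # background)
        box = build_measurement_box((0, 0), 23, 23, 5, 4, 11)
        assert box.m_peak == 171
        assert box.n_bg == 358
        assert box.m_peak + box.n_bg == 23 * 23

    def test_mm_symmetry(self):
        box = build_measurement_box((0, 0), 23, 23, 5, 4, 11)
        for mask in (box.peak_mask, box.bg_mask):
            np.testing.assert_array_equal(mask, mask[::-1, :])
            np.testing.assert_array_equal(mask, mask[:, ::-1])

    @pytest.mark.parametrize("bad", [
        dict(nx=22), dict(ny=8), dict(nrx=-1), dict(nrx=12),
    ])
    def test_invalid_parameters(self, bad):
        kw = dict(nx=23, ny=23, nrx=5, nry=4, nc=11)
        kw.update(bad)
        with pytest.raises(BoxError):
            build_measurement_box((0, 0), **kw)

    def test_scaled_box_for_raw_grid(self):
        # the physical 23x23 corrected-pixel box expressed on the 30 um
        # raw grid (pixel ratio 73 / (30 * 2.7) ~ 0.90)
        box = build_measurement_box((0, 0), 23, 23, 5, 4, 11)
        raw = box.scaled((0, 0), 73.0 / 81.0)
        assert (raw.nx, raw.ny, raw.nrx, raw.nry, raw.nc) == (21, 21, 5, 4, 10)

    def test_extract_box_bounds_checked(self):
        box = build_measurement_box((2, 2), 23, 23, 5, 4, 11)
        with pytest.raises(BoxError):
            extract_box(np.zeros((50, 50)), box)


class TestBackgroundPlane:
    def test_exact_plane_recovered(self):
        box = build_measurement_box((11, 11), 23, 23, 5, 4, 11)
        img = plane_image(23, 23, 0.7, -1.3, 42.0)
        plane = fit_background_plane(img, box)
        assert plane.a == pytest.approx(0.7, abs=1e-10)
        assert plane.b == pytest.approx(-1.3, abs=1e-10)
        assert plane.c == pytest.approx(42.0, abs=1e-10)

    def test_constant_background(self):
        box = build_measurement_box((11, 11), 23, 23, 5, 4, 11)
        plane = fit_background_plane(np.full((23, 23), 7.0), box)
        assert plane.a == pytest.approx(0.0, abs=1e-12)
        assert plane.b == pytest.approx(0.0, abs=1e-12)
        assert plane.c == pytest.approx(7.0)

    def test_matches_normal_equations_oracle(self, rng):
        box = build_measurement_box((2, 2), 5, 5, 1, 1, 99)
        img = rng.normal(10.0, 2.0, (5, 5))
        plane = fit_background_plane(img, box)
        dx, dy = box.offsets
        a = np.stack([dx[box.bg_mask], dy[box.bg_mask],
                      np.ones(box.n_bg)], axis=1)
        y = img[box.bg_mask]
        oracle = np.linalg.solve(a.T @ a, a.T @ y)
        assert np.allclose([plane.a, plane.b, plane.c], oracle)

    def test_pedestal_subtracted_before_fit(self):
        box = build_measurement_box((11, 11), 23, 23, 5, 4, 11)
        img = plane_image(23, 23, 0.0, 0.0, 30.0)
        plane = fit_background_plane(img, box, pedestal=10.0)
        assert plane.c == pytest.approx(20.0)


class TestSummation:
    def test_pure_plane_integrates_to_zero(self):
        box = build_measurement_box((11, 11), 23, 23, 5, 4, 11)
        img = plane_image(23, 23, 0.3, 0.2, 15.0)
        res = summation_integrate(img, box)
        assert res.intensity == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_toy_spot(self):
        # 3x3 peak rho = [[1,2,1],[2,10,2],[1,2,1]] on the plane (0,0,1):
        # I_S = 22 - 9 = 13
        box = build_measurement_box((2, 2), 5, 5, 1, 1, 99)
        img = np.ones((5, 5))
        img[1:4, 1:4] = [[1, 2, 1], [2, 10, 2], [1, 2, 1]]
        res = summation_integrate(img, box)
        assert res.intensity == pytest.approx(13.0)
        assert res.m_peak == 9

    def test_invariant_under_added_plane(self, rng):
        box = build_measurement_box((11, 11), 23, 23, 5, 4, 11)
        img = rng.poisson(50.0, (23, 23)).astype(float)
        base = summation_integrate(img, box).intensity
        shifted = summation_integrate(
            img + plane_image(23, 23, 2.0, -3.0, 100.0), box).intensity
        assert shifted == pytest.approx(base, rel=1e-12)


class TestVarianceEstimators:
    def test_zero_background_is_pure_poisson(self):
        box = build_measurement_box((2, 2), 5, 5, 1, 1, 99)
        img = np.zeros((5, 5))
        img[2, 2] = 120.0
        res = summation_integrate(img, box)
        v = variance_poisson_mosflm(res, gain_absorbed=1.44)
        assert v == pytest.approx(1.44 * 120.0)

    def test_poisson_formula_matches_symbolic_expansion(self, rng):
        box = build_measurement_box((11, 11), 23, 23, 5, 4, 11)
        img = rng.poisson(30.0, (23, 23)).astype(float)
        res = summation_integrate(img, box)
        g = 0.9655
        v = variance_poisson_mosflm(res, g)
        m, n = box.m_peak, box.n_bg
        i_bg = res.p_bg * m / n
        assert v == pytest.approx(
            g * (res.intensity + i_bg * (1 + m / n)), rel=1e-12)

    @settings(deadline=None, max_examples=60)
    @given(seed=st.integers(0, 10_000))
    def test_ideal_counter_limit_reduces_to_poisson(self, seed):
        # with gamma = 1, psi = 0 the cascade estimator equals the
        # classical Poisson estimator on any image
        rng = np.random.default_rng(seed)
        box = build_measurement_box((11, 11), 23, 23, 5, 4, 11)
        img = rng.gamma(2.0, 20.0, (23, 23))
        res = summation_integrate(img, box)
        g = rng.uniform(0.1, 3.0)
        ideal = NoiseBudget(gamma=1.0, psi=0.0, gain_absorbed=g,
                            gain_incident=g)
        assert variance_cascade(res, ideal) == pytest.approx(
            variance_poisson_mosflm(res, g), rel=1e-9)

    def test_cascade_exceeds_poisson_for_real_budget(self, budget, rng):
        box = build_measurement_box((11, 11), 23, 23, 5, 4, 11)
        img = rng.poisson(30.0, (23, 23)).astype(float)
        res = summation_integrate(img, box)
        assert variance_cascade(res, budget) > variance_poisson_mosflm(
            res, budget.gain_absorbed)


class TestProfileFitting:
    def make_profile(self, box, total=5000.0, sigma=2.0):
        dx, dy = box.offsets
        prof = np.exp(-(dx**2 + dy**2) / (2 * sigma**2))
        return np.rint(prof / prof.sum() * total)

    def test_reference_profile_from_noiseless_spot(self):
        box = build_measurement_box((11, 11), 23, 23, 5, 4, 11)
        spot = self.make_profile(box)
        img = spot + plane_image(23, 23, 0.5, -0.2, 30.0)
        prof = build_reference_profile(img[None], box)
        np.testing.assert_allclose(prof, spot, atol=0.5 + 1e-9)

    def test_profile_stable_under_image_scaling(self):
        box = build_measurement_box((11, 11), 23, 23, 5, 4, 11)
        spot = self.make_profile(box)
        p1 = build_reference_profile(spot[None], box)
        p2 = build_reference_profile(3.0 * spot[None], box)
        np.testing.assert_allclose(p2, 3.0 * p1, atol=1.0)

    def test_noiseless_scale_recovery_both_modes(self):
        box = build_measurement_box((11, 11), 23, 23, 5, 4, 11)
        prof = self.make_profile(box)
        k0 = 2.5
        img = k0 * prof + plane_image(23, 23, 0.1, 0.4, 25.0)
        res = profile_fit(img, box, prof, gain_absorbed=0.9655)
        assert res.intensity == pytest.approx(k0 * prof.sum(), rel=1e-9)
        mf = CovarianceModel(np.eye(23 * 23), 7)
        res_g = profile_fit(img, box, prof, 0.9655, weights=mf)
        assert res_g.intensity == pytest.approx(k0 * prof.sum(), rel=1e-9)

    def test_diagonal_variance_estimate_tracks_truth_for_independent_pixels(
            self, rng):
        # independent pixels whose variance really is G * value: the
        # residual-scaled estimate matches the observed scatter
        box = build_measurement_box((11, 11), 23, 23, 5, 4, 11)
        prof = self.make_profile(box)
        truth = prof + 40.0
        g = 0.9655
        imgs = truth[None] + np.sqrt(g * truth)[None] \
            * rng.standard_normal((3000, 23, 23))
        res = profile_fit(imgs, box, prof, gain_absorbed=g)
        observed = res.intensity.var(ddof=1)
        assert res.variance_fit.mean() == pytest.approx(observed, rel=0.1)

    def test_gls_with_true_covariance_is_calibrated(self, rng):
        # correlated pixels: diagonal weighting underestimates, GLS with
        # the true covariance matches the observed variance
        box = build_measurement_box((5, 5), 11, 11, 2, 2, 99)
        prof = self.make_profile(box, total=2000.0, sigma=1.5)
        n_px = 11 * 11
        dx, dy = box.offsets
        fdx, fdy = dx.ravel(), dy.ravel()
        dist2 = (fdx[:, None] - fdx[None, :])**2 + \
            (fdy[:, None] - fdy[None, :])**2
        true_cov = 25.0 * np.exp(-dist2 / (2 * 1.2**2))
        true_cov += 1e-6 * np.eye(n_px)
        chol = np.linalg.cholesky(true_cov)
        noise = rng.standard_normal((4000, n_px)) @ chol.T
        imgs = (prof + 40.0)[None] + noise.reshape(-1, 11, 11)
        diag = profile_fit(imgs, box, prof, gain_absorbed=1.0)
        gls = profile_fit(imgs, box, prof, 1.0,
                          weights=CovarianceModel(true_cov, 99))
        obs_diag = diag.intensity.var(ddof=1)
        obs_gls = gls.intensity.var(ddof=1)
        assert diag.variance_fit.mean() < 0.7 * obs_diag
        assert gls.variance_fit.mean() == pytest.approx(obs_gls, rel=0.1)

    def test_singular_profile_rejected(self):
        box = build_measurement_box((11, 11), 23, 23, 5, 4, 11)
        # profile identical to the constant column of the design
        prof = np.ones((23, 23))
        img = np.ones((23, 23))
        with pytest.raises(np.linalg.LinAlgError):
            profile_fit(img, box, prof, gain_absorbed=1.0)


class TestEmpiricalCovariance:
    def test_iid_noise_off_diagonals_vanish(self, rng):
        box = build_measurement_box((5, 5), 11, 11, 2, 2, 99)
        n = 4000
        imgs = rng.normal(10.0, 3.0, (n, 11, 11))
        mf = empirical_pixel_covariance(imgs, box, max_lag=7)
        off = mf.matrix[~np.eye(121, dtype=bool)]
        se = 9.0 / np.sqrt(n)
        assert np.abs(off).mean() < 3 * se
        assert np.diag(mf.matrix).mean() == pytest.approx(9.0, rel=0.1)

    def test_matches_direct_pairwise_covariance(self, rng):
        box = build_measurement_box((3, 3), 7, 7, 1, 1, 99)
        imgs = rng.normal(0.0, 1.0, (500, 7, 7))
        # correlate horizontal neighbours
        imgs[:, :, 1:] += 0.8 * imgs[:, :, :-1]
        mf = empirical_pixel_covariance(imgs, box, max_lag=7)
        flat = imgs.reshape(500, -1)
        oracle = np.cov(flat.T)
        np.testing.assert_allclose(mf.matrix, oracle, atol=0.15)

    def test_band_beyond_lag_is_zero(self, rng):
        box = build_measurement_box((11, 11), 23, 23, 5, 4, 11)
        imgs = rng.normal(0.0, 1.0, (60, 23, 23))
        mf = empirical_pixel_covariance(imgs, box, max_lag=2)
        dx, dy = box.offsets
        fdx, fdy = dx.ravel(), dy.ravel()
        far = (np.abs(fdx[:, None] - fdx[None, :]) > 2) \
            | (np.abs(fdy[:, None] - fdy[None, :]) > 2)
        # banding zeroes far pairs before the PSD projection; after the
        # projection they stay negligible against the diagonal
        assert np.abs(mf.matrix[far]).max() < 0.2 * np.diag(mf.matrix).mean()

    def test_psd_after_projection(self, rng):
        box = build_measurement_box((11, 11), 23, 23, 5, 4, 11)
        imgs = rng.normal(0.0, 1.0, (40, 23, 23))   # few samples: not PSD
        with pytest.warns(UserWarning):
            mf = empirical_pixel_covariance(imgs, box, max_lag=7)
        assert np.linalg.eigvalsh(mf.matrix)[0] >= -1e-8
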
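import numpy as np
import pandas as pd
import pytest

from dsaflow import (FitError, GammaVariateFit, ROISet, TimeGrid,
                     ValidationError, build_time_grid, compute_cct,
                     compute_fwhm, compute_ttp, correlate_markers,
                     default_schedule, fit_gamma_variate, fwhm_factor,
                     gamma_variate)
from dsaflow.segmentation import TDC


def dense_grid_fwhm(t0, alpha, beta, K, baseline=0.0):
    """Numeric FWHM oracle: half-crossings on a 1e-5 s grid."""
    tp = t0 + alpha * beta
    t = np.arange(t0, tp + 30 * beta, 1e-5)
    c = gamma_variate(t, t0, alpha, beta, K, baseline)
    half = baseline + (c.max() - baseline) / 2
    above = np.flatnonzero(c >= half)
    return t[above[-1]] - t[above[0]]


class TestGammaVariate:
    def test_baseline_at_and_before_arrival(self):
        t = np.array([0.0, 1.0, 1.5])
        c = gamma_variate(t, t0=1.5, alpha=3, beta=1, K=2, baseline=0.3)
        np.testing.assert_allclose(c, 0.3)

    def test_peak_value_at_ttp(self):
        val = gamma_variate(np.array([2.0 + 3.0 * 0.8]), 2.0, 3.0, 0.8, 1.5, 0.2)
        expected = 0.2 + 1.5 * (3.0 * 0.8) ** 3.0 * np.exp(-3.0)
        assert val[0] == pytest.approx(expected, rel=1e-12)

    def test_direct_evaluation(self):
        # alpha=3, beta=1, K=1, t0=0 at t=3: 27 e^-3
        val = gamma_variate(np.array([3.0]), 0.0, 3.0, 1.0, 1.0)
        assert val[0] == pytest.approx(27 * np.exp(-3), rel=1e-12)
        assert val[0] == pytest.approx(1.3443, abs=5e-5)

    def test_invalid_shape_scale_rejected(self):
        with pytest.raises(ValidationError):
            gamma_variate(np.array([1.0]), 0, -1, 1, 1)
        with pytest.raises(ValidationError):
            gamma_variate(np.array([1.0]), 0, 1, 0, 1)


class TestFWHM:
    def test_matches_dense_grid_oracle(self):
        fit = GammaVariateFit(t0=0, alpha=3, beta=1, K=1, baseline=0,
                              r_squared=1.0)
        assert compute_fwhm(fit) == pytest.approx(
            dense_grid_fwhm(0, 3, 1, 1), abs=1e-4)
        # the alpha=3 width factor itself
        assert fwhm_factor(3.0) == pytest.approx(4.1312, abs=5e-4)

    @pytest.mark.parametrize("alpha", [0.5, 1.0, 2.0, 3.0, 5.0, 8.0])
    def test_oracle_across_shapes(self, alpha):
        fit = GammaVariateFit(t0=1.0, alpha=alpha, beta=0.7, K=2.5,
                              baseline=0.1, r_squared=1.0)
        assert compute_fwhm(fit) == pytest.approx(
            dense_grid_fwhm(1.0, alpha, 0.7, 2.5, 0.1), abs=1e-4)

    @pytest.mark.parametrize("c", [0.5, 2.0, 10.0])
    def test_beta_scale_law(self, c):
        base = GammaVariateFit(t0=0, alpha=3, beta=1, K=1, baseline=0,
                               r_squared=1.0)
        scaled = GammaVariateFit(t0=0, alpha=3, beta=c, K=1, baseline=0,
                                 r_squared=1.0)
        assert compute_fwhm(scaled) == pytest.approx(c * compute_fwhm(base),
                                                     rel=1e-9)

    def test_invariant_to_amplitude_and_baseline(self):
        ref = GammaVariateFit(t0=0.5, alpha=2.5, beta=1.2, K=1, baseline=0,
                              r_squared=1.0)
        for K, b in ((5.0, 0.0), (1.0, 3.0), (0.2, -1.0)):
            other = GammaVariateFit(t0=0.5, alpha=2.5, beta=1.2, K=K,
                                    baseline=b, r_squared=1.0)
            assert compute_fwhm(other) == pytest.approx(compute_fwhm(ref),
                                                        rel=1e-9)

    def test_ttp_identity(self):
        fit = GammaVariateFit(t0=1.3, alpha=2.7, beta=0.9, K=4, baseline=0.1,
                              r_squared=1.0)
        assert abs(fit.ttp - (1.3 + 2.7 * 0.9)) < 1e-9


@pytest.fixture(scope="module")
def grid():
    return build_time_grid(default_schedule())


class TestFit:
    def _tdc(self, grid, density):
        return TDC(grid=grid, density=density, label="capillary", n_pixels=100)

    def test_exact_curve_recovered_within_1pct(self, grid):
        true = dict(t0=1.0, alpha=3.0, beta=0.8, K=2.0, baseline=0.0)
        d = gamma_variate(grid.timestamps, **true)
        fit = fit_gamma_variate(self._tdc(grid, d))
        assert fit.t0 == pytest.approx(1.0, abs=0.01)
        assert fit.alpha == pytest.approx(3.0, rel=0.01)
        assert fit.beta == pytest.approx(0.8, rel=0.01)
        assert fit.K == pytest.approx(2.0, rel=0.01)
        assert fit.r_squared > 0.999

    def test_noisy_fit_fwhm_error_median_below_5pct(self, grid):
        true_fwhm = 0.8 * fwhm_factor(3.0)
        clean = gamma_variate(grid.timestamps, 1.0, 3.0, 0.8, 2.0)
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            noisy = clean + rng.normal(0, 0.05 * clean.max(), clean.size)
            try:
                fit = fit_gamma_variate(self._tdc(grid, noisy))
                errs.append(abs(fit.fwhm - true_fwhm) / true_fwhm)
            except FitError:
                errs.append(np.inf)
        assert np.median(errs) <= 0.05

    def test_all_zero_tdc_fails(self, grid):
        with pytest.raises(FitError):
            fit_gamma_variate(self._tdc(grid, np.zeros(len(grid))))

    def test_monotone_tdc_fails(self, grid):
        with pytest.raises(FitError):
            fit_gamma_variate(self._tdc(grid, grid.timestamps.copy()))

    def test_low_r2_warned(self, grid):
        rng = np.random.default_rng(8)
        clean = gamma_variate(grid.timestamps, 1.0, 3.0, 0.8, 1.0)
        ugly = clean + rng.normal(0, 0.3 * clean.max(), clean.size)
        ugly[0] = clean[0]
        try:
            fit = fit_gamma_variate(self._tdc(grid, ugly))
            assert fit.r_squared >= 0.8 or fit.warnings_
        except FitError:
            pass  # heavy noise may legitimately kill the peak test


class TestTTP:
    def test_argmax_on_grid(self):
        tdc = TDC(grid=TimeGrid(np.array([0, 0.5, 1.0, 1.5])),
                  density=np.array([0, 1, 5, 2.0]), label="roi", n_pixels=1)
        assert compute_ttp(tdc, "argmax") == 1.0

    def test_tie_takes_earliest(self):
        tdc = TDC(grid=TimeGrid(np.array([0, 0.5, 1.0, 1.5])),
                  density=np.array([0, 5, 5, 2.0]), label="roi", n_pixels=1)
        assert compute_ttp(tdc, "argmax") == 0.5

    def test_fitted_matches_analytic_identity(self):
        grid = build_time_grid(default_schedule())
        d = gamma_variate(grid.timestamps, 1.0, 3.0, 0.8, 2.0)
        tdc = TDC(grid=grid, density=d, label="roi", n_pixels=1)
        assert compute_ttp(tdc, "fitted") == pytest.approx(1.0 + 3.0 * 0.8,
                                                           abs=1e-6)

    def test_constant_tdc_rejected(self):
        tdc = TDC(grid=TimeGrid(np.array([0, 0.5, 1.0])),
                  density=np.ones(3), label="roi", n_pixels=1)
        with pytest.raises(ValidationError):
            compute_ttp(tdc)


class TestCCT:
    def _series_with_two_rois(self):
        from dsaflow import DSASeries

        grid = build_time_grid(default_schedule())
        t = grid.timestamps
        frames = np.zeros((len(grid), 32, 32))
        art = np.zeros((32, 32), dtype=bool)
        art[4:8, 4:8] = True
        vein = np.zeros((32, 32), dtype=bool)
        vein[20:24, 20:24] = True
        frames[:, art] = gamma_variate(t, 0.8, 4.0, 0.3, 1.0)[:, None]
        frames[:, vein] = gamma_variate(t, 3.87, 3.0, 1.0, 1.0)[:, None]
        series = DSASeries(frames=frames, grid=grid, view="LAT")
        rois = ROISet(regions={"cavernous_ICA": art, "parietal_vein": vein},
                      shape=(32, 32))
        return series, rois

    def test_cct_recovered_within_local_frame_interval(self):
        series, rois = self._series_with_two_rois()
        res = compute_cct(series, rois)
        # true TTPs 2.0 s and 6.87 s -> difference 4.87 s
        assert abs(res.cct - 4.87) <= series.grid.local_interval(6.87)

    def test_identical_rois_give_zero(self):
        series, rois = self._series_with_two_rois()
        both = ROISet(regions={"cavernous_ICA": rois.regions["cavernous_ICA"],
                               "parietal_vein": rois.regions["cavernous_ICA"]},
                      shape=(32, 32))
        assert compute_cct(series, both).cct == 0.0

    def test_missing_label_errors(self):
        series, rois = self._series_with_two_rois()
        partial = ROISet(regions={"cavernous_ICA": rois.regions["cavernous_ICA"]},
                         shape=(32, 32))
        with pytest.raises(ValidationError):
            compute_cct(series, partial)

    def test_ap_view_warns_but_computes(self):
        series, rois = self._series_with_two_rois()
        series.view = "AP"
        res = compute_cct(series, rois)
        assert res.warnings_ and np.isfinite(res.cct)


class TestCorrelations:
    def test_perfect_line(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"x": x, "y": 2 * x + 1})
        out = correlate_markers(df)
        row = out.iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["significant"]

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=1000)
        y = rng.permutation(rng.normal(size=1000))
        out = correlate_markers(pd.DataFrame({"x": x, "y": y}))
        assert abs(out.iloc[0]["r"]) < 0.1

    def test_constant_column_reported_missing(self):
        df = pd.DataFrame({"x": np.arange(5.0), "c": np.ones(5)})
        out = correlate_markers(df)
        assert np.isnan(out.iloc[0]["r"]) and not out.iloc[0]["significant"]

    def test_too_few_cases_reported_missing(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "y": [2.0, 1.0]})
        out = correlate_markers(df)
        assert np.isnan(out.iloc[0]["r"])
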
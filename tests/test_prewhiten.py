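import numpy as np
import pytest
from scipy.signal import lfilter

import rsdenoise as rd
from conftest import ar1_noise


class TestEstimateAR:
    def test_white_noise_null(self, rng):
        ar = rd.estimate_ar(rng.standard_normal(10_000), 1)
        assert abs(ar.gamma[0]) < 0.03
        assert not ar.clipped

    def test_ar1_recovery_within_3se(self, rng):
        n, g = 10_000, 0.5
        e = ar1_noise(rng, n, 1, g)[:, 0]
        ar = rd.estimate_ar(e, 1)
        se = np.sqrt((1 - g**2) / n)
        assert abs(ar.gamma[0] - g) < 3 * se

    def test_ar2_recovery_within_3se(self, rng):
        n = 10_000
        g = np.array([0.5, -0.3])
        eps = rng.standard_normal(n)
        e = lfilter([1.0], np.r_[1.0, -g], eps)
        ar = rd.estimate_ar(e, 2)
        # conservative SE bound ~ 1/sqrt(n) per coefficient
        assert np.all(np.abs(ar.gamma - g) < 3.5 / np.sqrt(n))

    def test_constant_residuals_raise(self):
        with pytest.raises(ValueError, match="degenerate|constant"):
            rd.estimate_ar(np.ones(500), 1)

    def test_nonstationary_estimate_clipped(self, rng):
        # a near-unit-root random walk drives the raw estimate to ~1
        e = np.cumsum(rng.standard_normal(2000))
        ar = rd.estimate_ar(e, 1)
        assert abs(ar.gamma[0]) < 1.0


class TestARTransform:
    def test_zero_gamma_is_identity(self, rng):
        y = rng.standard_normal(100)
        out = rd.ar_transform(y, rd.ARModel(2, np.zeros(2), 1.0))
        assert np.array_equal(out, y[2:])

    def test_whitening_oracle(self, rng):
        n, g = 10_000, 0.7
        y = ar1_noise(rng, n, 1, g)[:, 0]
        out = rd.ar_transform(y, rd.ARModel(1, np.array([g]), 1.0))
        rho1 = np.corrcoef(out[1:], out[:-1])[0, 1]
        assert abs(rho1) < 3 / np.sqrt(n)

    def test_unit_root_on_constant_gives_zeros(self):
        out = rd.ar_transform(np.full(50, 3.0), rd.ARModel(1, np.array([1.0]), 0.0))
        assert np.abs(out).max() == 0.0


class TestPrewhitenedFit:
    def test_reduces_to_ols_on_white_noise(self, rng):
        n = 1000
        x = rng.standard_normal(n)
        design = rd.assemble_design([rd.Regressor("x1", x - x.mean(), 1.0)],
                                    rd.legendre_detrend(n, 2))
        y = 1.2 * design.matrix[:, 0] + rng.standard_normal(n)
        ols = rd.ols_fit(y, design)
        wf = rd.prewhitened_fit(y, design, 1)
        assert abs(wf.ar.gamma[0]) < 3 / np.sqrt(n)
        se_beta = np.sqrt(float(ols.sse_full) / ols.dof_error /
                          np.sum(design.matrix[:, 0] ** 2))
        assert np.abs(wf.beta_original_space[0] - ols.beta[0]) < 0.2 * se_beta
        assert wf.converged

    @staticmethod
    def _smooth_design(rng, n):
        # a physiological-like (autocorrelated) nuisance regressor: spurious
        # fits inflate only when BOTH regressor and data are coloured
        x = ar1_noise(rng, n, 1, 0.6)[:, 0]
        return rd.assemble_design([rd.Regressor("x1", x - x.mean(), 2.0)],
                                  rd.legendre_detrend(n, 2, dt=2.0))

    def test_null_column_p_rate_calibrated(self, rng):
        # AR(1) gamma=0.6 noise, truly-null smooth nuisance column, 10,000
        # replicates: whitened p<0.05 rate nominal, unwhitened rate inflated
        n, nvox, g = 160, 10_000, 0.6
        design = self._smooth_design(rng, n)
        y = ar1_noise(rng, n, nvox, g)
        wf = rd.prewhitened_fit(y, design, 1)
        ols = rd.ols_fit(y, design)
        rate_w = np.mean(wf.fit.p_value < 0.05)
        rate_o = np.mean(ols.p_value < 0.05)
        se = np.sqrt(0.05 * 0.95 / nvox)
        assert abs(rate_w - 0.05) < 2.58 * se
        assert rate_o > 0.05 + 2.58 * se

    def test_beta_unbiased_under_ar_noise(self, rng, small_design):
        n, nvox, g, b_true = 160, 5_000, 0.6, 0.8
        x1 = small_design.matrix[:, 0]
        y = b_true * x1[:, None] + ar1_noise(rng, n, nvox, g)
        wf = rd.prewhitened_fit(y, small_design, 1)
        betas = wf.beta_original_space[0]
        se_mean = betas.std() / np.sqrt(nvox)
        assert abs(betas.mean() - b_true) < 3 * se_mean

    def test_whitening_shrinks_null_r2(self, rng):
        design = self._smooth_design(rng, 160)
        y = ar1_noise(rng, 160, 1_000, 0.6)
        wf = rd.prewhitened_fit(y, design, 1)
        ols = rd.ols_fit(y, design)
        assert np.median(wf.fit.r2_noise) < np.median(ols.r2_noise)
        # aggregate significance count never increases under whitening
        assert np.mean(wf.fit.p_value < 0.05) <= np.mean(ols.p_value < 0.05)

    def test_idempotent_on_own_residuals(self, rng, small_design):
        y = ar1_noise(rng, 160, 200, 0.5)
        wf = rd.prewhitened_fit(y, small_design, 1)
        gam2 = rd.estimate_ar(wf.fit.residuals, 1).gamma
        assert np.abs(gam2).mean() < 3 / np.sqrt(160)


class TestArma11:
    def test_lambda_zero_nests_ar1(self, rng, small_design):
        y = 0.7 * small_design.matrix[:, 0] + ar1_noise(rng, 160, 1, 0.5)[:, 0]
        wf_ar = rd.prewhitened_fit(y, small_design, 1)
        wf_arma = rd.arma11_whitened_fit(y, small_design,
                                         grid_a=np.arange(0, 0.95, 0.05),
                                         grid_lambda=[0.0])
        assert wf_arma.selected_params["lambda"] == 0.0
        assert np.allclose(wf_arma.beta_original_space, wf_ar.beta_original_space,
                           atol=0.05)

    def test_grid_recovery(self, rng, small_design):
        # ARMA(1,1) noise: selected (a, lambda) within one grid step of truth
        # in >= 80% of 200 replicates at n = 500
        n, nreps = 500, 200
        a_true, l_true = 0.45, 0.15
        x1 = rng.standard_normal(n)
        design = rd.assemble_design([rd.Regressor("x1", x1 - x1.mean(), 1.0)],
                                    rd.legendre_detrend(n, 1))
        noise = lfilter([1.0, l_true], [1.0, -a_true],
                        rng.standard_normal((n, nreps)), axis=0)
        y = 0.5 * x1[:, None] + noise
        ga = np.arange(0.0, 0.76, 0.15)
        gl = np.arange(-0.3, 0.46, 0.15)
        wf = rd.arma11_whitened_fit(y, design, ga, gl)
        hit = ((np.abs(wf.selected_params["a"] - a_true) <= 0.15 + 1e-9)
               & (np.abs(wf.selected_params["lambda"] - l_true) <= 0.15 + 1e-9))
        assert hit.mean() >= 0.8

    def test_white_noise_selects_near_zero_a(self, rng, small_design):
        y = rng.standard_normal((160, 50))
        wf = rd.arma11_whitened_fit(y, small_design,
                                    grid_a=np.arange(0, 0.95, 0.05),
                                    grid_lambda=[0.0])
        assert np.median(wf.selected_params["a"]) <= 0.1

    def test_invalid_grid(self, small_design, rng):
        with pytest.raises(ValueError, match="stationarity|invertibility"):
            rd.arma11_whitened_fit(rng.standard_normal(160), small_design,
                                   grid_a=[1.2], grid_lambda=[0.0])


class TestDurbinWatson:
    def test_white_noise_near_two(self, rng):
        dw, verdict = rd.durbin_watson(rng.standard_normal(10_000))
        assert abs(dw - 2.0) < 0.06
        assert verdict == "pass"

    def test_alternating_closed_form(self):
        n = 1000
        e = np.tile([1.0, -1.0], n // 2)
        dw, verdict = rd.durbin_watson(e)
        assert dw == pytest.approx(4.0 * (n - 1) / n)
        assert verdict == "negative-autocorrelation"

    def test_ar_09_approximation(self, rng):
        e = ar1_noise(rng, 10_000, 1, 0.9)[:, 0]
        dw, verdict = rd.durbin_watson(e)
        assert dw == pytest.approx(2.0 * (1.0 - 0.9), abs=0.05)
        assert verdict == "positive-autocorrelation"

    def test_dw_rho1_identity(self, rng):
        # dw = 2(1 - rho1) up to an endpoint term (e_0^2 + e_{n-1}^2)/sum e^2,
        # which is O(1/n): the two diagnostics are interchangeable at fMRI n
        for _ in range(20):
            e = rng.standard_normal(200) + np.linspace(0, rng.uniform(-2, 2), 200)
            dw, _ = rd.durbin_watson(e)
            rho1 = (e[1:] @ e[:-1]) / (e @ e)
            endpoint = (e[0] ** 2 + e[-1] ** 2) / (e @ e)
            assert dw == pytest.approx(2.0 * (1.0 - rho1) - endpoint, abs=1e-10)
            assert abs(dw - 2.0 * (1.0 - rho1)) <= endpoint + 1e-10

    def test_degenerate_input(self):
        with pytest.raises(ValueError):
            rd.durbin_watson(np.zeros(100))
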
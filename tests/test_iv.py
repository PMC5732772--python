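from dataclasses import replace

import numpy as np
import pytest
import statsmodels.api as sm
from statsmodels.sandbox.regression.gmm import IV2SLS

from uratemr.iv import (
    DegenerateInstrumentError,
    TwoStageLeastSquares,
    first_stage,
    tsls_fit,
    wald_ratio,
)
from uratemr.regress import ols_fit
from uratemr.synthetic import SimParams, simulate_cohort
from uratemr.grs import weighted_grs


def _confounded_draw(rng, n, beta=2.0):
    z = rng.normal(size=n)
    u = rng.normal(size=n)
    x = 0.8 * z + u + rng.normal(size=n)
    y = beta * x - 1.5 * u + rng.normal(size=n)
    return y, x, z


class TestFirstStage:
    def test_closed_form_f_at_half_r2(self):
        """A construction with exactly half the exposure variance explained
        gives F = (0.5/0.5) * (12 - 2) = 10."""
        n = 12
        z = np.tile([1.0, -1.0], n // 2)
        w = np.concatenate([np.tile([1.0, -1.0], 3), np.tile([-1.0, 1.0], 3)])
        assert z @ w == 0 and w.sum() == 0
        x = z + w  # centered, equal-norm orthogonal parts -> R2 exactly 1/2
        fs = first_stage(x, z)
        assert fs.r2 == pytest.approx(0.5, rel=1e-12)
        assert fs.f_stat == pytest.approx(10.0, rel=1e-12)
        assert not fs.weak_instrument  # the weak flag is strictly F < 10

    def test_univariate_f_matches_statsmodels(self, rng):
        z = rng.normal(size=150)
        x = 0.4 * z + rng.normal(size=150)
        fs = first_stage(x, z)
        fit = sm.OLS(x, sm.add_constant(z)).fit()
        assert fs.f_stat == pytest.approx(float(fit.fvalue), rel=1e-10)
        assert fs.r2 == pytest.approx(float(fit.rsquared), rel=1e-10)
        assert fs.p == pytest.approx(float(fit.f_pvalue), rel=1e-10)

    def test_partial_f_is_squared_t_of_adjusted_regression(self, rng):
        z = rng.normal(size=120)
        C = rng.normal(size=(120, 2))
        x = 0.5 * z + C @ [1.0, -1.0] + rng.normal(size=120)
        fs = first_stage(x, z, C)
        fit = sm.OLS(x, sm.add_constant(np.column_stack([z, C]))).fit()
        assert fs.partial_f == pytest.approx(float(fit.tvalues[1] ** 2), rel=1e-8)

    def test_constant_instrument_raises(self):
        with pytest.raises(DegenerateInstrumentError, match="constant"):
            first_stage(np.arange(10.0), np.ones(10))

    def test_instrument_equal_to_exposure_is_degenerate(self):
        x = np.arange(12.0)
        with pytest.raises(DegenerateInstrumentError, match="R2 = 1"):
            first_stage(x, x)

    def test_null_instrument_f_near_one_and_weak(self):
        rng = np.random.default_rng(11)
        fs_list = [
            first_stage(rng.normal(size=2000), rng.normal(size=2000))
            for _ in range(200)
        ]
        assert all(f.weak_instrument for f in fs_list)
        mean_f = np.mean([f.f_stat for f in fs_list])
        assert mean_f == pytest.approx(1.0, abs=0.35)


class TestTsls:
    def test_wald_ratio_equivalence(self, rng):
        """Single instrument, no covariates: 2SLS is cov(z,y)/cov(z,x)."""
        for _ in range(200):
            n = int(rng.integers(10, 40))
            y, x, z = _confounded_draw(rng, n)
            assert tsls_fit(y, x, z).beta == pytest.approx(
                wald_ratio(y, x, z), rel=1e-10)

    def test_collapses_to_ols_when_instrument_is_exposure(self, rng):
        y, x, _ = _confounded_draw(rng, 80)
        assert tsls_fit(y, x, x).beta == pytest.approx(
            ols_fit(y, x).beta, rel=1e-10)

    def test_matches_statsmodels_iv2sls_with_covariates(self, rng):
        """Full agreement (beta, SE, p) with the independent 2SLS
        implementation, including the structural-residual variance."""
        for _ in range(10):
            n = 150
            y, x, z = _confounded_draw(rng, n)
            C = rng.normal(size=(n, 2))
            y = y + C @ [0.5, -0.3]
            res = tsls_fit(y, x, z, covariates=C)
            fit = IV2SLS(y, np.column_stack([np.ones(n), x, C]),
                         instrument=np.column_stack([np.ones(n), z, C])).fit()
            assert res.beta == pytest.approx(float(fit.params[1]), rel=1e-10)
            assert res.se == pytest.approx(float(fit.bse[1]), rel=1e-10)
            assert res.p == pytest.approx(float(fit.pvalues[1]), rel=1e-8)

    def test_se_uses_structural_not_fitted_residuals(self, rng):
        """Second-stage (fitted-exposure) residuals would give a much
        smaller error variance; guard against that classic mistake."""
        n = 400
        z = rng.normal(size=n)
        u = rng.normal(size=n)
        x = 0.8 * z + u + rng.normal(size=n)
        y = 2.0 * x - 3.0 * u + rng.normal(size=n)
        res = tsls_fit(y, x, z)
        stage1 = np.column_stack([np.ones(n), z])
        x_hat = stage1 @ np.linalg.lstsq(stage1, x, rcond=None)[0]
        naive = sm.OLS(y, sm.add_constant(x_hat)).fit()
        assert res.beta == pytest.approx(float(naive.params[1]), rel=1e-10)
        assert res.se > float(naive.bse[1])  # structural sigma2 is larger here

    def test_multiple_instruments_accepted(self, rng):
        n = 300
        z1, z2 = rng.normal(size=n), rng.normal(size=n)
        u = rng.normal(size=n)
        x = z1 + 0.5 * z2 + u + rng.normal(size=n)
        y = 1.2 * x - u + rng.normal(size=n)
        res = tsls_fit(y, x, np.column_stack([z1, z2]))
        assert res.beta == pytest.approx(1.2, abs=0.2)

    def test_sklearn_estimator_surface(self, rng):
        y, x, z = _confounded_draw(rng, 100)
        est = TwoStageLeastSquares()
        est.fit(x[:, None], y, instrument=z, feature_names=["su"])
        assert est.result_.adjusted_for == ()
        assert est.predict(x[:, None]).shape == (100,)
        assert TwoStageLeastSquares(**est.get_params()).df_mode == "t"

    def test_uncorrelated_instrument_raises(self):
        x = np.arange(20.0)
        with pytest.raises(ValueError):
            tsls_fit(np.ones(20), x, np.zeros(20))


class TestConsistencyUnderConfounding:
    """2SLS converges to the structural effect as n grows; OLS stays biased."""

    def test_bias_direction_and_shrinkage(self, default_params):
        truth = default_params.beta_causal
        tsls_err, ols_err = {}, {}
        for n, reps in ((500, 60), (5000, 20)):
            params = replace(default_params, n=n)
            t_betas, o_betas = [], []
            for r in range(reps):
                cohort = simulate_cohort(params, seed=1000 + r)
                score = weighted_grs(cohort, list(params.weights))
                t_betas.append(tsls_fit(cohort["tbil"], cohort["su"], score).beta)
                o_betas.append(ols_fit(cohort["tbil"], cohort["su"]).beta)
            tsls_err[n] = abs(np.mean(t_betas) - truth)
            ols_err[n] = abs(np.mean(o_betas) - truth)
        # OLS bias (~ +0.024) dwarfs the 2SLS error at every n
        assert ols_err[500] > 0.015 and ols_err[5000] > 0.015
        assert tsls_err[5000] < 0.005
        assert tsls_err[5000] < ols_err[5000] / 3
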
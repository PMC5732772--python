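from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from uratemr.grs import weighted_grs
from uratemr.synthetic import (
    SimParams,
    calibration_report,
    grs_population_moments,
    params_from_json,
    params_to_json,
    simulate_cohort,
)


class TestSimParams:
    @pytest.mark.parametrize("kwargs", [
        {"n": 0},
        {"mafs": (0.3, 0.3, 0.05, 0.6)},
        {"grs_r2": 0.0},
        {"su_sd": -1.0},
        {"mafs": (0.3, 0.3)},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimParams(**kwargs)

    def test_default_confounder_loading_solves_bias_target(self, default_params):
        # a*b / var(SU) is the OLS bias; defaults aim it at +0.024
        p = default_params
        bias = p.conf_on_su * p.conf_on_tbil_effective / p.su_sd ** 2
        assert bias == pytest.approx(0.024, rel=1e-12)

    def test_json_sidecar_round_trip(self, tmp_path, default_params):
        path = tmp_path / "params.json"
        params_to_json(default_params, path)
        assert params_from_json(path) == default_params


class TestSimulateCohort:
    def test_same_seed_is_bit_identical(self, default_params):
        a = simulate_cohort(default_params, seed=5)
        b = simulate_cohort(default_params, seed=5)
        pd.testing.assert_frame_equal(a, b, check_exact=True)

    def test_different_seed_differs(self, default_params):
        a = simulate_cohort(default_params, seed=5)
        b = simulate_cohort(default_params, seed=6)
        assert not a["su"].equals(b["su"])

    def test_marginal_moments_match_study_cohort(self, cohort, default_params):
        n = default_params.n
        assert len(cohort) == n
        assert cohort["su"].mean() == pytest.approx(
            347.24, abs=3 * 101.07 / np.sqrt(n))
        assert cohort["su"].std() == pytest.approx(101.07, rel=0.05)
        assert cohort["tbil"].mean() == pytest.approx(
            19.25, abs=3 * 8.21 / np.sqrt(n))
        assert cohort["tbil"].std() == pytest.approx(8.21, rel=0.05)
        male_frac = (cohort["sex"] == "male").mean()
        assert male_frac == pytest.approx(2713 / 3753, abs=0.03)
        assert (cohort[["age", "bmi", "fbg", "bun"]] > 0).all().all()
        assert not cohort["urate_lowering_drug"].any()

    def test_genotypes_are_in_hardy_weinberg_proportions(self, default_params):
        cohort = simulate_cohort(replace(default_params, n=10000), seed=31)
        for w, maf in zip(default_params.weights, default_params.mafs):
            counts = cohort[w.snp_id].value_counts().reindex(
                [0.0, 1.0, 2.0], fill_value=0)
            expected = 10000 * np.array(
                [(1 - maf) ** 2, 2 * maf * (1 - maf), maf ** 2])
            chi2 = float(((counts.to_numpy() - expected) ** 2 / expected).sum())
            assert stats.chi2.sf(chi2, 2) > 0.001

    def test_grs_explains_target_share_of_su_variance(self, cohort, default_params):
        score = weighted_grs(cohort, list(default_params.weights))
        r = np.corrcoef(score, cohort["su"])[0, 1]
        assert r ** 2 == pytest.approx(default_params.grs_r2, abs=0.01)

    def test_infeasible_su_budget_is_an_error(self, default_params):
        with pytest.raises(ValueError, match="SU variance budget"):
            simulate_cohort(replace(default_params, grs_r2=0.9, conf_on_su=80.0))

    def test_infeasible_tbil_budget_is_an_error(self, default_params):
        with pytest.raises(ValueError, match="TBIL variance budget"):
            simulate_cohort(replace(default_params, beta_causal=-0.5))

    def test_population_grs_moments_closed_form(self, default_params):
        mean, var = grs_population_moments(default_params)
        w = [wt.weight for wt in default_params.weights]
        maf = default_params.mafs
        assert mean == pytest.approx(2 * sum(wi * mi for wi, mi in zip(w, maf)))
        assert var == pytest.approx(
            sum(wi ** 2 * 2 * mi * (1 - mi) for wi, mi in zip(w, maf)))


class TestCalibrationReport:
    def test_scaled_down_first_stage_calibration(self, default_params):
        """Male-stratum conditions (R2 = 0.045, n = 2,713): mean first-stage
        F over replicates sits within 5% of the closed form (0.045/0.955)*2711."""
        params = replace(default_params, n=2713, grs_r2=0.045, prop_male=1.0,
                         su_mean=360.27, su_sd=95.61,
                         tbil_mean=20.11, tbil_sd=8.62)
        cal = calibration_report(params, replicates=100, seed=3)
        assert cal.means["f_stat"] == pytest.approx(127.7, rel=0.05)
        assert cal.means["r2"] == pytest.approx(0.045, abs=0.005)

    def test_fully_exogenous_null(self):
        """No confounding, no causal effect: both estimators are null and
        the endogeneity test rejects at about its nominal level."""
        params = SimParams(n=800, conf_on_su=0.0, conf_on_tbil=0.0,
                           beta_causal=0.0)
        cal = calibration_report(params, replicates=200, seed=9)
        se_t = cal.mc_se["tsls_beta_adjusted"]
        se_o = cal.mc_se["ols_beta_adjusted"]
        assert abs(cal.means["tsls_beta_adjusted"]) < 3 * se_t
        assert abs(cal.means["ols_beta_adjusted"]) < 3 * se_o
        reject = (cal.replicates["dwh_p"] < 0.05).mean()
        assert abs(reject - 0.05) < 0.05

    def test_designed_weakness_is_flagged(self):
        params = SimParams(n=100, grs_r2=0.001)
        cal = calibration_report(params, replicates=40, seed=13)
        assert cal.replicates["weak_instrument"].mean() > 0.9

    def test_invalid_replicates(self, default_params):
        with pytest.raises(ValueError):
            calibration_report(default_params, replicates=0)
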
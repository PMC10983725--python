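"""Prediction chains and interval behaviour, anchored on the reference
coefficient sets (relationship-2/3 ratio models feeding the incidence model)."""

import numpy as np
import pandas as pd
import pytest

from denomcast.params import FitResult, GaussianDispParams, ZinbAr1Params
from denomcast.predict import (
    bootstrap_intervals,
    predict_incidence_wrt_occupancy,
    predict_occupancy,
    predict_patients,
    predict_ratio,
)
from denomcast.simulate import DEFAULT_CASE_PARAMS, DEFAULT_RATIO_PARAMS
from denomcast.studies import REL3_TRUTH


def _gaussian_fit(params, covariates, vcov_scale=0.0):
    names = ["mean_intercept"] + [f"mean_{c}" for c in covariates]
    names += ["logvar_intercept"]
    k = len(names)
    return FitResult(
        model="gaussian_ratio", params=params, param_names=names,
        theta=np.concatenate([params.mean_coefs, params.logvar_coefs]),
        loglik=0.0, n_obs=147, converged=True,
        vcov=vcov_scale * np.eye(k),
    )


def _rel1_fit(params=DEFAULT_CASE_PARAMS, vcov_scale=0.0):
    names = ["cond_intercept", "cond_adult10", "cond_male10", "cond_npat10",
             "zi_intercept", "zi_npat10", "disp_intercept", "disp_reg",
             "log_sigma_ar", "atanh_phi"]
    theta = np.concatenate([params.beta, params.beta_zi, params.beta_disp,
                            [np.log(params.sigma_ar), np.arctanh(params.phi)]])
    return FitResult(model="relationship1_full", params=params, param_names=names,
                     theta=theta, loglik=0.0, n_obs=445, converged=True,
                     vcov=vcov_scale * np.eye(len(theta)))


REL2_COVS = ("adult_occ10", "male_occ10", "reg", "nocc10")
REL3_COVS = ("adult_pat10", "male_pat10", "reg")

OCC_ROW = pd.DataFrame({
    "centre_id": ["X"], "year_month": ["2020-05"], "centre_type": ["REC"],
    "pct_adult_occ": [80.0], "pct_male_occ": [60.0], "n_occ": [200.0],
})


class TestPredictRatio:
    def test_reference_coefficients_worked_example(self):
        # -0.01 + 0.08*8 - 0.01*6 + 0.00*20 = 0.57 for a REC row
        fit = _gaussian_fit(DEFAULT_RATIO_PARAMS, REL2_COVS)
        out = predict_ratio(fit, OCC_ROW)
        assert out["point"].iloc[0] == pytest.approx(0.57, abs=1e-12)

    def test_intercept_only_coefficients(self):
        pars = GaussianDispParams(mean_coefs=[0.4, 0, 0, 0, 0], logvar_coefs=[-3.0])
        out = predict_ratio(_gaussian_fit(pars, REL2_COVS), OCC_ROW)
        assert out["point"].iloc[0] == pytest.approx(0.4)

    def test_reg_effect_is_printed_contrast(self):
        fit = _gaussian_fit(DEFAULT_RATIO_PARAMS, REL2_COVS)
        reg_row = OCC_ROW.assign(centre_type="REG")
        diff = (predict_ratio(fit, reg_row)["point"].iloc[0]
                - predict_ratio(fit, OCC_ROW)["point"].iloc[0])
        assert diff == pytest.approx(0.32, abs=1e-12)

    def test_missing_covariate_named(self):
        fit = _gaussian_fit(DEFAULT_RATIO_PARAMS, REL2_COVS)
        with pytest.raises(KeyError, match="n_occ|nocc10"):
            predict_ratio(fit, OCC_ROW.drop(columns="n_occ"))


class TestPredictPatients:
    def test_scales_ratio_by_occupancy(self):
        fit = _gaussian_fit(DEFAULT_RATIO_PARAMS, REL2_COVS)
        out = predict_patients(fit, OCC_ROW)
        assert out["point"].iloc[0] == pytest.approx(114.0, abs=1e-9)

    def test_unit_ratio(self):
        pars = GaussianDispParams(mean_coefs=[1.0, 0, 0, 0, 0], logvar_coefs=[-3.0])
        row = OCC_ROW.assign(n_occ=50.0)
        out = predict_patients(_gaussian_fit(pars, REL2_COVS), row)
        assert out["point"].iloc[0] == pytest.approx(50.0)

    def test_zero_occupancy_warns_and_predicts_zero(self):
        fit = _gaussian_fit(DEFAULT_RATIO_PARAMS, REL2_COVS)
        with pytest.warns(UserWarning):
            out = predict_patients(fit, OCC_ROW.assign(n_occ=0.0))
        assert out["point"].iloc[0] == 0.0


class TestPredictOccupancy:
    EHR_ROW = pd.DataFrame({
        "centre_id": ["Y"], "year_month": ["2020-06"], "centre_type": ["REG"],
        "pct_adult_pat": [80.0], "pct_male_pat": [60.0], "n_pat": [130.0],
    })

    def test_reference_coefficients_worked_example(self):
        # 0.37 - 0.02*8 + 0.04*6 + 0.20 = 0.65; 130 / 0.65 = 200
        fit = _gaussian_fit(REL3_TRUTH, REL3_COVS)
        out = predict_occupancy(fit, self.EHR_ROW)
        assert out["point"].iloc[0] == pytest.approx(200.0, abs=1e-9)

    def test_half_ratio_doubles(self):
        pars = GaussianDispParams(mean_coefs=[0.5, 0, 0, 0], logvar_coefs=[-3.0])
        row = self.EHR_ROW.assign(n_pat=100.0)
        out = predict_occupancy(_gaussian_fit(pars, REL3_COVS), row)
        assert out["point"].iloc[0] == pytest.approx(200.0)

    def test_reg_contrast(self):
        fit = _gaussian_fit(REL3_TRUTH, REL3_COVS)
        rec_row = self.EHR_ROW.assign(centre_type="REC")
        r_reg = 130.0 / predict_occupancy(fit, self.EHR_ROW)["point"].iloc[0]
        r_rec = 130.0 / predict_occupancy(fit, rec_row)["point"].iloc[0]
        assert r_reg - r_rec == pytest.approx(0.20, abs=1e-12)

    def test_nonpositive_ratio_flagged_not_fixed(self):
        pars = GaussianDispParams(mean_coefs=[-0.5, 0, 0, 0], logvar_coefs=[-3.0])
        out = predict_occupancy(_gaussian_fit(pars, REL3_COVS), self.EHR_ROW)
        assert np.isnan(out["point"].iloc[0])
        assert out["flag"].iloc[0] == "nonpositive_ratio"

    def test_round_trip_with_same_ratio(self):
        pars = GaussianDispParams(mean_coefs=[0.57, 0, 0, 0, 0], logvar_coefs=[-3.0])
        fit2 = _gaussian_fit(pars, REL2_COVS)
        pat = predict_patients(fit2, OCC_ROW)["point"].iloc[0]
        pars3 = GaussianDispParams(mean_coefs=[0.57, 0, 0, 0], logvar_coefs=[-3.0])
        fit3 = _gaussian_fit(pars3, REL3_COVS)
        row = pd.DataFrame({
            "centre_type": ["REC"], "pct_adult_pat": [0.0], "pct_male_pat": [0.0],
            "n_pat": [pat],
        })
        # adult/male zero so that r-hat stays exactly 0.57
        occ_back = predict_occupancy(fit3, row)["point"].iloc[0]
        assert occ_back == pytest.approx(200.0, abs=1e-9)


class TestChainedIncidence:
    def test_worked_chain_hits_printed_incidence(self):
        fit2 = _gaussian_fit(DEFAULT_RATIO_PARAMS, REL2_COVS, vcov_scale=1e-12)
        fit1 = _rel1_fit(vcov_scale=1e-12)
        out = predict_incidence_wrt_occupancy(fit2, fit1, OCC_ROW, n_boot=100)
        # chain: r=0.57 -> n_pat=114 -> (1-p)*mu / 200 with the reference
        # incidence coefficients; printed-value arithmetic gives ~0.052
        assert out["n_pat_hat"].iloc[0] == pytest.approx(114.0, abs=1e-9)
        assert out["point"].iloc[0] == pytest.approx(0.05, abs=0.01)

    def test_certain_structural_zero_kills_incidence(self):
        pars = ZinbAr1Params(beta=DEFAULT_CASE_PARAMS.beta, beta_zi=[50.0, 0.0],
                             beta_disp=DEFAULT_CASE_PARAMS.beta_disp,
                             sigma_ar=0.3, phi=0.92)
        out = predict_incidence_wrt_occupancy(
            _gaussian_fit(DEFAULT_RATIO_PARAMS, REL2_COVS, 1e-12),
            _rel1_fit(pars, 1e-12), OCC_ROW, n_boot=100)
        assert out["point"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_monotone_in_occupancy(self):
        fit2 = _gaussian_fit(DEFAULT_RATIO_PARAMS, REL2_COVS, 1e-12)
        fit1 = _rel1_fit(vcov_scale=1e-12)
        rows = pd.concat([OCC_ROW, OCC_ROW.assign(n_occ=400.0)], ignore_index=True)
        out = predict_incidence_wrt_occupancy(fit2, fit1, rows, n_boot=100)
        assert out["n_pat_hat"].iloc[1] > out["n_pat_hat"].iloc[0]
        assert out["expected_cases"].iloc[1] > out["expected_cases"].iloc[0]

    def test_denominator_dominance(self):
        # incidence w.r.t. occupancy <= w.r.t. patients whenever r-hat <= 1
        fit2 = _gaussian_fit(DEFAULT_RATIO_PARAMS, REL2_COVS, 1e-12)
        fit1 = _rel1_fit(vcov_scale=1e-12)
        out = predict_incidence_wrt_occupancy(fit2, fit1, OCC_ROW, n_boot=100)
        inc_occ = out["point"].iloc[0]
        inc_pat = out["expected_cases"].iloc[0] / out["n_pat_hat"].iloc[0]
        assert inc_occ <= inc_pat


class TestIntervals:
    def test_zero_covariance_degenerate_width(self):
        fit = _gaussian_fit(DEFAULT_RATIO_PARAMS, REL2_COVS, vcov_scale=0.0)
        out = bootstrap_intervals(fit, OCC_ROW, n_boot=200, seed=0)
        assert out["upper95"].iloc[0] - out["lower95"].iloc[0] == pytest.approx(0.0)

    def test_width_scales_linearly_with_coefficient_sd(self):
        w = []
        for c in (1.0, 4.0):  # covariance scaled by c^2 -> width by c
            fit = _gaussian_fit(DEFAULT_RATIO_PARAMS, REL2_COVS,
                                vcov_scale=c * 1e-4)
            out = bootstrap_intervals(fit, OCC_ROW, n_boot=4000, seed=1)
            w.append(out["upper95"].iloc[0] - out["lower95"].iloc[0])
        assert w[1] / w[0] == pytest.approx(2.0, rel=0.1)

    def test_intervals_contain_point(self):
        fit = _gaussian_fit(DEFAULT_RATIO_PARAMS, REL2_COVS, vcov_scale=1e-3)
        for method in ("wald_delta", "parametric_bootstrap"):
            out = predict_ratio(fit, OCC_ROW, method=method, n_boot=300, seed=2)
            assert out["lower95"].iloc[0] <= out["point"].iloc[0] <= out["upper95"].iloc[0]

    def test_few_draws_warn(self):
        fit = _gaussian_fit(DEFAULT_RATIO_PARAMS, REL2_COVS, vcov_scale=1e-3)
        with pytest.warns(UserWarning, match="bootstrap"):
            bootstrap_intervals(fit, OCC_ROW, n_boot=50, seed=0)

    def test_bootstrap_reproducible_under_seed(self):
        fit = _gaussian_fit(DEFAULT_RATIO_PARAMS, REL2_COVS, vcov_scale=1e-3)
        a = bootstrap_intervals(fit, OCC_ROW, n_boot=300, seed=7)
        b = bootstrap_intervals(fit, OCC_ROW, n_boot=300, seed=7)
        pd.testing.assert_frame_equal(a, b)
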
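"""Model fitting: oracle equivalences, Wald intervals, AIC comparison."""

import numpy as np
import pandas as pd
import pytest

from denomcast.fit import (
    REL2_MEAN_COVARIATES,
    REL3_MEAN_COVARIATES,
    REL3_VARIANCE_COVARIATES,
    build_design,
    compare_models,
    fit_gaussian_ratio,
    fit_relationship1,
    wald_ci,
)
from denomcast.params import FitResult, GaussianDispParams
from denomcast.studies import simulate_ehr_panel, simulate_matched_panel


@pytest.fixture(scope="module")
def matched_panel():
    rng = np.random.default_rng(21)
    return simulate_matched_panel(rng, n=147, relationship=2)


class TestGaussianRatioFit:
    def test_constant_variance_equals_least_squares(self, matched_panel):
        fit = fit_gaussian_ratio(matched_panel, REL2_MEAN_COVARIATES, ())
        X = build_design(matched_panel, REL2_MEAN_COVARIATES)
        y = matched_panel["r"].to_numpy()
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.allclose(fit.params.mean_coefs, beta_ols, atol=1e-6)
        # ML variance = RSS / n
        rss = float(np.sum((y - X @ beta_ols) ** 2))
        assert fit.params.constant_variance == pytest.approx(rss / len(y), rel=1e-6)

    def test_noiseless_plane_recovered_exactly(self):
        rng = np.random.default_rng(3)
        df = simulate_matched_panel(rng, n=60, relationship=2)
        truth = np.array([0.1, 0.05, -0.02, 0.3, 0.0])
        X = build_design(df, REL2_MEAN_COVARIATES)
        df = df.assign(r=X @ truth)
        fit = fit_gaussian_ratio(df, REL2_MEAN_COVARIATES, ())
        assert np.allclose(fit.params.mean_coefs, truth, atol=1e-5)
        assert fit.boundary_sigma  # zero-variance boundary flagged

    def test_heteroscedastic_variance_submodel(self):
        rng = np.random.default_rng(4)
        df = simulate_matched_panel(rng, n=3000, relationship=3)
        fit = fit_gaussian_ratio(df, REL3_MEAN_COVARIATES, REL3_VARIANCE_COVARIATES)
        assert fit.converged
        # generating log-variance: -3.35 - 0.01 * n_pat/10
        assert fit.params.logvar_coefs[0] == pytest.approx(-3.35, abs=0.12)
        assert fit.params.logvar_coefs[1] == pytest.approx(-0.01, abs=0.01)

    def test_too_few_observations(self):
        rng = np.random.default_rng(5)
        df = simulate_matched_panel(rng, n=5, relationship=2)
        with pytest.raises(ValueError, match="observations"):
            fit_gaussian_ratio(df, REL2_MEAN_COVARIATES, ())

    def test_centre_type_relabel_invariance(self, matched_panel):
        # swapping the REG/REC encoding shifts the intercept, flips the sign
        fit_ref = fit_gaussian_ratio(matched_panel, REL2_MEAN_COVARIATES, ())
        flipped = matched_panel.copy()
        flipped["centre_type"] = np.where(flipped["centre_type"] == "REG", "REC", "REG")
        fit_flip = fit_gaussian_ratio(flipped, REL2_MEAN_COVARIATES, ())
        i_reg = fit_ref.param_names.index("mean_reg")
        assert fit_flip.theta[i_reg] == pytest.approx(-fit_ref.theta[i_reg], abs=1e-5)
        assert fit_flip.theta[0] == pytest.approx(
            fit_ref.theta[0] + fit_ref.theta[i_reg], abs=1e-5)
        assert fit_flip.loglik == pytest.approx(fit_ref.loglik, abs=1e-6)


class TestRelationship1Fit:
    def test_no_zi_no_latent_matches_statsmodels_nb2(self):
        # independent oracle: statsmodels NegativeBinomial (NB2) regression
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(6)
        # REC-only panel so the dispersion submodel reduces to a single theta
        panel = simulate_ehr_panel(rng, n_total=300, n_reg=0)
        # regenerate counts without zero inflation or latent noise
        from denomcast.params import ZinbAr1Params
        from denomcast.simulate import DEFAULT_CASE_PARAMS, GeneratorConfig, generate_cases

        pars = ZinbAr1Params(beta=DEFAULT_CASE_PARAMS.beta, beta_zi=[-50.0, 0.0],
                             beta_disp=[np.log(3.11), 0.0], sigma_ar=0.0, phi=0.0)
        panel = generate_cases(panel.drop(columns="n_cases"), pars,
                               GeneratorConfig(), rng=rng)
        panel = panel.rename(columns={"n_cases_true": "n_cases"})
        fit = fit_relationship1(panel, variant="no_zi", include_ar1=False, se=False)

        X = build_design(panel.sort_values(["centre_id", "month_index"]),
                         ("adult_pat10", "male_pat10", "npat10"))
        y = panel.sort_values(["centre_id", "month_index"])["n_cases"].to_numpy()
        oracle = sm.NegativeBinomial(y, X, loglike_method="nb2").fit(disp=0, maxiter=500)
        assert fit.loglik == pytest.approx(oracle.llf, abs=1e-4)
        assert np.allclose(fit.params.beta, oracle.params[:4], atol=1e-3)
        # statsmodels parameterises alpha = 1/theta
        assert np.exp(-fit.params.beta_disp[0]) == pytest.approx(
            oracle.params[-1], abs=2e-3)

    def test_intercept_only_matches_sample_moments(self):
        rng = np.random.default_rng(8)
        n = 4000
        panel = pd.DataFrame({
            "centre_id": "A", "centre_type": "REC", "month_index": np.arange(n),
            "n_pat": 1.0, "pct_male_pat": 0.0, "pct_adult_pat": 0.0,
            "n_cases": rng.negative_binomial(3.0, 3.0 / (3.0 + 12.0), n),
        })
        fit = fit_relationship1(panel, variant="no_zi", include_ar1=False, se=False)
        # with covariates fixed at 0 only the intercept is identified: mu ~ ybar
        mu_hat = np.exp(fit.params.beta[0])
        assert mu_hat == pytest.approx(panel["n_cases"].mean(), rel=1e-4)

    def test_rejects_nonpositive_patient_counts(self):
        panel = pd.DataFrame({
            "centre_id": ["A"], "centre_type": ["REC"], "month_index": [0],
            "n_pat": [0], "pct_male_pat": [50.0], "pct_adult_pat": [50.0],
            "n_cases": [2],
        })
        with pytest.raises(ValueError, match="n_pat"):
            fit_relationship1(panel)

    def test_unknown_variant(self, matched_panel):
        with pytest.raises(ValueError, match="variant"):
            fit_relationship1(matched_panel, variant="bayes")


class TestWaldCi:
    def _dummy_fit(self, est, se):
        k = len(est)
        return FitResult(
            model="gaussian_ratio",
            params=GaussianDispParams(mean_coefs=est[:-1], logvar_coefs=est[-1:]),
            param_names=[f"p{i}" for i in range(k)],
            theta=np.asarray(est, dtype=float),
            loglik=-1.0, n_obs=10, converged=True,
            vcov=np.diag(np.asarray(se, dtype=float) ** 2),
        )

    def test_standard_normal_quantile(self):
        lo, hi = wald_ci(self._dummy_fit([0.0, 0.0], [1.0, 0.0]))
        assert lo[0] == pytest.approx(-1.959964, abs=1e-5)
        assert hi[0] == pytest.approx(1.959964, abs=1e-5)

    def test_exponentiated_degenerate(self):
        lo, hi = wald_ci(self._dummy_fit([0.0, 0.0], [0.0, 0.0]), transform="exp")
        assert lo[0] == hi[0] == pytest.approx(1.0)

    def test_ci_ordering_and_positivity(self):
        fit = self._dummy_fit([0.5, -2.0], [0.2, 0.6])
        lo, hi = wald_ci(fit, transform="exp")
        assert (lo <= hi).all() and (lo > 0).all()

    def test_requires_covariance(self, matched_panel):
        fit = fit_gaussian_ratio(matched_panel, REL2_MEAN_COVARIATES, (), se=False)
        with pytest.raises(ValueError, match="covariance"):
            wald_ci(fit)


class TestCompareModels:
    def _fit(self, loglik, k, tag="d1"):
        return FitResult(
            model=f"m{k}", params=GaussianDispParams(np.zeros(k - 1), np.zeros(1)),
            param_names=[f"p{i}" for i in range(k)], theta=np.zeros(k),
            loglik=loglik, n_obs=100, converged=True, dataset_tag=tag)

    def test_aic_arithmetic_and_ranking(self):
        table = compare_models([self._fit(-12.0, 3), self._fit(-10.0, 3)])
        assert table["aic"].tolist() == [26.0, 30.0]
        assert table["delta_aic"].tolist() == [0.0, 4.0]
        assert table.loc[0, "loglik"] == -10.0

    def test_identical_fits_tie(self):
        table = compare_models([self._fit(-10.0, 3), self._fit(-10.0, 3)])
        assert (table["delta_aic"] == 0).all()

    def test_mixed_datasets_rejected(self):
        with pytest.raises(ValueError, match="same dataset"):
            compare_models([self._fit(-10.0, 3, "d1"), self._fit(-10.0, 3, "d2")])

    def test_aic_identity_on_real_fits(self, matched_panel):
        fit = fit_gaussian_ratio(matched_panel, REL2_MEAN_COVARIATES, ())
        assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.loglik, abs=1e-12)

    def test_null_covariate_rarely_preferred(self):
        # adding a pure-noise covariate should not beat the smaller model by
        # more than the AIC penalty in the typical replicate
        wins = 0
        for rep in range(10):
            rng = np.random.default_rng(100 + rep)
            df = simulate_matched_panel(rng, n=400, relationship=2)
            df["noise"] = rng.standard_normal(len(df))
            small = fit_gaussian_ratio(df, REL2_MEAN_COVARIATES, (), se=False)
            big = fit_gaussian_ratio(df, REL2_MEAN_COVARIATES + ("noise",), (),
                                     se=False)
            if big.aic < small.aic - 1e-9:
                wins += 1
        assert wins <= 3


class TestFitResultSerialisation:
    def test_json_round_trip(self, matched_panel, tmp_path):
        fit = fit_gaussian_ratio(matched_panel, REL2_MEAN_COVARIATES, ())
        path = tmp_path / "fit.json"
        fit.to_json(path)
        back = FitResult.from_json(path)
        assert back.model == fit.model
        assert np.allclose(back.theta, fit.theta)
        assert np.allclose(back.vcov, fit.vcov)
        assert back.aic == pytest.approx(fit.aic)
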
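"""Simulation-based residual diagnostics for fitted models.

Implements the randomized-quantile-residual idea: simulate replicate response
vectors from the fitted generative model, place each observation within its
simulated distribution (randomising over ties), and check the resulting
residuals against U(0, 1) — a KS test for overall distributional fit, a
dispersion ratio (observed vs simulated response variance) and a count of
observations outside the simulation envelope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .fit import _rel1_design, build_design
from .params import FitResult, GaussianDispParams, ZinbAr1Params
from .simulate import simulate_latent_ar1

__all__ = ["ResidualDiagnostics", "simulate_from_fit", "quantile_residuals"]

ENVELOPE_TAIL = 0.005  # outliers counted beyond the 0.5% simulation tails


@dataclass
class ResidualDiagnostics:
    """Randomized-quantile residuals with summary checks."""

    residuals: np.ndarray  # in (0, 1), one per observation
    ks_stat: float
    ks_pvalue: float
    dispersion_ratio: float  # observed response variance / mean simulated variance
    n_outliers: int
    n_obs: int

    @property
    def outlier_fraction(self) -> float:
        return self.n_outliers / self.n_obs if self.n_obs else 0.0

    def summary(self) -> dict:
        return {
            "ks_stat": self.ks_stat,
            "ks_pvalue": self.ks_pvalue,
            "dispersion_ratio": self.dispersion_ratio,
            "n_outliers": self.n_outliers,
            "n_obs": self.n_obs,
            "residual_mean": float(np.mean(self.residuals)),
            "residual_var": float(np.var(self.residuals)),
        }


def _sorted_frame(fit: FitResult, df: pd.DataFrame) -> pd.DataFrame:
    if isinstance(fit.params, ZinbAr1Params):
        return df.sort_values(["centre_id", "month_index"]).reset_index(drop=True)
    return df.reset_index(drop=True)


def simulate_from_fit(fit: FitResult, df: pd.DataFrame, n_sim: int, seed: int = 0) -> np.ndarray:
    """Draw ``n_sim`` replicate response vectors from the fitted model.

    Rows follow ``df`` sorted by centre and month for the incidence model
    (the same ordering the likelihood uses), or ``df`` order for ratio models.
    Includes all fitted components: zero-inflation, dispersion submodel and
    fresh latent AR(1) draws for relationship 1.
    """
    rng = np.random.default_rng(seed)
    work = _sorted_frame(fit, df)
    n = len(work)
    if n_sim == 0:
        return np.empty((0, n))

    if isinstance(fit.params, GaussianDispParams):
        covs = tuple(c[len("mean_"):] for c in fit.param_names
                     if c.startswith("mean_") and c != "mean_intercept")
        vcovs = tuple(c[len("logvar_"):] for c in fit.param_names
                      if c.startswith("logvar_") and c != "logvar_intercept")
        X = build_design(work, covs)
        Zv = build_design(work, vcovs)
        mean = X @ fit.params.mean_coefs
        sd = np.sqrt(np.exp(Zv @ fit.params.logvar_coefs))
        return mean[None, :] + sd[None, :] * rng.standard_normal((n_sim, n))

    pars: ZinbAr1Params = fit.params
    use_zi = pars.beta_zi.size > 0
    extra = tuple(c[len("cond_"):] for c in fit.param_names
                  if c.startswith("cond_") and
                  c not in ("cond_intercept", "cond_adult10", "cond_male10", "cond_npat10"))
    X = build_design(work, ("adult_pat10", "male_pat10", "npat10") + extra)
    eta = X @ pars.beta
    p_zi = expit(build_design(work, ("npat10",)) @ pars.beta_zi) if use_zi else np.zeros(n)
    theta = np.exp(build_design(work, ("reg",)) @ pars.beta_disp)

    groups = [(sub.index.to_numpy(), sub["month_index"].to_numpy())
              for _, sub in work.groupby("centre_id", sort=True)]
    out = np.empty((n_sim, n), dtype=float)
    for b in range(n_sim):
        latent = np.zeros(n)
        if pars.sigma_ar > 0:
            for idx, months in groups:
                latent[idx] = simulate_latent_ar1(months, pars.sigma_ar, pars.phi, rng)
        mu = np.exp(np.minimum(eta + latent, 30.0))
        lam = rng.gamma(shape=theta, scale=mu / theta)
        y = rng.poisson(lam).astype(float)
        if use_zi:
            y[rng.random(n) < p_zi] = 0.0
        out[b] = y
    return out


def quantile_residuals(fit: FitResult, df: pd.DataFrame, n_sim: int = 250,
                       seed: int = 0) -> ResidualDiagnostics:
    """Randomized quantile residuals of the observed responses under the fit.

    Each residual is the (tie-randomised) empirical quantile of the observed
    value within its simulated distribution; under a correctly specified
    model the residuals are U(0, 1).
    """
    work = _sorted_frame(fit, df)
    if isinstance(fit.params, ZinbAr1Params):
        y = work["n_cases"].to_numpy(dtype=float)
    else:
        y = work["r"].to_numpy(dtype=float)
    sims = simulate_from_fit(fit, work, n_sim, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])

    less = (sims < y[None, :]).sum(axis=0)
    equal = (sims == y[None, :]).sum(axis=0)
    u = rng.random(y.size)
    resid = (less + u * (1 + equal)) / (n_sim + 1.0)
    resid = np.clip(resid, 1e-12, 1.0 - 1e-12)

    ks = stats.kstest(resid, "uniform")
    var_obs = float(np.var(y, ddof=1))
    var_sim = float(np.mean(np.var(sims, axis=1, ddof=1)))
    dispersion = var_obs / var_sim if var_sim > 0 else np.inf
    n_out = int(np.sum((resid < ENVELOPE_TAIL) | (resid > 1.0 - ENVELOPE_TAIL)))
    return ResidualDiagnostics(
        residuals=resid,
        ks_stat=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
        dispersion_ratio=dispersion,
        n_outliers=n_out,
        n_obs=y.size,
    )
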
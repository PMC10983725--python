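"""Maximum-likelihood fitting of the three surveillance relationships.

* Relationship 1 — zero-inflated NB2 with log-linear dispersion and latent
  per-centre AR(1) (disease incidence given patient counts and demographics).
* Relationship 2 — Gaussian model of the patient/occupancy ratio given
  occupancy demographics, centre type and occupancy (constant variance).
* Relationship 3 — Gaussian model of the ratio given patient demographics and
  centre type, with the residual variance depending on the patient count.

Covariates named with a ``10`` suffix enter per 10 percentage points (adult,
male) or per 10 persons (n_pat, n_occ); raw-scale columns are transformed
internally.  Any other numeric column of the data frame may be named as an
extra covariate, which covers e.g. country-of-origin composition shares.
"""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.tools.numdiff import approx_hess

from .likelihood import (
    Rel1Data,
    gaussian_nll,
    gaussian_nll_grad,
    marginal_loglik_zinb_ar1,
)
from .params import FitResult, GaussianDispParams, ZinbAr1Params

__all__ = [
    "fit_relationship1",
    "fit_gaussian_ratio",
    "wald_ci",
    "compare_models",
    "build_design",
    "REL2_MEAN_COVARIATES",
    "REL3_MEAN_COVARIATES",
    "REL3_VARIANCE_COVARIATES",
]

REL2_MEAN_COVARIATES = ("adult_occ10", "male_occ10", "reg", "nocc10")
REL3_MEAN_COVARIATES = ("adult_pat10", "male_pat10", "reg")
REL3_VARIANCE_COVARIATES = ("npat10",)

_BOUNDARY_SIGMA = 1e-3


def _covariate_column(df: pd.DataFrame, name: str) -> np.ndarray:
    """Resolve a covariate name to a numeric column on the model scale."""
    builders = {
        "adult_occ10": lambda: df["pct_adult_occ"] / 10.0,
        "male_occ10": lambda: df["pct_male_occ"] / 10.0,
        "adult_pat10": lambda: df["pct_adult_pat"] / 10.0,
        "male_pat10": lambda: df["pct_male_pat"] / 10.0,
        "npat10": lambda: df["n_pat"] / 10.0,
        "nocc10": lambda: df["n_occ"] / 10.0,
        "reg": lambda: (df["centre_type"] == "REG").astype(float),
    }
    if name in builders:
        col = builders[name]()
    elif name in df.columns:
        col = df[name]
    else:
        raise KeyError(f"covariate {name!r} not recognised and not a column")
    return np.asarray(col, dtype=float)


def build_design(df: pd.DataFrame, covariates) -> np.ndarray:
    """Intercept-first design matrix for the named covariates."""
    cols = [np.ones(len(df))]
    cols.extend(_covariate_column(df, c) for c in covariates)
    return np.column_stack(cols)


def _dataset_tag(df: pd.DataFrame) -> str:
    key = f"{len(df)}|" + "|".join(sorted(map(str, df.columns)))
    if "n_cases" in df.columns:
        key += "|" + str(float(pd.to_numeric(df["n_cases"], errors="coerce").sum()))
    return hashlib.sha1(key.encode()).hexdigest()[:12]


def _rel1_design(df: pd.DataFrame, extra_covariates=(), use_zi=True) -> Rel1Data:
    work = df.sort_values(["centre_id", "month_index"]).reset_index(drop=True)
    X = build_design(work, ("adult_pat10", "male_pat10", "npat10") + tuple(extra_covariates))
    Z = build_design(work, ("npat10",)) if use_zi else np.zeros((len(work), 0))
    D = build_design(work, ("reg",))
    groups = []
    for _, sub in work.groupby("centre_id", sort=True):
        groups.append((sub.index.to_numpy(), sub["month_index"].to_numpy(dtype=int)))
    return Rel1Data(y=work["n_cases"].to_numpy(dtype=float), X=X, Z=Z, D=D, groups=groups)


def _unpack_rel1(theta, p_cond, use_zi, include_ar1):
    pos = p_cond
    beta = theta[:pos]
    if use_zi:
        beta_zi = theta[pos : pos + 2]
        pos += 2
    else:
        beta_zi = np.zeros(0)
    beta_disp = theta[pos : pos + 2]
    pos += 2
    if include_ar1:
        sigma = float(np.exp(np.clip(theta[pos], -20.0, 5.0)))
        phi = float(np.tanh(theta[pos + 1]))
    else:
        sigma, phi = 0.0, 0.0
    return ZinbAr1Params(beta=beta, beta_zi=beta_zi, beta_disp=beta_disp,
                         sigma_ar=sigma, phi=phi)


def fit_relationship1(
    df: pd.DataFrame,
    variant: str = "full",
    include_ar1: bool = True,
    extra_covariates=(),
    se: bool = True,
    n_starts: int = 3,
    seed: int = 0,
    sigma_start: float = 0.2,
    phi_start: float = 0.5,
) -> FitResult:
    """Fit the zero-inflated NB2-AR(1) disease-incidence model by ML.

    ``variant='no_zi'`` drops the zero-inflation component (used when rows
    with zero case counts are excluded, so structural zeros cannot occur).
    The latent process is first profiled out by fitting the closed-form
    no-latent model, whose optimum seeds the full Laplace-marginal fit;
    additional randomised starts guard against local optima.

    Standard errors come from the numerically differentiated Hessian of the
    marginal log-likelihood at the optimum (``se=False`` skips them, useful in
    simulation studies that only need point estimates).
    """
    if variant not in {"full", "no_zi"}:
        raise ValueError(f"unknown variant {variant!r}")
    use_zi = variant == "full"
    data = _rel1_design(df, extra_covariates, use_zi=use_zi)
    if np.any(df["n_pat"].to_numpy() <= 0):
        raise ValueError("relationship 1 requires n_pat > 0 for every row")
    p_cond = data.X.shape[1]
    rng = np.random.default_rng(seed)

    # ---- stage A: closed-form fit without the latent process -------------
    def nll_nolatent(theta):
        pars = _unpack_rel1(theta, p_cond, use_zi, include_ar1=False)
        val = -marginal_loglik_zinb_ar1(pars, data)
        return val if np.isfinite(val) else 1e10

    k_a = p_cond + (2 if use_zi else 0) + 2
    ybar = max(float(np.mean(data.y)), 0.1)
    start_a = np.zeros(k_a)
    start_a[0] = np.log(ybar)
    if use_zi:
        zero_share = float(np.mean(data.y == 0))
        start_a[p_cond] = np.log((zero_share + 0.02) / (1.0 - zero_share + 0.02))
    bounds_a = [(-15.0, 15.0)] * k_a
    res_a = optimize.minimize(nll_nolatent, start_a, method="L-BFGS-B",
                              bounds=bounds_a, options={"maxiter": 500, "ftol": 1e-11})

    if not include_ar1:
        best, theta_hat = res_a, res_a.x
        pars = _unpack_rel1(theta_hat, p_cond, use_zi, include_ar1=False)
        boundary = False
    else:
        sigma_start, phi_start = _latent_moment_start(
            res_a.x, data, p_cond, use_zi, default=(sigma_start, phi_start))
        # ---- stage B: full Laplace-marginal fit --------------------------
        warm: dict = {}
        cov_cache: dict = {}

        def nll(theta):
            pars = _unpack_rel1(theta, p_cond, use_zi, include_ar1=True)
            val = -marginal_loglik_zinb_ar1(pars, data, warm_starts=warm,
                                            cov_cache=cov_cache)
            return val if np.isfinite(val) else 1e10

        base = np.concatenate([res_a.x, [np.log(sigma_start), np.arctanh(phi_start)]])
        starts = [base]
        for _ in range(max(0, n_starts - 1)):
            jit = rng.normal(0.0, 0.1, size=base.size)
            jit[-1] = rng.normal(0.0, 0.5)
            starts.append(base + jit)
        # boxes keep the search out of numerically hostile regions:
        # |phi| <= tanh(3) ~ 0.995, sigma_ar <= e^1 ~ 2.7
        bounds = [(-15.0, 15.0)] * k_a + [(-7.0, 1.0), (-3.0, 3.0)]
        best = None
        for s in starts[:n_starts]:
            r = optimize.minimize(nll, np.clip(s, [b[0] for b in bounds],
                                               [b[1] for b in bounds]),
                                  method="L-BFGS-B", bounds=bounds,
                                  options={"maxiter": 400, "ftol": 1e-10})
            if best is None or r.fun < best.fun:
                best = r
        theta_hat = best.x
        pars = _unpack_rel1(theta_hat, p_cond, use_zi, include_ar1=True)
        boundary = pars.sigma_ar < _BOUNDARY_SIGMA

    names = ["cond_intercept", "cond_adult10", "cond_male10", "cond_npat10"]
    names += [f"cond_{c}" for c in extra_covariates]
    if use_zi:
        names += ["zi_intercept", "zi_npat10"]
    names += ["disp_intercept", "disp_reg"]
    if include_ar1:
        names += ["log_sigma_ar", "atanh_phi"]

    vcov = None
    if se:
        def nll_se(theta):
            pars_l = _unpack_rel1(theta, p_cond, use_zi, include_ar1)
            return -marginal_loglik_zinb_ar1(pars_l, data)

        vcov = _vcov_from_hessian(nll_se, theta_hat)

    return FitResult(
        model=f"relationship1_{variant}" + ("" if include_ar1 else "_noar1"),
        params=pars,
        param_names=names,
        theta=theta_hat,
        loglik=-float(best.fun),
        n_obs=data.n,
        converged=bool(best.success),
        vcov=vcov,
        boundary_sigma=boundary,
        trace={"n_starts": n_starts, "stage_a_nll": float(res_a.fun),
               "optimizer": "L-BFGS-B", "n_iter": int(best.nit)},
        dataset_tag=_dataset_tag(df),
    )


def _latent_moment_start(theta_a, data, p_cond, use_zi, default=(0.2, 0.5)):
    """Moment-based starting values for the latent AR(1) parameters.

    Uses the no-latent fit's log-scale residuals ``log((y + 0.5) / mu_hat)``:
    their within-centre lag-1 autocorrelation seeds phi and their standard
    deviation (shrunk, since it also carries count noise) seeds sigma.
    """
    pars_a = _unpack_rel1(theta_a, p_cond, use_zi, include_ar1=False)
    mu = np.exp(np.clip(data.X @ pars_a.beta, -30.0, 30.0))
    d = np.log((data.y + 0.5) / np.maximum(mu, 1e-8))
    num = den = 0.0
    for idx, months in data.groups:
        if idx.size < 2:
            continue
        dg = d[idx] - d[idx].mean()
        consecutive = np.diff(months) == 1
        num += float(np.sum(dg[:-1][consecutive] * dg[1:][consecutive]))
        den += float(np.sum(dg**2))
    phi = num / den if den > 0 else default[1]
    phi = float(np.clip(phi, 0.05, 0.95))
    # half the residual spread: the rest is count-level noise
    sigma = float(np.clip(0.5 * np.std(d), 0.05, 1.0))
    return sigma, phi


def fit_gaussian_ratio(
    df: pd.DataFrame,
    mean_covariates=REL2_MEAN_COVARIATES,
    variance_covariates=(),
    se: bool = True,
) -> FitResult:
    """Jointly fit mean and log-variance coefficients of a Gaussian ratio model.

    With ``variance_covariates=()`` the variance is a single constant
    ``exp(intercept)`` (relationship 2); naming ``npat10`` reproduces the
    patient-count-dependent dispersion of relationship 3.
    """
    if "r" not in df.columns:
        raise ValueError("dataset must carry the ratio column 'r'")
    y = df["r"].to_numpy(dtype=float)
    X = build_design(df, mean_covariates)
    Zv = build_design(df, variance_covariates)
    k = X.shape[1] + Zv.shape[1]
    if len(df) <= k:
        raise ValueError(f"need more than {k} observations to fit {k} parameters")

    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta0) ** 2))
    gamma0 = np.zeros(Zv.shape[1])
    gamma0[0] = np.log(max(rss / len(y), 1e-12))
    start = np.concatenate([beta0, gamma0])
    p = X.shape[1]

    def nll(theta):
        return gaussian_nll(theta[:p], theta[p:], y, X, Zv)

    def grad(theta):
        return gaussian_nll_grad(theta[:p], theta[p:], y, X, Zv)

    res = optimize.minimize(nll, start, jac=grad, method="BFGS",
                            options={"maxiter": 500, "gtol": 1e-8})
    theta_hat = res.x
    # BFGS may flag precision loss at an already-converged point
    grad_ok = float(np.max(np.abs(grad(theta_hat)))) < 1e-4 * max(1.0, len(df) / 100)
    converged = bool(res.success or grad_ok)
    pars = GaussianDispParams(mean_coefs=theta_hat[:p], logvar_coefs=theta_hat[p:])
    names = ["mean_intercept"] + [f"mean_{c}" for c in mean_covariates]
    names += ["logvar_intercept"] + [f"logvar_{c}" for c in variance_covariates]

    vcov = _vcov_from_hessian(nll, theta_hat) if se else None
    variance_boundary = pars.constant_variance is not None and pars.constant_variance < 1e-10
    return FitResult(
        model="gaussian_ratio",
        params=pars,
        param_names=names,
        theta=theta_hat,
        loglik=-float(res.fun),
        n_obs=len(df),
        converged=converged,
        vcov=vcov,
        boundary_sigma=variance_boundary,
        trace={"optimizer": "BFGS", "n_iter": int(res.nit)},
        dataset_tag=_dataset_tag(df),
    )


def _vcov_from_hessian(nll, theta_hat) -> np.ndarray:
    """Wald covariance from the numerically differentiated Hessian."""
    H = approx_hess(np.asarray(theta_hat, dtype=float), nll)
    H = 0.5 * (H + H.T)
    try:
        vcov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        vcov = np.linalg.pinv(H)
    diag = np.diag(vcov)
    if np.any(diag < 0):
        # non-PD Hessian (e.g. at a variance boundary): flag by widening
        vcov = np.linalg.pinv(0.5 * (H + H.T) + 1e-8 * np.eye(H.shape[0]))
    return vcov


def wald_ci(fit: FitResult, level: float = 0.95, transform: str | None = None):
    """Wald intervals ``estimate +/- z * se`` on the optimisation scale.

    ``transform='exp'`` exponentiates the bounds (IRR / odds-ratio scale).
    Returns ``(lower, upper)`` arrays aligned with ``fit.param_names``.
    """
    if fit.vcov is None:
        raise ValueError("fit carries no covariance; refit with se=True")
    z = stats.norm.ppf(0.5 + level / 2.0)
    se = fit.se
    est = np.asarray(fit.theta, dtype=float)
    lo, hi = est - z * se, est + z * se
    if transform == "exp":
        lo, hi = np.exp(lo), np.exp(hi)
    elif transform is not None:
        raise ValueError(f"unknown transform {transform!r}")
    return lo, hi


def compare_models(fits: list[FitResult]) -> pd.DataFrame:
    """Rank fits of the same dataset by AIC (ascending), with deltas."""
    if not fits:
        raise ValueError("no fits to compare")
    tags = {f.dataset_tag for f in fits}
    ns = {f.n_obs for f in fits}
    if len(tags) > 1 or len(ns) > 1:
        raise ValueError("compare_models requires fits on the same dataset")
    rows = [
        {"model": f.model, "k": f.k, "loglik": f.loglik, "aic": f.aic}
        for f in fits
    ]
    table = pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)
    table["delta_aic"] = table["aic"] - table["aic"].iloc[0]
    return table
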
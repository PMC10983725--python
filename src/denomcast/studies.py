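"""Parameter-recovery and calibration studies for the three relationships.

These simulation experiments generate panels whose covariate marginals match
the surveillance study conditions (21 centres enrolled 2-45 months, 445 EHR
centre-months with mean 230 patients sd 202, 147 matched centre-months), use
the reference coefficient sets as generating truth, refit the corresponding
model and summarise how well the generating values are recovered.  They back
both the test suite and the acceptance script.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .fit import (
    REL2_MEAN_COVARIATES,
    REL3_MEAN_COVARIATES,
    REL3_VARIANCE_COVARIATES,
    fit_gaussian_ratio,
    fit_relationship1,
)
from .params import GaussianDispParams, ZinbAr1Params
from .predict import bootstrap_intervals
from .simulate import (
    DEFAULT_CASE_PARAMS,
    GeneratorConfig,
    _rescale_windows,
    generate_cases,
)

__all__ = [
    "REL3_TRUTH",
    "simulate_ehr_panel",
    "simulate_matched_panel",
    "run_relationship1_recovery",
    "run_gaussian_recovery",
    "run_ratio_coverage",
]

# Generating truth for the patient-side ratio model (relationship 3): mean
# part [intercept, adult%/10, male%/10, REG], log-variance part
# [intercept, n_pat/10].
REL3_TRUTH = GaussianDispParams(
    mean_coefs=[0.37, -0.02, 0.04, 0.20],
    logvar_coefs=[-3.35, -0.01],
)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    s2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - s2 / 2.0, math.sqrt(s2)


def simulate_ehr_panel(rng, n_total: int = 445, n_centres: int = 21, n_reg: int = 5,
                       truth: ZinbAr1Params = DEFAULT_CASE_PARAMS) -> pd.DataFrame:
    """One EHR-layout panel: 21 centres, windows 2-45 months totalling 445 rows.

    Covariates follow the EHR marginals (male% ~ N(60, 14), adult% ~ N(80, 10),
    n_pat lognormal with mean 230 / sd 202, floor 5); case counts come from the
    incidence model under ``truth``, uncensored.
    """
    lengths = rng.integers(2, 46, size=n_centres).astype(float)
    lengths = _rescale_windows(lengths, n_total, 2, 45)
    types = np.array(["REG"] * n_reg + ["REC"] * (n_centres - n_reg))
    rng.shuffle(types)
    mu_l, s_l = _lognormal_params(230.0, 202.0)

    rows = []
    for i, (L, ctype) in enumerate(zip(lengths, types)):
        start = rng.integers(0, 46 - L)
        for t in range(int(L)):
            n_pat = max(5, int(round(rng.lognormal(mu_l, s_l))))
            rows.append({
                "centre_id": f"S{i + 1:02d}",
                "centre_type": ctype,
                "month_index": int(start + t),
                "n_pat": n_pat,
                "pct_male_pat": float(np.clip(rng.normal(60.0, 14.0), 5.0, 100.0)),
                "pct_adult_pat": float(np.clip(rng.normal(80.0, 10.0), 30.0, 100.0)),
            })
    panel = pd.DataFrame(rows)
    cfg = GeneratorConfig(case_params=truth)
    cases = generate_cases(panel, truth, cfg, rng=rng)
    cases = cases.rename(columns={"n_cases_true": "n_cases"})
    return cases


def simulate_matched_panel(rng, n: int = 147, relationship: int = 2,
                           truth: GaussianDispParams | None = None) -> pd.DataFrame:
    """One matched-layout panel of ratio observations (147 centre-months).

    Covariate marginals follow the matched dataset: male% ~ N(60, 13),
    adult% ~ N(80, 10), ~29% REG rows, occupancy lognormal mean 394 / sd 312
    and patient count lognormal mean 212 / sd 195.  The ratio r is drawn from
    the Gaussian mean/variance model of the requested relationship.
    """
    if truth is None:
        from .simulate import DEFAULT_RATIO_PARAMS

        truth = DEFAULT_RATIO_PARAMS if relationship == 2 else REL3_TRUTH
    reg = rng.random(n) < 43.0 / 147.0
    male = np.clip(rng.normal(60.0, 13.0, n), 5.0, 100.0)
    adult = np.clip(rng.normal(80.0, 10.0, n), 30.0, 100.0)
    mu_o, s_o = _lognormal_params(394.0, 312.0)
    mu_p, s_p = _lognormal_params(212.0, 195.0)
    n_occ = np.maximum(30, np.round(rng.lognormal(mu_o, s_o, n))).astype(int)
    n_pat = np.maximum(5, np.round(rng.lognormal(mu_p, s_p, n))).astype(int)

    df = pd.DataFrame({
        "centre_id": [f"M{i:03d}" for i in range(n)],
        "centre_type": np.where(reg, "REG", "REC"),
        "pct_male_occ": male, "pct_adult_occ": adult,
        "pct_male_pat": male, "pct_adult_pat": adult,
        "n_occ": n_occ, "n_pat": n_pat,
    })
    from .fit import build_design

    if relationship == 2:
        X = build_design(df, REL2_MEAN_COVARIATES)
        Zv = build_design(df, ())
    elif relationship == 3:
        X = build_design(df, REL3_MEAN_COVARIATES)
        Zv = build_design(df, REL3_VARIANCE_COVARIATES)
    else:
        raise ValueError("relationship must be 2 or 3")
    mean = X @ truth.mean_coefs
    sd = np.sqrt(np.exp(Zv @ truth.logvar_coefs))
    df["r"] = mean + sd * rng.standard_normal(n)
    return df


def run_relationship1_recovery(n_replicates: int = 20, seed: int = 0,
                               truth: ZinbAr1Params = DEFAULT_CASE_PARAMS,
                               n_total: int = 445, n_starts: int = 1):
    """Refit the incidence model to panels simulated under the reference truth.

    Returns ``(per_replicate_frame, summary)`` where the summary holds the
    across-replicate mean of the exponentiated conditional and zero-inflation
    coefficients and the median estimated AR(1) correlation (median for
    robustness near the parameter boundary).
    """
    seeds = np.random.SeedSequence(seed).spawn(n_replicates)
    recs = []
    for rep, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        panel = simulate_ehr_panel(rng, n_total=n_total, truth=truth)
        fit = fit_relationship1(panel, variant="full", se=False,
                                n_starts=n_starts, seed=rep)
        p = fit.params
        recs.append({
            "replicate": rep,
            "intercept_irr": math.exp(p.beta[0]),
            "adult_irr": math.exp(p.beta[1]),
            "male_irr": math.exp(p.beta[2]),
            "npat_irr": math.exp(p.beta[3]),
            "zi_odds": math.exp(p.beta_zi[0]),
            "zi_or": math.exp(p.beta_zi[1]),
            "theta_rec": math.exp(p.beta_disp[0]),
            "theta_reg_factor": math.exp(p.beta_disp[1]),
            "sigma_ar": p.sigma_ar,
            "phi": p.phi,
            "converged": fit.converged,
            "n_obs": fit.n_obs,
        })
    frame = pd.DataFrame(recs)
    summary = {
        "male_irr_mean": float(frame["male_irr"].mean()),
        "adult_irr_mean": float(frame["adult_irr"].mean()),
        "zi_odds_mean": float(frame["zi_odds"].mean()),
        "zi_or_mean": float(frame["zi_or"].mean()),
        "phi_median": float(frame["phi"].median()),
        "n_replicates": n_replicates,
        "n_obs": int(frame["n_obs"].iloc[0]),
    }
    return frame, summary


def run_gaussian_recovery(relationship: int = 2, n_replicates: int = 50,
                          seed: int = 0, n: int = 147):
    """Refit a Gaussian ratio model to matched panels simulated under truth.

    Summarises mean estimated coefficients (and, for relationship 2, the
    constant-variance estimate ``exp(logvar intercept)``).
    """
    seeds = np.random.SeedSequence(seed + relationship).spawn(n_replicates)
    recs = []
    for rep, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        df = simulate_matched_panel(rng, n=n, relationship=relationship)
        if relationship == 2:
            fit = fit_gaussian_ratio(df, REL2_MEAN_COVARIATES, (), se=False)
        else:
            fit = fit_gaussian_ratio(df, REL3_MEAN_COVARIATES,
                                     REL3_VARIANCE_COVARIATES, se=False)
        rec = {"replicate": rep}
        for name, val in zip(fit.param_names, fit.theta):
            rec[name] = float(val)
        rec["constant_variance"] = (
            float(math.exp(fit.params.logvar_coefs[0]))
            if fit.params.logvar_coefs.size == 1 else float("nan"))
        recs.append(rec)
    frame = pd.DataFrame(recs)
    summary = {c: float(frame[c].mean()) for c in frame.columns if c != "replicate"}
    summary["n_replicates"] = n_replicates
    summary["n_obs"] = n
    return frame, summary


def run_ratio_coverage(n_replicates: int = 400, n: int = 147, n_boot: int = 500,
                       seed: int = 0, level: float = 0.95):
    """Empirical coverage of parametric-bootstrap intervals for the ratio.

    Simulates matched panels from the relationship-2 truth, fits, builds the
    bootstrap interval for the expected ratio at a fixed covariate row, and
    counts how often the generating value is covered.
    """
    from .simulate import DEFAULT_RATIO_PARAMS

    target_row = pd.DataFrame({
        "pct_adult_occ": [80.0], "pct_male_occ": [60.0],
        "centre_type": ["REC"], "n_occ": [200.0],
    })
    x = np.array([1.0, 8.0, 6.0, 0.0, 20.0])
    true_ratio = float(x @ DEFAULT_RATIO_PARAMS.mean_coefs)

    seeds = np.random.SeedSequence(seed).spawn(n_replicates)
    hits = 0
    for rep, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        df = simulate_matched_panel(rng, n=n, relationship=2)
        fit = fit_gaussian_ratio(df, REL2_MEAN_COVARIATES, (), se=True)
        iv = bootstrap_intervals(fit, target_row, n_boot=n_boot, seed=rep, level=level)
        if iv["lower95"].iloc[0] <= true_ratio <= iv["upper95"].iloc[0]:
            hits += 1
    return {
        "coverage": hits / n_replicates,
        "true_ratio": true_ratio,
        "n_replicates": n_replicates,
        "n_obs": n,
    }
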
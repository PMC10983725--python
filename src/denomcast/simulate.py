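"""Synthetic centre-month surveillance panels with known ground truth.

The generator emulates a multi-centre refugee-accommodation surveillance
panel: ~21 centres of two types (REG registration / REC reception centres),
each enrolled for a window of 2-45 months, with a monthly occupancy census
(residents by sex x adult/child), a monthly EHR export (patients by sex and
age group plus incident digestive-disease cases, small counts censored to 0
for anonymisation), and fragmentation into matched, EHR-only and
occupancy-only centre-months.

Default marginals and generating coefficients are the study conditions of the
German surveillance panel the package models: mean monthly occupancy 348
(sd 287), patient/occupancy ratio averaging ~0.54-0.6, digestive-disease
incidence ~9% of patients, counts below 3 exported as 0.  The ratio and case
models used as generating truth are the reference coefficient sets in
``DEFAULT_RATIO_PARAMS`` / ``DEFAULT_CASE_PARAMS``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .months import index_to_month
from .panel import OCC_STRATA, compute_totals
from .params import GaussianDispParams, ZinbAr1Params

__all__ = [
    "ConfigError",
    "GeneratorConfig",
    "GroundTruth",
    "StudyData",
    "DEFAULT_RATIO_PARAMS",
    "DEFAULT_CASE_PARAMS",
    "generate_centres",
    "generate_occupancy",
    "generate_patients",
    "generate_cases",
    "simulate_latent_ar1",
    "apply_censoring",
    "generate_study",
    "write_study",
]

# Reference generating truth: coefficient sets of the fitted surveillance
# models that the synthetic conditions reproduce.  Ratio model (mean part,
# order: intercept, adult%/10, male%/10, REG, n_occ/10; constant variance
# 0.0206) and incidence model (log-link conditional part: intercept,
# adult%/10, male%/10, n_pat/10; logit zero-inflation: intercept, n_pat/10;
# log-link NB2 dispersion: intercept, REG; latent AR(1) sd 0.3, lag-1
# correlation 0.92).
DEFAULT_RATIO_PARAMS = GaussianDispParams(
    mean_coefs=[-0.01, 0.08, -0.01, 0.32, 0.00],
    logvar_coefs=[math.log(0.0206)],
)
DEFAULT_CASE_PARAMS = ZinbAr1Params(
    beta=[math.log(3.55), math.log(1.03), math.log(1.12), math.log(1.03)],
    beta_zi=[math.log(0.44), math.log(0.93)],
    beta_disp=[math.log(3.11), math.log(7.05)],
    sigma_ar=0.3,
    phi=0.92,
)


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the field."""


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic panel (defaults: see module docstring)."""

    n_centres: int = 21
    reg_fraction: float = 5.0 / 21.0
    months_range: tuple = (2, 45)
    horizon_months: int = 45
    occupancy_mean: float = 348.0
    occupancy_sd: float = 287.0
    within_centre_sd: float = 0.15  # multiplicative month-to-month sd (log scale)
    male_pct_mean: float = 66.0
    male_pct_sd: float = 14.0
    adult_pct_mean: float = 77.0
    adult_pct_sd: float = 10.0
    patient_pct_jitter: float = 5.0  # patient demographics = occupancy +/- jitter
    ratio_params: GaussianDispParams = field(
        default_factory=lambda: replace(DEFAULT_RATIO_PARAMS))
    case_params: ZinbAr1Params = field(
        default_factory=lambda: replace(DEFAULT_CASE_PARAMS))
    high_turnover_rate: float = 0.05  # fraction of rows with ratio drawn > 1
    censor_threshold: int = 3
    censor_scope: str = "cases"  # "cases" or "all" exported EHR cells
    matched_fraction: float = 147.0 / 457.0
    ehr_only_fraction: float = 270.0 / 457.0
    occ_only_fraction: float = 40.0 / 457.0
    duplicate_report_rate: float = 33.0 / 215.0
    target_total_months: int | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_centres < 0:
            raise ConfigError("n_centres must be non-negative")
        if not 0.0 <= self.reg_fraction <= 1.0:
            raise ConfigError("reg_fraction must lie in [0, 1]")
        lo, hi = self.months_range
        if lo < 1 or hi < lo:
            raise ConfigError("months_range must satisfy 1 <= min <= max")
        if self.occupancy_mean <= 0:
            raise ConfigError("occupancy_mean must be positive")
        if self.occupancy_sd < 0:
            raise ConfigError("occupancy_sd must be non-negative")
        fr = self.matched_fraction + self.ehr_only_fraction + self.occ_only_fraction
        if abs(fr - 1.0) > 1e-9:
            raise ConfigError(
                "matched_fraction + ehr_only_fraction + occ_only_fraction must sum to 1")
        if not 0.0 <= self.duplicate_report_rate <= 1.0:
            raise ConfigError("duplicate_report_rate must lie in [0, 1]")
        if self.censor_threshold < 0:
            raise ConfigError("censor_threshold must be non-negative")
        if self.censor_scope not in {"cases", "all"}:
            raise ConfigError("censor_scope must be 'cases' or 'all'")


@dataclass
class GroundTruth:
    """Uncensored panel with latent values and the generating parameter sets."""

    panel: pd.DataFrame  # full uncensored centre-month table incl. latent, r_true
    ratio_params: GaussianDispParams
    case_params: ZinbAr1Params

    def to_json(self, path) -> None:
        payload = {
            "ratio_params": self.ratio_params.to_dict(),
            "case_params": self.case_params.to_dict(),
            "panel": self.panel.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


@dataclass
class StudyData:
    """The two observable streams plus ground truth for one synthetic study."""

    ehr: pd.DataFrame
    occupancy: pd.DataFrame
    truth: GroundTruth


def _rescale_windows(lengths: np.ndarray, target: int, lo: int, hi: int) -> np.ndarray:
    """Rescale window lengths to a fixed total (largest remainder, clipped)."""
    raw = lengths * (target / lengths.sum())
    out = np.clip(np.floor(raw).astype(int), lo, hi)
    rem = raw - np.floor(raw)
    deficit = target - out.sum()
    order = np.argsort(-rem, kind="stable")
    i = 0
    while deficit != 0 and i < 10 * len(out):
        j = order[i % len(out)]
        step = 1 if deficit > 0 else -1
        cand = out[j] + step
        if lo <= cand <= hi:
            out[j] = cand
            deficit -= step
        i += 1
    return out


def generate_centres(config: GeneratorConfig, rng=None) -> pd.DataFrame:
    """Draw centres with typology and enrolment windows.

    Returns one row per centre: ``centre_id``, ``centre_type`` (REG with
    probability ``reg_fraction``), ``start_month`` and ``n_months`` (window
    length uniform over ``months_range``, placed inside the study horizon).
    """
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_centres
    if n == 0:
        return pd.DataFrame(columns=["centre_id", "centre_type", "start_month", "n_months"])
    types = np.where(rng.random(n) < config.reg_fraction, "REG", "REC")
    lo, hi = config.months_range
    lengths = rng.integers(lo, hi + 1, size=n)
    if config.target_total_months is not None:
        lengths = _rescale_windows(lengths.astype(float), config.target_total_months, lo, hi)
    horizon = max(config.horizon_months, hi)
    starts = np.array([rng.integers(0, horizon - L + 1) for L in lengths])
    return pd.DataFrame({
        "centre_id": [f"C{i + 1:02d}" for i in range(n)],
        "centre_type": types,
        "start_month": starts,
        "n_months": lengths,
    })


def generate_occupancy(centres: pd.DataFrame, config: GeneratorConfig, rng=None) -> pd.DataFrame:
    """Simulate the occupancy census for every enrolled centre-month.

    Centre size is lognormal across centres with month-to-month multiplicative
    jitter, calibrated so the marginal mean/sd of the total approach the
    configured values; the four sex x age strata are split from drawn adult
    and male percentages, so strata always add to the total.
    """
    if centres.empty:
        raise ValueError("generate_occupancy requires a non-empty centre table")
    config.validate()
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng

    mean, sd = config.occupancy_mean, config.occupancy_sd
    w = config.within_centre_sd if sd > 0 else 0.0
    m_level = mean / math.exp(w**2 / 2.0)
    if sd > 0:
        second_moment_level = (sd**2 + mean**2) / math.exp(2.0 * w**2)
        s2 = math.log(max(second_moment_level / m_level**2, 1.0 + 1e-12))
        mu_log = math.log(m_level) - s2 / 2.0
        s_log = math.sqrt(s2)
    else:
        mu_log, s_log = math.log(m_level), 0.0

    rows = []
    for _, c in centres.iterrows():
        level = math.exp(mu_log + s_log * rng.standard_normal())
        for t in range(int(c.n_months)):
            month = int(c.start_month) + t
            eps = w * rng.standard_normal() if w > 0 else 0.0
            total = max(1, int(round(level * math.exp(eps))))
            adult_pct = float(np.clip(rng.normal(config.adult_pct_mean, config.adult_pct_sd), 30.0, 100.0))
            male_pct = float(np.clip(rng.normal(config.male_pct_mean, config.male_pct_sd), 5.0, 100.0))
            n_adult = int(round(total * adult_pct / 100.0))
            n_child = total - n_adult
            n_ma = int(round(n_adult * male_pct / 100.0))
            n_mc = int(round(n_child * male_pct / 100.0))
            rows.append({
                "centre_id": c.centre_id,
                "centre_type": c.centre_type,
                "month_index": month,
                "year_month": index_to_month(month),
                "n_male_adult": n_ma,
                "n_female_adult": n_adult - n_ma,
                "n_male_child": n_mc,
                "n_female_child": n_child - n_mc,
            })
    return compute_totals(pd.DataFrame(rows))


def generate_patients(occ: pd.DataFrame, ratio_params: GaussianDispParams,
                      config: GeneratorConfig, rng=None) -> pd.DataFrame:
    """Invert the ratio model to simulate patient counts from occupancy.

    The patient/occupancy ratio is drawn from the Gaussian mean/variance model
    given occupancy covariates, truncated to (0, 1]; a configurable
    ``high_turnover_rate`` share of rows instead receives a ratio above 1
    (census undercount in high-turnover months) to exercise the exclusion
    rule.  Patient demographics follow occupancy demographics with bounded
    jitter.
    """
    if occ.empty:
        raise ValueError("generate_patients requires occupancy rows")
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    from .fit import REL2_MEAN_COVARIATES, build_design

    covs = REL2_MEAN_COVARIATES[: ratio_params.mean_coefs.size - 1]
    X = build_design(occ, covs)
    Zv = build_design(occ, ())
    mean_r = X @ ratio_params.mean_coefs
    sd_r = np.sqrt(np.exp(Zv @ ratio_params.logvar_coefs[:1]))
    r = mean_r + sd_r * rng.standard_normal(len(occ))
    r = np.clip(r, 0.02, 1.0)
    hi_turn = rng.random(len(occ)) < config.high_turnover_rate
    r = np.where(hi_turn, rng.uniform(1.02, 1.5, len(occ)), r)

    out = occ.copy()
    out["r_true"] = r
    n_occ = out["n_occ"].to_numpy(dtype=float)
    n_pat = np.maximum(1, np.round(r * n_occ)).astype(int)
    out["n_pat"] = n_pat
    jit = config.patient_pct_jitter
    pm = np.clip(out["pct_male_occ"].to_numpy() + rng.uniform(-jit, jit, len(out)), 0, 100)
    pa = np.clip(out["pct_adult_occ"].to_numpy() + rng.uniform(-jit, jit, len(out)), 0, 100)
    out["n_male"] = np.round(n_pat * pm / 100.0).astype(int)
    out["n_female"] = n_pat - out["n_male"]
    out["n_adult"] = np.round(n_pat * pa / 100.0).astype(int)
    out["n_minor"] = n_pat - out["n_adult"]
    out["pct_male_pat"] = 100.0 * out["n_male"] / n_pat
    out["pct_adult_pat"] = 100.0 * out["n_adult"] / n_pat
    return out


def simulate_latent_ar1(months: np.ndarray, sigma: float, phi: float, rng) -> np.ndarray:
    """Stationary Gaussian AR(1) sampled at (possibly gapped) integer months."""
    months = np.asarray(months, dtype=int)
    n = months.size
    u = np.empty(n)
    if n == 0:
        return u
    u[0] = sigma * rng.standard_normal()
    for i in range(1, n):
        gap = months[i] - months[i - 1]
        rho = phi**gap
        innov_sd = sigma * math.sqrt(max(1.0 - rho**2, 0.0))
        u[i] = rho * u[i - 1] + innov_sd * rng.standard_normal()
    return u


def generate_cases(patients: pd.DataFrame, case_params: ZinbAr1Params,
                   config: GeneratorConfig, rng=None) -> pd.DataFrame:
    """Simulate uncensored digestive-disease case counts from the incidence model.

    Per centre a stationary latent AR(1) series enters the log-mean; counts
    are NB2 (gamma-Poisson mixture) with centre-type-dependent dispersion,
    replaced by structural zeros with the zero-inflation probability.
    """
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    work = patients.sort_values(["centre_id", "month_index"]).reset_index(drop=True)
    from .fit import build_design

    X = build_design(work, ("adult_pat10", "male_pat10", "npat10"))
    eta = X @ case_params.beta
    if case_params.beta_zi.size:
        Z = build_design(work, ("npat10",))
        p_zi = expit(Z @ case_params.beta_zi)
    else:
        p_zi = np.zeros(len(work))
    D = build_design(work, ("reg",))
    theta = np.exp(D @ case_params.beta_disp)

    latent = np.zeros(len(work))
    for _, sub in work.groupby("centre_id", sort=True):
        idx = sub.index.to_numpy()
        latent[idx] = simulate_latent_ar1(
            sub["month_index"].to_numpy(), case_params.sigma_ar, case_params.phi, rng)

    mu = np.exp(np.minimum(eta + latent, 30.0))
    lam = rng.gamma(shape=theta, scale=mu / theta)
    counts = rng.poisson(lam)
    structural = rng.random(len(work)) < p_zi
    counts = np.where(structural, 0, counts)

    out = work.copy()
    out["latent_ar1"] = latent
    out["structural_zero"] = structural
    out["n_cases_true"] = counts.astype(int)
    return out


def apply_censoring(counts, threshold: int = 3):
    """Anonymisation rule: integer counts below ``threshold`` become 0."""
    arr = np.asarray(counts)
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    return np.where(arr < threshold, 0, arr)


def generate_study(config: GeneratorConfig) -> StudyData:
    """End-to-end synthetic study: occupancy -> patients -> cases -> censoring
    -> fragmentation into matched / EHR-only / occupancy-only streams.

    Duplicate occupancy reports are injected at ``duplicate_report_rate``.
    Returns the two observable streams and the uncensored ground truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    centres = generate_centres(config, rng)
    occ = generate_occupancy(centres, config, rng)
    pat = generate_patients(occ, config.ratio_params, config, rng)
    full = generate_cases(pat, config.case_params, config, rng)

    # fragmentation of each centre-month into the three observation patterns
    assign = rng.choice(
        np.array(["matched", "ehr_only", "occ_only"]),
        size=len(full),
        p=[config.matched_fraction, config.ehr_only_fraction, config.occ_only_fraction],
    )
    full = full.copy()
    full["subset"] = assign
    full["n_cases"] = apply_censoring(full["n_cases_true"], config.censor_threshold)

    ehr_rows = full[full["subset"].isin(["matched", "ehr_only"])]
    ehr = pd.DataFrame({
        "centre_id": ehr_rows["centre_id"],
        "year_month": ehr_rows["year_month"],
        "type": ehr_rows["centre_type"],
        "n_pat": ehr_rows["n_pat"],
        "n_male": ehr_rows["n_male"],
        "n_female": ehr_rows["n_female"],
        "n_adult": ehr_rows["n_adult"],
        "n_minor": ehr_rows["n_minor"],
        "n_cases_digestive": ehr_rows["n_cases"],
    })
    if config.censor_scope == "all":
        for col in ["n_male", "n_female", "n_adult", "n_minor"]:
            ehr[col] = apply_censoring(ehr[col], config.censor_threshold)

    occ_rows = full[full["subset"].isin(["matched", "occ_only"])]
    occ_out = pd.DataFrame({
        "centre_id": occ_rows["centre_id"],
        "year_month": occ_rows["year_month"],
        "type": occ_rows["centre_type"],
        "report_id": 1,
        "n_male_adult": occ_rows["n_male_adult"],
        "n_female_adult": occ_rows["n_female_adult"],
        "n_male_child": occ_rows["n_male_child"],
        "n_female_child": occ_rows["n_female_child"],
    })
    dup_mask = rng.random(len(occ_out)) < config.duplicate_report_rate
    dups = occ_out[dup_mask].copy()
    if len(dups):
        dups["report_id"] = 2
        for col in OCC_STRATA:
            noise = rng.lognormal(0.0, 0.05, size=len(dups))
            dups[col] = np.maximum(0, np.round(dups[col] * noise)).astype(int)
        occ_out = pd.concat([occ_out, dups], ignore_index=True)
    occ_out = occ_out.sort_values(["centre_id", "year_month", "report_id"]).reset_index(drop=True)

    truth = GroundTruth(panel=full, ratio_params=config.ratio_params,
                        case_params=config.case_params)
    return StudyData(ehr=ehr.reset_index(drop=True), occupancy=occ_out, truth=truth)


def write_study(study: StudyData, outdir) -> dict:
    """Write ``ehr.csv``, ``occupancy.csv`` and ``truth.json``; return paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "ehr": outdir / "ehr.csv",
        "occupancy": outdir / "occupancy.csv",
        "truth": outdir / "truth.json",
    }
    study.ehr.to_csv(paths["ehr"], index=False)
    study.occupancy.to_csv(paths["occupancy"], index=False)
    study.truth.to_json(paths["truth"])
    return {k: str(v) for k, v in paths.items()}
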
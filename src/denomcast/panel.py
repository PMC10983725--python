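"""Reading, deduplicating, matching and summarising centre-month panels.

Two delimited streams exist at centre x calendar-month granularity: an EHR
monitoring export (patient counts by sex / age group plus incident
digestive-disease cases, with counts below the anonymisation threshold
exported as 0) and an occupancy census (residents by sex x adult/child,
possibly with duplicate reports for a month).  This module derives totals and
percentage covariates, averages duplicate occupancy reports, inner-joins the
streams into the matched dataset, applies the analysis exclusion rules, and
produces Table-style descriptive summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .months import month_to_index

__all__ = [
    "CentreInfo",
    "PanelSplit",
    "ReadError",
    "read_ehr",
    "read_occupancy",
    "aggregate_duplicates",
    "compute_totals",
    "match",
    "apply_exclusions",
    "describe",
]

EHR_COLUMNS = [
    "centre_id", "year_month", "type", "n_pat", "n_male", "n_female",
    "n_adult", "n_minor", "n_cases_digestive",
]
OCC_COLUMNS = [
    "centre_id", "year_month", "report_id",
    "n_male_adult", "n_female_adult", "n_male_child", "n_female_child",
]
OCC_STRATA = ["n_male_adult", "n_female_adult", "n_male_child", "n_female_child"]

CENTRE_TYPES = ("REC", "REG")


class ReadError(ValueError):
    """Raised when an input CSV is malformed; message carries the location."""


@dataclass(frozen=True)
class CentreInfo:
    """A centre identifier with its typology (REG: registration, REC: reception)."""

    centre_id: str
    centre_type: str

    def __post_init__(self):
        if self.centre_type not in CENTRE_TYPES:
            raise ValueError(f"centre_type must be one of {CENTRE_TYPES}")


@dataclass
class PanelSplit:
    """The five derived analysis datasets plus the exclusion audit log."""

    matched: pd.DataFrame
    ehr_unmatched: pd.DataFrame
    occ_unmatched: pd.DataFrame
    ehr_all: pd.DataFrame
    occ_all: pd.DataFrame
    exclusion_log: list = field(default_factory=list)

    def counts(self) -> dict:
        return {
            "matched": len(self.matched),
            "ehr_unmatched": len(self.ehr_unmatched),
            "occ_unmatched": len(self.occ_unmatched),
            "ehr_all": len(self.ehr_all),
            "occ_all": len(self.occ_all),
            "excluded": len(self.exclusion_log),
        }


def _check_counts(df: pd.DataFrame, cols, path) -> None:
    for col in cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()]
        if len(bad):
            raise ReadError(f"{path}: non-numeric {col!r} in data row(s) {list(bad + 2)}")
        neg = df.index[vals < 0]
        if len(neg):
            raise ReadError(f"{path}: negative {col!r} in data row(s) {list(neg + 2)}")
        nonint = df.index[vals != np.floor(vals)]
        if len(nonint):
            raise ReadError(f"{path}: non-integer {col!r} in data row(s) {list(nonint + 2)}")
        df[col] = vals.astype(int)


def read_ehr(path) -> pd.DataFrame:
    """Read the EHR monitoring export into typed centre-month records.

    Adds the integer ``month_index`` and the percentage covariates
    ``pct_male_pat`` / ``pct_adult_pat`` (undefined rows flagged, not dropped).
    """
    df = pd.read_csv(path, dtype={"centre_id": str, "year_month": str, "type": str})
    missing = [c for c in EHR_COLUMNS if c not in df.columns]
    if missing:
        raise ReadError(f"{path}: missing required column(s) {missing}")
    count_cols = ["n_pat", "n_male", "n_female", "n_adult", "n_minor", "n_cases_digestive"]
    _check_counts(df, count_cols, path)
    bad_type = df.index[~df["type"].isin(CENTRE_TYPES)]
    if len(bad_type):
        raise ReadError(f"{path}: unknown centre type in data row(s) {list(bad_type + 2)}")
    try:
        df["month_index"] = df["year_month"].map(month_to_index)
    except ValueError as exc:
        raise ReadError(f"{path}: {exc}") from exc
    df = df.rename(columns={"type": "centre_type", "n_cases_digestive": "n_cases"})
    npat = df["n_pat"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        df["pct_male_pat"] = np.where(npat > 0, 100.0 * df["n_male"] / npat, np.nan)
        df["pct_adult_pat"] = np.where(npat > 0, 100.0 * df["n_adult"] / npat, np.nan)
    df["pct_pat_flag"] = npat <= 0
    return df


def read_occupancy(path) -> pd.DataFrame:
    """Read the occupancy census (one row per report; duplicates allowed)."""
    df = pd.read_csv(path, dtype={"centre_id": str, "year_month": str})
    required = [c for c in OCC_COLUMNS if c != "report_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ReadError(f"{path}: missing required column(s) {missing}")
    if "report_id" not in df.columns:
        df["report_id"] = 1
    _check_counts(df, OCC_STRATA, path)
    try:
        df["month_index"] = df["year_month"].map(month_to_index)
    except ValueError as exc:
        raise ReadError(f"{path}: {exc}") from exc
    if "type" in df.columns:
        df = df.rename(columns={"type": "centre_type"})
    return df


def aggregate_duplicates(occ: pd.DataFrame) -> pd.DataFrame:
    """Average duplicate occupancy reports per centre-month, per stratum.

    Means are rounded half away from zero to a natural number, and totals are
    recomputed from the rounded strata.  Idempotent on deduplicated input.
    """
    keep_first = {c: "first" for c in occ.columns
                  if c not in OCC_STRATA + ["centre_id", "year_month", "report_id"]}
    agg = {**{c: "mean" for c in OCC_STRATA}, **keep_first}
    out = occ.groupby(["centre_id", "year_month"], as_index=False, sort=True).agg(agg)
    for c in OCC_STRATA:
        out[c] = np.floor(out[c] + 0.5).astype(int)  # half away from zero (counts >= 0)
    out["report_id"] = 1
    out = compute_totals(out)
    # stable column order (input columns first) so the operation is idempotent
    ordered = [c for c in occ.columns if c in out.columns]
    ordered += [c for c in out.columns if c not in ordered]
    return out[ordered]


def compute_totals(occ: pd.DataFrame) -> pd.DataFrame:
    """Derive adult/child/total occupancy and percentage covariates from strata."""
    missing = [c for c in OCC_STRATA if c not in occ.columns]
    if missing:
        raise ValueError(f"occupancy records lack stratum column(s) {missing}")
    out = occ.copy()
    out["n_occ_adult"] = out["n_male_adult"] + out["n_female_adult"]
    out["n_occ_child"] = out["n_male_child"] + out["n_female_child"]
    out["n_occ"] = out["n_occ_adult"] + out["n_occ_child"]
    n_male = out["n_male_adult"] + out["n_male_child"]
    tot = out["n_occ"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["pct_adult_occ"] = np.where(tot > 0, 100.0 * out["n_occ_adult"] / tot, np.nan)
        out["pct_male_occ"] = np.where(tot > 0, 100.0 * n_male / tot, np.nan)
    out["pct_occ_flag"] = tot <= 0
    return out


def match(ehr: pd.DataFrame, occ: pd.DataFrame) -> PanelSplit:
    """Inner-join the two streams on centre x month into the matched dataset.

    Occupancy duplicates must already be aggregated.  The ratio
    ``r = n_pat / n_occ`` is computed on matched rows.  Conflicting centre
    typology across streams for the same centre raises.
    """
    dup = occ.duplicated(subset=["centre_id", "year_month"])
    if dup.any():
        raise ValueError("occupancy stream has duplicate centre-months; "
                         "run aggregate_duplicates first")
    if "n_occ" not in occ.columns:
        occ = compute_totals(occ)
    occ_typed = occ  # keep typology for occupancy-only rows (prediction needs it)
    if "centre_type" in occ.columns:
        types = pd.concat([
            ehr[["centre_id", "centre_type"]], occ[["centre_id", "centre_type"]]
        ]).drop_duplicates()
        conflict = types["centre_id"][types["centre_id"].duplicated()]
        if len(conflict):
            raise ValueError(
                f"conflicting centre_type across streams for centre(s) {sorted(set(conflict))}")
        occ = occ.drop(columns=["centre_type"])
    occ = occ.drop(columns=[c for c in ("month_index",) if c in occ.columns])

    merged = ehr.merge(occ, on=["centre_id", "year_month"], how="outer",
                       indicator=True, sort=True)
    matched = merged[merged["_merge"] == "both"].drop(columns="_merge").copy()
    ehr_unm = merged[merged["_merge"] == "left_only"]
    occ_unm_keys = merged[merged["_merge"] == "right_only"][["centre_id", "year_month"]]

    ehr_unmatched = ehr.merge(ehr_unm[["centre_id", "year_month"]],
                              on=["centre_id", "year_month"]).copy()
    occ_unmatched = occ_typed.merge(occ_unm_keys,
                                    on=["centre_id", "year_month"]).copy()

    nocc = matched["n_occ"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        matched["r"] = np.where(nocc > 0, matched["n_pat"] / nocc, np.nan)
    return PanelSplit(
        matched=matched.reset_index(drop=True),
        ehr_unmatched=ehr_unmatched.reset_index(drop=True),
        occ_unmatched=occ_unmatched.reset_index(drop=True),
        ehr_all=ehr.reset_index(drop=True),
        occ_all=occ.reset_index(drop=True),
    )


def apply_exclusions(matched: pd.DataFrame, mode: str = "main"):
    """Apply the analysis exclusion rules to the matched dataset.

    ``main``    drop rows where occupancy is below the patient count (high
                turnover makes the census denominator implausible);
    ``full``    keep everything (sensitivity variant);
    ``nonzero`` main rule plus dropping rows with zero recorded cases (the
                zero-exclusion sensitivity, where structural zeros are read
                as non-reporting).

    Returns ``(filtered, log)`` where ``log`` lists ``(key, reason)`` for
    every dropped row; nothing is silently deleted.
    """
    if mode not in {"main", "full", "nonzero"}:
        raise ValueError(f"unknown exclusion mode {mode!r}")
    log: list[tuple[str, str]] = []
    keep = np.ones(len(matched), dtype=bool)
    if mode in {"main", "nonzero"}:
        occ_lt_pat = matched["n_occ"].to_numpy() < matched["n_pat"].to_numpy()
        for _, row in matched[occ_lt_pat].iterrows():
            log.append((f"{row['centre_id']}:{row['year_month']}", "occ<pat"))
        keep &= ~occ_lt_pat
    if mode == "nonzero":
        zero = matched["n_cases"].to_numpy() == 0
        for _, row in matched[keep & zero].iterrows():
            log.append((f"{row['centre_id']}:{row['year_month']}", "zero_cases"))
        keep &= ~zero
    return matched[keep].reset_index(drop=True), log


_DESCRIBE_VARS = [
    "n_pat", "n_occ", "n_cases", "pct_male_pat", "pct_adult_pat",
    "pct_male_occ", "pct_adult_occ", "r", "incidence_pat", "incidence_occ",
]


def describe(df: pd.DataFrame, variables=None) -> pd.DataFrame:
    """Descriptive summary in the surveillance-report layout.

    Per numeric variable: N, N missing, mean, sd, median, Q1, Q3, min, max
    (quartiles by linear interpolation between order statistics); per
    categorical variable: level counts and percentages.
    """
    if df.empty:
        import warnings

        warnings.warn("describe called on an empty dataset", stacklevel=2)
        return pd.DataFrame()
    work = df.copy()
    if "n_cases" in work.columns and "n_pat" in work.columns:
        npat = work["n_pat"].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            work["incidence_pat"] = np.where(npat > 0, work["n_cases"] / npat, np.nan)
    if "n_cases" in work.columns and "n_occ" in work.columns:
        nocc = work["n_occ"].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            work["incidence_occ"] = np.where(nocc > 0, work["n_cases"] / nocc, np.nan)

    if variables is None:
        variables = [v for v in _DESCRIBE_VARS if v in work.columns]
    rows = []
    for v in variables:
        x = pd.to_numeric(work[v], errors="coerce")
        obs = x.dropna()
        rows.append({
            "variable": v,
            "N": int(obs.size),
            "N_miss": int(x.isna().sum()),
            "mean": obs.mean() if obs.size else np.nan,
            "sd": obs.std(ddof=1) if obs.size > 1 else (0.0 if obs.size else np.nan),
            "median": obs.median() if obs.size else np.nan,
            "q1": obs.quantile(0.25) if obs.size else np.nan,
            "q3": obs.quantile(0.75) if obs.size else np.nan,
            "min": obs.min() if obs.size else np.nan,
            "max": obs.max() if obs.size else np.nan,
        })
    for cat in ("centre_type", "centre_id"):
        if cat in work.columns:
            counts = work[cat].value_counts()
            for level, n in counts.items():
                rows.append({"variable": f"{cat}={level}", "N": int(n),
                             "N_miss": 0, "mean": 100.0 * n / len(work)})
    return pd.DataFrame(rows)


def write_split(split: PanelSplit, outdir) -> None:
    """Write the derived datasets and the exclusion log under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    split.matched.to_csv(outdir / "matched.csv", index=False)
    split.ehr_unmatched.to_csv(outdir / "ehr_unmatched.csv", index=False)
    split.occ_unmatched.to_csv(outdir / "occ_unmatched.csv", index=False)
    with open(outdir / "exclusions.log", "w") as fh:
        for key, reason in split.exclusion_log:
            fh.write(f"{key}\t{reason}\n")
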
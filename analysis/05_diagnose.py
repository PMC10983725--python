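"""Residual diagnostics for the three fitted models.

Randomized-quantile residuals from model simulations: KS test against
uniformity, dispersion ratio and envelope outliers, written to
results/diagnostics.json.
"""

import json
from pathlib import Path

import pandas as pd

from denomcast.diagnostics import quantile_residuals
from denomcast.months import month_to_index
from denomcast.params import FitResult

ROOT = Path(__file__).resolve().parent.parent / "results"


def _load(name: str) -> pd.DataFrame:
    df = pd.read_csv(ROOT / "derived" / name,
                     dtype={"centre_id": str, "year_month": str})
    if "month_index" not in df.columns:
        df["month_index"] = df["year_month"].map(month_to_index)
    return df


def main() -> None:
    from denomcast.panel import read_ehr

    matched = _load("matched.csv")
    ehr = read_ehr(ROOT / "data" / "ehr.csv")
    ehr = ehr[ehr["n_pat"] > 0]

    out = {}
    for name, data in [("fit1", ehr), ("fit2", matched), ("fit3", matched)]:
        fit = FitResult.from_json(ROOT / f"{name}.json")
        diag = quantile_residuals(fit, data, n_sim=250, seed=21)
        out[name] = diag.summary()
        print(f"{name}: KS p={diag.ks_pvalue:.3f} "
              f"dispersion={diag.dispersion_ratio:.2f} "
              f"outliers={diag.n_outliers}/{diag.n_obs}")
    (ROOT / "diagnostics.json").write_text(json.dumps(out, indent=1))


if __name__ == "__main__":
    main()
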
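"""Run the three prediction chains on the unmatched datasets.

Patients from occupancy (relationship 2), occupancy from patients
(relationship 3), and disease incidence with respect to occupancy
(relationship 2 then 1), each with parametric-bootstrap 95% intervals.
Writes predictions under results/ and prints the headline incidence
contrast: per-patient versus per-resident incidence on matched rows.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from denomcast.months import month_to_index
from denomcast.params import FitResult
from denomcast.predict import (
    predict_incidence_wrt_occupancy,
    predict_occupancy,
    predict_patients,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def _load(name: str) -> pd.DataFrame:
    df = pd.read_csv(ROOT / "derived" / name,
                     dtype={"centre_id": str, "year_month": str})
    if "month_index" not in df.columns and "year_month" in df.columns:
        df["month_index"] = df["year_month"].map(month_to_index)
    return df


def main() -> None:
    fit1 = FitResult.from_json(ROOT / "fit1.json")
    fit2 = FitResult.from_json(ROOT / "fit2.json")
    fit3 = FitResult.from_json(ROOT / "fit3.json")
    occ_unm = _load("occ_unmatched.csv")
    ehr_unm = _load("ehr_unmatched.csv")
    matched = _load("matched.csv")

    pats = predict_patients(fit2, occ_unm, method="parametric_bootstrap",
                            n_boot=1000, seed=11)
    occs = predict_occupancy(fit3, ehr_unm, method="parametric_bootstrap",
                             n_boot=1000, seed=12)
    inc = predict_incidence_wrt_occupancy(fit2, fit1, occ_unm, n_boot=1000, seed=13)
    pats.to_csv(ROOT / "predictions_patients.csv", index=False)
    occs.to_csv(ROOT / "predictions_occupancy.csv", index=False)
    inc.to_csv(ROOT / "predictions_incidence.csv", index=False)

    print(f"predicted patients on {len(pats)} occupancy-only rows "
          f"(mean {pats['point'].mean():.0f})")
    print(f"predicted occupancy on {len(occs)} EHR-only rows "
          f"(mean {occs['point'].dropna().mean():.0f})")
    print(f"predicted incidence w.r.t. occupancy: mean {inc['point'].mean():.3f}")

    inc_pat = (matched["n_cases"] / matched["n_pat"]).mean()
    inc_occ = (matched["n_cases"] / matched["n_occ"]).mean()
    print(f"matched rows: incidence w.r.t. patients {inc_pat:.3f} "
          f"vs w.r.t. occupancy {inc_occ:.3f}")

    # observed (matched) vs predicted (occupancy-only) patient counts
    from denomcast.plots import plot_observed_vs_predicted

    pats_plot = pats.merge(occ_unm[["centre_id", "year_month", "month_index",
                                    "centre_type"]], on=["centre_id", "year_month"])
    plot_observed_vs_predicted(matched, pats_plot, "n_pat",
                               ROOT / "fig_patients.png",
                               title="patients: observed (matched) vs predicted "
                                     "(occupancy-only months)")
    print(f"wrote {ROOT / 'fig_patients.png'}")


if __name__ == "__main__":
    main()
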
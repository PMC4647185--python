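"""CSV interchange for cohorts: one visits table, one pregnancies table.

`visits.csv` has one row per blood-pressure measurement (id, ga, sbp, dbp,
proteinuria); `pregnancies.csv` one row per pregnancy with covariates,
delivery information and outcome flags.  Empty cells denote missing values.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import BPMeasurement, Pregnancy

_FLAG_COLS = ["smoking", "essential_htn", "prev_gest_htn", "diabetes",
              "prev_gest_diab", "nonwhite", "pe", "preterm", "sga"]


def _flag_to_cell(v):
    return "" if v is None else int(bool(v))


def cohort_to_frames(cohort):
    """Return (pregnancies, visits) DataFrames for a list of pregnancies."""
    preg_rows, visit_rows = [], []
    for p in cohort:
        row = {
            "id": p.id, "bmi": p.bmi, "height": p.height, "age": p.age,
            "parity": p.parity, "ga_delivery": p.ga_delivery,
            "birthweight": p.birthweight,
        }
        for c in _FLAG_COLS:
            row[c] = _flag_to_cell(getattr(p, c))
        preg_rows.append(row)
        for v in p.visits:
            visit_rows.append({
                "id": p.id, "ga": v.ga, "sbp": v.sbp, "dbp": v.dbp,
                "proteinuria": int(v.proteinuria_1plus),
            })
    return pd.DataFrame(preg_rows), pd.DataFrame(visit_rows)


def write_cohort(cohort, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    preg, visits = cohort_to_frames(cohort)
    preg.to_csv(out / "pregnancies.csv", index=False)
    visits.to_csv(out / "visits.csv", index=False)


def read_cohort(in_dir):
    """Read `pregnancies.csv`/`visits.csv` back into Pregnancy records."""
    in_dir = Path(in_dir)
    preg = pd.read_csv(in_dir / "pregnancies.csv", dtype={"id": str, "parity": str})
    visits = pd.read_csv(in_dir / "visits.csv", dtype={"id": str})
    by_id = {}
    for _, r in visits.iterrows():
        by_id.setdefault(r["id"], []).append(
            BPMeasurement(ga=float(r["ga"]), sbp=float(r["sbp"]),
                          dbp=float(r["dbp"]),
                          proteinuria_1plus=bool(r["proteinuria"])))
    cohort = []
    for _, r in preg.iterrows():
        def flag(c):
            v = r[c]
            if pd.isna(v) or v == "":
                return None
            return bool(int(v))
        vs = sorted(by_id.get(r["id"], []), key=lambda v: v.ga)
        cohort.append(Pregnancy(
            id=r["id"],
            bmi=float(r["bmi"]) if pd.notna(r["bmi"]) else np.nan,
            height=float(r["height"]) if pd.notna(r["height"]) else np.nan,
            age=float(r["age"]) if pd.notna(r["age"]) else np.nan,
            parity=r["parity"] if pd.notna(r["parity"]) else None,
            smoking=flag("smoking"), essential_htn=flag("essential_htn"),
            prev_gest_htn=flag("prev_gest_htn"), diabetes=flag("diabetes"),
            prev_gest_diab=flag("prev_gest_diab"), nonwhite=flag("nonwhite"),
            visits=vs,
            ga_delivery=float(r["ga_delivery"]) if pd.notna(r["ga_delivery"]) else np.nan,
            birthweight=float(r["birthweight"]) if pd.notna(r["birthweight"]) else np.nan,
            pe=flag("pe"), preterm=flag("preterm"), sga=flag("sga"),
        ))
    return cohort
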
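"""Derivation of analysis variables from raw visit/pregnancy records.

Mean arterial pressure (MAP) is the measure of blood pressure used
throughout: MAP = (SBP + 2 DBP)/3.  The initial MAP is the first antenatal
measurement provided it falls before 18 weeks' gestation; gestational-age-
specific MAP values at 20, 25, 28, 31, 34 and 36 weeks are taken from the
visit closest to the target week and within two weeks of it.  Outcome
indicators: pre-eclampsia (ISSHP: new hypertension >=140/90 together with
proteinuria >=1+ on two occasions after 20 weeks), preterm birth (delivery
before 37 weeks) and small-for-gestational-age (birthweight below the 10th
centile adjusted for gestational age at birth by internal standardisation).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

TARGET_WEEKS = (20, 25, 28, 31, 34, 36)
INITIAL_GA_LIMIT = 18.0
MAP_WINDOW = 2.0


class InvalidMeasurementError(ValueError):
    pass


def mean_arterial_pressure(sbp, dbp):
    """MAP = (SBP + 2 DBP) / 3, unrounded. Requires DBP < SBP."""
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    if np.any(dbp >= sbp):
        raise InvalidMeasurementError("diastolic must be below systolic")
    out = (sbp + 2.0 * dbp) / 3.0
    return float(out) if out.ndim == 0 else out


def initial_map(visits):
    """(MAP, ga) of the first visit if it occurred before 18 weeks, else None.

    Visits must be sorted by gestational age; a first visit at or after 18
    weeks means no valid initial measurement exists for this pregnancy.
    """
    if not visits:
        return None
    first = visits[0]
    if first.ga >= INITIAL_GA_LIMIT:
        return None
    return mean_arterial_pressure(first.sbp, first.dbp), first.ga


def map_at_gestation(visits, target):
    """MAP from the visit closest to ``target`` weeks and within 2 weeks.

    Ties in distance are broken toward the earlier visit (the measurement
    that would have been available first).  Returns None if no visit falls
    inside the window.
    """
    best = None
    best_key = None
    for v in visits:
        d = abs(v.ga - target)
        if d > MAP_WINDOW:
            continue
        key = (d, v.ga)
        if best_key is None or key < best_key:
            best, best_key = v, key
    if best is None:
        return None
    return mean_arterial_pressure(best.sbp, best.dbp)


def define_preeclampsia_isshp(visits, same_visit=True):
    """ISSHP pre-eclampsia flag from the visit series.

    True iff at least two visits strictly after 20 weeks each show new
    hypertension (SBP >= 140 and/or DBP >= 90) together with proteinuria
    >=1+.  With ``same_visit=False`` the alternative reading is used: two
    hypertensive visits and two proteinuric visits after 20 weeks, not
    necessarily coinciding.
    """
    late = [v for v in visits if v.ga > 20.0]
    htn = [v for v in late if v.sbp >= 140.0 or v.dbp >= 90.0]
    if same_visit:
        qualifying = [v for v in htn if v.proteinuria_1plus]
        return len(qualifying) >= 2
    prot = [v for v in late if v.proteinuria_1plus]
    return len(htn) >= 2 and len(prot) >= 2


def define_preterm(ga_delivery):
    """Birth before 37 completed weeks."""
    return bool(ga_delivery < 37.0)


def define_sga(ga_delivery, birthweight, centile=0.10, return_resid=False):
    """Small-for-gestational-age by internal standardisation.

    Birthweight is regressed on a cubic polynomial of gestational age at
    delivery within the cohort; pregnancies whose residual falls below the
    empirical ``centile`` quantile of residuals are flagged.  Location
    shifts of birthweight leave the flags unchanged.
    """
    ga = np.asarray(ga_delivery, dtype=float)
    bw = np.asarray(birthweight, dtype=float)
    if ga.size < 50:
        raise ValueError("internal standardisation needs at least 50 births")
    gac = ga - ga.mean()
    X = np.column_stack([np.ones(ga.size), gac, gac ** 2, gac ** 3])
    beta, *_ = np.linalg.lstsq(X, bw, rcond=None)
    resid = bw - X @ beta
    cut = np.quantile(resid, centile)
    flags = resid < cut
    if return_resid:
        return flags, resid
    return flags


def derive_table(cohort, pe_from_visits=False, sga_centile=0.10) -> pd.DataFrame:
    """One row per pregnancy: covariates, MAP variables and outcomes.

    ``pe_from_visits`` re-derives the pre-eclampsia flag from the BP /
    proteinuria series via the ISSHP criteria; by default a recorded
    diagnosis on the pregnancy record is used when present (as with a
    validation cohort relying on clinical records), falling back to the
    visit-based derivation.
    """
    rows = []
    for p in cohort:
        im = initial_map(p.visits)
        if p.pe is None or pe_from_visits:
            pe = define_preeclampsia_isshp(p.visits)
        else:
            pe = bool(p.pe)
        row = {
            "id": p.id, "bmi": p.bmi, "height": p.height, "age": p.age,
            "age_ge35": float(p.age >= 35) if np.isfinite(p.age) else np.nan,
            "parity": p.parity,
            "smoking": _f(p.smoking), "essential_htn": _f(p.essential_htn),
            "prev_gest_htn": _f(p.prev_gest_htn), "diabetes": _f(p.diabetes),
            "prev_gest_diab": _f(p.prev_gest_diab), "nonwhite": _f(p.nonwhite),
            "ga_delivery": p.ga_delivery, "birthweight": p.birthweight,
            "initial_map": im[0] if im else np.nan,
            "initial_ga": im[1] if im else np.nan,
            "pe": float(pe),
            "preterm": float(define_preterm(p.ga_delivery)),
        }
        for g in TARGET_WEEKS:
            m = map_at_gestation(p.visits, g)
            row[f"map_{g}"] = m if m is not None else np.nan
        rows.append(row)
    df = pd.DataFrame(rows)
    ok = df["birthweight"].notna() & df["ga_delivery"].notna()
    flags = define_sga(df.loc[ok, "ga_delivery"], df.loc[ok, "birthweight"],
                       centile=sga_centile)
    df["sga"] = np.nan
    df.loc[ok, "sga"] = flags.astype(float)
    return df


def _f(v):
    return np.nan if v is None else float(bool(v))
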
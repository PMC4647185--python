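"""Stage 2: gestation-indexed logistic prediction models.

For each outcome (pre-eclampsia, preterm birth, small-for-gestational-age)
four nested models are built on the development cohort:

* model 1 — early-pregnancy characteristics selected by backward
  elimination (pooled Wald P < 0.2) with initial MAP always forced in;
* model 2 — model 1 plus the current MAP at the index gestation;
* model 3 — model 1 plus the deviation of current MAP from the woman's
  conditional normative value;
* model 4 — model 1 plus both.

At each index gestation (20, 25, 28, 31, 34, 36 weeks) models are fit on
the women who have not yet delivered, and coefficients are pooled across
imputed tables by Rubin's rules.  Model 1's term set is selected once at
booking and only refit (not re-selected) on later undelivered populations.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .impute import ImputationSet, pooled_wald, rubin_combine, _ridge_logistic

GESTATIONS = (20, 25, 28, 31, 34, 36)
OUTCOMES = ("pe", "preterm", "sga")

#: candidate predictor groups for backward selection (multi-column groups
#: are tested jointly); initial MAP is forced and is not a candidate.
CANDIDATE_GROUPS = (
    ("bmi", ("bmi",)),
    ("height", ("height",)),
    ("age_ge35", ("age_ge35",)),
    ("parity", ("parity_1", "parity_2plus")),
    ("smoking", ("smoking",)),
    ("essential_htn", ("essential_htn",)),
    ("prev_gest_htn", ("prev_gest_htn",)),
    ("diabetes", ("diabetes",)),
    ("prev_gest_diab", ("prev_gest_diab",)),
    ("nonwhite", ("nonwhite",)),
)
FORCED_TERMS = ("initial_map",)


def candidate_set():
    """Names of the candidate predictor groups (10 groups)."""
    return [name for name, _ in CANDIDATE_GROUPS]


def design_columns(table: pd.DataFrame) -> pd.DataFrame:
    """Numeric model-ready columns from a completed derived table.

    Only columns derivable from the table are produced; models referring
    to absent terms fail loudly at prediction time.
    """
    out = pd.DataFrame(index=table.index)
    for c in ("bmi", "height"):
        if c in table:
            out[c] = table[c].astype(float)
    if "age" in table:
        out["age_ge35"] = (table["age"].astype(float) >= 35).astype(float)
    if "parity" in table:
        out["parity_1"] = (table["parity"] == "1").astype(float)
        out["parity_2plus"] = (table["parity"] == "2+").astype(float)
    for c in ("smoking", "essential_htn", "prev_gest_htn", "diabetes",
              "prev_gest_diab", "nonwhite", "initial_map"):
        if c in table:
            out[c] = table[c].astype(float)
    for c in table.columns:
        if c.startswith(("map_", "deviation_", "expected_")):
            out[c] = table[c].astype(float)
    return out


@dataclass
class PredictionModel:
    """A fitted gestation-indexed logistic model with pooled coefficients."""

    outcome: str
    model_id: int
    gestation: object                  # week number, or "booking"
    terms: list                        # design columns, intercept excluded
    coef: dict                         # name -> pooled log-odds coefficient
    coef_var: dict                     # name -> pooled total variance
    recal: tuple = None                # optional (intercept a, slope b)
    n_population: int = 0
    n_events: int = 0
    notes: list = field(default_factory=list)

    def linear_predictor(self, table: pd.DataFrame,
                         on_missing="raise") -> np.ndarray:
        X = design_columns(table)
        absent = [t for t in self.terms if t not in X.columns]
        if absent:
            raise ValueError(f"table lacks model terms {absent}")
        lp = np.full(len(table), self.coef["const"])
        for t in self.terms:
            lp = lp + self.coef[t] * X[t].to_numpy()
        if on_missing == "raise" and np.isnan(lp).any():
            bad = [t for t in self.terms if X[t].isna().any()]
            raise ValueError(f"prediction requires completed data; missing {bad}")
        return lp

    def predict_risk(self, table: pd.DataFrame, on_missing="raise") -> np.ndarray:
        """Predicted outcome probability per row (recalibration applied).

        ``on_missing='nan'`` propagates NaN for rows lacking a model term
        instead of raising.
        """
        lp = self.linear_predictor(table, on_missing=on_missing)
        if self.recal is not None:
            a, b = self.recal
            lp = a + b * lp
        return expit(lp)

    def to_dict(self):
        return {
            "outcome": self.outcome, "model_id": self.model_id,
            "gestation": self.gestation, "terms": list(self.terms),
            "coef": {k: float(v) for k, v in self.coef.items()},
            "coef_var": {k: float(v) for k, v in self.coef_var.items()},
            "recal": None if self.recal is None else list(self.recal),
            "n_population": self.n_population, "n_events": self.n_events,
            "notes": list(self.notes),
        }

    @classmethod
    def from_dict(cls, d):
        return cls(outcome=d["outcome"], model_id=d["model_id"],
                   gestation=d["gestation"], terms=list(d["terms"]),
                   coef=d["coef"], coef_var=d["coef_var"],
                   recal=None if d["recal"] is None else tuple(d["recal"]),
                   n_population=d["n_population"], n_events=d["n_events"],
                   notes=list(d.get("notes", [])))


def _undelivered(table: pd.DataFrame, gestation) -> pd.DataFrame:
    if gestation in (None, "booking"):
        return table
    return table[table["ga_delivery"].astype(float) > float(gestation)]


def _fit_one_table(y, X, notes):
    """Logistic MLE on one table; ridge fallback on separation."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not np.all(np.isfinite(res.bse)):
            raise np.linalg.LinAlgError
        return np.asarray(res.params), np.asarray(res.cov_params())
    except Exception:
        notes.append("separation: ridge-penalized fallback fit")
        beta = _ridge_logistic(y, X, lam=0.5)
        p = expit(X @ beta)
        W = np.maximum(p * (1 - p), 1e-8)
        cov = np.linalg.inv(X.T @ (W[:, None] * X) + 0.5 * np.eye(X.shape[1]))
        return beta, cov


def _fit_terms(imputation_set: ImputationSet, outcome, terms, gestation):
    """Per-imputation fits restricted to the undelivered population."""
    params, covs, notes = [], [], []
    n_pop = n_ev = 0
    for table in imputation_set.completed_tables:
        sub = _undelivered(table, gestation)
        y = sub[outcome].astype(float).to_numpy()
        X = design_columns(sub)[list(terms)].to_numpy()
        X = np.column_stack([np.ones(len(sub)), X])
        # complete-case within the risk set (a handful of women can lack a
        # windowed MAP value even in complete data)
        ok = np.isfinite(X).all(axis=1) & np.isfinite(y)
        y, X = y[ok], X[ok]
        b, c = _fit_one_table(y, X, notes)
        params.append(b)
        covs.append(c)
        n_pop, n_ev = len(sub), int(y.sum())
    return params, covs, notes, n_pop, n_ev


def fit_logistic(imputation_set: ImputationSet, outcome, terms,
                 gestation=None, model_id=1) -> PredictionModel:
    """Fit and Rubin-pool a logistic model on the undelivered population."""
    terms = list(terms)
    params, covs, notes, n_pop, n_ev = _fit_terms(
        imputation_set, outcome, terms, gestation)
    names = ["const"] + terms
    m = len(params)
    coef, coef_var = {}, {}
    for j, name in enumerate(names):
        if m >= 2:
            pe = rubin_combine([p[j] for p in params], [c[j, j] for c in covs])
            coef[name], coef_var[name] = pe.estimate, pe.total_var
        else:
            coef[name], coef_var[name] = float(params[0][j]), float(covs[0][j, j])
    return PredictionModel(
        outcome=outcome, model_id=model_id,
        gestation=gestation if gestation is not None else "booking",
        terms=terms, coef=coef, coef_var=coef_var,
        n_population=n_pop, n_events=n_ev, notes=sorted(set(notes)))


def backward_select(imputation_set: ImputationSet, outcome,
                    candidates=CANDIDATE_GROUPS, threshold=0.2,
                    forced=FORCED_TERMS, gestation=None):
    """Backward elimination on pooled Wald tests.

    Repeatedly drops the candidate group with the largest pooled Wald
    P value above ``threshold`` (multi-column groups tested jointly),
    refitting after each removal.  Forced terms are never candidates.
    Ties in P value are broken by removing the later-listed group.
    Returns the retained design columns (forced terms included).
    """
    groups = list(candidates)

    def current_terms(gs):
        cols = []
        for _, gcols in gs:
            cols.extend(gcols)
        return cols + list(forced)

    while groups:
        terms = current_terms(groups)
        params, covs, _, _, _ = _fit_terms(imputation_set, outcome, terms,
                                           gestation)
        names = ["const"] + terms
        worst_p, worst_idx = -1.0, None
        for gi, (_, gcols) in enumerate(groups):
            idx = [names.index(c) for c in gcols]
            ests = [np.asarray(p)[idx] for p in params]
            cvs = [np.asarray(c)[np.ix_(idx, idx)] for c in covs]
            p_val = pooled_wald(ests, cvs)
            if p_val >= worst_p:  # >= breaks ties toward the later group
                worst_p, worst_idx = p_val, gi
        if worst_p > threshold:
            groups.pop(worst_idx)
        else:
            break
    return current_terms(groups)


def _collinearity_note(imputation_set, terms):
    table = imputation_set.completed_tables[0]
    X = design_columns(table)[list(terms)].to_numpy()
    X = np.column_stack([np.ones(len(table)), X])
    X = X[np.isfinite(X).all(axis=1)]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        return [f"design rank {rank} < {X.shape[1]} columns (collinear terms)"]
    return []


def build_all_models(imputation_set: ImputationSet, outcomes=OUTCOMES,
                     gestations=GESTATIONS, threshold=0.2,
                     min_population=100) -> dict:
    """Build the full model registry.

    Returns ``{(outcome, model_id, gestation): PredictionModel}``; model 1
    also appears at gestation "booking".  Model 1's selected term set is
    re-used at every gestation with coefficients refit on the undelivered
    population; models 2-4 add the current MAP and/or normogram deviation.
    """
    registry = {}
    for outcome in outcomes:
        base_terms = backward_select(imputation_set, outcome,
                                     threshold=threshold)
        m1_booking = fit_logistic(imputation_set, outcome, base_terms,
                                  gestation=None, model_id=1)
        registry[(outcome, 1, "booking")] = m1_booking
        for g in gestations:
            n_undeliv = len(_undelivered(imputation_set.completed_tables[0], g))
            if n_undeliv < min_population:
                warnings.warn(f"{outcome} at {g} weeks: population "
                              f"{n_undeliv} below minimum; skipped")
                continue
            extra = {2: [f"map_{g}"], 3: [f"deviation_{g}"],
                     4: [f"map_{g}", f"deviation_{g}"]}
            registry[(outcome, 1, g)] = fit_logistic(
                imputation_set, outcome, base_terms, gestation=g, model_id=1)
            for mid, add in extra.items():
                terms = base_terms + add
                model = fit_logistic(imputation_set, outcome, terms,
                                     gestation=g, model_id=mid)
                model.notes.extend(_collinearity_note(imputation_set, terms))
                registry[(outcome, mid, g)] = model
    return registry


def save_registry(registry: dict, path) -> None:
    ser = [{"key": [k[0], k[1], k[2]], "model": v.to_dict()}
           for k, v in registry.items()]
    Path(path).write_text(json.dumps(ser, indent=1))


def load_registry(path) -> dict:
    data = json.loads(Path(path).read_text())
    return {(e["key"][0], e["key"][1], e["key"][2]
             if e["key"][2] == "booking" else int(e["key"][2])):
            PredictionModel.from_dict(e["model"]) for e in data}
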
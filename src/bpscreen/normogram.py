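"""Stage 1: stratified normograms of mean arterial pressure across gestation.

A two-level linear mixed model (measurement occasion within woman) is fit on
the normal-pregnancy subset, separately for nulliparous and multiparous
women.  The fixed part is a restricted cubic spline of gestational age with
BMI-category and smoking main effects and their interactions with every
spline term; the random part is an individual intercept plus random
coefficients on the leading trajectory terms, with unstructured covariance.

From a fitted model, the normative MAP for any woman at a target gestation
is obtained by Gaussian conditioning on her initial (booking) measurement:

    E[MAP(t) | MAP(t0) = y0] = m_t + (z_t' G z_0 / (z_0' G z_0 + s2)) (y0 - m_0)

where m are fixed-part means for her covariate cell, G the random-effect
covariance, s2 the residual variance, and z the random-effect design.  The
observed value's variance includes the residual; the prediction targets the
noise-free expected pressure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .preprocess import define_sga
from .splines import DEFAULT_KNOTS, rcs_basis

_BMI_DUMMIES = (("bmi_under", "underweight"), ("bmi_over", "overweight"),
                ("bmi_obese", "obese"))


class ModelIntegrityError(RuntimeError):
    pass


def fixed_design(ga, bmi_category, smoking, knots=DEFAULT_KNOTS):
    """Fixed-effects design matrix and column names.

    Columns: intercept, 4 spline terms, BMI-category dummies and smoking,
    and each covariate's interaction with every spline term.
    """
    ga = np.atleast_1d(np.asarray(ga, dtype=float))
    B = np.atleast_2d(rcs_basis(ga, knots))
    n, k = B.shape
    bmi_category = np.asarray(bmi_category, dtype=object)
    if bmi_category.ndim == 0:
        bmi_category = np.repeat(bmi_category, n)
    smoking = np.broadcast_to(np.asarray(smoking, dtype=float), (n,))

    cols = [np.ones(n)]
    names = ["const"]
    for j in range(k):
        cols.append(B[:, j])
        names.append(f"t{j + 1}")
    covs = [(name, (bmi_category == level).astype(float))
            for name, level in _BMI_DUMMIES]
    covs.append(("smoking", smoking.astype(float)))
    for cname, cvec in covs:
        cols.append(cvec)
        names.append(cname)
        for j in range(k):
            cols.append(cvec * B[:, j])
            names.append(f"{cname}:t{j + 1}")
    return np.column_stack(cols), names


def random_design(ga, knots=DEFAULT_KNOTS, n_random=3):
    """Random-effects design: first ``n_random`` of (1, t, s1, s2, s3)."""
    ga = np.atleast_1d(np.asarray(ga, dtype=float))
    B = np.atleast_2d(rcs_basis(ga, knots))
    Z = np.column_stack([np.ones(ga.size), B])
    return Z[:, :n_random]


@dataclass
class NormogramFit:
    """Per-stratum fitted normogram."""

    stratum: str                      # "nulliparous" | "multiparous"
    knots: tuple
    term_names: list
    beta: np.ndarray                  # fixed effects
    G: np.ndarray                     # random-effect covariance (mm Hg^2)
    sigma2: float                     # residual variance (mm Hg^2)
    n_random: int = 3
    converged: bool = True
    loglik: float = np.nan
    n_women: int = 0
    n_obs: int = 0
    beta_se: np.ndarray = None

    def to_dict(self):
        return {
            "stratum": self.stratum, "knots": list(self.knots),
            "term_names": list(self.term_names),
            "beta": np.asarray(self.beta).tolist(),
            "G": np.asarray(self.G).tolist(), "sigma2": float(self.sigma2),
            "n_random": int(self.n_random), "converged": bool(self.converged),
            "loglik": float(self.loglik), "n_women": int(self.n_women),
            "n_obs": int(self.n_obs),
            "beta_se": None if self.beta_se is None else np.asarray(self.beta_se).tolist(),
        }

    @classmethod
    def from_dict(cls, d):
        return cls(
            stratum=d["stratum"], knots=tuple(d["knots"]),
            term_names=list(d["term_names"]), beta=np.asarray(d["beta"]),
            G=np.asarray(d["G"]), sigma2=float(d["sigma2"]),
            n_random=int(d["n_random"]), converged=bool(d["converged"]),
            loglik=float(d["loglik"]), n_women=int(d["n_women"]),
            n_obs=int(d["n_obs"]),
            beta_se=None if d.get("beta_se") is None else np.asarray(d["beta_se"]),
        )


def normal_subset_mask(derived: pd.DataFrame) -> pd.Series:
    """Normal-pregnancy selector for normogram fitting.

    Keeps pregnancies with no pre-eclampsia, no essential hypertension, no
    diabetes, a term delivery (>= 37 weeks), and a birthweight appropriate
    for gestational age (between the internal 10th and 90th centiles).
    """
    ok = derived["birthweight"].notna() & derived["ga_delivery"].notna()
    resid = pd.Series(np.nan, index=derived.index)
    _, r = define_sga(derived.loc[ok, "ga_delivery"],
                      derived.loc[ok, "birthweight"], return_resid=True)
    resid.loc[ok] = r
    lo = resid.quantile(0.10)
    hi = resid.quantile(0.90)
    mask = (
        (derived["pe"] == 0)
        & (derived["essential_htn"] == 0)
        & (derived["diabetes"] == 0)
        & (derived["ga_delivery"] >= 37.0)
        & resid.between(lo, hi, inclusive="both")
    )
    mask &= mask.notna()
    if not mask.any():
        raise ValueError("normal-pregnancy subset is empty")
    return mask.fillna(False)


def visits_long(cohort, ids=None) -> pd.DataFrame:
    """Long table of repeated MAP measurements with covariates."""
    keep = None if ids is None else set(ids)
    rows = []
    for p in cohort:
        if keep is not None and p.id not in keep:
            continue
        for v in p.visits:
            rows.append({
                "id": p.id, "ga": v.ga, "map": v.map,
                "bmi_category": p.bmi_category,
                "smoking": float(bool(p.smoking)),
                "parity": p.parity,
            })
    return pd.DataFrame(rows)


def fit_multilevel(long_df: pd.DataFrame, knots=DEFAULT_KNOTS, n_random=3,
                   stratum="", min_women=200, maxiter=500) -> NormogramFit:
    """REML fit of the two-level spline model on one parity stratum.

    ``long_df`` needs columns id, ga, map, bmi_category, smoking.  Women
    contribute all their repeated measurements at exact gestational ages.
    Non-convergence is reported on the returned fit, never silently.
    """
    df = long_df.dropna(subset=["ga", "map", "bmi_category", "smoking"])
    n_women = df["id"].nunique()
    if n_women < min_women:
        raise ValueError(
            f"stratum '{stratum}': {n_women} women with usable visits; "
            f"need at least {min_women}")
    X, names = fixed_design(df["ga"].to_numpy(), df["bmi_category"].to_numpy(),
                            df["smoking"].to_numpy(), knots)
    Z = random_design(df["ga"].to_numpy(), knots, n_random)
    # scale random-effect columns to comparable magnitude: the raw columns
    # (1, t, s1) differ by orders of magnitude, which degrades the variance
    # optimization; G is mapped back to natural units afterwards
    scale = np.maximum(np.abs(Z).max(axis=0), 1e-12)
    model = sm.regression.mixed_linear_model.MixedLM(
        df["map"].to_numpy(), X, groups=df["id"].to_numpy(),
        exog_re=Z / scale)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=True, maxiter=maxiter, method=["lbfgs", "cg"])
    G = np.asarray(res.cov_re) / np.outer(scale, scale)
    sigma2 = float(res.scale)
    return NormogramFit(
        stratum=stratum, knots=tuple(knots), term_names=names,
        beta=np.asarray(res.fe_params), G=G, sigma2=sigma2,
        n_random=n_random, converged=bool(res.converged),
        loglik=float(res.llf), n_women=int(n_women), n_obs=int(len(df)),
        beta_se=np.asarray(res.bse_fe),
    )


def fit_normograms(cohort, derived: pd.DataFrame, knots=DEFAULT_KNOTS,
                   n_random=3, subsample=None, seed=0, min_women=200) -> dict:
    """Fit both parity strata on the normal-pregnancy subset.

    ``subsample`` caps the number of women per stratum (random, seeded) —
    the population curves are estimated with high precision well below the
    full cohort size, so large runs may subsample for speed.
    """
    mask = normal_subset_mask(derived)
    ids = derived.loc[mask, "id"]
    parity = derived.set_index("id")["parity"]
    fits = {}
    rng = np.random.default_rng(seed)
    for stratum, sel in (("nulliparous", parity == "0"),
                         ("multiparous", parity != "0")):
        sids = [i for i in ids if sel.get(i, False)]
        if subsample is not None and len(sids) > subsample:
            sids = list(rng.choice(sids, size=subsample, replace=False))
        long_df = visits_long(cohort, sids)
        fits[stratum] = fit_multilevel(long_df, knots=knots, n_random=n_random,
                                       stratum=stratum, min_women=min_women)
    return fits


def population_trajectory(fit: NormogramFit, bmi_category, smoking, ga):
    """Fixed-part expected MAP at ``ga`` for a covariate cell."""
    if bmi_category not in ("underweight", "normal", "overweight", "obese"):
        raise ValueError(f"unknown BMI category: {bmi_category!r}")
    X, _ = fixed_design(ga, bmi_category, float(smoking), fit.knots)
    out = X @ fit.beta
    return float(out[0]) if np.size(ga) == 1 else out


def conditional_normative(fit: NormogramFit, bmi_category, smoking,
                          initial_map, initial_ga, target_ga):
    """Expected MAP at ``target_ga`` given the initial measurement.

    Gaussian conditioning under the fitted mixed model; the shrinkage
    coefficient is z_t' G z_0 / (z_0' G z_0 + sigma2).
    """
    m0 = population_trajectory(fit, bmi_category, smoking, initial_ga)
    mt = population_trajectory(fit, bmi_category, smoking, target_ga)
    z0 = random_design(initial_ga, fit.knots, fit.n_random)[0]
    zt = random_design(target_ga, fit.knots, fit.n_random)[0]
    v0 = float(z0 @ fit.G @ z0) + fit.sigma2
    if v0 <= 0:
        raise ModelIntegrityError("non-positive marginal variance at initial visit")
    c = float(zt @ fit.G @ z0)
    return mt + (c / v0) * (float(initial_map) - m0)


def deviation(observed, expected):
    """Observed minus expected MAP (mm Hg)."""
    return observed - expected


def marginal_loglik(fit: NormogramFit, long_df: pd.DataFrame) -> float:
    """Exact marginal Gaussian log-likelihood of repeated measurements.

    Assembles, per woman, the joint normal N(X beta, Z G Z' + sigma2 I) and
    sums log densities.  Used as an independent check of the fitted model's
    likelihood on small instances.
    """
    total = 0.0
    for _, grp in long_df.groupby("id"):
        X, _ = fixed_design(grp["ga"].to_numpy(), grp["bmi_category"].to_numpy(),
                            grp["smoking"].to_numpy(), fit.knots)
        Z = random_design(grp["ga"].to_numpy(), fit.knots, fit.n_random)
        mu = X @ fit.beta
        V = Z @ fit.G @ Z.T + fit.sigma2 * np.eye(len(grp))
        r = grp["map"].to_numpy() - mu
        sign, logdet = np.linalg.slogdet(V)
        if sign <= 0:
            raise ModelIntegrityError("non-PD marginal covariance")
        total += -0.5 * (len(grp) * np.log(2 * np.pi) + logdet
                         + r @ np.linalg.solve(V, r))
    return float(total)


def simulate_from_normogram(fit: NormogramFit, n_women, seed=0,
                            booking_window=(9.0, 16.0),
                            nominal_visits=(20, 25, 28, 31, 34, 36, 38, 40),
                            jitter_sd=0.7,
                            bmi_category_p=(0.06, 0.72, 0.16, 0.06),
                            smoking_p=0.25) -> pd.DataFrame:
    """Draw a long table of repeated measurements from known parameters.

    Inverse of :func:`fit_multilevel` for parameter-recovery checks: women
    get random covariate cells, a booking visit plus jittered scheduled
    visits, and MAP values from the fit's (beta, G, sigma2).
    """
    rng = np.random.default_rng(seed)
    cats = np.array(["underweight", "normal", "overweight", "obese"])
    rows = []
    for i in range(int(n_women)):
        cat = rng.choice(cats, p=bmi_category_p)
        smk = float(rng.random() < smoking_p)
        gas = [rng.uniform(*booking_window)]
        gas += [g + rng.normal(0, jitter_sd) for g in nominal_visits]
        gas = np.sort(np.asarray(gas))
        X, _ = fixed_design(gas, cat, smk, fit.knots)
        Z = random_design(gas, fit.knots, fit.n_random)
        b = rng.multivariate_normal(np.zeros(fit.n_random), fit.G,
                                    method="eigh")
        y = X @ fit.beta + Z @ b + rng.normal(0, np.sqrt(fit.sigma2), gas.size)
        for g, v in zip(gas, y):
            rows.append({"id": f"sim-{i}", "ga": float(g), "map": float(v),
                         "bmi_category": cat, "smoking": smk, "parity": "0"})
    return pd.DataFrame(rows)


def save_normograms(fits: dict, path) -> None:
    Path(path).write_text(json.dumps(
        {k: v.to_dict() for k, v in fits.items()}, indent=1))


def load_normograms(path) -> dict:
    d = json.loads(Path(path).read_text())
    return {k: NormogramFit.from_dict(v) for k, v in d.items()}


def add_normative_columns(derived: pd.DataFrame, fits: dict,
                          target_weeks=(20, 25, 28, 31, 34, 36)) -> pd.DataFrame:
    """Append expected_g and deviation_g columns to a derived table.

    Expected values are the conditional normatives given each woman's
    initial MAP; deviations are observed minus expected and are missing
    wherever the observed gestation-specific MAP is missing.  Rows with a
    missing initial MAP or covariates get missing normative values (they
    are filled passively after imputation).
    """
    out = derived.copy()
    bmi_cat = pd.cut(out["bmi"], [-np.inf, 18.5, 25.0, 30.0, np.inf],
                     right=False, labels=["underweight", "normal",
                                          "overweight", "obese"])
    for g in target_weeks:
        exp_col = np.full(len(out), np.nan)
        for i, (_, r) in enumerate(out.iterrows()):
            if (pd.isna(r["initial_map"]) or pd.isna(r["initial_ga"])
                    or pd.isna(r["bmi"]) or pd.isna(r["smoking"])
                    or pd.isna(r["parity"]) or r["parity"] is None):
                continue
            fit = fits["nulliparous" if r["parity"] == "0" else "multiparous"]
            exp_col[i] = conditional_normative(
                fit, str(bmi_cat.iloc[i]), float(r["smoking"]),
                float(r["initial_map"]), float(r["initial_ga"]), float(g))
        out[f"expected_{g}"] = exp_col
        out[f"deviation_{g}"] = out[f"map_{g}"] - exp_col
    return out
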
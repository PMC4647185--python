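"""Chained-equations multiple imputation and Rubin's-rules pooling.

Missing covariates and gestation-specific MAP values are imputed with
fully conditional specification: each incomplete variable is regressed on
all other analysis variables (including the outcomes) and refilled from a
posterior-draw conditional model — Bayesian linear regression for
continuous variables, logistic regression for binary ones, multinomial
logistic for parity.  Normative values are never imputed directly: they
are recomputed ("passively") in every completed table from that table's
covariates and initial MAP.

Pooling across the m completed tables follows Rubin's rules: the pooled
estimate is the mean, and the total variance is the mean within-imputation
variance plus (1 + 1/m) times the between-imputation variance, with the
standard small-sample degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

CONTINUOUS_VARS = ("bmi", "height", "age", "initial_map", "initial_ga",
                   "map_20", "map_25", "map_28", "map_31", "map_34", "map_36")
BINARY_VARS = ("smoking", "essential_htn", "prev_gest_htn", "diabetes",
               "prev_gest_diab", "nonwhite")
CATEGORICAL_VARS = ("parity",)
OUTCOME_VARS = ("pe", "preterm", "sga")


@dataclass
class ImputationSet:
    """m completed copies of a derived table from one chained-equations run."""

    m: int
    completed_tables: list
    seed: int = 0
    log: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.m != len(self.completed_tables):
            raise ValueError("m must match the number of completed tables")


@dataclass
class PooledEstimate:
    estimate: float
    within_var: float
    between_var: float
    total_var: float
    df: float
    ci_low: float
    ci_high: float

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_var))

    @property
    def p_value(self) -> float:
        if self.total_var == 0:
            return 0.0 if self.estimate != 0 else 1.0
        t = self.estimate / self.se
        return float(2 * stats.t.sf(abs(t), self.df))


def rubin_combine(estimates, variances, alpha=0.05) -> PooledEstimate:
    """Pool one scalar across imputations by Rubin's rules."""
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.shape != u.shape or q.ndim != 1:
        raise ValueError("estimates and variances must be equal-length 1-d lists")
    m = q.size
    if m < 2:
        raise ValueError("Rubin's rules need at least 2 imputations")
    qbar = q.mean()
    within = u.mean()
    between = q.var(ddof=1)
    total = within + (1 + 1 / m) * between
    if between > 0:
        r = (1 + 1 / m) * between / within if within > 0 else np.inf
        df = (m - 1) * (1 + 1 / r) ** 2 if np.isfinite(r) else m - 1.0
    else:
        df = np.inf
    half = stats.t.ppf(1 - alpha / 2, df) * np.sqrt(total) if total > 0 else 0.0
    return PooledEstimate(float(qbar), float(within), float(between),
                          float(total), float(df),
                          float(qbar - half), float(qbar + half))


def pooled_wald(estimates, covariances):
    """Multivariate Wald test of a parameter block pooled across imputations.

    ``estimates``: list of length-k vectors (one per imputation);
    ``covariances``: matching k-by-k covariance matrices.  Returns a
    p-value from the multivariate pooling statistic (an F reference with
    the Li-Raghunathan-Rubin denominator degrees of freedom).  With a
    single imputation this reduces to the ordinary Wald chi-square test.
    """
    Q = np.asarray(estimates, dtype=float)
    if Q.ndim == 1:
        Q = Q[:, None]
    m, k = Q.shape
    covs = [np.atleast_2d(np.asarray(c, dtype=float)) for c in covariances]
    qbar = Q.mean(axis=0)
    Wbar = np.mean(covs, axis=0)
    Winv = np.linalg.pinv(Wbar)
    if m == 1:
        stat = float(qbar @ Winv @ qbar)
        return float(stats.chi2.sf(stat, k))
    B = np.cov(Q.T, ddof=1).reshape(k, k)
    r = max((1 + 1 / m) * np.trace(B @ Winv) / k, 1e-12)
    F = float(qbar @ Winv @ qbar) / (k * (1 + r))
    t = k * (m - 1)
    if t > 4:
        df2 = 4 + (t - 4) * (1 + (1 - 2 / t) / r) ** 2
    else:
        df2 = t * (1 + 1 / k) * (1 + 1 / r) ** 2 / 2
    return float(stats.f.sf(F, k, df2))


# ---------------------------------------------------------------------------
# chained equations
# ---------------------------------------------------------------------------

def _design(df, predictors):
    """Numeric predictor matrix with parity expanded to indicator contrasts."""
    cols = [np.ones(len(df))]
    for c in predictors:
        if c == "parity":
            cols.append((df["parity"] == "1").astype(float).to_numpy())
            cols.append((df["parity"] == "2+").astype(float).to_numpy())
        else:
            cols.append(df[c].astype(float).to_numpy())
    return np.column_stack(cols)


def _draw_linear(y, X, Xmis, rng):
    """Posterior-draw Bayesian linear regression imputation."""
    n, p = X.shape
    XtX = X.T @ X + 1e-8 * np.eye(p)
    betahat = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ betahat
    dof = max(n - p, 2)
    sigma2 = resid @ resid / rng.chisquare(dof)
    cov = sigma2 * np.linalg.inv(XtX)
    beta = rng.multivariate_normal(betahat, (cov + cov.T) / 2, method="cholesky")
    return Xmis @ beta + rng.normal(0, np.sqrt(sigma2), Xmis.shape[0])


def _draw_logistic(y, X, Xmis, rng, log):
    """Posterior-draw logistic imputation with a penalized fallback."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
        if not np.all(np.isfinite(res.bse)):
            raise np.linalg.LinAlgError
        cov = np.asarray(res.cov_params())
        beta = rng.multivariate_normal(np.asarray(res.params),
                                       (cov + cov.T) / 2,
                                       check_valid="ignore")
    except Exception:
        # separation or non-convergence: ridge-penalized point fit
        log.append("logistic fallback: penalized fit (possible separation)")
        beta = _ridge_logistic(y, X)
    p = expit(Xmis @ beta)
    return (rng.random(Xmis.shape[0]) < p).astype(float)


def _ridge_logistic(y, X, lam=1.0, iters=50):
    beta = np.zeros(X.shape[1])
    for _ in range(iters):
        p = expit(X @ beta)
        W = np.maximum(p * (1 - p), 1e-6)
        H = X.T @ (W[:, None] * X) + lam * np.eye(X.shape[1])
        g = X.T @ (y - p) - lam * beta
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    return beta


def _draw_multinomial(y, X, Xmis, rng, levels, log):
    """Multinomial-logistic imputation for a categorical variable."""
    codes = pd.Categorical(y, categories=levels).codes
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MNLogit(codes, X).fit(disp=0, maxiter=100)
        P = np.asarray(res.predict(Xmis))
    except Exception:
        log.append("multinomial fallback: observed-frequency draw")
        freq = np.bincount(codes, minlength=len(levels)).astype(float)
        P = np.tile(freq / freq.sum(), (Xmis.shape[0], 1))
    draws = [rng.choice(len(levels), p=P[i] / P[i].sum())
             for i in range(Xmis.shape[0])]
    return np.array([levels[d] for d in draws], dtype=object)


def impute_chained(derived: pd.DataFrame, m: int = 20, n_cycles: int = 10,
                   seed: int = 0) -> ImputationSet:
    """Multiple imputation of an incomplete derived table.

    Runs ``m`` independent chains of ``n_cycles`` full cycles each.  All
    early-pregnancy characteristics, derived MAP variables and the outcomes
    enter every conditional model; observed cells are never altered.
    """
    variables = [c for c in CONTINUOUS_VARS + BINARY_VARS + CATEGORICAL_VARS
                 if c in derived.columns]
    predictors_all = variables + [c for c in OUTCOME_VARS if c in derived.columns]
    missing_cols = [c for c in variables if derived[c].isna().any()]
    for c in variables:
        if derived[c].isna().all():
            raise ValueError(f"variable '{c}' is 100% missing; cannot impute")

    parity_levels = ["0", "1", "2+"]
    tables, log = [], []
    for chain in range(m):
        rng = np.random.default_rng((seed + 1) * 100003 + chain)
        df = derived.copy()
        # initial fill: random draws from the observed margin
        for c in missing_cols:
            mis = df[c].isna()
            obs = df.loc[~mis, c].to_numpy()
            df.loc[mis, c] = rng.choice(obs, size=int(mis.sum()))
        chain_log = []
        for _ in range(n_cycles if missing_cols else 0):
            for c in missing_cols:
                mis = derived[c].isna().to_numpy()
                preds = [p for p in predictors_all if p != c]
                X = _design(df.loc[~mis], preds)
                Xmis = _design(df.loc[mis], preds)
                if c in CATEGORICAL_VARS:
                    df.loc[mis, c] = _draw_multinomial(
                        df.loc[~mis, c].to_numpy(), X, Xmis, rng,
                        parity_levels, chain_log)
                elif c in BINARY_VARS:
                    df.loc[mis, c] = _draw_logistic(
                        df.loc[~mis, c].astype(float).to_numpy(), X, Xmis,
                        rng, chain_log)
                else:
                    df.loc[mis, c] = _draw_linear(
                        df.loc[~mis, c].astype(float).to_numpy(), X, Xmis, rng)
        if "age" in df.columns and "age_ge35" in df.columns:
            df["age_ge35"] = (df["age"].astype(float) >= 35).astype(float)
        tables.append(df)
        log.append(chain_log)
    return ImputationSet(m=m, completed_tables=tables, seed=seed,
                         log={"chains": log, "imputed_columns": missing_cols})


def passive_normative(imputation_set: ImputationSet, fits,
                      target_weeks=(20, 25, 28, 31, 34, 36)) -> ImputationSet:
    """Recompute expected/deviation columns in every completed table."""
    from .normogram import add_normative_columns
    tables = [add_normative_columns(t, fits, target_weeks)
              for t in imputation_set.completed_tables]
    return ImputationSet(m=imputation_set.m, completed_tables=tables,
                         seed=imputation_set.seed, log=imputation_set.log)


def complete_data_set(derived: pd.DataFrame) -> ImputationSet:
    """Wrap a complete table as a trivial single-'imputation' set."""
    return ImputationSet(m=1, completed_tables=[derived.copy()])
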
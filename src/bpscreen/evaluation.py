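"""Discrimination, calibration, recalibration and rule-out metrics.

The area under the ROC curve is computed as the concordance probability
P(score_case > score_noncase) + 1/2 P(tie) via rank statistics, with an
analytic (DeLong) variance for confidence intervals; under multiple
imputation AUCs are averaged and variances pooled by Rubin's rules.
Model comparisons use a Wald test with a bootstrap standard error of the
paired AUC difference.  Calibration is assessed over tenths of the risk
score, and models are recalibrated on a validation cohort by refitting the
intercept and slope of the logistic model on the linear predictor.
Rule-out operating points fix sensitivity (e.g. 95%, 99%) and report the
full 2x2 classification table with likelihood ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .impute import ImputationSet, rubin_combine


def _check_outcomes(y):
    y = np.asarray(y, dtype=float)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("need at least one case and one non-case")
    return y


def auc_rank(scores, outcomes) -> float:
    """Concordance-probability AUC via the rank (Mann-Whitney) statistic."""
    y = _check_outcomes(outcomes)
    s = np.asarray(scores, dtype=float)
    n1 = int(y.sum())
    n0 = y.size - n1
    ranks = stats.rankdata(s)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _delong_variance(scores, outcomes):
    """DeLong placement-value variance of the AUC."""
    y = np.asarray(outcomes, dtype=float)
    s = np.asarray(scores, dtype=float)
    cases = s[y == 1]
    ctrls = s[y == 0]
    m, n = cases.size, ctrls.size
    # placement of each case among controls and vice versa
    order = np.argsort(ctrls)
    cs = ctrls[order]
    v10 = (np.searchsorted(cs, cases, "left")
           + np.searchsorted(cs, cases, "right")) / (2.0 * n)
    order = np.argsort(cases)
    ks = cases[order]
    v01 = 1.0 - (np.searchsorted(ks, ctrls, "left")
                 + np.searchsorted(ks, ctrls, "right")) / (2.0 * m)
    return float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)


def auc(scores, outcomes, alpha=0.05):
    """(AUC, (ci_low, ci_high)) by rank statistic with DeLong variance."""
    a = auc_rank(scores, outcomes)
    v = _delong_variance(scores, outcomes)
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(max(v, 0.0))
    return a, (max(a - half, 0.0), min(a + half, 1.0))


def pooled_auc(model, imputation_set: ImputationSet, outcome=None, alpha=0.05):
    """AUC of a prediction model pooled over imputed tables."""
    outcome = outcome or model.outcome
    aucs, vars_ = [], []
    for table in imputation_set.completed_tables:
        sub = table if model.gestation == "booking" else \
            table[table["ga_delivery"].astype(float) > float(model.gestation)]
        s = model.predict_risk(sub, on_missing="nan")
        y = sub[outcome].astype(float).to_numpy()
        ok = np.isfinite(s) & np.isfinite(y)
        aucs.append(auc_rank(s[ok], y[ok]))
        vars_.append(_delong_variance(s[ok], y[ok]))
    if len(aucs) >= 2:
        pe = rubin_combine(aucs, vars_, alpha=alpha)
        return pe.estimate, (pe.ci_low, pe.ci_high)
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(vars_[0])
    return aucs[0], (aucs[0] - half, aucs[0] + half)


def compare_auc_bootstrap(scores_a, scores_b, outcomes, B=500, seed=0):
    """Two-sided Wald p-value for a paired AUC difference.

    The standard error of AUC(a) - AUC(b) comes from ``B`` bootstrap
    resamples of individuals; both scores are resampled jointly so the
    pairing is preserved.
    """
    if B < 100:
        import warnings
        warnings.warn("fewer than 100 bootstrap replicates; p-value unstable")
    y = _check_outcomes(outcomes)
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    d0 = auc_rank(sa, y) - auc_rank(sb, y)
    rng = np.random.default_rng(seed)
    n = y.size
    diffs = []
    for _ in range(B):
        idx = rng.integers(0, n, n)
        yy = y[idx]
        if yy.sum() == 0 or yy.sum() == n:
            continue
        diffs.append(auc_rank(sa[idx], yy) - auc_rank(sb[idx], yy))
    se = np.std(diffs, ddof=1)
    if se == 0:
        return 1.0 if d0 == 0 else 0.0
    return float(2 * stats.norm.sf(abs(d0) / se))


def calibration_deciles(pred, outcomes, alpha=0.05) -> pd.DataFrame:
    """Observed vs predicted risk across tenths of the risk score."""
    p = np.asarray(pred, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if p.size < 100:
        raise ValueError("calibration deciles need at least 100 individuals")
    order = np.argsort(p, kind="stable")
    splits = np.array_split(order, 10)
    rows = []
    for d, idx in enumerate(splits, start=1):
        n = idx.size
        k = int(y[idx].sum())
        lo, hi = _binom_ci(k, n, alpha)
        rows.append({"decile": d, "n": n, "mean_predicted": float(p[idx].mean()),
                     "observed": k / n, "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows)


def _binom_ci(k, n, alpha=0.05):
    """Wilson score interval."""
    if n == 0:
        return np.nan, np.nan
    z = stats.norm.ppf(1 - alpha / 2)
    ph = k / n
    den = 1 + z ** 2 / n
    ctr = (ph + z ** 2 / (2 * n)) / den
    half = z * np.sqrt(ph * (1 - ph) / n + z ** 2 / (4 * n ** 2)) / den
    return float(max(ctr - half, 0.0)), float(min(ctr + half, 1.0))


def recalibrate(linear_predictor, outcomes):
    """Intercept/slope recalibration on a validation cohort.

    Fits outcome ~ a + b * linear_predictor by logistic MLE and returns
    (a, b).  By the logistic score equations the recalibrated mean
    predicted risk equals the observed prevalence.
    """
    lp = np.asarray(linear_predictor, dtype=float)
    y = _check_outcomes(outcomes)
    if np.ptp(lp) < 1e-12:
        raise ValueError("degenerate linear predictor: no variation")
    X = np.column_stack([np.ones(lp.size), lp])
    res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    a, b = res.params
    return float(a), float(b)


def recalibrate_model(model, validation_table):
    """Set a model's recalibration pair from validation data (in place)."""
    sub = validation_table if model.gestation == "booking" else \
        validation_table[validation_table["ga_delivery"].astype(float)
                         > float(model.gestation)]
    lp = model.linear_predictor(sub, on_missing="nan")
    y = sub[model.outcome].astype(float).to_numpy()
    ok = np.isfinite(lp) & np.isfinite(y)
    model.recal = recalibrate(lp[ok], y[ok])
    return model


def threshold_for_sensitivity(scores, outcomes, target) -> float:
    """Largest threshold keeping at least ``target`` of cases test-positive.

    Test-positive means score >= threshold, so the threshold is the
    ceil(target * n_cases)-th largest case score.
    """
    if not 0 < target <= 1:
        raise ValueError("target sensitivity must be in (0, 1]")
    y = _check_outcomes(outcomes)
    cs = np.sort(np.asarray(scores, dtype=float)[y == 1])[::-1]
    k = int(np.ceil(target * cs.size))
    return float(cs[k - 1])


@dataclass
class MetricRow:
    """Classification metrics of one operating point (score >= threshold)."""

    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float = np.nan
    specificity: float = np.nan
    ppv: float = np.nan
    npv: float = np.nan
    lr_pos: Optional[float] = None
    lr_neg: Optional[float] = None
    ci: dict = field(default_factory=dict)
    undefined: dict = field(default_factory=dict)

    @property
    def n(self):
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n_positive(self):
        return self.tp + self.fp


def classification_metrics(scores, outcomes, threshold, alpha=0.05) -> MetricRow:
    """Full 2x2 table and derived metrics at a fixed risk-score threshold."""
    y = np.asarray(outcomes, dtype=float)
    s = np.asarray(scores, dtype=float)
    pos = s >= threshold
    tp = int(np.sum(pos & (y == 1)))
    fp = int(np.sum(pos & (y == 0)))
    tn = int(np.sum(~pos & (y == 0)))
    fn = int(np.sum(~pos & (y == 1)))
    return metrics_from_counts(tp, fp, tn, fn, threshold=threshold, alpha=alpha)


def metrics_from_counts(tp, fp, tn, fn, threshold=np.nan, alpha=0.05) -> MetricRow:
    row = MetricRow(threshold=float(threshold), tp=tp, fp=fp, tn=tn, fn=fn)
    ci = row.ci

    def prop(name, k, n):
        if n == 0:
            row.undefined[name] = "zero denominator"
            return np.nan
        ci[name] = _binom_ci(k, n, alpha)
        return k / n

    row.sensitivity = prop("sensitivity", tp, tp + fn)
    row.specificity = prop("specificity", tn, tn + fp)
    row.ppv = prop("ppv", tp, tp + fp)
    row.npv = prop("npv", tn, tn + fn)

    sens, spec = row.sensitivity, row.specificity
    z = stats.norm.ppf(1 - alpha / 2)
    if np.isfinite(sens) and np.isfinite(spec) and spec < 1.0:
        row.lr_pos = sens / (1 - spec)
        if tp > 0 and fp > 0:
            se = np.sqrt(1 / tp - 1 / (tp + fn) + 1 / fp - 1 / (fp + tn))
            ci["lr_pos"] = (row.lr_pos * np.exp(-z * se),
                            row.lr_pos * np.exp(z * se))
    else:
        row.undefined["lr_pos"] = "specificity = 1 (no false positives)"
    if np.isfinite(sens) and np.isfinite(spec) and spec > 0.0:
        row.lr_neg = (1 - sens) / spec
        if fn > 0 and tn > 0:
            se = np.sqrt(1 / fn - 1 / (tp + fn) + 1 / tn - 1 / (fp + tn))
            ci["lr_neg"] = (row.lr_neg * np.exp(-z * se),
                            row.lr_neg * np.exp(z * se))
    else:
        row.undefined["lr_neg"] = "specificity = 0"
    return row


def evaluate_registry(registry, imputation_set: ImputationSet,
                      cohort_name="development") -> pd.DataFrame:
    """AUC table (one row per outcome x model x gestation) for a cohort."""
    rows = []
    for (outcome, mid, g), model in sorted(
            registry.items(), key=lambda kv: (kv[0][0], str(kv[0][2]), kv[0][1])):
        a, (lo, hi) = pooled_auc(model, imputation_set)
        rows.append({"cohort": cohort_name, "outcome": outcome,
                     "model": mid, "gestation": g, "auc": a,
                     "auc_ci_low": lo, "auc_ci_high": hi,
                     "n": model.n_population, "events": model.n_events})
    return pd.DataFrame(rows)
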
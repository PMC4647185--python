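"""Sequential rule-out screening for pre-eclampsia.

Women are screened with the booking model (model 1) and, if still
high-risk, re-screened with the current-MAP model (model 2) at 20, 25, 28
and 31 weeks, using one fixed risk-score threshold throughout.  A woman
who scores below the threshold at any stage moves to the low-risk group
and is not screened again; women who deliver between stages exit the
flow.  The threshold is derived on the development cohort as the average,
over the index gestations, of the threshold giving a target sensitivity
(95% or 99%) at each gestation — after the initial screen, within the
surviving high-risk group only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import threshold_for_sensitivity
from .prediction import GESTATIONS

SCREEN_STAGES = ("booking", 20, 25, 28, 31)


def average_threshold(dev_table: pd.DataFrame, registry, target_sensitivity,
                      outcome="pe", gestations=GESTATIONS) -> float:
    """Average fixed-sensitivity threshold across index gestations.

    The booking screen (model 1 at its own fixed-sensitivity threshold)
    first defines the high-risk group; each gestation's threshold is then
    the fixed-sensitivity cut of model 2's risk scores among surviving
    high-risk women not yet delivered, and the returned value is the
    unweighted mean over gestations.
    """
    y_all = dev_table[outcome].astype(float).to_numpy()
    m1 = registry[(outcome, 1, "booking")]
    s0 = m1.predict_risk(dev_table)
    t0 = threshold_for_sensitivity(s0, y_all, target_sensitivity)
    high = s0 >= t0
    thresholds = []
    for g in gestations:
        sub = dev_table[high & (dev_table["ga_delivery"].astype(float) > g)]
        y = sub[outcome].astype(float).to_numpy()
        m2 = registry[(outcome, 2, g)]
        s = m2.predict_risk(sub, on_missing="nan")
        ok = np.isfinite(s)
        if y[ok].sum() == 0:
            warnings.warn(f"no cases undelivered at {g} weeks; gestation skipped")
            continue
        thresholds.append(threshold_for_sensitivity(s[ok], y[ok],
                                                    target_sensitivity))
    if not thresholds:
        raise ValueError("no gestation yielded a threshold")
    return float(np.mean(thresholds))


@dataclass
class StageResult:
    stage: object
    n_screened: int
    n_low: int
    n_high: int
    n_exited_delivered: int           # delivered since the previous stage
    n_future_cases_in_high: int
    n_future_cases_in_low: int


@dataclass
class ScreeningFlow:
    """Per-stage allocation counts of the sequential rule-out strategy."""

    threshold: float
    n_initial: int
    n_cases: int
    stages: list = field(default_factory=list)
    #: eventual cases ruled out low at some stage yet undelivered at the
    #: final stage — the complement of the captured cases
    n_cases_missed_at_final: int = 0

    @property
    def n_low_total(self) -> int:
        return sum(s.n_low for s in self.stages)

    @property
    def n_final_high(self) -> int:
        return self.stages[-1].n_high if self.stages else 0

    @property
    def n_exited_total(self) -> int:
        return sum(s.n_exited_delivered for s in self.stages)

    def check_conservation(self):
        """Raise if any stage leaks or double-counts women."""
        carried = self.n_initial
        for s in self.stages:
            if s.n_screened != s.n_low + s.n_high:
                raise AssertionError(f"stage {s.stage}: screened != low + high")
            if carried - s.n_exited_delivered != s.n_screened:
                raise AssertionError(f"stage {s.stage}: entry count mismatch")
            carried = s.n_high
        if self.n_low_total + self.n_final_high + self.n_exited_total \
                != self.n_initial:
            raise AssertionError("totals do not account for every woman")

    def captured_fraction(self) -> float:
        """Fraction of eventual cases, still pregnant at the final stage,
        who remain in the high-risk group there."""
        captured = self.stages[-1].n_future_cases_in_high
        denom = captured + self.n_cases_missed_at_final
        return captured / denom if denom else np.nan

    def low_risk_fraction(self) -> float:
        """Fraction of all initial women ever allocated low-risk."""
        return self.n_low_total / self.n_initial

    def scaled(self, per=1000) -> list:
        """Stage counts scaled to ``per`` initial women."""
        f = per / self.n_initial
        return [{
            "stage": s.stage,
            "n_screened": round(s.n_screened * f, 1),
            "n_low": round(s.n_low * f, 1),
            "n_high": round(s.n_high * f, 1),
            "n_exited_delivered": round(s.n_exited_delivered * f, 1),
            "n_future_cases_in_high": round(s.n_future_cases_in_high * f, 2),
            "n_future_cases_in_low": round(s.n_future_cases_in_low * f, 2),
        } for s in self.stages]

    def to_dict(self):
        return {
            "threshold": self.threshold, "n_initial": self.n_initial,
            "n_cases": self.n_cases,
            "stages": [vars(s) for s in self.stages],
            "captured_fraction": self.captured_fraction(),
            "low_risk_fraction": self.low_risk_fraction(),
            "scaled_per_1000": self.scaled(),
        }


def sequential_screen(table: pd.DataFrame, registry, threshold,
                      outcome="pe", stages=SCREEN_STAGES,
                      keep_diagnosed=True) -> ScreeningFlow:
    """Run the sequential rule-out strategy on a completed cohort table.

    ``registry`` supplies model 1 (booking) and model 2 at each later
    stage, with any recalibration already attached.  If the table carries
    a ``pe_onset`` column and ``keep_diagnosed`` is set, cases already
    diagnosed before a stage stay in the high-risk stream without being
    re-scored (clinically they are under surveillance).  Counts are
    verified to conserve at every stage.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1) on the risk scale")
    df = table.reset_index(drop=True)
    y = df[outcome].astype(float).to_numpy()
    ga_del = df["ga_delivery"].astype(float).to_numpy()
    onset = df["pe_onset"].astype(float).to_numpy() if "pe_onset" in df else None

    flow = ScreeningFlow(threshold=float(threshold), n_initial=len(df),
                         n_cases=int(y.sum()))
    active = np.ones(len(df), dtype=bool)   # still in the high-risk stream
    low = np.zeros(len(df), dtype=bool)     # ever ruled out
    for stage in stages:
        if stage == "booking":
            exited = np.zeros(len(df), dtype=bool)
            model = registry[(outcome, 1, "booking")]
        else:
            exited = active & (ga_del <= float(stage))
            active = active & ~exited
            model = registry[(outcome, 2, stage)]
        idx = np.where(active)[0]
        scores = model.predict_risk(df.iloc[idx], on_missing="nan")
        # a woman who cannot be scored at this visit cannot be ruled out
        high = ~(scores < threshold)
        if keep_diagnosed and onset is not None and stage != "booking":
            high = high | ((y[idx] == 1) & (onset[idx] <= float(stage)))
        low_idx = idx[~high]
        high_idx = idx[high]
        flow.stages.append(StageResult(
            stage=stage, n_screened=int(idx.size),
            n_low=int(low_idx.size), n_high=int(high_idx.size),
            n_exited_delivered=int(exited.sum()),
            n_future_cases_in_high=int(y[high_idx].sum()),
            n_future_cases_in_low=int(y[low_idx].sum()),
        ))
        active[low_idx] = False
        low[low_idx] = True
    final_g = 0.0 if stages[-1] == "booking" else float(stages[-1])
    flow.n_cases_missed_at_final = int(((y == 1) & low & (ga_del > final_g)).sum())
    flow.check_conservation()
    return flow


def render_flowchart(flow: ScreeningFlow, per=1000) -> str:
    """Plain-text flowchart of the scaled screening flow."""
    lines = [f"Sequential rule-out screening (threshold {flow.threshold:.4f}, "
             f"scaled to {per} women)"]
    for s in flow.scaled(per):
        stage = s["stage"]
        name = "booking" if stage == "booking" else f"{stage} weeks"
        lines.append(f"  {name}: screened {s['n_screened']}")
        if s["n_exited_delivered"]:
            lines.append(f"    delivered before visit: {s['n_exited_delivered']}")
        lines.append(f"    -> high risk {s['n_high']} "
                     f"(future cases {s['n_future_cases_in_high']})")
        lines.append(f"    -> low risk  {s['n_low']} "
                     f"(future cases {s['n_future_cases_in_low']})")
    return "\n".join(lines)
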
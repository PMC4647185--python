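"""Synthetic antenatal cohort generator.

Emulates UK population-based pregnancy cohorts of the ALSPAC / SWS type:
repeated routine blood-pressure measurements across gestation with a
mid-pregnancy nadir and late rise, pre-eclampsia driven by the woman's own
trajectory (elevated baseline and steeper post-nadir slope) plus classical
maternal risk factors, delivery-truncated visit schedules, and realistic
missing data.  Every downstream stage of the package (normogram fitting,
imputation, prediction modelling, screening) is exercised on these cohorts.

The generative model for mean arterial pressure (MAP, mm Hg) of woman *i*
at gestational age *t* (weeks) is

    MAP_i(t) = m_s(t) + offset(covariates_i) + z(t)' b_i + ramp_i(t) + e_it

where ``m_s`` is a per-parity-stratum restricted-cubic-spline population
curve, ``z(t) = (1, t, s1(t))`` spans a random intercept and two random
trajectory-shape coefficients with unstructured covariance G, ``ramp_i``
is a late-gestation pressure rise applied to pre-eclamptic pregnancies
before clinical onset, and ``e_it`` is i.i.d. Gaussian residual noise.
Systolic/diastolic pairs are back-generated from MAP through a
pulse-pressure model so that (SBP + 2 DBP)/3 reproduces the latent MAP.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .splines import DEFAULT_KNOTS, rcs_basis

BMI_CATEGORIES = ("underweight", "normal", "overweight", "obese")
PARITY_LEVELS = ("0", "1", "2+")

# Anchor points (weeks, mm Hg) of the population MAP curve for a
# reference-cell nulliparous non-smoker of normal BMI: mid-pregnancy nadir
# near 20 weeks then an accelerating rise to term.
_ANCHOR_GA = np.array([8, 11, 14, 16, 18, 20, 22, 25, 28, 31, 34, 36, 38, 40.0])
_ANCHOR_MAP = np.array(
    [81.7, 81.4, 81.0, 80.7, 80.4, 80.1, 80.3, 80.7, 81.2, 81.9, 82.8, 84.0, 85.3, 86.8]
)


def _anchor_beta(knots, shift: float = 0.0) -> np.ndarray:
    """Least-squares projection of the anchor curve onto (1, rcs basis)."""
    X = np.column_stack([np.ones(_ANCHOR_GA.size), rcs_basis(_ANCHOR_GA, knots)])
    beta, *_ = np.linalg.lstsq(X, _ANCHOR_MAP + shift, rcond=None)
    return beta


@dataclass
class BPMeasurement:
    """One routine antenatal blood-pressure reading."""

    ga: float  # weeks, continuous
    sbp: float  # mm Hg
    dbp: float  # mm Hg
    proteinuria_1plus: bool = False

    @property
    def map(self) -> float:
        return (self.sbp + 2.0 * self.dbp) / 3.0


@dataclass
class Pregnancy:
    """One pregnancy: covariates, visit series, delivery and outcomes."""

    id: str
    bmi: float
    height: float
    age: float
    parity: str  # "0", "1", "2+"
    smoking: bool
    essential_htn: bool
    prev_gest_htn: bool
    diabetes: bool
    prev_gest_diab: bool
    nonwhite: bool
    visits: list = field(default_factory=list)
    ga_delivery: float = np.nan
    birthweight: float = np.nan
    pe: Optional[bool] = None
    preterm: Optional[bool] = None
    sga: Optional[bool] = None
    # latent quantities kept for truth-recovery tests
    latent_map: list = field(default_factory=list)
    pe_onset: float = np.nan

    @property
    def bmi_category(self) -> str:
        if np.isnan(self.bmi):
            return "missing"
        if self.bmi < 18.5:
            return "underweight"
        if self.bmi < 25.0:
            return "normal"
        if self.bmi < 30.0:
            return "overweight"
        return "obese"

    @property
    def age_ge35(self) -> bool:
        return self.age >= 35


@dataclass
class TrajectoryParams:
    """Population trajectory and random-effect structure of the generator."""

    knots: tuple = DEFAULT_KNOTS
    # fixed population curves per parity stratum (intercept + 4 spline terms)
    beta_nulliparous: np.ndarray = None
    beta_multiparous: np.ndarray = None
    # constant covariate offsets, mm Hg (centred internally at generation)
    offsets: dict = field(default_factory=lambda: {
        "underweight": -1.5, "overweight": 2.5, "obese": 5.0,
        "smoking": -1.5, "essential_htn": 7.0, "prev_gest_htn": 2.0,
    })
    re_sd: tuple = (7.2, 0.18, 0.12)          # (intercept, linear, spline-1)
    re_corr: tuple = (-0.6, 0.1, -0.2)        # (01, 02, 12)
    residual_sd: float = 5.3                  # mm Hg
    pulse_pressure_mean: float = 45.0         # mm Hg
    pulse_pressure_sd: float = 5.0
    pe_ramp_rate: float = 1.5                 # mm Hg / week in the ramp window
    pe_ramp_lead: float = 5.0                 # ramp starts this many weeks before onset

    def __post_init__(self):
        if self.beta_nulliparous is None:
            self.beta_nulliparous = _anchor_beta(self.knots, 0.4)
        if self.beta_multiparous is None:
            self.beta_multiparous = _anchor_beta(self.knots, -0.6)
        if self.residual_sd <= 0:
            raise ValueError("residual SD must be positive")

    def random_effect_cov(self) -> np.ndarray:
        s = np.asarray(self.re_sd, dtype=float)
        r01, r02, r12 = self.re_corr
        C = np.array([[1.0, r01, r02], [r01, 1.0, r12], [r02, r12, 1.0]])
        G = C * np.outer(s, s)
        if not np.all(np.linalg.eigvalsh((G + G.T) / 2) >= -1e-10):
            raise ValueError("random-effect covariance is not positive semi-definite")
        return G

    def curve(self, ga, parity: str) -> np.ndarray:
        beta = self.beta_nulliparous if parity == "0" else self.beta_multiparous
        X = np.column_stack([np.ones(np.size(ga)), np.atleast_2d(rcs_basis(ga, self.knots))])
        return X @ beta


@dataclass
class PEMechanism:
    """Pre-eclampsia risk model: trajectory features plus risk factors.

    Risk is logistic in the woman's random intercept (mm Hg above her
    stratum curve) and post-nadir slope deviation (mm Hg/week), with
    classical maternal risk-factor log odds.  The intercept is solved at
    generation time so the realized prevalence hits the configured target.
    """

    baseline_map_coef: float = 0.17   # log-odds per mm Hg of random intercept
    slope_coef: float = 9.0           # log-odds per mm Hg/week slope deviation
    covariate_logodds: dict = field(default_factory=lambda: {
        "parity_1": -1.65, "parity_2+": -1.43, "bmi_per_unit": 0.18,
        "essential_htn": 1.95, "diabetes": 3.3, "prev_gest_htn": 0.9,
        "prev_gest_diab": 1.35, "smoking": -0.9, "nonwhite": 0.68,
        "age_ge35": 0.53, "height_per_cm": -0.03,
    })
    # clinical onset precedes delivery by a short interval: pre-eclampsia
    # is managed by delivering the baby, so diagnosis-to-delivery lags are
    # drawn uniformly from this range (weeks)
    onset_lag_range: tuple = (2.5, 6.5)
    # affected pregnancies are induced rather than left to run far past
    # term; term deliveries of cases are capped at this gestation
    pe_delivery_cap: float = 40.5
    proteinuria_p_after_onset: float = 0.9
    proteinuria_p_background: float = 0.01


@dataclass
class MissingnessConfig:
    """MAR missingness: visit drop-out plus per-covariate missing cells."""

    visit_p: float = 0.05
    visit_p_late: Optional[float] = None   # override for visits after 18 weeks
    covariate_p: dict = field(default_factory=lambda: {
        "bmi": 0.12, "height": 0.06, "age": 0.01, "smoking": 0.05,
        "essential_htn": 0.05, "prev_gest_htn": 0.05, "diabetes": 0.03,
        "prev_gest_diab": 0.03, "nonwhite": 0.04,
    })
    # MAR shift: log-odds increments for missingness given observed features
    mar_smoking_logodds: float = 0.5
    mar_age_slope: float = -0.02      # per year above/below 28

    def validate(self):
        probs = [self.visit_p, *self.covariate_p.values()]
        if self.visit_p_late is not None:
            probs.append(self.visit_p_late)
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("missingness probabilities must lie in [0, 1]")


@dataclass
class GeneratorConfig:
    """Full specification of one synthetic cohort."""

    n_pregnancies: int = 13000
    seed: int = 0
    label: str = "alspac_like"
    # visit schedule: booking uniform in [8, 17), then nominal weeks + jitter
    booking_window: tuple = (8.0, 17.0)
    nominal_visits: tuple = (20.0, 25.0, 28.0, 31.0, 34.0, 36.0, 38.0, 40.0)
    visit_jitter_sd: float = 0.7
    # prevalence targets
    pe_prevalence: float = 317 / 12996
    preterm_prevalence: float = 0.054
    sga_centile: float = 0.10
    preterm_or_pe: float = 7.0
    # covariate marginals
    bmi_category_p: tuple = (0.059, 0.724, 0.164, 0.054)
    parity_p: tuple = (0.459, 0.344, 0.197)
    smoking_p: float = 0.259
    essential_htn_p: float = 0.037
    prev_gest_htn_p: float = 0.090
    diabetes_p: float = 0.004
    prev_gest_diab_p: float = 0.005
    nonwhite_p: float = 0.028
    age_mean: float = 27.9
    age_sd: float = 5.0
    height_mean: float = 163.9
    height_sd: float = 6.7
    # birthweight mechanism
    bw_pe_shift: float = -290.0       # g, beyond the gestational-age effect
    bw_smoking_shift: float = -170.0
    bw_residual_sd: float = 430.0
    # optional clinical-diagnosis label noise for PE (validation cohorts)
    pe_label_sensitivity: Optional[float] = None
    pe_label_specificity: Optional[float] = None
    trajectory: TrajectoryParams = field(default_factory=TrajectoryParams)
    pe_mechanism: PEMechanism = field(default_factory=PEMechanism)
    missingness: MissingnessConfig = field(default_factory=MissingnessConfig)

    def validate(self):
        for p in (self.pe_prevalence, self.preterm_prevalence, self.sga_centile,
                  self.smoking_p, self.essential_htn_p, self.prev_gest_htn_p,
                  self.diabetes_p, self.prev_gest_diab_p, self.nonwhite_p):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        self.trajectory.random_effect_cov()  # raises if non-PSD
        self.missingness.validate()


def alspac_like_config(n: int = 13000, seed: int = 0) -> GeneratorConfig:
    """Development-cohort defaults (large UK birth cohort, early 1990s)."""
    return GeneratorConfig(n_pregnancies=n, seed=seed, label="alspac_like")


def sws_like_config(n: int = 3005, seed: int = 1) -> GeneratorConfig:
    """Validation-cohort defaults (smaller UK cohort, later recruitment).

    Differs in covariate mix (more overweight/obese, older, fewer smokers,
    many more with previous gestational hypertension) and PE prevalence.
    """
    return GeneratorConfig(
        n_pregnancies=n, seed=seed, label="sws_like",
        pe_prevalence=88 / 3005,
        preterm_prevalence=0.056,
        bmi_category_p=(0.027, 0.576, 0.266, 0.131),
        parity_p=(0.507, 0.330, 0.163),
        smoking_p=0.166,
        essential_htn_p=0.026,
        prev_gest_htn_p=0.376,
        diabetes_p=0.006,
        prev_gest_diab_p=0.083,
        nonwhite_p=0.046,
        age_mean=30.6, age_sd=3.8,
        height_mean=163.2, height_sd=6.4,
    )


def _solve_intercept(lp: np.ndarray, target: float) -> float:
    """Intercept c with mean(expit(c + lp)) == target."""
    f = lambda c: expit(c + lp).mean() - target
    return brentq(f, -30.0, 30.0, xtol=1e-10)


def _slope_deriv_weight(traj: TrajectoryParams, at: float = 30.0) -> float:
    """d s1/dt at the post-nadir reference age (finite difference)."""
    h = 1e-5
    s = rcs_basis(np.array([at - h, at + h]), traj.knots)[:, 1]
    return float((s[1] - s[0]) / (2 * h))


def generate_cohort(config: GeneratorConfig) -> list:
    """Generate a cohort of :class:`Pregnancy` records.

    Reproducible given ``config.seed``.  Outcome-model intercepts are solved
    against the realized covariate/random-effect draws so that cohort
    prevalences match the configured targets up to binomial noise.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_pregnancies
    traj = config.trajectory
    mech = config.pe_mechanism

    # --- covariates -------------------------------------------------------
    # printed cohort percentages can carry rounding slack; renormalize
    p_bmi = np.asarray(config.bmi_category_p, dtype=float)
    p_bmi = p_bmi / p_bmi.sum()
    p_par = np.asarray(config.parity_p, dtype=float)
    p_par = p_par / p_par.sum()
    bmi_cat = rng.choice(4, size=n, p=p_bmi)
    bmi = np.empty(n)
    bmi[bmi_cat == 0] = rng.uniform(16.0, 18.4, (bmi_cat == 0).sum())
    bmi[bmi_cat == 1] = rng.uniform(18.5, 24.9, (bmi_cat == 1).sum())
    bmi[bmi_cat == 2] = rng.uniform(25.0, 29.9, (bmi_cat == 2).sum())
    bmi[bmi_cat == 3] = 30.0 + rng.exponential(2.8, (bmi_cat == 3).sum())
    parity = rng.choice(3, size=n, p=p_par)
    smoking = rng.random(n) < config.smoking_p
    ess_htn = rng.random(n) < config.essential_htn_p
    prev_gh = rng.random(n) < config.prev_gest_htn_p
    diab = rng.random(n) < config.diabetes_p
    prev_gd = rng.random(n) < config.prev_gest_diab_p
    nonwhite = rng.random(n) < config.nonwhite_p
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 15, 45)
    height = np.clip(rng.normal(config.height_mean, config.height_sd, n), 124, 201)

    # --- trajectory random effects ---------------------------------------
    G = traj.random_effect_cov()
    if np.allclose(G, 0.0):
        b = np.zeros((n, 3))
    else:
        b = rng.multivariate_normal(np.zeros(3), G, size=n, method="eigh")
    w1 = _slope_deriv_weight(traj)
    slope_dev = b[:, 1] + w1 * b[:, 2]

    # centred covariate offsets: overall curve stays anchored at the
    # configured population means
    off = traj.offsets
    cat_names = np.array(BMI_CATEGORIES)[bmi_cat]
    offset = (
        np.where(cat_names == "underweight", off.get("underweight", 0.0), 0.0)
        + np.where(cat_names == "overweight", off.get("overweight", 0.0), 0.0)
        + np.where(cat_names == "obese", off.get("obese", 0.0), 0.0)
        + smoking * off.get("smoking", 0.0)
        + ess_htn * off.get("essential_htn", 0.0)
        + prev_gh * off.get("prev_gest_htn", 0.0)
    )
    p_u, _, p_o, p_ob = config.bmi_category_p
    mean_offset = (
        p_u * off.get("underweight", 0.0) + p_o * off.get("overweight", 0.0)
        + p_ob * off.get("obese", 0.0) + config.smoking_p * off.get("smoking", 0.0)
        + config.essential_htn_p * off.get("essential_htn", 0.0)
        + config.prev_gest_htn_p * off.get("prev_gest_htn", 0.0)
    )
    offset -= mean_offset

    # --- pre-eclampsia ----------------------------------------------------
    cl = mech.covariate_logodds
    lp_pe = (
        mech.baseline_map_coef * b[:, 0]
        + mech.slope_coef * slope_dev
        + np.where(parity == 1, cl.get("parity_1", 0.0), 0.0)
        + np.where(parity == 2, cl.get("parity_2+", 0.0), 0.0)
        + cl.get("bmi_per_unit", 0.0) * (bmi - 23.0)
        + cl.get("height_per_cm", 0.0) * (height - 164.0)
        + ess_htn * cl.get("essential_htn", 0.0)
        + diab * cl.get("diabetes", 0.0)
        + prev_gh * cl.get("prev_gest_htn", 0.0)
        + prev_gd * cl.get("prev_gest_diab", 0.0)
        + smoking * cl.get("smoking", 0.0)
        + nonwhite * cl.get("nonwhite", 0.0)
        + (age >= 35) * cl.get("age_ge35", 0.0)
    )
    if config.pe_prevalence > 0 and (mech.baseline_map_coef or mech.slope_coef
                                     or np.ptp(lp_pe) > 0):
        c_pe = _solve_intercept(lp_pe, config.pe_prevalence)
    else:
        c_pe = np.log(config.pe_prevalence / (1 - config.pe_prevalence)) if config.pe_prevalence > 0 else -np.inf
    pe = rng.random(n) < expit(c_pe + lp_pe)

    # --- preterm flag, then delivery GA consistent with it ----------------
    lp_pt = np.log(config.preterm_or_pe) * pe.astype(float)
    c_pt = _solve_intercept(lp_pt, config.preterm_prevalence)
    preterm = rng.random(n) < expit(c_pt + lp_pt)
    ga_del = np.where(
        preterm,
        np.clip(rng.normal(34.8 - 0.8 * pe, 1.8, n), 28.0, 36.9),
        np.clip(rng.normal(40.0 - 0.6 * pe, 1.1, n), 37.0, 43.0),
    )
    ga_del = np.where(pe, np.minimum(ga_del, mech.pe_delivery_cap), ga_del)

    # PE clinical onset: a short lag before delivery, floored after 20 weeks
    lag = rng.uniform(*mech.onset_lag_range, n)
    onset = np.clip(ga_del - lag, 20.5, ga_del)

    # --- birthweight ------------------------------------------------------
    short = 40.0 - np.minimum(ga_del, 40.0)
    bw_mean = 3480.0 - 160.0 * short - 3.5 * short ** 2 + 6.0 * (height - 164.0)
    bw = bw_mean + config.bw_pe_shift * pe + config.bw_smoking_shift * smoking \
        + rng.normal(0.0, config.bw_residual_sd, n)
    bw = np.clip(bw, 350.0, 6500.0)

    # internal standardisation for the generator's own SGA flag
    X = np.column_stack([np.ones(n), ga_del, ga_del ** 2, ga_del ** 3])
    resid = bw - X @ np.linalg.lstsq(X, bw, rcond=None)[0]
    sga = resid < np.quantile(resid, config.sga_centile)

    # --- visit series -----------------------------------------------------
    cohort = []
    width = len(str(n))
    for i in range(n):
        booking = rng.uniform(*config.booking_window)
        gas = [booking]
        for nominal in config.nominal_visits:
            g = nominal + rng.normal(0.0, config.visit_jitter_sd)
            if booking < g < ga_del[i]:
                gas.append(g)
        gas = np.sort(np.asarray(gas))
        mean_curve = traj.curve(gas, "0" if parity[i] == 0 else "1")
        Z = np.column_stack([np.ones(gas.size), gas, rcs_basis(gas, traj.knots)[:, 1]])
        latent = mean_curve + offset[i] + Z @ b[i]
        if pe[i]:
            ramp_start = onset[i] - traj.pe_ramp_lead
            latent = latent + traj.pe_ramp_rate * np.clip(gas - ramp_start, 0.0, 25.0)
        latent = latent + rng.normal(0.0, traj.residual_sd, gas.size)

        pp = np.maximum(rng.normal(traj.pulse_pressure_mean, traj.pulse_pressure_sd,
                                   gas.size), 20.0)
        sbp = np.round(latent + 2.0 * pp / 3.0)
        dbp = np.round(latent - pp / 3.0)

        visits = []
        for j, g in enumerate(gas):
            if pe[i] and g > onset[i]:
                prot = rng.random() < mech.proteinuria_p_after_onset
            else:
                prot = rng.random() < mech.proteinuria_p_background
            visits.append(BPMeasurement(ga=float(g), sbp=float(sbp[j]),
                                        dbp=float(dbp[j]), proteinuria_1plus=bool(prot)))

        label_pe = bool(pe[i])
        if config.pe_label_sensitivity is not None:
            if label_pe:
                label_pe = bool(rng.random() < config.pe_label_sensitivity)
            else:
                label_pe = bool(rng.random() > (config.pe_label_specificity or 1.0))

        cohort.append(Pregnancy(
            id=f"{config.label}-{i:0{width}d}",
            bmi=float(bmi[i]), height=float(height[i]), age=float(age[i]),
            parity=PARITY_LEVELS[parity[i]], smoking=bool(smoking[i]),
            essential_htn=bool(ess_htn[i]), prev_gest_htn=bool(prev_gh[i]),
            diabetes=bool(diab[i]), prev_gest_diab=bool(prev_gd[i]),
            nonwhite=bool(nonwhite[i]),
            visits=visits, ga_delivery=float(ga_del[i]), birthweight=float(bw[i]),
            pe=label_pe, preterm=bool(preterm[i]), sga=bool(sga[i]),
            latent_map=[float(v) for v in latent], pe_onset=float(onset[i]),
        ))
    return cohort


def apply_missingness(cohort: list, config: GeneratorConfig, seed=None) -> list:
    """Return a copy of the cohort with MAR missingness applied.

    Visit records are dropped and covariate cells blanked (NaN) with
    probabilities that depend on observed covariates only (smoking status
    and maternal age), never on the value being removed.  The input cohort
    is left untouched for truth-recovery comparisons.
    """
    mc = config.missingness
    mc.validate()
    rng = np.random.default_rng(config.seed + 104729 if seed is None else seed)
    out = []
    for p in cohort:
        q = dataclasses.replace(p)
        q.visits = list(p.visits)
        # MAR tilt on the logit scale from observed covariates
        smoking = bool(p.smoking) if p.smoking is not None else False
        age = p.age if np.isfinite(p.age) else 28.0
        tilt = mc.mar_smoking_logodds * smoking + mc.mar_age_slope * (age - 28.0)

        def p_drop(base_p):
            if base_p <= 0.0:
                return 0.0
            if base_p >= 1.0:
                return 1.0
            return float(expit(np.log(base_p / (1 - base_p)) + tilt))

        kept = []
        for v in q.visits:
            base_p = mc.visit_p if (mc.visit_p_late is None or v.ga <= 18.0) \
                else mc.visit_p_late
            if rng.random() >= p_drop(base_p):
                kept.append(v)
        q.visits = kept
        for name, pc in mc.covariate_p.items():
            if pc <= 0:
                continue
            if rng.random() < p_drop(pc):
                if name in ("bmi", "height", "age"):
                    setattr(q, name, float("nan"))
                else:
                    setattr(q, name, None)
        out.append(q)
    return out
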
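"""Synthetic patients, cohorts and two-arm trials.

The generator turns the dynamical model into longitudinal study data with no
external inputs: each patient owns a true coefficient vector drawn from the
priors, parametric injury signals, baseline reflex biomarkers, and noisy
scheduled symptom assessments on a 0-100 scale.

Observation model
-----------------
The model state itself is monotone (adaptability never recovers), while
post-concussion symptom scores in recovering patients decay roughly
exponentially.  Symptoms therefore track a mixture of the *instantaneous*
total load (weight ``w_load``, normalized by its value at injury, so it
decays with the injury input) and the *accumulated* adaptability loss
``1 - N(t)`` (weight ``w_N``); entrapped patients carry an additional
persistent symptom floor.  Observation noise is Gaussian with variance equal
to ``noise_fraction / (1 - noise_fraction)`` times the variance of the
noiseless scores, so noise contributes ``noise_fraction`` of the total score
variance.

Risk structure
--------------
Baseline biomarkers define exposure strata: VOR gain asymmetry > 20%
(targeting a 3-fold risk of persistent symptoms at three months), >= 2
re-emergent primitive reflexes (4-fold), and an abnormal Sensory
Organization Test composite < 60 (2-fold symptom burden).  The generator
realizes these as follows: each patient is assigned a *mild* or *severe*
injury class, with the severe probability chosen per (VOR, reflex) stratum
so that the marginal stratum risk ratios equal their targets in
expectation.  The class-conditional persistence probabilities needed for
that calibration are estimated from an internal pilot simulation run per
stratum, which keeps the mechanistic chain (biomarkers -> parameters ->
dynamics -> outcome) intact — no outcome labels are ever flipped post hoc.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.optimize import brentq

from ._errors import ConfigError, DomainError
from .model import (
    InjurySignal, ModelConfig, NerdParameters, Trajectory, integrate_trajectory,
)
from .priors import PriorSet, default_priors

__all__ = [
    "ObservationModel", "BiomarkerModel", "Biomarkers", "PatientRecord",
    "Cohort", "TrialConfig", "CohortCalibration",
    "assessment_schedule", "noiseless_scores", "observe_symptoms",
    "assign_biomarkers", "phenotype_recovery", "generate_cohort",
    "generate_trial", "synthesize_patient", "persistence_score",
]


@dataclass(frozen=True)
class ObservationModel:
    """Mapping from a model trajectory to noisy 0-100 symptom scores."""

    S_max: float = 100.0
    w_load: float = 0.8
    w_N: float = 0.2
    noise_fraction: float = 0.2
    floor_persistent: float = 10.0

    def __post_init__(self):
        if abs(self.w_load + self.w_N - 1.0) > 1e-9:
            raise ConfigError("w_load + w_N must equal 1")
        if self.w_load < 0 or self.w_N < 0:
            raise ConfigError("mixture weights must be nonnegative")
        if not (0.0 <= self.noise_fraction < 1.0):
            raise ConfigError("noise_fraction must lie in [0, 1)")
        if self.S_max <= 0:
            raise ConfigError("S_max must be positive")


@dataclass(frozen=True)
class BiomarkerModel:
    """Baseline biomarker thresholds, risk targets, and parameter couplings.

    ``rr_vor`` / ``rr_reflex`` are the target risk ratios of three-month
    symptom persistence across the VOR-asymmetry and primitive-reflex
    strata; ``burden_ratio_sot`` is the target ratio of mean symptom burden
    across the SOT stratum.  ``p_vor`` / ``p_reflex`` / ``p_sot`` are the
    marginal exposure prevalences and ``base_rate`` the persistence risk in
    the doubly-unexposed stratum.  ``coupling_alpha`` (``coupling_rho``)
    tilts VOR (reflex-count) exposure probability with the patient's alpha
    (rho), linking biomarkers to the mechanistic parameters.
    """

    vor_threshold: float = 20.0
    rr_vor: float = 3.0
    sot_threshold: float = 60.0
    burden_ratio_sot: float = 2.0
    reflex_count_threshold: int = 2
    rr_reflex: float = 4.0
    p_vor: float = 0.25
    p_reflex: float = 0.20
    p_sot: float = 0.12
    base_rate: float = 0.06
    coupling_alpha: float = 1.2
    coupling_rho: float = 1.2

    def __post_init__(self):
        for name in ("rr_vor", "rr_reflex", "burden_ratio_sot"):
            if getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must exceed 1")
        if not (0.0 < self.vor_threshold < 100.0) or not (0.0 < self.sot_threshold < 100.0):
            raise ConfigError("biomarker thresholds must lie inside physiological ranges")
        for name in ("p_vor", "p_reflex", "p_sot", "base_rate"):
            if not (0.0 < getattr(self, name) < 1.0):
                raise ConfigError(f"{name} must lie in (0, 1)")


@dataclass(frozen=True)
class Biomarkers:
    vor_asym_pct: float
    sot_composite: float
    primitive_reflex_count: int


@dataclass(frozen=True)
class SeverityModel:
    """Injury-magnitude distributions for the mild and severe classes.

    Ranges are uniform draws in weeks-scaled injury units; the taus are
    exponential decay times of the injury inputs.  ``coupling`` tilts the
    effective magnitude with the patient's standardized (alpha, rho, eta)
    coordinates — vulnerable profiles (high alpha, high rho, low eta in the
    recovery-phenotype sense) sustain larger effective loads — capped to
    ``multiplier_range``.
    """

    mild_I0: Tuple[float, float] = (0.4, 1.2)
    mild_CI0: Tuple[float, float] = (0.1, 0.5)
    severe_I0: Tuple[float, float] = (8.0, 12.0)
    severe_CI0: Tuple[float, float] = (3.0, 5.0)
    tau_I: Tuple[float, float] = (2.0, 3.5)
    tau_CI: Tuple[float, float] = (2.5, 4.5)
    coupling: Tuple[float, float, float] = (0.35, 0.20, 0.35)  # (z_alpha, z_rho, -z_eta)
    multiplier_range: Tuple[float, float] = (0.4, 3.0)

    def multiplier(self, p: NerdParameters, priors: PriorSet) -> float:
        za = (p.alpha - priors["alpha"].mean) / priors["alpha"].sd
        zr = (p.rho - priors["rho"].mean) / priors["rho"].sd
        ze = (p.eta - priors["eta"].mean) / priors["eta"].sd
        ca, cr, ce = self.coupling
        m = float(np.exp(ca * za + cr * zr - ce * ze))
        return float(np.clip(m, *self.multiplier_range))


#: Symptom score above which a patient still counts as symptomatic.
RECOVERY_CRITERION = 15.0
#: Assessments at or after this week define three-month persistence.
PERSISTENCE_FROM_WEEK = 12.0


@dataclass
class PatientRecord:
    id: int
    params: NerdParameters
    I: InjurySignal
    CI: InjurySignal
    severity: str
    biomarkers: Biomarkers
    schedule: np.ndarray
    scores: np.ndarray
    trajectory: Optional[Trajectory]
    persistent_at_3mo: bool
    persistence_score: float
    recovery_phenotype: str
    arm: Optional[str] = None

    @property
    def assessments(self) -> List[Tuple[float, float]]:
        return list(zip(self.schedule.tolist(), self.scores.tolist()))

    @property
    def baseline_score(self) -> float:
        return float(self.scores[0])

    def score_at(self, week: float) -> float:
        i = int(np.argmin(np.abs(self.schedule - week)))
        if abs(self.schedule[i] - week) > 1e-6:
            raise DomainError(f"no assessment at week {week}")
        return float(self.scores[i])


@dataclass
class Cohort:
    patients: List[PatientRecord]
    design: str
    seed: Optional[int] = None
    metadata: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    def __getitem__(self, i):
        return self.patients[i]


@dataclass(frozen=True)
class TrialConfig:
    """Two-arm reflex-targeted intervention trial design.

    The intervention mechanism multiplies the decay *rate* of both injury
    inputs (faster injury resolution under reflex-targeted therapy); the
    multiplier is calibrated internally so that the expected percent
    advantage in mean baseline-to-week-12 symptom reduction equals
    ``intervention_effect``.
    """

    n_per_arm: int = 40
    intervention_effect: float = 0.40
    mechanism: str = "decay_rate"
    duration_weeks: float = 12.0

    def __post_init__(self):
        if self.n_per_arm < 2:
            raise ConfigError("n_per_arm must be >= 2")
        if self.intervention_effect < 0:
            raise ConfigError("intervention_effect must be >= 0")
        if self.mechanism != "decay_rate":
            raise ConfigError(f"unknown intervention mechanism {self.mechanism!r}")


# ---------------------------------------------------------------------------
# schedules and observation
# ---------------------------------------------------------------------------

def assessment_schedule(design: str) -> np.ndarray:
    """Assessment times in weeks for a named study design.

    ``protocol4``: weekly for 12 weeks then monthly to 6 months
    (weeks 0..12, 16, 20, 24).  ``protocol1``: baseline then months 1, 3, 6.
    """
    if design == "protocol4":
        return np.concatenate([np.arange(13.0), [16.0, 20.0, 24.0]])
    if design == "protocol1":
        return np.array([0.0, 4.33, 13.0, 26.0])
    raise ConfigError(f"unknown study design {design!r}")


def noiseless_scores(traj: Trajectory, obs: ObservationModel, schedule) -> np.ndarray:
    """Noise-free symptom scores at the scheduled times."""
    schedule = np.asarray(schedule, dtype=float)
    if schedule.size and schedule.max() > traj.times[-1] + 1e-9:
        raise DomainError("assessment schedule extends beyond the trajectory horizon")
    load0 = traj.total_load[0]
    load_rel = traj.interp_total_load(schedule) / load0 if load0 > 0 else np.zeros_like(schedule)
    n_t = traj.interp_N(schedule)
    s = obs.S_max * (obs.w_load * load_rel + obs.w_N * (1.0 - n_t))
    if traj.entrapped:
        s = s + obs.floor_persistent
    return np.clip(s, 0.0, obs.S_max)


def observe_symptoms(traj: Trajectory, obs: ObservationModel, schedule, seed=None) -> np.ndarray:
    """Noisy scheduled assessments; deterministic given the seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    clean = noiseless_scores(traj, obs, schedule)
    var = float(np.var(clean))
    sd = np.sqrt(obs.noise_fraction / (1.0 - obs.noise_fraction) * var)
    noisy = clean + rng.normal(0.0, sd, size=clean.shape) if sd > 0 else clean.copy()
    return np.clip(noisy, 0.0, obs.S_max)


def persistence_score(schedule, scores, from_week: float = PERSISTENCE_FROM_WEEK) -> float:
    """Mean symptom score over assessments at or after ``from_week``.

    Three-month persistence is judged on sustained late symptoms rather than
    a single noisy reading: the week-13 status is operationalized as the
    average of all assessments from week 12 onward.
    """
    schedule = np.asarray(schedule, dtype=float)
    scores = np.asarray(scores, dtype=float)
    late = scores[schedule >= from_week - 1e-9]
    return float(late.mean()) if late.size else float(scores[-1])


# ---------------------------------------------------------------------------
# biomarkers
# ---------------------------------------------------------------------------

def _exposure_prob(base: float, coupling: float, value: float, center: float) -> float:
    return float(np.clip(base + coupling * (value - center), 0.01, 0.99))


def assign_biomarkers(
    p: NerdParameters,
    bm: BiomarkerModel,
    seed=None,
    priors: Optional[PriorSet] = None,
    severe: Optional[bool] = None,
    sot_exposure_probs: Optional[Tuple[float, float]] = None,
) -> Biomarkers:
    """Draw baseline reflex biomarkers coupled to the patient's parameters.

    VOR-asymmetry exceedance of the 20% threshold is positively coupled to
    ``alpha``; the primitive-reflex count is coupled to ``rho``; the SOT
    composite is negatively coupled to ``rho`` and, when the injury class is
    known, abnormal SOT is more frequent among severely injured patients
    (probabilities supplied by the cohort calibration).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    priors = priors or default_priors()
    a_mean, r_mean = priors["alpha"].mean, priors["rho"].mean

    vor_exposed = rng.random() < _exposure_prob(bm.p_vor, bm.coupling_alpha, p.alpha, a_mean)
    if vor_exposed:
        vor = bm.vor_threshold + rng.exponential(5.0 + 15.0 * max(p.alpha - 0.3, 0.0))
    else:
        vor = bm.vor_threshold * rng.beta(2.0, 5.0)

    reflex_exposed = rng.random() < _exposure_prob(bm.p_reflex, bm.coupling_rho, p.rho, r_mean)
    if reflex_exposed:
        count = bm.reflex_count_threshold + rng.poisson(0.5 + p.rho)
    else:
        count = rng.binomial(
            bm.reflex_count_threshold - 1,
            float(np.clip(0.25 + 0.5 * (p.rho - r_mean), 0.02, 0.98)),
        )

    if sot_exposure_probs is not None and severe is not None:
        p_sot = sot_exposure_probs[1] if severe else sot_exposure_probs[0]
    else:
        p_sot = _exposure_prob(bm.p_sot, bm.coupling_rho * 0.5, p.rho, r_mean)
    if rng.random() < p_sot:
        sot = bm.sot_threshold - rng.exponential(8.0 + 10.0 * max(p.rho - 0.4, 0.0))
        sot = float(np.clip(sot, 0.0, bm.sot_threshold - 0.5))
    else:
        sot = bm.sot_threshold + (100.0 - bm.sot_threshold) * rng.beta(2.5, 1.5)
        sot = float(np.clip(sot - 5.0 * (p.rho - r_mean), bm.sot_threshold + 0.5, 100.0))

    return Biomarkers(
        vor_asym_pct=float(min(vor, 100.0)),
        sot_composite=sot,
        primitive_reflex_count=int(count),
    )


def phenotype_recovery(p: NerdParameters, priors: PriorSet) -> str:
    """Recovery phenotype from the parameter profile.

    Slow (> 6 months): alpha above its prior 75th percentile and eta below
    its 25th.  Fast (< 6 weeks): rho below its 25th percentile and eta above
    its 75th.  Otherwise intermediate.
    """
    if p.alpha > priors["alpha"].ppf(0.75) and p.eta < priors["eta"].ppf(0.25):
        return "slow"
    if p.rho < priors["rho"].ppf(0.25) and p.eta > priors["eta"].ppf(0.75):
        return "fast"
    return "intermediate"


# ---------------------------------------------------------------------------
# patient simulation
# ---------------------------------------------------------------------------

def _draw_signals(severe: bool, mult: float, sev: SeverityModel, rng) -> Tuple[InjurySignal, InjurySignal]:
    i_rng = sev.severe_I0 if severe else sev.mild_I0
    c_rng = sev.severe_CI0 if severe else sev.mild_CI0
    I = InjurySignal("exp_decay", magnitude=rng.uniform(*i_rng) * mult, tau=rng.uniform(*sev.tau_I))
    CI = InjurySignal("exp_decay", magnitude=rng.uniform(*c_rng) * mult, tau=rng.uniform(*sev.tau_CI))
    return I, CI


def _simulate_outcome(params, I, CI, cfg, obs, schedule, rng, keep_traj=False):
    traj = integrate_trajectory(params, I, CI, cfg, horizon=float(np.max(schedule)))
    scores = observe_symptoms(traj, obs, schedule, seed=rng)
    return (traj if keep_traj else None), scores


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

@dataclass
class CohortCalibration:
    """Pilot-estimated quantities that pin the printed risk structure.

    ``p_severe`` maps each (vor_exposed, reflex_exposed) stratum to the
    probability of the severe injury class; ``persist_severe`` /
    ``persist_mild`` are the pilot class-conditional persistence
    probabilities per stratum; ``sot_probs`` are P(abnormal SOT | mild) and
    P(abnormal SOT | severe).
    """

    risk_targets: Dict[Tuple[int, int], float]
    p_severe: Dict[Tuple[int, int], float]
    persist_severe: Dict[Tuple[int, int], float]
    persist_mild: Dict[Tuple[int, int], float]
    prevalence_vor: float
    prevalence_reflex: float
    sot_probs: Tuple[float, float]
    sot_ratio_achievable: bool
    n_pilot: int


def _solve_stratum_risks(bm: BiomarkerModel, p_v: float, p_r: float) -> Dict[Tuple[int, int], float]:
    """Additive stratum risks hitting both marginal risk-ratio targets.

    With risks ``r(xv, xr) = r0 + d1*xv + d2*xr`` and independent exposures,
    the marginal risk ratio across each stratum is exact by construction;
    the pair (d1, d2) solves the two marginal constraints.
    """
    r0 = bm.base_rate
    kv, kr = bm.rr_vor - 1.0, bm.rr_reflex - 1.0
    denom = 1.0 - kv * kr * p_v * p_r
    if denom <= 0:
        raise ConfigError("infeasible risk-ratio calibration: exposure prevalences too high")
    d1 = kv * r0 * (1.0 + kr * p_r) / denom
    d2 = kr * (r0 + d1 * p_v)
    targets = {
        (0, 0): r0,
        (1, 0): r0 + d1,
        (0, 1): r0 + d2,
        (1, 1): r0 + d1 + d2,
    }
    if targets[(1, 1)] >= 1.0:
        raise ConfigError("infeasible risk-ratio calibration: saturated joint-stratum risk")
    return targets


def _calibrate(priors, bm, obs, cfg, sev, schedule, n_pilot, rng) -> CohortCalibration:
    from .priors import sample_parameters

    params = sample_parameters(priors, n_pilot, seed=rng)
    a_mean, r_mean = priors["alpha"].mean, priors["rho"].mean
    strata = np.empty((n_pilot, 2), dtype=int)
    persist = np.empty((n_pilot, 2))  # columns: mild, severe
    burden = np.empty((n_pilot, 2))
    for i, p in enumerate(params):
        strata[i, 0] = rng.random() < _exposure_prob(bm.p_vor, bm.coupling_alpha, p.alpha, a_mean)
        strata[i, 1] = rng.random() < _exposure_prob(bm.p_reflex, bm.coupling_rho, p.rho, r_mean)
        mult = sev.multiplier(p, priors)
        for j, severe in enumerate((False, True)):
            I, CI = _draw_signals(severe, mult, sev, rng)
            _, scores = _simulate_outcome(p, I, CI, cfg, obs, schedule, rng)
            persist[i, j] = persistence_score(schedule, scores) > RECOVERY_CRITERION
            burden[i, j] = scores.mean()

    p_v_hat = float(strata[:, 0].mean())
    p_r_hat = float(strata[:, 1].mean())
    targets = _solve_stratum_risks(bm, p_v_hat, p_r_hat)

    p_severe, a_hat, b_hat = {}, {}, {}
    for s in targets:
        mask = (strata[:, 0] == s[0]) & (strata[:, 1] == s[1])
        if mask.sum() < 20:
            raise ConfigError(f"pilot too small to calibrate stratum {s}: n={int(mask.sum())}")
        b = float(persist[mask, 0].mean())
        a = float(persist[mask, 1].mean())
        a_hat[s], b_hat[s] = a, b
        if a - b < 0.05:
            raise ConfigError(f"stratum {s}: injury classes do not separate persistence (a={a:.3f}, b={b:.3f})")
        ps = (targets[s] - b) / (a - b)
        if ps < -0.02 or ps > 1.02:
            raise ConfigError(
                f"infeasible calibration in stratum {s}: target risk {targets[s]:.3f} "
                f"outside achievable [{b:.3f}, {a:.3f}]"
            )
        p_severe[s] = float(np.clip(ps, 0.0, 1.0))

    # SOT stratum: abnormal-composite probability per injury class chosen so
    # the mean-burden ratio across the SOT stratum hits its target.
    w = np.array([((strata[:, 0] == s[0]) & (strata[:, 1] == s[1])).mean() for s in targets])
    f_sev = float(sum(wi * p_severe[s] for wi, s in zip(w, targets)))
    b_mild = float(burden[:, 0].mean())
    b_sev = float(burden[:, 1].mean())
    total_burden = f_sev * b_sev + (1.0 - f_sev) * b_mild
    p_sot, ratio = bm.p_sot, bm.burden_ratio_sot
    n1 = ratio * p_sot * total_burden / (1.0 - p_sot + ratio * p_sot)
    achievable = True
    if f_sev > 0 and b_sev > b_mild:
        q_sev = (n1 - p_sot * b_mild) / (f_sev * (b_sev - b_mild))
    else:
        q_sev, achievable = p_sot, False
    if not (0.0 <= q_sev <= 1.0):
        q_sev, achievable = float(np.clip(q_sev, 0.0, 1.0)), False
    q_mild = (p_sot - q_sev * f_sev) / (1.0 - f_sev) if f_sev < 1 else p_sot
    if not (0.0 <= q_mild <= 1.0):
        q_mild, achievable = float(np.clip(q_mild, 0.0, 1.0)), False

    return CohortCalibration(
        risk_targets=targets, p_severe=p_severe,
        persist_severe=a_hat, persist_mild=b_hat,
        prevalence_vor=p_v_hat, prevalence_reflex=p_r_hat,
        sot_probs=(q_mild, q_sev), sot_ratio_achievable=achievable,
        n_pilot=n_pilot,
    )


# ---------------------------------------------------------------------------
# cohort and trial generation
# ---------------------------------------------------------------------------

def generate_cohort(
    n: int,
    priors: Optional[PriorSet] = None,
    bm: Optional[BiomarkerModel] = None,
    obs: Optional[ObservationModel] = None,
    design: str = "protocol4",
    seed=None,
    cfg: Optional[ModelConfig] = None,
    severity: Optional[SeverityModel] = None,
    calibration: Optional[CohortCalibration] = None,
    n_pilot: int = 12_000,
    keep_trajectories: bool = False,
) -> Cohort:
    """Generate ``n`` synthetic patients with calibrated risk structure."""
    if n < 1:
        raise ConfigError("n must be >= 1")
    priors = priors or default_priors()
    bm = bm or BiomarkerModel()
    obs = obs or ObservationModel()
    cfg = cfg or ModelConfig()
    sev = severity or SeverityModel()
    schedule = assessment_schedule(design)

    ss = np.random.SeedSequence(seed)
    pilot_ss, main_ss = ss.spawn(2)
    if calibration is None:
        calibration = _calibrate(priors, bm, obs, cfg, sev, schedule,
                                 n_pilot, np.random.default_rng(pilot_ss))

    from .priors import sample_parameters

    rng = np.random.default_rng(main_ss)
    params_list = sample_parameters(priors, n, seed=rng)
    a_mean, r_mean = priors["alpha"].mean, priors["rho"].mean
    patients = []
    for pid, p in enumerate(params_list):
        vor_exp = rng.random() < _exposure_prob(bm.p_vor, bm.coupling_alpha, p.alpha, a_mean)
        ref_exp = rng.random() < _exposure_prob(bm.p_reflex, bm.coupling_rho, p.rho, r_mean)
        stratum = (int(vor_exp), int(ref_exp))
        severe = rng.random() < calibration.p_severe[stratum]
        mult = sev.multiplier(p, priors)
        I, CI = _draw_signals(severe, mult, sev, rng)
        biom = _draw_biomarkers_for_stratum(
            p, bm, rng, priors, vor_exp, ref_exp, severe, calibration.sot_probs
        )
        traj, scores = _simulate_outcome(p, I, CI, cfg, obs, schedule, rng,
                                         keep_traj=keep_trajectories)
        pscore = persistence_score(schedule, scores)
        patients.append(PatientRecord(
            id=pid, params=p, I=I, CI=CI,
            severity="severe" if severe else "mild",
            biomarkers=biom, schedule=schedule.copy(), scores=scores,
            trajectory=traj, persistent_at_3mo=pscore > RECOVERY_CRITERION,
            persistence_score=pscore,
            recovery_phenotype=phenotype_recovery(p, priors),
        ))
    meta = {
        "n": n, "design": design,
        "risk_targets": {f"{k[0]}{k[1]}": v for k, v in calibration.risk_targets.items()},
        "p_severe": {f"{k[0]}{k[1]}": v for k, v in calibration.p_severe.items()},
        "sot_probs": list(calibration.sot_probs),
        "n_pilot": calibration.n_pilot,
    }
    return Cohort(patients=patients, design=design, seed=seed, metadata=meta)


def _draw_biomarkers_for_stratum(p, bm, rng, priors, vor_exp, ref_exp, severe, sot_probs):
    """Biomarker values consistent with pre-drawn exposure indicators."""
    if vor_exp:
        vor = bm.vor_threshold + rng.exponential(5.0 + 15.0 * max(p.alpha - 0.3, 0.0))
    else:
        vor = bm.vor_threshold * rng.beta(2.0, 5.0)
    if ref_exp:
        count = bm.reflex_count_threshold + rng.poisson(0.5 + p.rho)
    else:
        count = rng.binomial(
            bm.reflex_count_threshold - 1,
            float(np.clip(0.25 + 0.5 * (p.rho - priors["rho"].mean), 0.02, 0.98)),
        )
    q = sot_probs[1] if severe else sot_probs[0]
    if rng.random() < q:
        sot = bm.sot_threshold - rng.exponential(8.0 + 10.0 * max(p.rho - 0.4, 0.0))
        sot = float(np.clip(sot, 0.0, bm.sot_threshold - 0.5))
    else:
        sot = bm.sot_threshold + (100.0 - bm.sot_threshold) * rng.beta(2.5, 1.5)
        sot = float(np.clip(sot - 5.0 * (p.rho - priors["rho"].mean),
                            bm.sot_threshold + 0.5, 100.0))
    return Biomarkers(float(min(vor, 100.0)), sot, int(count))


# -- trials -----------------------------------------------------------------

@dataclass(frozen=True)
class _TrialPopulation:
    """Magnitude/decay distributions of the persistent-symptom trial population."""

    I0: Tuple[float, float] = (1.0, 4.0)
    CI0: Tuple[float, float] = (0.2, 1.2)
    tau_I: Tuple[float, float] = (5.0, 9.0)
    tau_CI: Tuple[float, float] = (6.0, 10.0)


def _simulate_trial_patient(p, pop, rate_multiplier, cfg, obs, schedule, patient_seed):
    rng = np.random.default_rng(patient_seed)
    I0 = rng.uniform(*pop.I0)
    CI0 = rng.uniform(*pop.CI0)
    tau_i = rng.uniform(*pop.tau_I) / rate_multiplier
    tau_c = rng.uniform(*pop.tau_CI) / rate_multiplier
    I = InjurySignal("exp_decay", magnitude=I0, tau=tau_i)
    CI = InjurySignal("exp_decay", magnitude=CI0, tau=tau_c)
    traj = integrate_trajectory(p, I, CI, cfg, horizon=float(np.max(schedule)))
    scores = observe_symptoms(traj, obs, schedule, seed=rng)
    return I, CI, traj, scores


def _pilot_advantage(rate_multiplier, pilot_params, pop, cfg, obs, schedule, pilot_seeds, week):
    """Paired-pilot percent advantage in mean baseline-to-week-12 reduction."""
    idx = int(np.argmin(np.abs(schedule - week)))
    red_c, red_i = [], []
    for p, s in zip(pilot_params, pilot_seeds):
        _, _, _, sc = _simulate_trial_patient(p, pop, 1.0, cfg, obs, schedule, s)
        red_c.append(sc[0] - sc[idx])
        _, _, _, sc = _simulate_trial_patient(p, pop, rate_multiplier, cfg, obs, schedule, s)
        red_i.append(sc[0] - sc[idx])
    dc, di = float(np.mean(red_c)), float(np.mean(red_i))
    if dc <= 0:
        raise ConfigError("control arm shows no mean symptom reduction; cannot calibrate")
    return 100.0 * (di - dc) / dc


def generate_trial(
    tc: TrialConfig,
    priors: Optional[PriorSet] = None,
    obs: Optional[ObservationModel] = None,
    seed=None,
    cfg: Optional[ModelConfig] = None,
    population: Optional[_TrialPopulation] = None,
    n_pilot: int = 3000,
) -> Cohort:
    """Simulate a two-arm randomized trial with a calibrated intervention.

    The intervention multiplies both injury decay rates; the multiplier is
    found by bisection on a paired pilot simulation (the same pilot patients
    and noise streams evaluated under both arms) so that the expected percent
    advantage in mean baseline-to-week-12 symptom reduction equals
    ``tc.intervention_effect``.
    """
    from .priors import sample_parameters

    priors = priors or default_priors()
    obs = obs or ObservationModel()
    cfg = cfg or ModelConfig()
    pop = population or _TrialPopulation()
    schedule = assessment_schedule("protocol4")
    week = tc.duration_weeks

    ss = np.random.SeedSequence(seed)
    pilot_ss, main_ss = ss.spawn(2)
    if tc.intervention_effect > 0:
        pilot_rng = np.random.default_rng(pilot_ss)
        pilot_params = sample_parameters(priors, n_pilot, seed=pilot_rng)
        pilot_seeds = pilot_rng.integers(0, 2**31 - 1, size=n_pilot)

        def gap(mult):
            return _pilot_advantage(mult, pilot_params, pop, cfg, obs, schedule,
                                    pilot_seeds, week) - 100.0 * tc.intervention_effect

        hi = 60.0
        if gap(hi) < 0:
            raise ConfigError("requested intervention effect unreachable by decay-rate mechanism")
        multiplier = float(brentq(gap, 1.0 + 1e-6, hi, xtol=1e-3, rtol=1e-4))
    else:
        multiplier = 1.0

    rng = np.random.default_rng(main_ss)
    n_total = 2 * tc.n_per_arm
    params_list = sample_parameters(priors, n_total, seed=rng)
    arms = np.array(["control"] * tc.n_per_arm + ["intervention"] * tc.n_per_arm)
    rng.shuffle(arms)
    patient_seeds = rng.integers(0, 2**31 - 1, size=n_total)
    dummy_priors = priors
    patients = []
    for pid, (p, arm, s) in enumerate(zip(params_list, arms, patient_seeds)):
        mult = multiplier if arm == "intervention" else 1.0
        I, CI, traj, scores = _simulate_trial_patient(p, pop, mult, cfg, obs, schedule, s)
        pscore = persistence_score(schedule, scores)
        patients.append(PatientRecord(
            id=pid, params=p, I=I, CI=CI, severity="trial",
            biomarkers=assign_biomarkers(p, BiomarkerModel(), seed=rng, priors=dummy_priors),
            schedule=schedule.copy(), scores=scores, trajectory=None,
            persistent_at_3mo=pscore > RECOVERY_CRITERION,
            persistence_score=pscore,
            recovery_phenotype=phenotype_recovery(p, priors),
            arm=str(arm),
        ))
    meta = {"rate_multiplier": multiplier, "n_per_arm": tc.n_per_arm,
            "target_effect": tc.intervention_effect, "n_pilot": n_pilot}
    return Cohort(patients=patients, design="protocol3", seed=seed, metadata=meta)


# ---------------------------------------------------------------------------
# single-patient convenience
# ---------------------------------------------------------------------------

def synthesize_patient(
    seed=None,
    priors: Optional[PriorSet] = None,
    obs: Optional[ObservationModel] = None,
    cfg: Optional[ModelConfig] = None,
    design: str = "protocol4",
    I0: float = 3.0,
    CI0: float = 1.0,
    tau_I: float = 3.0,
    tau_CI: float = 4.0,
    params: Optional[NerdParameters] = None,
) -> PatientRecord:
    """One synthetic patient with a moderate, informative injury course."""
    priors = priors or default_priors()
    obs = obs or ObservationModel()
    cfg = cfg or ModelConfig()
    schedule = assessment_schedule(design)
    rng = np.random.default_rng(seed)
    if params is None:
        from .priors import sample_parameters
        params = sample_parameters(priors, 1, seed=rng)[0]
    I = InjurySignal("exp_decay", magnitude=I0, tau=tau_I)
    CI = InjurySignal("exp_decay", magnitude=CI0, tau=tau_CI)
    traj = integrate_trajectory(params, I, CI, cfg, horizon=float(np.max(schedule)))
    scores = observe_symptoms(traj, obs, schedule, seed=rng)
    pscore = persistence_score(schedule, scores)
    return PatientRecord(
        id=0, params=params, I=I, CI=CI, severity="moderate",
        biomarkers=assign_biomarkers(params, BiomarkerModel(), seed=rng, priors=priors),
        schedule=schedule, scores=scores, trajectory=traj,
        persistent_at_3mo=pscore > RECOVERY_CRITERION, persistence_score=pscore,
        recovery_phenotype=phenotype_recovery(params, priors),
    )
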
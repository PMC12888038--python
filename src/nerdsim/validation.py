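"""Predictive validation, risk stratification, and trial-effect estimation.

These operations reproduce a planned validation program on synthetic
cohorts: chronological train/test splits of each patient's trajectory with
pooled out-of-sample R^2 and RMSE, rank-based AUC of risk scores for
three-month persistence, 2x2 risk ratios with log-normal confidence
intervals, and the percent advantage and standardized effect size of a
two-arm trial.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import rankdata

from ._errors import ConfigError, DomainError
from .cohort import Cohort, ObservationModel, PatientRecord
from .inference import FitSpec, fit_mcmc, predict_scores
from .model import ModelConfig
from .priors import PriorSet

__all__ = [
    "SplitResult", "RiskRatioResult", "TrialEffect", "RecoveryTime", "ValidationReport",
    "split_trajectory", "pooled_r2", "predictive_r2", "risk_ratio_2x2",
    "risk_ratio_for_stratum", "stratification_auc", "parameter_risk_score",
    "trial_effect", "time_to_recovery", "protocol4_validation",
]


@dataclass
class SplitResult:
    train_times: np.ndarray
    train_scores: np.ndarray
    test_times: np.ndarray
    test_scores: np.ndarray
    warning: bool = False


def split_trajectory(patient: PatientRecord, fraction: float = 0.7) -> SplitResult:
    """Chronological split: the first ``ceil(fraction * n)`` points train.

    The orientation is forecasting — later assessments are predicted from
    earlier ones.  Fewer than two test points sets the warning flag.
    """
    n = len(patient.schedule)
    if n < 4:
        raise DomainError("need at least 4 assessments to split")
    if not (0.0 < fraction <= 1.0):
        raise ConfigError("split fraction must lie in (0, 1]")
    n_train = int(np.ceil(fraction * n))
    return SplitResult(
        train_times=patient.schedule[:n_train].copy(),
        train_scores=patient.scores[:n_train].copy(),
        test_times=patient.schedule[n_train:].copy(),
        test_scores=patient.scores[n_train:].copy(),
        warning=(n - n_train) < 2,
    )


def pooled_r2(observed: Sequence[np.ndarray], predicted: Sequence[np.ndarray]):
    """Pooled ``R^2 = 1 - SSE/SST`` and RMSE over all points of all patients.

    SST is taken about the pooled mean of the observed values.  Zero SST
    makes R^2 undefined (returned as ``None``).
    """
    obs = np.concatenate([np.asarray(o, float).ravel() for o in observed])
    pred = np.concatenate([np.asarray(p, float).ravel() for p in predicted])
    if obs.size != pred.size:
        raise DomainError("observed and predicted lengths differ")
    sse = float(np.sum((obs - pred) ** 2))
    sst = float(np.sum((obs - obs.mean()) ** 2))
    rmse = float(np.sqrt(sse / obs.size))
    r2 = None if sst == 0 else 1.0 - sse / sst
    return r2, rmse


# alias matching the operation name used in reports
predictive_r2 = pooled_r2


@dataclass
class RiskRatioResult:
    rr: float
    ci_low: float
    ci_high: float
    exposed_risk: float
    unexposed_risk: float
    corrected: bool = False
    infinite: bool = False
    counts: Tuple[int, int, int, int] = (0, 0, 0, 0)


def risk_ratio_2x2(exposed_events: int, exposed_n: int,
                   unexposed_events: int, unexposed_n: int,
                   level: float = 0.95) -> RiskRatioResult:
    """Risk ratio with a log-normal confidence interval.

    Zero event cells receive a 0.5 continuity correction (added to every
    cell of the 2x2 table) and set the ``corrected`` flag.
    """
    if min(exposed_events, unexposed_events) < 0 or exposed_n < 1 or unexposed_n < 1:
        raise DomainError("counts must be nonnegative with group sizes >= 1")
    if exposed_events > exposed_n or unexposed_events > unexposed_n:
        raise DomainError("events cannot exceed group size")
    from scipy.stats import norm

    a, n1, c, n0 = float(exposed_events), float(exposed_n), float(unexposed_events), float(unexposed_n)
    corrected = False
    if a == 0 or c == 0 or a == n1 or c == n0:
        corrected = True
        a, c = a + 0.5, c + 0.5
        n1, n0 = n1 + 1.0, n0 + 1.0
    risk1, risk0 = a / n1, c / n0
    if risk0 == 0:
        return RiskRatioResult(np.inf, np.nan, np.nan, risk1, risk0,
                               corrected=corrected, infinite=True,
                               counts=(exposed_events, exposed_n, unexposed_events, unexposed_n))
    rr = risk1 / risk0
    se = np.sqrt(max(1.0 / a - 1.0 / n1 + 1.0 / c - 1.0 / n0, 0.0))
    z = norm.ppf(0.5 + level / 2.0)
    return RiskRatioResult(
        rr=float(rr), ci_low=float(rr * np.exp(-z * se)), ci_high=float(rr * np.exp(z * se)),
        exposed_risk=float(risk1), unexposed_risk=float(risk0), corrected=corrected,
        counts=(exposed_events, exposed_n, unexposed_events, unexposed_n),
    )


def risk_ratio_for_stratum(cohort: Cohort, stratum: str,
                           outcome: Optional[Callable[[PatientRecord], bool]] = None) -> RiskRatioResult:
    """Risk ratio of three-month persistence across a named biomarker stratum.

    ``stratum`` is ``"vor"`` (asymmetry > 20%), ``"reflex"`` (count >= 2) or
    ``"sot"`` (composite < 60).
    """
    from .cohort import BiomarkerModel

    bm = BiomarkerModel()
    exposures = {
        "vor": lambda p: p.biomarkers.vor_asym_pct > bm.vor_threshold,
        "reflex": lambda p: p.biomarkers.primitive_reflex_count >= bm.reflex_count_threshold,
        "sot": lambda p: p.biomarkers.sot_composite < bm.sot_threshold,
    }
    if stratum not in exposures:
        raise ConfigError(f"unknown stratum {stratum!r}")
    exposed = np.array([exposures[stratum](p) for p in cohort], dtype=bool)
    outcome = outcome or (lambda p: p.persistent_at_3mo)
    events = np.array([outcome(p) for p in cohort], dtype=bool)
    return risk_ratio_2x2(int(events[exposed].sum()), int(exposed.sum()),
                          int(events[~exposed].sum()), int((~exposed).sum()))


def parameter_risk_score(means: Dict[str, float]) -> float:
    """Default parameter-based stratification score ``alpha * (1 - eta)``.

    High reflex-to-motor scaling combined with a low degradation-rate
    parameter marks the slow-recovery profile.
    """
    return float(means["alpha"] * (1.0 - means["eta"]))


def stratification_auc(cohort: Cohort, score_rule: Callable[[PatientRecord], float]):
    """AUC of a risk score for three-month persistence.

    Computed as the normalized rank statistic — the probability a random
    persistent patient scores above a random non-persistent one, ties
    counted half.  Undefined (``None``) for a single-class cohort.
    """
    labels = np.array([p.persistent_at_3mo for p in cohort], dtype=bool)
    scores = np.array([score_rule(p) for p in cohort], dtype=float)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class TrialEffect:
    percent_advantage: Optional[float]
    standardized_effect: float
    reduction_control: float
    reduction_active: float
    absolute_difference: float
    se_difference: float


def trial_effect(trial: Cohort, week: float = 12.0) -> TrialEffect:
    """Arm-wise mean baseline-to-week-``week`` symptom reduction comparison.

    Percent advantage is ``(delta_active - delta_control) / delta_control *
    100``; the standardized effect divides the difference in reductions by
    the pooled standard deviation of per-patient reductions.  A non-positive
    control reduction leaves the percent advantage undefined.
    """
    arms: Dict[str, List[float]] = {}
    for p in trial:
        if p.arm is None:
            raise DomainError("trial cohort has unlabelled patients")
        arms.setdefault(p.arm, []).append(p.baseline_score - p.score_at(week))
    if set(arms) != {"control", "intervention"}:
        raise DomainError(f"expected control/intervention arms, got {sorted(arms)}")
    red_c = np.asarray(arms["control"])
    red_i = np.asarray(arms["intervention"])
    dc, di = float(red_c.mean()), float(red_i.mean())
    diff = di - dc
    pooled_var = (
        (red_c.size - 1) * red_c.var(ddof=1) + (red_i.size - 1) * red_i.var(ddof=1)
    ) / (red_c.size + red_i.size - 2)
    pooled_sd = float(np.sqrt(pooled_var))
    se = float(np.sqrt(red_c.var(ddof=1) / red_c.size + red_i.var(ddof=1) / red_i.size))
    pct = None if dc <= 0 else 100.0 * diff / dc
    return TrialEffect(
        percent_advantage=pct,
        standardized_effect=float(diff / pooled_sd) if pooled_sd > 0 else 0.0,
        reduction_control=dc, reduction_active=di,
        absolute_difference=float(diff), se_difference=se,
    )


@dataclass
class RecoveryTime:
    weeks: float
    censored: bool


def time_to_recovery(patient: PatientRecord, criterion: float = 15.0) -> RecoveryTime:
    """First assessment week of sustained recovery (two consecutive scores
    below the criterion); censored at the last assessment otherwise."""
    s = patient.scores
    for i in range(len(s) - 1):
        if s[i] < criterion and s[i + 1] < criterion:
            return RecoveryTime(weeks=float(patient.schedule[i]), censored=False)
    return RecoveryTime(weeks=float(patient.schedule[-1]), censored=True)


@dataclass
class ValidationReport:
    pooled_r2: Optional[float]
    rmse: float
    per_patient_r2: List[Optional[float]] = field(default_factory=list)
    n_patients: int = 0
    n_test_points: int = 0
    split_fraction: float = 0.7


def protocol4_validation(
    cohort: Cohort,
    priors: PriorSet,
    spec: FitSpec,
    obs: Optional[ObservationModel] = None,
    cfg: Optional[ModelConfig] = None,
    split: float = 0.7,
    seed: Optional[int] = None,
) -> ValidationReport:
    """Train/test predictive validation over a cohort.

    Each patient's assessments are split chronologically; the free
    coefficients are fitted by MCMC on the training window, and the
    posterior-mean parameters forecast the held-out tail.  R^2 and RMSE are
    pooled over all test points of all patients.
    """
    obs = obs or ObservationModel()
    cfg = cfg or ModelConfig()
    seeds = np.random.SeedSequence(seed).spawn(len(cohort.patients))
    observed, predicted, per_r2 = [], [], []
    for patient, pseed in zip(cohort, seeds):
        parts = split_trajectory(patient, split)
        train = dataclasses.replace(patient, schedule=parts.train_times,
                                    scores=parts.train_scores)
        fit_seed = int(pseed.generate_state(1)[0] % (2**31 - 1))
        sample = fit_mcmc(train, priors, dataclasses.replace(spec, seed=fit_seed),
                          obs=obs, cfg=cfg)
        fitted = sample.fixed.updated(**sample.posterior_mean())
        pred = predict_scores(fitted, patient, obs, cfg, schedule=parts.test_times)
        observed.append(parts.test_scores)
        predicted.append(pred)
        r2_i, _ = pooled_r2([parts.test_scores], [pred])
        per_r2.append(r2_i)
    r2, rmse = pooled_r2(observed, predicted)
    return ValidationReport(
        pooled_r2=r2, rmse=rmse, per_patient_r2=per_r2,
        n_patients=len(cohort.patients),
        n_test_points=int(sum(len(o) for o in observed)),
        split_fraction=split,
    )
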
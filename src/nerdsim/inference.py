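"""Bayesian estimation of patient-specific model coefficients.

A patient's longitudinal symptom assessments are modelled as the noiseless
observation-model prediction for a candidate coefficient vector plus i.i.d.
Gaussian noise.  Priors are the Beta distributions of :mod:`nerdsim.priors`.
Because several coefficients enter the dynamics only through products
(``gamma*alpha``, ``lambda_*mu``), the full twelve-coefficient vector is not
identifiable from a single scalar trajectory; the default fit frees the
subset ``{alpha, eta, rho}`` and fixes the rest at their prior means.

Sampling is random-walk Metropolis in the logit transform of the free
coefficients (proposals can never leave the unit interval), with the
per-chain proposal scale adapted during burn-in toward a 20-40% acceptance
rate.  Convergence is judged by the split Gelman-Rubin statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from ._errors import ConfigError, ContractError, DomainError
from .cohort import ObservationModel, PatientRecord, noiseless_scores
from .model import (
    COEFFICIENT_NAMES, ModelConfig, NerdParameters, integrate_trajectory, _time_grid,
)
from .priors import PriorSet

__all__ = [
    "FitSpec", "PosteriorSample", "FitDiagnostics",
    "predict_scores", "estimate_noise_sd", "log_likelihood", "log_posterior",
    "fit_mcmc", "gelman_rubin", "effective_sample_size", "credible_intervals",
    "posterior_predictive_check", "information_criteria", "summarize_fit",
]


@dataclass(frozen=True)
class FitSpec:
    """What to fit and how to sample."""

    free_parameters: Tuple[str, ...] = ("alpha", "eta", "rho")
    fixed: Optional[NerdParameters] = None  # defaults to the prior-mean point
    chains: int = 4
    iterations: int = 5000
    burn_in: float = 0.5
    proposal_scale: float = 0.3
    seed: Optional[int] = None

    def __post_init__(self):
        if not self.free_parameters:
            raise ConfigError("free parameter set must be non-empty")
        unknown = set(self.free_parameters) - set(COEFFICIENT_NAMES)
        if unknown:
            raise ConfigError(f"unknown free parameters: {sorted(unknown)}")
        if self.chains < 1:
            raise ConfigError("need at least one chain")
        if not (0.0 < self.burn_in < 1.0):
            raise ConfigError("burn_in must be a fraction in (0, 1)")
        if self.iterations < 10:
            raise ConfigError("iterations must be >= 10")


@dataclass
class PosteriorSample:
    """Post-burn-in MCMC draws with chain structure preserved."""

    param_names: Tuple[str, ...]
    draws: np.ndarray       # (chains, kept_iterations, n_params)
    log_post: np.ndarray    # (chains, kept_iterations)
    log_lik: np.ndarray     # (chains, kept_iterations)
    acceptance_rate: float
    noise_sd: float
    fixed: Optional[NerdParameters] = None
    seed: Optional[int] = None
    low_acceptance: bool = False

    @property
    def pooled(self) -> np.ndarray:
        """All draws pooled across chains, shape (chains*kept, n_params)."""
        return self.draws.reshape(-1, self.draws.shape[-1])

    def posterior_mean(self) -> Dict[str, float]:
        m = self.pooled.mean(axis=0)
        return {n: float(v) for n, v in zip(self.param_names, m)}

    def posterior_median(self) -> Dict[str, float]:
        m = np.median(self.pooled, axis=0)
        return {n: float(v) for n, v in zip(self.param_names, m)}


@dataclass
class FitDiagnostics:
    r_hat: Dict[str, float]
    ess: Dict[str, float]
    intervals: Dict[str, Tuple[float, float]]
    means: Dict[str, float]
    medians: Dict[str, float]
    aic: float
    bic: float

    def as_dict(self) -> dict:
        return {
            "r_hat": self.r_hat, "ess": self.ess,
            "credible_intervals": {k: list(v) for k, v in self.intervals.items()},
            "posterior_means": self.means, "posterior_medians": self.medians,
            "aic": self.aic, "bic": self.bic,
        }


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def predict_scores(
    params: NerdParameters,
    patient: PatientRecord,
    obs: ObservationModel,
    cfg: ModelConfig,
    schedule=None,
) -> np.ndarray:
    """Noiseless predicted symptom scores for a candidate coefficient vector."""
    schedule = patient.schedule if schedule is None else np.asarray(schedule, float)
    traj = integrate_trajectory(params, patient.I, patient.CI, cfg,
                                horizon=float(np.max(schedule)))
    return noiseless_scores(traj, obs, schedule)


def estimate_noise_sd(patient: PatientRecord, obs: ObservationModel) -> float:
    """Observation-noise standard deviation implied by the noise fraction.

    The noise contributes ``noise_fraction`` of the total score variance, so
    ``sd = sqrt(noise_fraction * var(observed scores))``.
    """
    var = float(np.var(patient.scores))
    sd = float(np.sqrt(obs.noise_fraction * var))
    if sd <= 0:
        raise ConfigError("observed scores have zero variance: noise sd undefined")
    return sd


def log_likelihood(
    candidate: NerdParameters,
    patient: PatientRecord,
    obs: ObservationModel,
    cfg: ModelConfig,
    noise_sd: Optional[float] = None,
) -> float:
    """Gaussian log-likelihood of the observed scores around the prediction."""
    if len(patient.scores) == 0:
        raise DomainError("patient has no assessments")
    sd = estimate_noise_sd(patient, obs) if noise_sd is None else float(noise_sd)
    if sd <= 0:
        raise ConfigError("noise sd must be positive")
    resid = patient.scores - predict_scores(candidate, patient, obs, cfg)
    n = resid.size
    return float(-0.5 * n * np.log(2.0 * np.pi * sd * sd)
                 - 0.5 * np.sum(resid ** 2) / (sd * sd))


def log_posterior(
    candidate: NerdParameters,
    patient: PatientRecord,
    priors: PriorSet,
    obs: ObservationModel,
    cfg: ModelConfig,
    free: Sequence[str] = ("alpha", "eta", "rho"),
    noise_sd: Optional[float] = None,
) -> float:
    """Log-likelihood plus Beta log-prior density of the free coefficients.

    A candidate with any free coefficient on or outside the unit-interval
    boundary has zero prior density and returns ``-inf`` (rejection by
    contract, not an exception).
    """
    lp = 0.0
    for name in free:
        x = getattr(candidate, name)
        if not (0.0 < x < 1.0):
            return -np.inf
        lp += priors[name].logpdf(x)
    if not np.isfinite(lp):
        return -np.inf
    return lp + log_likelihood(candidate, patient, obs, cfg, noise_sd=noise_sd)


# ---------------------------------------------------------------------------
# fast per-patient predictor (precomputed signal arrays)
# ---------------------------------------------------------------------------

class _Predictor:
    """Evaluates predicted scores for many candidates on one patient.

    The injury signals and time grid are fixed per patient, so they are
    evaluated once; each candidate then costs a few vectorized operations.
    """

    def __init__(self, patient: PatientRecord, obs: ObservationModel, cfg: ModelConfig):
        self.obs, self.cfg = obs, cfg
        self.schedule = np.asarray(patient.schedule, float)
        self.times = _time_grid(float(np.max(self.schedule)), cfg.step)
        # signal values/integrals are candidate-independent: evaluate once
        self.I_sched = np.asarray(patient.I.evaluate(self.schedule), float)
        self.CI_sched = np.asarray(patient.CI.evaluate(self.schedule), float)
        self.I_int_grid = np.asarray(patient.I.integral(self.times), float)
        self.CI_int_grid = np.asarray(patient.CI.integral(self.times), float)
        self.I_int_sched = np.asarray(patient.I.integral(self.schedule), float)
        self.CI_int_sched = np.asarray(patient.CI.integral(self.schedule), float)
        self.I0 = float(patient.I.evaluate(0.0))
        self.CI0 = float(patient.CI.evaluate(0.0))
        self.scores = np.asarray(patient.scores, float)

    def _slopes(self, p: NerdParameters):
        c_i, c_ci = p.behavioral_slope_I, p.behavioral_slope_CI
        if self.cfg.collapse_convention == "literal":
            return (c_i - p.psi * p.degradation_slope_I,
                    c_ci - p.psi * p.degradation_slope_CI, p.psi * p.G0)
        return (c_i + p.psi * p.degradation_slope_I,
                c_ci + p.psi * p.degradation_slope_CI, 0.0)

    def __call__(self, p: NerdParameters) -> np.ndarray:
        cfg, obs = self.cfg, self.obs
        k_i, k_ci, k0 = self._slopes(p)
        cum_grid = k_i * self.I_int_grid + k_ci * self.CI_int_grid + k0 * self.times
        N_grid = np.clip(p.N0 - p.eta * cum_grid, cfg.N_floor, p.N0)
        cum_s = k_i * self.I_int_sched + k_ci * self.CI_int_sched + k0 * self.schedule
        n_t = np.clip(p.N0 - p.eta * cum_s, cfg.N_floor, p.N0)
        load0 = k_i * self.I0 + k_ci * self.CI0 + k0
        if load0 > 0:
            load_rel = (k_i * self.I_sched + k_ci * self.CI_sched + k0) / load0
        else:
            load_rel = np.zeros_like(self.schedule)
        s = obs.S_max * (obs.w_load * load_rel + obs.w_N * (1.0 - n_t))
        if np.any(N_grid < cfg.entrapment_threshold):
            s = s + obs.floor_persistent
        return np.clip(s, 0.0, obs.S_max)


def _logit(x):
    return np.log(x) - np.log1p(-x)


def _expit(z):
    return 1.0 / (1.0 + np.exp(-z))


def fit_mcmc(patient: PatientRecord, priors: PriorSet, spec: FitSpec,
             obs: Optional[ObservationModel] = None,
             cfg: Optional[ModelConfig] = None,
             noise_sd: Optional[float] = None) -> PosteriorSample:
    """Random-walk Metropolis over the logit of the free coefficients."""
    obs = obs or ObservationModel()
    cfg = cfg or ModelConfig()
    if len(np.unique(patient.schedule)) < 2:
        raise DomainError("need at least two distinct assessment times")
    priors.require(spec.free_parameters)
    sd = estimate_noise_sd(patient, obs) if noise_sd is None else float(noise_sd)
    if sd <= 0:
        raise ConfigError("noise sd must be positive")

    fixed = spec.fixed or priors.mean_parameters()
    free = spec.free_parameters
    predictor = _Predictor(patient, obs, cfg)
    observed = predictor.scores
    n_obs = observed.size
    const = -0.5 * n_obs * np.log(2.0 * np.pi * sd * sd)
    prior_dists = [priors[name].distribution() for name in free]
    # Beta log-density evaluated directly: (a-1)ln x + (b-1)ln(1-x) - ln B(a,b)
    from scipy.special import betaln

    shape_a = np.array([priors[name].shape_a for name in free])
    shape_b = np.array([priors[name].shape_b for name in free])
    log_beta_norm = float(np.sum(betaln(shape_a, shape_b)))

    def log_target(z):
        """Posterior density in logit space (Beta prior + Jacobian + likelihood)."""
        x = _expit(z)
        if np.any(x <= 0.0) or np.any(x >= 1.0):
            return -np.inf, -np.inf
        lx, l1x = np.log(x), np.log1p(-x)
        lp = float(np.sum((shape_a - 1.0) * lx + (shape_b - 1.0) * l1x)) - log_beta_norm
        lp += float(np.sum(lx + l1x))  # d expit / dz Jacobian
        p = fixed.updated(**{name: float(xi) for name, xi in zip(free, x)})
        resid = observed - predictor(p)
        ll = const - 0.5 * float(np.sum(resid ** 2)) / (sd * sd)
        return lp + ll, ll

    k = len(free)
    n_burn = int(spec.burn_in * spec.iterations)
    n_keep = spec.iterations - n_burn
    draws = np.empty((spec.chains, n_keep, k))
    lps = np.empty((spec.chains, n_keep))
    lls = np.empty((spec.chains, n_keep))
    accepted_post = 0

    chain_seeds = np.random.SeedSequence(spec.seed).spawn(spec.chains)
    for c, css in enumerate(chain_seeds):
        rng = np.random.default_rng(css)
        x0 = np.array([d.rvs(random_state=rng) for d in prior_dists])
        z = _logit(np.clip(x0, 1e-6, 1 - 1e-6))
        lp, ll = log_target(z)
        scale = spec.proposal_scale
        window_acc = 0
        for it in range(spec.iterations):
            prop = z + rng.normal(0.0, scale, size=k)
            lp_new, ll_new = log_target(prop)
            if np.log(rng.random()) < lp_new - lp:
                z, lp, ll = prop, lp_new, ll_new
                window_acc += 1
                if it >= n_burn:
                    accepted_post += 1
            if it < n_burn and (it + 1) % 100 == 0:
                rate = window_acc / 100.0
                if rate < 0.20:
                    scale *= 0.8
                elif rate > 0.40:
                    scale *= 1.25
                window_acc = 0
            if it >= n_burn:
                j = it - n_burn
                draws[c, j] = _expit(z)
                lps[c, j] = lp
                lls[c, j] = ll

    acc_rate = accepted_post / (spec.chains * n_keep)
    return PosteriorSample(
        param_names=tuple(free), draws=draws, log_post=lps, log_lik=lls,
        acceptance_rate=float(acc_rate), noise_sd=sd, fixed=fixed,
        seed=spec.seed, low_acceptance=acc_rate < 0.01,
    )


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def gelman_rubin(sample: PosteriorSample) -> Dict[str, float]:
    """Split Gelman-Rubin statistic per free parameter.

    Each chain is halved, and R-hat compares between- and within-half-chain
    variances: ``sqrt(((n-1)/n * W + B/n) / W)``.
    """
    chains, n, k = sample.draws.shape
    if chains < 2:
        raise ContractError("split R-hat requires at least two chains")
    if n < 20:
        raise ContractError("need at least 10 post-burn-in draws per half-chain")
    half = n // 2
    split = np.concatenate(
        [sample.draws[:, :half, :], sample.draws[:, half:2 * half, :]], axis=0
    )  # (2*chains, half, k)
    out = {}
    for j, name in enumerate(sample.param_names):
        x = split[:, :, j]
        w = x.var(axis=1, ddof=1).mean()
        b = half * x.mean(axis=1).var(ddof=1)
        if w <= 0:
            out[name] = np.inf if b > 0 else 1.0
            continue
        var_plus = (half - 1) / half * w + b / half
        out[name] = float(np.sqrt(var_plus / w))
    return out


def effective_sample_size(sample: PosteriorSample) -> Dict[str, float]:
    """Bulk effective sample size per parameter (via ArviZ)."""
    import arviz as az

    out = {}
    for j, name in enumerate(sample.param_names):
        out[name] = float(az.ess(np.asarray(sample.draws[:, :, j])))
    return out


def credible_intervals(sample: PosteriorSample, level: float = 0.95) -> Dict[str, Tuple[float, float]]:
    """Equal-tailed posterior intervals of the pooled draws."""
    if not (0.0 < level < 1.0):
        raise ConfigError("credible level must lie in (0, 1)")
    tail = (1.0 - level) / 2.0
    pooled = sample.pooled
    out = {}
    for j, name in enumerate(sample.param_names):
        lo, hi = np.quantile(pooled[:, j], [tail, 1.0 - tail])
        out[name] = (float(lo), float(hi))
    return out


@dataclass
class PPCResult:
    level: float
    coverage_by_time: np.ndarray
    overall_coverage: float


def posterior_predictive_check(
    sample: PosteriorSample,
    patient: PatientRecord,
    obs: Optional[ObservationModel] = None,
    cfg: Optional[ModelConfig] = None,
    n_rep: int = 200,
    seed=None,
    level: float = 0.95,
) -> PPCResult:
    """Coverage of the observations by posterior-predictive intervals.

    Replicated datasets are simulated from ``n_rep`` pooled posterior draws
    (prediction plus observation noise); at each assessment time the
    pointwise ``level`` predictive interval either covers the observed score
    or not.
    """
    if n_rep < 50:
        raise ConfigError("n_rep must be >= 50 for stable predictive quantiles")
    obs = obs or ObservationModel()
    cfg = cfg or ModelConfig()
    rng = np.random.default_rng(seed)
    predictor = _Predictor(patient, obs, cfg)
    pooled = sample.pooled
    idx = rng.integers(0, pooled.shape[0], size=n_rep)
    base = sample.fixed if sample.fixed is not None else patient.params
    reps = np.empty((n_rep, patient.scores.size))
    for r, i in enumerate(idx):
        p = base.updated(**{n: float(v) for n, v in zip(sample.param_names, pooled[i])})
        clean = predictor(p)
        reps[r] = np.clip(clean + rng.normal(0.0, sample.noise_sd, size=clean.shape),
                          0.0, obs.S_max)
    tail = (1.0 - level) / 2.0
    lo = np.quantile(reps, tail, axis=0)
    hi = np.quantile(reps, 1.0 - tail, axis=0)
    covered = (patient.scores >= lo) & (patient.scores <= hi)
    return PPCResult(level=level, coverage_by_time=covered.astype(float),
                     overall_coverage=float(covered.mean()))


def information_criteria(
    sample: PosteriorSample,
    patient: PatientRecord,
    obs: Optional[ObservationModel] = None,
    cfg: Optional[ModelConfig] = None,
) -> Tuple[float, float]:
    """(AIC, BIC) using the best posterior draw as the max-likelihood proxy.

    ``AIC = 2k - 2 max logL``; ``BIC = k ln(n) - 2 max logL`` with ``k`` free
    parameters and ``n`` assessments.  Using the best posterior draw rather
    than a dedicated optimizer slightly understates the maximum likelihood.
    """
    max_ll = float(np.max(sample.log_lik))
    k = len(sample.param_names)
    n = len(patient.scores)
    aic = 2.0 * k - 2.0 * max_ll
    bic = k * np.log(n) - 2.0 * max_ll
    return float(aic), float(bic)


def summarize_fit(sample: PosteriorSample, patient: PatientRecord,
                  obs: Optional[ObservationModel] = None,
                  cfg: Optional[ModelConfig] = None) -> FitDiagnostics:
    aic, bic = information_criteria(sample, patient, obs, cfg)
    return FitDiagnostics(
        r_hat=gelman_rubin(sample),
        ess=effective_sample_size(sample),
        intervals=credible_intervals(sample),
        means=sample.posterior_mean(),
        medians=sample.posterior_median(),
        aic=aic, bic=bic,
    )
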
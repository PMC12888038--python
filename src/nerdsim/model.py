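"""Core reflex-entrapment dynamics.

The model tracks a single scalar state, cortical network adaptability
``N(t)`` (dimensionless, 1 = fully flexible), which declines under two
forcing components driven by a reflex-circuit injury input ``I(t)`` and a
cortical injury load ``C_I(t)``:

* behavioral load — reflex injury amplified into aberrant motor output
  (``gamma * alpha``), fed into maladaptive behavior directly (``kappa``)
  and through re-recruited primitive reflexes (``nu * rho``) acting on
  distorted reafference (``lambda * mu * gamma * alpha * I + sigma * C_I``),
  all weighted by ``chi``;
* gain-control collapse — loss of thalamocortical gain-modulation
  headroom relative to the reserve ``G0``, weighted by ``psi``.

The decline rate is ``dN/dt = -eta * (behavioral_load + gain_collapse)``.
The right-hand side never depends on ``N`` itself, so the trajectory is a
clamped quadrature of the forcing.

Two conventions are provided for the gain-collapse bracket.  The printed
form ("literal") is ``psi * (G* - lambda*mu*gamma*alpha*I - lambda*sigma*C_I
- xi*C_I)``, which equals ``psi * G0`` at zero injury and therefore decays
``N`` even in the uninjured brain.  The prose description of the same term
is a *shortfall* from the reserve, which vanishes at zero injury.  Both are
implemented behind ``ModelConfig.collapse_convention``; the shortfall is the
default because it yields a sensible no-injury fixed point.

An optional receptor extension replaces the static reserve with
``H(t) = max(0, G0 + zeta * R_net(t))``, modelling afferent receptor input
that props up gain reserve.  Under the literal convention ``H(t)`` simply
substitutes for ``G0``; under the shortfall convention stimulation enters as
an additive relief term ``max(0, zeta * R_stim(t))`` subtracted from the
degradations (the bracket stays floored at zero).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from ._errors import ConfigError, ContractError, DomainError, NumericalError

__all__ = [
    "COEFFICIENT_NAMES",
    "NerdParameters",
    "InjurySignal",
    "ReceptorExtension",
    "ModelConfig",
    "Trajectory",
    "evaluate_injury",
    "behavioral_load",
    "gain_collapse",
    "dN_dt",
    "receptor_gain_support",
    "integrate_trajectory",
    "classify_entrapment",
]

#: Canonical ordering of the twelve dimensionless coupling coefficients.
COEFFICIENT_NAMES = (
    "alpha", "gamma", "mu", "lambda_", "rho", "nu",
    "chi", "kappa", "sigma", "xi", "psi", "eta",
)


@dataclass(frozen=True)
class NerdParameters:
    """The twelve coupling coefficients plus gain reserve and initial state.

    All coefficients are dimensionless influence weights in ``[0, 1]``.
    ``G0`` is the baseline gain-modulation reserve (>= 0) and ``N0`` the
    initial adaptability in ``(0, 1]``.
    """

    alpha: float
    gamma: float
    mu: float
    lambda_: float
    rho: float
    nu: float
    chi: float
    kappa: float
    sigma: float
    xi: float
    psi: float
    eta: float
    G0: float = 1.0
    N0: float = 1.0

    def __post_init__(self):
        for name in COEFFICIENT_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v) or not (0.0 <= v <= 1.0):
                raise DomainError(f"coefficient {name}={v!r} outside [0, 1]")
        if not np.isfinite(self.G0) or self.G0 < 0:
            raise DomainError(f"G0={self.G0!r} must be >= 0")
        if not np.isfinite(self.N0) or not (0.0 < self.N0 <= 1.0):
            raise DomainError(f"N0={self.N0!r} must lie in (0, 1]")

    # -- linear load coefficients -------------------------------------------------
    # Both forcing components are linear in (I, C_I); exposing the four slopes
    # lets the integrator and the MCMC likelihood work on whole time grids with
    # a handful of vectorized operations.

    @property
    def behavioral_slope_I(self) -> float:
        ga = self.gamma * self.alpha
        return self.chi * (self.kappa * ga + self.nu * self.rho * self.lambda_ * self.mu * ga)

    @property
    def behavioral_slope_CI(self) -> float:
        return self.chi * self.nu * self.rho * self.sigma

    @property
    def degradation_slope_I(self) -> float:
        """Gain-reserve degradation per unit reflex injury (inside the bracket)."""
        return self.lambda_ * self.mu * self.gamma * self.alpha

    @property
    def degradation_slope_CI(self) -> float:
        """Gain-reserve degradation per unit cortical injury (inside the bracket)."""
        return self.lambda_ * self.sigma + self.xi

    def as_dict(self) -> dict:
        d = {name: getattr(self, name) for name in COEFFICIENT_NAMES}
        d["G0"] = self.G0
        d["N0"] = self.N0
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NerdParameters":
        return cls(**d)

    def updated(self, **kwargs) -> "NerdParameters":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class InjurySignal:
    """Parametric nonnegative time course for an injury input.

    Kinds: ``constant`` (time-invariant ``magnitude``), ``exp_decay``
    (``magnitude * exp(-t / tau)``, ``tau`` in weeks) and
    ``piecewise_constant`` (``levels[0]`` before the first breakpoint, then
    ``levels[k]`` from ``breakpoints[k-1]`` onward).
    """

    kind: str = "constant"
    magnitude: float = 0.0
    tau: Optional[float] = None
    breakpoints: Optional[tuple] = None
    levels: Optional[tuple] = None

    def __post_init__(self):
        if self.kind not in ("constant", "exp_decay", "piecewise_constant"):
            raise ConfigError(f"unknown injury signal kind {self.kind!r}")
        if self.kind in ("constant", "exp_decay"):
            if not np.isfinite(self.magnitude) or self.magnitude < 0:
                raise DomainError(f"magnitude={self.magnitude!r} must be >= 0")
        if self.kind == "exp_decay":
            if self.tau is None or not np.isfinite(self.tau) or self.tau <= 0:
                raise ConfigError("exp_decay requires tau > 0")
        if self.kind == "piecewise_constant":
            bp = np.asarray(self.breakpoints if self.breakpoints is not None else ())
            lv = np.asarray(self.levels if self.levels is not None else ())
            if lv.size != bp.size + 1:
                raise ConfigError("piecewise_constant needs len(levels) == len(breakpoints) + 1")
            if bp.size and not np.all(np.diff(bp) > 0):
                raise ConfigError("piecewise breakpoints must be strictly increasing")
            if np.any(lv < 0):
                raise DomainError("piecewise levels must be >= 0")
            object.__setattr__(self, "breakpoints", tuple(float(b) for b in bp))
            object.__setattr__(self, "levels", tuple(float(v) for v in lv))

    def evaluate(self, t):
        """Signal value at time(s) ``t`` (weeks, >= 0). Scalar in, scalar out."""
        arr = np.asarray(t, dtype=float)
        if np.any(arr < 0):
            raise DomainError("injury signals are defined for t >= 0 only")
        if self.kind == "constant":
            out = np.full_like(arr, self.magnitude)
        elif self.kind == "exp_decay":
            out = self.magnitude * np.exp(-arr / self.tau)
        else:
            idx = np.searchsorted(np.asarray(self.breakpoints), arr, side="right")
            out = np.asarray(self.levels)[idx]
        return float(out) if np.isscalar(t) or arr.ndim == 0 else out

    def integral(self, t):
        """Exact integral of the signal from 0 to ``t`` (closed form).

        Keeps quadrature of the forcing exact for the built-in signal
        families, including piecewise-constant inputs whose breakpoints need
        not align with the integration grid.
        """
        arr = np.asarray(t, dtype=float)
        if np.any(arr < 0):
            raise DomainError("injury signals are defined for t >= 0 only")
        if self.kind == "constant":
            out = self.magnitude * arr
        elif self.kind == "exp_decay":
            out = self.magnitude * self.tau * (1.0 - np.exp(-arr / self.tau))
        else:
            bp = np.asarray(self.breakpoints)
            lv = np.asarray(self.levels)
            starts = np.concatenate([[0.0], bp])
            # cumulative integral up to each segment start
            base = (np.concatenate([[0.0], np.cumsum(lv[:-1] * np.diff(starts))])
                    if bp.size else np.array([0.0]))
            idx = np.searchsorted(bp, arr, side="right")
            out = base[idx] + lv[idx] * (arr - starts[idx])
        return float(out) if np.isscalar(t) or arr.ndim == 0 else out

    def scaled(self, factor: float) -> "InjurySignal":
        """Same time course with magnitude(s) multiplied by ``factor`` >= 0."""
        if factor < 0:
            raise DomainError("scale factor must be >= 0")
        if self.kind == "piecewise_constant":
            return replace(self, levels=tuple(v * factor for v in self.levels))
        return replace(self, magnitude=self.magnitude * factor)

    def as_dict(self) -> dict:
        d = {"kind": self.kind}
        if self.kind in ("constant", "exp_decay"):
            d["magnitude"] = self.magnitude
        if self.kind == "exp_decay":
            d["tau"] = self.tau
        if self.kind == "piecewise_constant":
            d["breakpoints"] = list(self.breakpoints)
            d["levels"] = list(self.levels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "InjurySignal":
        d = dict(d)
        if "breakpoints" in d and d["breakpoints"] is not None:
            d["breakpoints"] = tuple(d["breakpoints"])
        if "levels" in d and d["levels"] is not None:
            d["levels"] = tuple(d["levels"])
        return cls(**d)


ZERO_SIGNAL = InjurySignal(kind="constant", magnitude=0.0)


def _course_value(course, t):
    """Evaluate a scalar-or-signal receptor term at time t."""
    if course is None:
        return 0.0
    if isinstance(course, InjurySignal):
        return course.evaluate(t)
    return float(course) if np.isscalar(t) else np.full_like(np.asarray(t, dtype=float), float(course))


@dataclass(frozen=True)
class ReceptorExtension:
    """Receptor-driven gain support ``H(t) = max(0, G0 + zeta * R_net(t))``.

    ``R_net(t) = R0 + R_stim(t) + R_loss(t)`` with ``R_loss`` conventionally
    <= 0.  ``R_stim``/``R_loss`` may be plain reals or :class:`InjurySignal`
    time courses; a signal supplied for ``R_loss`` contributes its (negated)
    nonnegative value, i.e. it is interpreted as the magnitude of the loss.
    """

    enabled: bool = False
    zeta: float = 0.5
    R0: float = 0.0
    R_stim: Union[float, InjurySignal] = 0.0
    R_loss: Union[float, InjurySignal] = 0.0

    def net(self, t):
        loss = _course_value(self.R_loss, t)
        if isinstance(self.R_loss, InjurySignal):
            loss = -loss
        return self.R0 + _course_value(self.R_stim, t) + loss

    def stim_relief(self, t, ):
        """Shortfall-convention relief term ``max(0, zeta * R_stim(t))``."""
        return np.maximum(0.0, self.zeta * _course_value(self.R_stim, t))


@dataclass(frozen=True)
class ModelConfig:
    """Integration and classification settings.

    ``collapse_convention`` selects the gain-collapse bracket ("shortfall"
    default, "literal" for the printed equation).  ``step`` is the
    integration step in weeks; ``entrapment_threshold`` is the adaptability
    level below which a trajectory counts as entrapped.
    """

    collapse_convention: str = "shortfall"
    N_floor: float = 0.0
    step: float = 0.1
    entrapment_threshold: float = 0.3

    def __post_init__(self):
        if self.collapse_convention not in ("literal", "shortfall"):
            raise ConfigError(f"unknown collapse convention {self.collapse_convention!r}")
        if self.step <= 0:
            raise ConfigError("integration step must be > 0")
        if self.N_floor < 0:
            raise ConfigError("N_floor must be >= 0")
        if not (0.0 < self.entrapment_threshold < 1.0):
            raise ConfigError("entrapment threshold must lie in (0, 1)")


@dataclass
class Trajectory:
    """Integrated adaptability trajectory on a uniform weekly grid.

    ``cumulative_load`` is the running integral of the total load, so the
    pre-clamp decline at any grid time is ``eta * cumulative_load``.
    """

    times: np.ndarray
    N: np.ndarray
    behavioral_load: np.ndarray
    gain_collapse: np.ndarray
    total_load: np.ndarray
    cumulative_load: np.ndarray
    entrapped: bool = False
    crossing_time: Optional[float] = None

    def interp_N(self, t):
        return np.interp(t, self.times, self.N)

    def interp_total_load(self, t):
        return np.interp(t, self.times, self.total_load)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_weeks": self.times,
            "N": self.N,
            "behavioral_load": self.behavioral_load,
            "gain_collapse": self.gain_collapse,
            "total_load": self.total_load,
        })


# ---------------------------------------------------------------------------
# scalar operations
# ---------------------------------------------------------------------------

def evaluate_injury(signal: InjurySignal, t: float) -> float:
    """Value of an injury signal at time ``t`` (weeks)."""
    return signal.evaluate(t)


def _check_nonneg_inputs(I_t, CI_t):
    if I_t < 0 or CI_t < 0:
        raise DomainError(f"injury inputs must be >= 0 (got I={I_t}, C_I={CI_t})")


def behavioral_load(p: NerdParameters, I_t: float, CI_t: float) -> float:
    """Chi-weighted behavioral stress component.

    ``chi * (kappa*gamma*alpha*I + nu*rho*(lambda*mu*gamma*alpha*I + sigma*C_I))``,
    linear and nonnegative in the injury inputs.
    """
    _check_nonneg_inputs(I_t, CI_t)
    return p.behavioral_slope_I * I_t + p.behavioral_slope_CI * CI_t


def gain_collapse(
    p: NerdParameters,
    I_t: float,
    CI_t: float,
    cfg: ModelConfig,
    H_t: Optional[float] = None,
    relief_t: float = 0.0,
    receptor_enabled: bool = False,
) -> float:
    """Psi-weighted gain-control collapse component.

    Literal convention: ``psi * (G* - degradations)`` with ``G*`` the
    receptor support ``H_t`` when the extension is enabled, else ``G0``.
    Shortfall convention: ``psi * max(0, degradations - relief_t)``.
    """
    _check_nonneg_inputs(I_t, CI_t)
    degradation = p.degradation_slope_I * I_t + p.degradation_slope_CI * CI_t
    if cfg.collapse_convention == "literal":
        if receptor_enabled:
            if H_t is None:
                raise ContractError("receptor extension enabled but H_t not supplied")
            g_star = H_t
        else:
            g_star = p.G0 if H_t is None else H_t
        return p.psi * (g_star - degradation)
    return p.psi * max(0.0, degradation - relief_t)


def dN_dt(
    p: NerdParameters,
    I_t: float,
    CI_t: float,
    cfg: ModelConfig,
    H_t: Optional[float] = None,
    relief_t: float = 0.0,
    receptor_enabled: bool = False,
) -> float:
    """Instantaneous adaptability decline ``-eta * (behavioral + collapse)``."""
    return -p.eta * (
        behavioral_load(p, I_t, CI_t)
        + gain_collapse(p, I_t, CI_t, cfg, H_t, relief_t, receptor_enabled)
    )


def receptor_gain_support(ext: ReceptorExtension, t: float, G0: float) -> float:
    """``H(t) = max(0, G0 + zeta * R_net(t))``; requires an enabled extension."""
    if not ext.enabled:
        raise ContractError("receptor extension is disabled")
    if np.any(np.asarray(t) < 0):
        raise DomainError("t must be >= 0")
    return np.maximum(0.0, G0 + ext.zeta * ext.net(t))


# ---------------------------------------------------------------------------
# trajectory integration
# ---------------------------------------------------------------------------

def _time_grid(horizon: float, step: float) -> np.ndarray:
    if horizon <= 0:
        raise DomainError("horizon must be > 0")
    n = int(np.floor(horizon / step + 1e-9))
    times = np.arange(n + 1) * step
    if horizon - times[-1] > 1e-9 * max(1.0, horizon):
        times = np.append(times, horizon)  # tolerate a partial last step
    return times


def load_components(
    p: NerdParameters,
    I_arr: np.ndarray,
    CI_arr: np.ndarray,
    cfg: ModelConfig,
    ext: Optional[ReceptorExtension],
    times: np.ndarray,
):
    """Vectorized behavioral-load and gain-collapse arrays on a time grid."""
    bl = p.behavioral_slope_I * I_arr + p.behavioral_slope_CI * CI_arr
    degradation = p.degradation_slope_I * I_arr + p.degradation_slope_CI * CI_arr
    if cfg.collapse_convention == "literal":
        if ext is not None and ext.enabled:
            g_star = receptor_gain_support(ext, times, p.G0)
        else:
            g_star = p.G0
        gc = p.psi * (g_star - degradation)
    else:
        relief = ext.stim_relief(times) if (ext is not None and ext.enabled) else 0.0
        gc = p.psi * np.maximum(0.0, degradation - relief)
    return bl, gc


def cumulative_load_exact(
    p: NerdParameters,
    I: InjurySignal,
    CI: InjurySignal,
    cfg: ModelConfig,
    times: np.ndarray,
) -> np.ndarray:
    """Closed-form running integral of the total load (no receptor extension).

    Shortfall bracket degradations are nonnegative whenever the inputs are,
    so the max(0, .) clamp never binds and the total load is exactly
    ``c_I * I(t) + c_CI * C_I(t)`` (plus ``psi * G0`` under the literal
    convention), integrable via the signals' own closed-form integrals.
    """
    i_int = np.asarray(I.integral(times), dtype=float)
    ci_int = np.asarray(CI.integral(times), dtype=float)
    c_i = p.behavioral_slope_I
    c_ci = p.behavioral_slope_CI
    if cfg.collapse_convention == "literal":
        return (
            (c_i - p.psi * p.degradation_slope_I) * i_int
            + (c_ci - p.psi * p.degradation_slope_CI) * ci_int
            + p.psi * p.G0 * times
        )
    return (
        (c_i + p.psi * p.degradation_slope_I) * i_int
        + (c_ci + p.psi * p.degradation_slope_CI) * ci_int
    )


def integrate_trajectory(
    p: NerdParameters,
    I: InjurySignal,
    CI: InjurySignal,
    cfg: ModelConfig,
    ext: Optional[ReceptorExtension] = None,
    horizon: float = 24.0,
) -> Trajectory:
    """Integrate ``N(t)`` over ``[0, horizon]`` weeks by trapezoidal quadrature.

    The forcing does not depend on ``N``, so ``N(t) = N0 - eta * integral of
    the total load``, clamped to ``[N_floor, N0]``.  When the load can change
    sign (literal convention with receptor support), clamping is applied
    stepwise so that decline restarts from the clamp rather than from the
    unclamped quadrature.
    """
    times = _time_grid(horizon, cfg.step)
    if cfg.N_floor >= p.N0:
        raise ConfigError("N_floor must be below N0")
    I_arr = np.asarray(I.evaluate(times), dtype=float)
    CI_arr = np.asarray(CI.evaluate(times), dtype=float)
    bl, gc = load_components(p, I_arr, CI_arr, cfg, ext, times)
    bl = np.broadcast_to(np.asarray(bl, dtype=float), times.shape)
    gc = np.broadcast_to(np.asarray(gc, dtype=float), times.shape)
    total = bl + gc
    if not np.all(np.isfinite(total)):
        bad = int(np.argmax(~np.isfinite(total)))
        raise NumericalError(
            f"non-finite load at t={times[bad]:.4g} weeks", time=float(times[bad])
        )
    if ext is None or not ext.enabled:
        # both load components are linear combinations of I and C_I (plus a
        # constant under the literal convention), so the quadrature is exact
        cum = cumulative_load_exact(p, I, CI, cfg, times)
    else:
        cum = cumulative_trapezoid(total, times, initial=0.0)
    if np.all(np.diff(cum) >= 0.0):
        # monotone decline: clamping the quadrature is the exact clamped path
        N = np.clip(p.N0 - p.eta * cum, cfg.N_floor, p.N0)
    else:
        N = np.empty_like(times)
        N[0] = p.N0
        steps = p.eta * np.diff(cum)
        for i, s in enumerate(steps):
            N[i + 1] = min(max(N[i] - s, cfg.N_floor), p.N0)
    traj = Trajectory(
        times=times, N=N, behavioral_load=bl.copy(), gain_collapse=gc.copy(),
        total_load=total, cumulative_load=cum,
    )
    traj.entrapped, traj.crossing_time = classify_entrapment(traj, cfg.entrapment_threshold)
    return traj


def classify_entrapment(traj: Trajectory, threshold: float):
    """Whether ``N`` ever falls strictly below ``threshold``, and when.

    The crossing time is linearly interpolated between the bracketing grid
    points; touching the threshold exactly does not count as crossing.
    """
    if not (0.0 < threshold < 1.0):
        raise ConfigError("entrapment threshold must lie in (0, 1)")
    below = traj.N < threshold
    if not np.any(below):
        return False, None
    i = int(np.argmax(below))
    if i == 0:
        return True, float(traj.times[0])
    n_prev, n_cur = traj.N[i - 1], traj.N[i]
    t_prev, t_cur = traj.times[i - 1], traj.times[i]
    frac = (n_prev - threshold) / (n_prev - n_cur)
    return True, float(t_prev + frac * (t_cur - t_prev))
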
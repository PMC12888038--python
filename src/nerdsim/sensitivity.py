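"""Parameter sensitivity of trajectory-level outputs.

Two complementary views: local central-difference derivatives of a scalar
output at a base point, and global first-order variance-based indices over
the priors, estimated with a binned correlation-ratio estimator (conditional
means over equal-count bins of each input).  The supported outputs are the
final adaptability ``final_N``, the entrapment ``crossing_time`` (censored
at the horizon when no crossing occurs, for the global analysis), and the
``integrated_load`` (time integral of the total forcing, before the eta
scaling).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np

from ._errors import ConfigError
from .model import (
    COEFFICIENT_NAMES, InjurySignal, ModelConfig, NerdParameters,
    ReceptorExtension, integrate_trajectory,
)
from .priors import PriorSet, sample_parameters

__all__ = ["OUTPUTS", "SensitivityReport", "local_sensitivity", "variance_sensitivity"]

OUTPUTS = ("final_N", "crossing_time", "integrated_load")


def _output_value(p, I, CI, cfg, ext, horizon, output):
    traj = integrate_trajectory(p, I, CI, cfg, ext=ext, horizon=horizon)
    if output == "final_N":
        return float(traj.N[-1])
    if output == "crossing_time":
        return None if traj.crossing_time is None else float(traj.crossing_time)
    if output == "integrated_load":
        return float(traj.cumulative_load[-1])
    raise ConfigError(f"unknown sensitivity output {output!r}")


@dataclass
class SensitivityReport:
    output: str
    derivatives: Dict[str, Optional[float]] = field(default_factory=dict)
    indices: Dict[str, float] = field(default_factory=dict)
    degenerate_output: bool = False

    @property
    def ranking(self):
        """Parameter names by decreasing first-order index."""
        return sorted(self.indices, key=self.indices.get, reverse=True)


def local_sensitivity(
    p: NerdParameters,
    I: InjurySignal,
    CI: InjurySignal,
    cfg: ModelConfig,
    output: str = "final_N",
    h: float = 1e-4,
    ext: Optional[ReceptorExtension] = None,
    horizon: float = 24.0,
    parameters: Optional[Sequence[str]] = None,
) -> Dict[str, Optional[float]]:
    """Central finite-difference derivatives of ``output`` at the base point.

    Coefficients near the unit-interval boundary fall back to a one-sided
    difference.  A crossing time undefined at the base point (or at a
    perturbed point) yields ``None`` for the affected entries.
    """
    if h <= 0:
        raise ConfigError("finite-difference step h must be > 0")
    if output not in OUTPUTS:
        raise ConfigError(f"unknown sensitivity output {output!r}")
    names = list(parameters) if parameters is not None else list(COEFFICIENT_NAMES) + ["G0"]
    base = _output_value(p, I, CI, cfg, ext, horizon, output)
    out: Dict[str, Optional[float]] = {}
    for name in names:
        x = getattr(p, name)
        upper = np.inf if name == "G0" else 1.0
        lo, hi = max(x - h, 0.0), min(x + h, upper)
        if hi <= lo:
            out[name] = None
            continue
        f_lo = _output_value(p.updated(**{name: lo}), I, CI, cfg, ext, horizon, output)
        f_hi = _output_value(p.updated(**{name: hi}), I, CI, cfg, ext, horizon, output)
        if base is None or f_lo is None or f_hi is None:
            out[name] = None
            continue
        out[name] = (f_hi - f_lo) / (hi - lo)
    return out


def _first_order_index(x: np.ndarray, y: np.ndarray, n_bins: int) -> float:
    """Correlation-ratio estimate Var(E[Y|X in bin]) / Var(Y), equal-count bins."""
    order = np.argsort(x, kind="mergesort")
    ys = y[order]
    groups = np.array_split(ys, n_bins)
    sizes = np.array([g.size for g in groups], dtype=float)
    means = np.array([g.mean() for g in groups])
    grand = ys.mean()
    between = np.sum(sizes * (means - grand) ** 2) / ys.size
    total = y.var()
    return float(np.clip(between / total, 0.0, 1.0))


def variance_sensitivity(
    priors: PriorSet,
    I: InjurySignal,
    CI: InjurySignal,
    cfg: ModelConfig,
    output: str = "final_N",
    n: int = 10_000,
    seed=None,
    ext: Optional[ReceptorExtension] = None,
    horizon: float = 24.0,
    n_bins: int = 20,
    output_fn=None,
) -> SensitivityReport:
    """First-order variance-based indices of ``output`` over the priors.

    ``output_fn``, when given, overrides the named output with an arbitrary
    callable of a :class:`NerdParameters` (used for constructed test
    functions).  Crossing times are censored at the horizon.  A (nearly)
    constant output yields all-zero indices with the degenerate flag set.
    """
    if n < 1000:
        raise ConfigError("variance-based indices need n >= 1000 draws")
    params = sample_parameters(priors, n, seed=seed)
    if output_fn is None:
        if output not in OUTPUTS:
            raise ConfigError(f"unknown sensitivity output {output!r}")

        def output_fn(p):
            v = _output_value(p, I, CI, cfg, ext, horizon, output)
            return horizon if v is None else v

    y = np.array([output_fn(p) for p in params], dtype=float)
    names = list(COEFFICIENT_NAMES)
    report = SensitivityReport(output=output)
    if y.var() <= 1e-12 * max(1.0, abs(y.mean())) ** 2:
        report.indices = {name: 0.0 for name in names}
        report.degenerate_output = True
        return report
    x = {name: np.array([getattr(p, name) for p in params]) for name in names}
    report.indices = {name: _first_order_index(x[name], y, n_bins) for name in names}
    return report
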
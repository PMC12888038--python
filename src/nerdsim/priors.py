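"""Beta priors for the model coefficients, moment-matched to literature ranges.

Each coefficient has a published plausible range inside the unit interval.
The prior is the Beta distribution whose mean is the range midpoint (the
reflex-to-motor scaling ``alpha`` is the one exception: its worked example
fixes the mean at 0.5) and whose standard deviation is a quarter of the
range width, so the range covers roughly the central 95% of prior mass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional

import numpy as np
from scipy import stats

from ._errors import ConfigError
from .model import COEFFICIENT_NAMES, NerdParameters

__all__ = ["PriorSpec", "PriorSet", "beta_from_range", "default_priors", "sample_parameters"]

#: Literature ranges for the twelve coefficients (low, high) and, where a
#: worked example pins it, an explicit prior mean.
DEFAULT_RANGES: Dict[str, tuple] = {
    "alpha": (0.3, 0.8, 0.5),
    "gamma": (0.4, 0.9, None),
    "mu": (0.2, 0.6, None),
    "lambda_": (0.3, 0.7, None),
    "rho": (0.4, 0.8, None),
    "nu": (0.2, 0.5, None),
    "chi": (0.3, 0.6, None),
    "kappa": (0.2, 0.5, None),
    "sigma": (0.3, 0.7, None),
    "xi": (0.4, 0.8, None),
    "psi": (0.3, 0.7, None),
    "eta": (0.1, 0.3, None),
}


@dataclass(frozen=True)
class PriorSpec:
    """A Beta prior on (0, 1) for one named coefficient."""

    name: str
    range_lo: float
    range_hi: float
    mean: float
    shape_a: float
    shape_b: float

    def __post_init__(self):
        if not (0.0 <= self.range_lo < self.range_hi <= 1.0):
            raise ConfigError(f"{self.name}: invalid range [{self.range_lo}, {self.range_hi}]")
        if not (self.range_lo <= self.mean <= self.range_hi):
            raise ConfigError(f"{self.name}: mean {self.mean} outside its range")
        if self.shape_a <= 0 or self.shape_b <= 0:
            raise ConfigError(f"{self.name}: Beta shapes must be positive")
        implied = self.shape_a / (self.shape_a + self.shape_b)
        if abs(implied - self.mean) > 1e-9:
            raise ConfigError(f"{self.name}: shapes imply mean {implied}, stated {self.mean}")

    @property
    def sd(self) -> float:
        a, b = self.shape_a, self.shape_b
        return float(np.sqrt(a * b / ((a + b) ** 2 * (a + b + 1))))

    def distribution(self):
        return stats.beta(self.shape_a, self.shape_b)

    def logpdf(self, x: float) -> float:
        return float(stats.beta.logpdf(x, self.shape_a, self.shape_b))

    def ppf(self, q: float) -> float:
        return float(stats.beta.ppf(q, self.shape_a, self.shape_b))

    def sample(self, rng: np.random.Generator, size=None):
        return rng.beta(self.shape_a, self.shape_b, size=size)

    def as_dict(self) -> dict:
        return {
            "lo": self.range_lo, "hi": self.range_hi, "mean": self.mean,
            "a": self.shape_a, "b": self.shape_b,
        }

    @classmethod
    def from_dict(cls, name: str, d: dict) -> "PriorSpec":
        return cls(name=name, range_lo=d["lo"], range_hi=d["hi"],
                   mean=d["mean"], shape_a=d["a"], shape_b=d["b"])


def beta_from_range(lo: float, hi: float, mean: Optional[float] = None,
                    name: str = "", sd: Optional[float] = None) -> PriorSpec:
    """Moment-match a Beta prior to a plausible range.

    The mean defaults to the range midpoint; the standard deviation defaults
    to ``(hi - lo) / 4`` so the stated range carries ~95% of the mass under a
    normal approximation.  Shapes solve the moment equations
    ``concentration = m(1-m)/v - 1``, ``a = m * concentration``,
    ``b = (1-m) * concentration``.
    """
    if not (0.0 <= lo < hi <= 1.0):
        raise ConfigError(f"degenerate or out-of-bounds range [{lo}, {hi}]")
    m = 0.5 * (lo + hi) if mean is None else float(mean)
    if not (0.0 < m < 1.0):
        raise ConfigError(f"prior mean {m} must lie strictly inside (0, 1)")
    s = (hi - lo) / 4.0 if sd is None else float(sd)
    v = s * s
    if v >= m * (1.0 - m):
        raise ConfigError(
            f"variance {v:.4g} >= m(1-m) = {m * (1 - m):.4g}: no valid Beta distribution"
        )
    concentration = m * (1.0 - m) / v - 1.0
    return PriorSpec(
        name=name, range_lo=lo, range_hi=hi, mean=m,
        shape_a=m * concentration, shape_b=(1.0 - m) * concentration,
    )


@dataclass
class PriorSet:
    """Named collection of coefficient priors (optionally including ``G0``)."""

    specs: Dict[str, PriorSpec]
    provenance: str = ""

    def __getitem__(self, name: str) -> PriorSpec:
        return self.specs[name]

    def __contains__(self, name: str) -> bool:
        return name in self.specs

    def names(self) -> Iterable[str]:
        return self.specs.keys()

    def require(self, names: Iterable[str]) -> None:
        missing = [n for n in names if n not in self.specs]
        if missing:
            raise ConfigError(f"missing priors for: {', '.join(missing)}")

    def mean_parameters(self, G0: float = 1.0, N0: float = 1.0) -> NerdParameters:
        """Point at every prior mean — the default fixed values when fitting."""
        self.require(COEFFICIENT_NAMES)
        vals = {n: self.specs[n].mean for n in COEFFICIENT_NAMES}
        if "G0" in self.specs:
            G0 = self.specs["G0"].mean
        return NerdParameters(**vals, G0=G0, N0=N0)

    def as_dict(self) -> dict:
        return {name: spec.as_dict() for name, spec in self.specs.items()}

    @classmethod
    def from_dict(cls, d: dict, provenance: str = "") -> "PriorSet":
        return cls({name: PriorSpec.from_dict(name, sub) for name, sub in d.items()},
                   provenance=provenance)


def default_priors() -> PriorSet:
    """One moment-matched Beta prior per coefficient from the default ranges."""
    specs = {
        name: beta_from_range(lo, hi, mean=mean, name=name)
        for name, (lo, hi, mean) in DEFAULT_RANGES.items()
    }
    return PriorSet(specs, provenance="literature ranges, sd = width/4")


def sample_parameters(priors: PriorSet, n: int, seed=None) -> list:
    """Draw ``n`` independent coefficient vectors from the priors.

    Coefficients are drawn in canonical name order so draws are reproducible
    for a given seed.  ``G0`` is fixed at 1.0 unless a G0 prior is supplied.
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    priors.require(COEFFICIENT_NAMES)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = {name: priors[name].sample(rng, size=n) for name in COEFFICIENT_NAMES}
    g0 = priors["G0"].sample(rng, size=n) if "G0" in priors else np.ones(n)
    return [
        NerdParameters(**{name: float(draws[name][i]) for name in COEFFICIENT_NAMES},
                       G0=float(g0[i]))
        for i in range(n)
    ]
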
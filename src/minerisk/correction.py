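"""Eight-factor correction model for unsafe-behavior probabilities.

A raw behavior frequency P' understates or overstates the true occurrence
probability depending on the working conditions of the role. Eight
influencing factors, each an expert-elicited dimensionless score on
[0, 10] treated as a triangular random variable, enter a linear correction
factor in three families:

- organizational: a (rules and regulations), b (education and training),
  c (safety reward), combined with weights (0.2, 0.6, 0.2);
- human-machine: d (workload), e (device), f (working environment),
  combined as an unweighted mean;
- personal: g (safety physiology/psychology), h (skills and knowledge),
  combined as an unweighted mean.

The correction factor is

    F = intercept - slope * [ (0.2a + 0.6b + 0.2c) + (d+e+f)/3 + (g+h)/2 ]

with default slope 0.0167 and intercept 1.5, so F is strictly decreasing
in every factor and lies in [0.999, 1.5] for scores in [0, 10]. The revised
probability is P = P' * F.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "FACTORS",
    "FactorRange",
    "FactorProfile",
    "ModelCoefficients",
    "FactorSampleSet",
    "DEFAULT_COEFFICIENTS",
    "correction_factor",
    "correction_factor_mean",
    "sample_factors",
    "revised_probability",
]

#: The eight influencing factors, in family order.
FACTORS: Tuple[str, ...] = ("a", "b", "c", "d", "e", "f", "g", "h")

_ORG = ("a", "b", "c")
_HUMAN_MACHINE = ("d", "e", "f")
_PERSONAL = ("g", "h")


@dataclass(frozen=True)
class FactorRange:
    """Triangular elicitation range for one factor.

    ``mode`` defaults to the midpoint (symmetric triangular), which makes
    the triangular mean equal the midpoint. Scores live on [0, 10]; the
    elicitation bands in use are [0, 1], [1, 3] and [3, 10].
    """

    factor: str
    lower: float
    upper: float
    mode: Optional[float] = None

    def __post_init__(self) -> None:
        if self.factor not in FACTORS:
            raise ValueError(f"unknown factor {self.factor!r}")
        m = self.midmode
        if not (0.0 <= self.lower <= m <= self.upper <= 10.0):
            raise ValueError(
                f"factor {self.factor!r}: require 0 <= lower <= mode <= upper <= 10, "
                f"got ({self.lower}, {m}, {self.upper})"
            )

    @property
    def midmode(self) -> float:
        return (self.lower + self.upper) / 2.0 if self.mode is None else self.mode

    @property
    def mean(self) -> float:
        """Triangular mean (lower + mode + upper) / 3."""
        return (self.lower + self.midmode + self.upper) / 3.0

    @property
    def variance(self) -> float:
        l, m, u = self.lower, self.midmode, self.upper
        return (l * l + m * m + u * u - l * m - l * u - m * u) / 18.0

    def ppf(self, q: np.ndarray) -> np.ndarray:
        """Triangular inverse CDF; degenerate ranges return the point mass."""
        l, m, u = self.lower, self.midmode, self.upper
        width = u - l
        if width == 0.0:
            return np.full_like(np.asarray(q, dtype=float), l)
        c = (m - l) / width
        return stats.triang.ppf(q, c, loc=l, scale=width)


@dataclass
class FactorProfile:
    """Per-working-type ranges for all eight factors."""

    working_type: str
    ranges: Dict[str, FactorRange]

    def __post_init__(self) -> None:
        missing = [f for f in FACTORS if f not in self.ranges]
        extra = [f for f in self.ranges if f not in FACTORS]
        if missing or extra:
            raise ValueError(
                f"profile for {self.working_type!r} must hold exactly the factors "
                f"{''.join(FACTORS)}; missing {missing}, unexpected {extra}"
            )


@dataclass(frozen=True)
class ModelCoefficients:
    """Coefficients of the linear correction model (taken from prior work)."""

    org_weights: Tuple[float, float, float] = (0.2, 0.6, 0.2)
    slope: float = 0.0167
    intercept: float = 1.5

    def __post_init__(self) -> None:
        if abs(sum(self.org_weights) - 1.0) > 1e-9:
            raise ValueError("organizational weights must sum to 1")


DEFAULT_COEFFICIENTS = ModelCoefficients()


@dataclass
class FactorSampleSet:
    """Seeded triangular realizations of the eight factors."""

    n: int
    seed: Optional[int]
    values: Dict[str, np.ndarray] = field(default_factory=dict)

    def correction_factors(
        self, coeffs: ModelCoefficients = DEFAULT_COEFFICIENTS
    ) -> np.ndarray:
        """Vectorized F over the sampled factor vectors."""
        return _factor_combination(self.values, coeffs)


def _validate_values(values: Mapping[str, float | np.ndarray]) -> None:
    for f in FACTORS:
        if f not in values:
            raise ValueError(f"missing factor {f!r}")
        v = np.asarray(values[f], dtype=float)
        if np.any(v < 0.0) or np.any(v > 10.0):
            raise ValueError(f"factor {f!r} outside the score range [0, 10]")


def _factor_combination(
    values: Mapping[str, float | np.ndarray], coeffs: ModelCoefficients
) -> np.ndarray | float:
    wa, wb, wc = coeffs.org_weights
    org = wa * np.asarray(values["a"]) + wb * np.asarray(values["b"]) + wc * np.asarray(values["c"])
    hm = (np.asarray(values["d"]) + np.asarray(values["e"]) + np.asarray(values["f"])) / 3.0
    per = (np.asarray(values["g"]) + np.asarray(values["h"])) / 2.0
    return coeffs.intercept - coeffs.slope * (org + hm + per)


def correction_factor(
    values: Mapping[str, float], coeffs: ModelCoefficients = DEFAULT_COEFFICIENTS
) -> float:
    """Evaluate the correction factor F at one set of factor scores.

    All eight factors must be supplied, each in [0, 10]. With the default
    coefficients the result lies in [0.999, 1.5].
    """
    _validate_values(values)
    return float(_factor_combination(values, coeffs))


def correction_factor_mean(
    profile: FactorProfile, coeffs: ModelCoefficients = DEFAULT_COEFFICIENTS
) -> float:
    """F evaluated at each factor's triangular mean.

    Because F is linear in the factors this equals the expectation of F
    over the triangular factor distributions; with default (symmetric)
    modes it coincides with F at the range midpoints.
    """
    means = {f: profile.ranges[f].mean for f in FACTORS}
    return correction_factor(means, coeffs)


def sample_factors(
    profile: FactorProfile, n: int, seed: Optional[int] = None
) -> FactorSampleSet:
    """Draw independent triangular samples for each factor.

    Samples are generated as the triangular inverse CDF of uniform draws,
    so a shared uniform stream can reproduce them (used by the pooled
    sensitivity run). Identical (profile, n, seed) gives identical output.
    """
    if n < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    values = {f: profile.ranges[f].ppf(rng.random(n)) for f in FACTORS}
    return FactorSampleSet(n=n, seed=seed, values=values)


def revised_probability(p_raw: float, F: float) -> float:
    """Revised occurrence probability P = P' * F, clamped to at most 1."""
    if p_raw < 0.0 or p_raw > 1.0:
        raise ValueError(f"raw probability {p_raw} outside [0, 1]")
    if F <= 0.0:
        raise ValueError(f"correction factor must be positive, got {F}")
    p = p_raw * F
    if p > 1.0:
        warnings.warn(
            f"revised probability {p:.4g} exceeds 1; clamped", stacklevel=2
        )
        return 1.0
    return p
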
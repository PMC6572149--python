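"""Accident-hazard index: possibility and severity grades, I = B * C.

The consequence of an unsafe behavior is measured by the accident hazard
index I, the product of the possibility score B that the behavior triggers
an accident (five grades from 0.01 "scarcely possible" to 1 "very likely")
and the severity score C of the resulting loss (five grades from 1, one
minor injury, to 5, multiple fatalities). Per (working type, behavior)
cell, I is modelled as a normal random variable whose mean and standard
deviation come from expert elicitation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

__all__ = [
    "POSSIBILITY_GRADES",
    "SEVERITY_GRADES",
    "HazardIndexSpec",
    "hazard_index",
    "sample_hazard_index",
]

#: Possibility grades B: label -> score.
POSSIBILITY_GRADES: Mapping[str, float] = {
    "Very likely": 1.0,
    "Probably": 0.5,
    "Occasionally": 0.1,
    "Unlikely": 0.05,
    "Scarcely possible": 0.01,
}

#: Severity grades C: degree of injury -> score. The associated economic-loss
#: bands (CNY) are documentation only and do not enter any computation.
SEVERITY_GRADES: Mapping[str, int] = {
    "One person was slightly injured": 1,
    "More than one person was slightly injured": 2,
    "More than one person was seriously injured": 3,
    "One person died": 4,
    "More than one person died": 5,
}

_B_SCORES = frozenset(POSSIBILITY_GRADES.values())
_C_SCORES = frozenset(float(c) for c in SEVERITY_GRADES.values())


@dataclass(frozen=True)
class HazardIndexSpec:
    """Normal distribution of the hazard index for one (type, behavior) cell."""

    working_type: str
    behavior: str
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.mean <= 0.0:
            raise ValueError(
                f"hazard mean must be positive "
                f"({self.working_type}/{self.behavior}: {self.mean})"
            )
        if self.sd < 0.0:
            raise ValueError(
                f"hazard sd must be non-negative "
                f"({self.working_type}/{self.behavior}: {self.sd})"
            )


def hazard_index(B: float, C: float, strict: bool = True) -> float:
    """Accident hazard index I = B * C.

    In strict mode B and C must be grade scores; the permissive mode
    accepts any B in (0, 1] and C in [1, 5].
    """
    if strict:
        if B not in _B_SCORES:
            raise ValueError(f"B={B} is not a possibility grade score")
        if float(C) not in _C_SCORES:
            raise ValueError(f"C={C} is not a severity grade score")
    else:
        if not (0.0 < B <= 1.0):
            raise ValueError(f"B={B} outside (0, 1]")
        if not (1.0 <= C <= 5.0):
            raise ValueError(f"C={C} outside [1, 5]")
    return float(B) * float(C)


def sample_hazard_index(
    spec: HazardIndexSpec,
    n: int,
    seed: Optional[int] = None,
    truncation: str = "none",
) -> np.ndarray:
    """Draw n normal hazard-index samples under a truncation policy.

    Policies: ``none`` returns raw normal draws (the default: the published
    risk moments match untruncated propagation); ``resample`` redraws
    non-positive values, so the empirical mean exceeds the spec mean by the
    analytic truncation bias; ``clip`` sets negative draws to zero.
    """
    if n < 1:
        raise ValueError("need at least one sample")
    if truncation not in ("none", "resample", "clip"):
        raise ValueError(f"unknown truncation policy {truncation!r}")
    rng = np.random.default_rng(seed)
    # affine form: scaling (mean, sd) by k scales the draws by k exactly
    draws = spec.mean + spec.sd * rng.standard_normal(n)
    if truncation == "resample":
        bad = draws <= 0.0
        while np.any(bad):
            draws[bad] = spec.mean + spec.sd * rng.standard_normal(int(bad.sum()))
            bad = draws <= 0.0
    elif truncation == "clip":
        np.clip(draws, 0.0, None, out=draws)
    return draws
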
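"""Monte Carlo propagation of the behavior-risk model R = P * I.

Each iteration draws one set of factor scores per working type (the
correction factor is a property of the role's working conditions, so one
realization is shared by all behavior classes of that type), giving the
revised probability P = P' * F, and one hazard-index realization per
behavior class, giving the per-behavior risk R = P * I. Simulated risk
distributions are summarized by arithmetic moments, a five-number summary
and a best-fit family; in this model they come out right-skewed and are
typically best fit by a lognormal.

Per-working-type totals sum the per-behavior risks. Under the default
comonotonic aggregation the components are coupled at perfect rank
correlation, so the total's standard deviation equals the sum of the
component standard deviations; the independent mode couples them at zero
correlation (total variance equals the sum of variances).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .correction import DEFAULT_COEFFICIENTS, FactorProfile, ModelCoefficients
from .hazard import HazardIndexSpec

__all__ = [
    "SimulationConfig",
    "RiskSummary",
    "WorkingTypeRiskReport",
    "simulate_behavior_risk",
    "simulate_working_type",
    "summarize",
    "fit_distribution",
    "total_risk",
    "total_risk_samples",
    "assess_working_type",
]

_FIT_FAMILIES = ("normal", "lognormal", "triangular", "uniform")


@dataclass(frozen=True)
class SimulationConfig:
    """Settings of one Monte Carlo run."""

    iterations: int = 10_000
    seed: int = 0
    confidence: float = 0.95
    truncation: str = "none"
    total_mode: str = "comonotonic"
    coefficients: ModelCoefficients = DEFAULT_COEFFICIENTS

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not (0.0 < self.confidence < 1.0):
            raise ValueError("confidence must be in (0, 1)")
        if self.truncation not in ("none", "resample", "clip"):
            raise ValueError(f"unknown truncation policy {self.truncation!r}")
        if self.total_mode not in ("comonotonic", "independent"):
            raise ValueError(f"unknown total mode {self.total_mode!r}")


@dataclass
class RiskSummary:
    """Moments, quantiles and best-fit family of a simulated risk distribution."""

    mean: float
    sd: float
    quantiles: Dict[str, float]
    fit_family: Optional[str] = None
    fit_params: Optional[Dict[str, float]] = None
    n: int = 0

    def as_dict(self) -> dict:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "quantiles": dict(self.quantiles),
            "fit_family": self.fit_family,
            "fit_params": dict(self.fit_params) if self.fit_params else None,
            "n": self.n,
        }


@dataclass
class WorkingTypeRiskReport:
    """Per-behavior summaries and the aggregated total for one working type."""

    working_type: str
    per_behavior: Dict[str, RiskSummary] = field(default_factory=dict)
    total: Optional[RiskSummary] = None


def _spawn_rngs(seed: int, n: int) -> list:
    children = np.random.SeedSequence(seed).spawn(n)
    return [np.random.default_rng(c) for c in children]


def _hazard_draws(
    spec: HazardIndexSpec, rng: np.random.Generator, n: int, truncation: str
) -> np.ndarray:
    draws = spec.mean + spec.sd * rng.standard_normal(n)
    if truncation == "resample":
        bad = draws <= 0.0
        while np.any(bad):
            draws[bad] = spec.mean + spec.sd * rng.standard_normal(int(bad.sum()))
            bad = draws <= 0.0
    elif truncation == "clip":
        np.clip(draws, 0.0, None, out=draws)
    return draws


def _factor_draws(
    profile: FactorProfile, rng: np.random.Generator, n: int
) -> Dict[str, np.ndarray]:
    from .correction import FACTORS

    return {f: profile.ranges[f].ppf(rng.random(n)) for f in FACTORS}


def simulate_working_type(
    p_raw: Mapping[str, float],
    profile: FactorProfile,
    specs: Mapping[str, HazardIndexSpec],
    cfg: SimulationConfig,
) -> Dict[str, np.ndarray]:
    """Simulate risk sample sequences for all behavior classes of one type.

    One factor realization per iteration is shared across the behavior
    classes; hazard-index draws are per-behavior from independently spawned
    streams. Returns a mapping behavior code -> length-``iterations`` array.
    """
    codes = list(specs)
    missing = [c for c in codes if c not in p_raw]
    if missing:
        raise ValueError(f"no raw probability for behavior(s) {missing}")
    rngs = _spawn_rngs(cfg.seed, 1 + len(codes))
    from .correction import _factor_combination

    values = _factor_draws(profile, rngs[0], cfg.iterations)
    F = np.asarray(_factor_combination(values, cfg.coefficients))
    out: Dict[str, np.ndarray] = {}
    for code, rng in zip(codes, rngs[1:]):
        P = np.minimum(p_raw[code] * F, 1.0)
        I = _hazard_draws(specs[code], rng, cfg.iterations, cfg.truncation)
        out[code] = P * I
    return out


def simulate_behavior_risk(
    p_raw: float,
    profile: FactorProfile,
    spec: HazardIndexSpec,
    cfg: SimulationConfig,
) -> np.ndarray:
    """Simulate the risk sample sequence of a single behavior class."""
    if not (0.0 <= p_raw <= 1.0):
        raise ValueError(f"raw probability {p_raw} outside [0, 1]")
    return simulate_working_type(
        {spec.behavior: p_raw}, profile, {spec.behavior: spec}, cfg
    )[spec.behavior]


def summarize(
    samples: Sequence[float] | np.ndarray, confidence: float = 0.95
) -> RiskSummary:
    """Arithmetic mean/SD, five-number-plus-interval quantiles, fitted family.

    The reported moments are sample moments of the simulated values (not
    log-space parameters). The ``ci_low``/``ci_high`` quantiles bound the
    central ``confidence`` mass. Distribution fitting is attempted only for
    at least 50 non-degenerate samples.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples to summarize")
    alpha = (1.0 - confidence) / 2.0
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    quantiles = {
        "min": float(x.min()),
        "ci_low": float(np.quantile(x, alpha)),
        "q25": float(np.quantile(x, 0.25)),
        "q50": float(np.quantile(x, 0.50)),
        "q75": float(np.quantile(x, 0.75)),
        "ci_high": float(np.quantile(x, 1.0 - alpha)),
        "max": float(x.max()),
    }
    family, params = (None, None)
    if x.size >= 50 and sd > 0.0:
        family, params = fit_distribution(x)
    return RiskSummary(
        mean=mean, sd=sd, quantiles=quantiles,
        fit_family=family, fit_params=params, n=int(x.size),
    )


def _moment_matched(family: str, mean: float, sd: float):
    """Frozen scipy distribution with the given first two moments."""
    if family == "normal":
        return stats.norm(loc=mean, scale=sd), {"mean": mean, "sd": sd}
    if family == "lognormal":
        cv2 = (sd / mean) ** 2
        sigma2 = np.log1p(cv2)
        mu = np.log(mean) - sigma2 / 2.0
        return (
            stats.lognorm(s=np.sqrt(sigma2), scale=np.exp(mu)),
            {"mean": mean, "sd": sd, "mu_log": float(mu), "sigma_log": float(np.sqrt(sigma2))},
        )
    if family == "uniform":
        half = np.sqrt(3.0) * sd
        return stats.uniform(loc=mean - half, scale=2 * half), {"mean": mean, "sd": sd}
    if family == "triangular":
        half = np.sqrt(6.0) * sd
        return (
            stats.triang(c=0.5, loc=mean - half, scale=2 * half),
            {"mean": mean, "sd": sd},
        )
    raise ValueError(f"unknown family {family!r}")


def fit_distribution(
    samples: Sequence[float] | np.ndarray,
    candidates: Tuple[str, ...] = _FIT_FAMILIES,
) -> Tuple[str, Dict[str, float]]:
    """Select the moment-matched family minimizing the KS statistic.

    Positive-support families (lognormal) are skipped when the samples
    contain non-positive values. Emulates the family-selection step of
    spreadsheet risk tools; parameters are matched to the sample's first
    two moments rather than max-likelihood fitted.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 50:
        raise ValueError("need at least 50 samples to fit a distribution")
    unknown = [c for c in candidates if c not in _FIT_FAMILIES]
    if unknown:
        raise ValueError(f"unknown candidate families {unknown}")
    mean, sd = float(x.mean()), float(x.std(ddof=1))
    if sd <= 0.0 or (mean <= 0.0 and "lognormal" in candidates and len(candidates) == 1):
        raise ValueError("degenerate samples: cannot fit a distribution")
    best: Optional[Tuple[float, str, Dict[str, float]]] = None
    for family in candidates:
        if family == "lognormal" and (x.min() <= 0.0 or mean <= 0.0):
            continue
        dist, params = _moment_matched(family, mean, sd)
        ks = stats.kstest(x, dist.cdf).statistic
        if best is None or ks < best[0]:
            best = (float(ks), family, params)
    if best is None:
        raise ValueError("no candidate family applicable to these samples")
    _, family, params = best
    return family, params


def total_risk_samples(
    per_behavior: Mapping[str, np.ndarray],
    mode: str = "comonotonic",
    seed: int = 0,
) -> np.ndarray:
    """Couple per-behavior marginals and return per-iteration total risk.

    ``comonotonic`` aligns the sorted samples (perfect rank correlation:
    total SD equals the sum of component SDs); ``independent`` shuffles
    each component with its own seeded stream before summing. Both modes
    preserve every marginal, hence the total mean.
    """
    if not per_behavior:
        raise ValueError("no behavior samples supplied")
    arrays = {c: np.asarray(v, dtype=float) for c, v in per_behavior.items()}
    lengths = {v.size for v in arrays.values()}
    if len(lengths) != 1:
        raise ValueError(f"sample sequences differ in length: {sorted(lengths)}")
    if mode == "comonotonic":
        return np.sum([np.sort(v) for v in arrays.values()], axis=0)
    if mode == "independent":
        rngs = _spawn_rngs(seed, len(arrays))
        return np.sum(
            [rng.permutation(v) for rng, v in zip(rngs, arrays.values())], axis=0
        )
    raise ValueError(f"unknown total mode {mode!r}")


def total_risk(
    per_behavior: Mapping[str, np.ndarray],
    mode: str = "comonotonic",
    confidence: float = 0.95,
    seed: int = 0,
) -> RiskSummary:
    """Summarize the per-working-type total risk under a coupling mode."""
    return summarize(total_risk_samples(per_behavior, mode, seed), confidence)


def assess_working_type(
    working_type: str,
    p_raw: Mapping[str, float],
    profile: FactorProfile,
    specs: Mapping[str, HazardIndexSpec],
    cfg: SimulationConfig,
) -> WorkingTypeRiskReport:
    """Full per-type assessment: simulate, summarize each behavior, total."""
    samples = simulate_working_type(p_raw, profile, specs, cfg)
    report = WorkingTypeRiskReport(working_type=working_type)
    for code, x in samples.items():
        report.per_behavior[code] = summarize(x, cfg.confidence)
    report.total = total_risk(samples, cfg.total_mode, cfg.confidence, cfg.seed)
    return report
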
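"""Contribution-to-variance sensitivity analysis.

Attributes the variability of a simulated risk output to each stochastic
input by the signed, normalized squared Spearman rank correlation — the
"contribution to variance" convention of spreadsheet Monte Carlo tools.
For input i with rank correlation rho_i to the output,

    contribution_i = sign(rho_i) * rho_i^2 / sum_j rho_j^2 * 100 .

Being rank-based, contributions are invariant under strictly monotone
transformations of any input.

In this risk model the hazard index enters R = P * I positively while
every influencing factor a-h lowers the correction factor F, so the
expected sign structure is one positive hazard contribution and eight
negative factor contributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .correction import FACTORS, ModelCoefficients, DEFAULT_COEFFICIENTS

__all__ = [
    "SensitivityResult",
    "contribution_to_variance",
    "rank_sensitivities",
    "pooled_sensitivity",
]


@dataclass
class SensitivityResult:
    """Signed contribution-to-variance percentages per stochastic input."""

    output: str
    contributions: Dict[str, float] = field(default_factory=dict)
    rank_correlations: Dict[str, float] = field(default_factory=dict)


def contribution_to_variance(
    input_samples: Mapping[str, Sequence[float]],
    output_samples: Sequence[float],
    output: str = "output",
) -> SensitivityResult:
    """Decompose output variability over the given input sample sequences.

    All sequences must share one length of at least 100 (paired
    per-iteration draws). A zero-variance input contributes 0 with a
    warning; if no input correlates with the output at all there is no
    attributable variance and a ValueError is raised.
    """
    y = np.asarray(output_samples, dtype=float)
    if y.size < 100:
        raise ValueError("need at least 100 paired samples")
    rho: Dict[str, float] = {}
    for name, xs in input_samples.items():
        x = np.asarray(xs, dtype=float)
        if x.size != y.size:
            raise ValueError(
                f"input {name!r} has {x.size} samples, output has {y.size}"
            )
        if np.ptp(x) == 0.0:
            warnings.warn(f"input {name!r} has zero variance; contribution set to 0")
            rho[name] = 0.0
        else:
            rho[name] = float(stats.spearmanr(x, y).statistic)
    denom = sum(r * r for r in rho.values())
    if denom == 0.0:
        raise ValueError("no input correlates with the output; nothing to attribute")
    contributions = {
        name: float(np.sign(r) * r * r / denom * 100.0) for name, r in rho.items()
    }
    return SensitivityResult(
        output=output, contributions=contributions, rank_correlations=rho
    )


def rank_sensitivities(result: SensitivityResult) -> List[Tuple[str, float]]:
    """Inputs ordered by descending |contribution|, ties broken by name."""
    if not result.contributions:
        raise ValueError("empty sensitivity result")
    return sorted(result.contributions.items(), key=lambda kv: (-abs(kv[1]), kv[0]))


def pooled_sensitivity(
    p_raw: Mapping[str, Mapping[str, float]],
    profiles: Mapping[str, "FactorProfile"],
    specs: Mapping[str, Mapping[str, "HazardIndexSpec"]],
    iterations: int = 10_000,
    seed: int = 0,
    coefficients: ModelCoefficients = DEFAULT_COEFFICIENTS,
) -> SensitivityResult:
    """Decompose the pooled total risk over the factor and hazard inputs.

    The pooled run sums the per-behavior risks of all supplied working
    types per iteration. Each factor a-h is one pooled input: a single
    uniform stream per factor per iteration is mapped through each working
    type's triangular inverse CDF, so every type sees its own marginal but
    one shared rank sequence. The hazard index is one pooled input: a
    single standard-normal stream drives all per-cell normal draws
    (comonotonic coupling), reported under the name ``I``.
    """
    from .correction import _factor_combination

    rng = np.random.default_rng(seed)
    u = {f: rng.random(iterations) for f in FACTORS}
    z = rng.standard_normal(iterations)
    total = np.zeros(iterations)
    for wt, profile in profiles.items():
        values = {f: profile.ranges[f].ppf(u[f]) for f in FACTORS}
        F = np.asarray(_factor_combination(values, coefficients))
        for code, spec in specs[wt].items():
            P = np.minimum(p_raw[wt][code] * F, 1.0)
            total += P * (spec.mean + spec.sd * z)
    inputs: Dict[str, np.ndarray] = {f: u[f] for f in FACTORS}
    inputs["I"] = z
    return contribution_to_variance(inputs, total, output="pooled_total_risk")
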
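import numpy as np
import pytest
from hypothesis import settings

import minerisk as mr

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference():
    """Packaged 200-accident reference table and study configuration."""
    return mr.reference_study()


@pytest.fixture(scope="session")
def table(reference):
    records, _ = reference
    return mr.tabulate_occurrences(records)


@pytest.fixture(scope="session")
def config(reference):
    return reference[1]


@pytest.fixture(scope="session")
def study_inputs(table, config):
    """(p_raw, profile, hazard specs) per key working type."""
    out = {}
    for wt in mr.KEY_WORKING_TYPE_IDS:
        block = config.working_types[wt]
        out[wt] = (
            {c: mr.occurrence_probability(table, wt, c) for c in block.behaviors},
            block.profile,
            {c: b.hazard for c, b in block.behaviors.items()},
        )
    return out


def triangular_var(lower, upper, mode=None):
    m = (lower + upper) / 2 if mode is None else mode
    return (
        lower**2 + m**2 + upper**2 - lower * m - lower * upper - m * upper
    ) / 18.0


def analytic_moments(p_raw, profile, spec, coeffs=mr.DEFAULT_COEFFICIENTS):
    """Closed-form mean and SD of R = p_raw * F * I for independent F, I.

    Moment propagation for a product of independent variables:
    E[R] = E[P] mu_I, Var(R) = E[P]^2 s_I^2 + Var(P) (s_I^2 + mu_I^2),
    with Var(P) = p_raw^2 slope^2 Var(S) from the triangular factor
    variances entering the linear score S.
    """
    wa, wb, wc = coeffs.org_weights
    var_s = (
        wa**2 * profile.ranges["a"].variance
        + wb**2 * profile.ranges["b"].variance
        + wc**2 * profile.ranges["c"].variance
        + sum(profile.ranges[f].variance for f in "def") / 9.0
        + sum(profile.ranges[f].variance for f in "gh") / 4.0
    )
    F_bar = mr.correction_factor_mean(profile, coeffs)
    EP = p_raw * F_bar
    var_p = p_raw**2 * coeffs.slope**2 * var_s
    mean = EP * spec.mean
    var = EP**2 * spec.sd**2 + var_p * (spec.sd**2 + spec.mean**2)
    return mean, float(np.sqrt(var))
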
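"""Correction factor F, triangular factor sampling, revised probabilities."""

import warnings

import numpy as np
import pytest
from hypothesis import given, strategies as st

import minerisk as mr
from minerisk.correction import FACTORS, FactorRange

MIDPOINTS_VENTILATION = dict(a=0.5, b=0.5, c=6.5, d=6.5, e=0.5, f=6.5, g=2.0, h=0.5)


def _point_profile(value: float) -> mr.FactorProfile:
    return mr.FactorProfile(
        "ventilation", {f: FactorRange(f, value, value) for f in FACTORS}
    )


@pytest.mark.parametrize(
    "values, expected",
    [
        (MIDPOINTS_VENTILATION, 1.376),
        ({**MIDPOINTS_VENTILATION, "c": 2.0}, 1.391),  # gas prevention midpoints
        ({f: 0.0 for f in FACTORS}, 1.5),  # intercept
        ({f: 10.0 for f in FACTORS}, 0.999),  # 1.5 - 0.0167*(10+10+10)
    ],
)
def test_correction_factor_values(values, expected):
    assert round(mr.correction_factor(values), 3) == expected


@pytest.mark.parametrize(
    "wt, expected",
    [
        ("ventilation", 1.376),
        ("gas_prevention_fire", 1.391),
        ("blasting", 1.378),  # the formula value; see methods note
        ("electrician", 1.376),
    ],
)
def test_correction_factor_mean_reference(config, wt, expected):
    F = mr.correction_factor_mean(config.working_types[wt].profile)
    assert round(F, 3) == expected


def test_mean_equals_midpoint_for_symmetric_modes(config):
    profile = config.working_types["ventilation"].profile
    assert mr.correction_factor_mean(profile) == pytest.approx(
        mr.correction_factor(MIDPOINTS_VENTILATION)
    )


def test_point_mass_profile_mean_exact():
    profile = _point_profile(4.0)
    assert mr.correction_factor_mean(profile) == pytest.approx(
        mr.correction_factor({f: 4.0 for f in FACTORS})
    )


def test_validation_errors():
    with pytest.raises(ValueError, match="missing factor"):
        mr.correction_factor({f: 1.0 for f in FACTORS[:-1]})
    with pytest.raises(ValueError, match="outside the score range"):
        mr.correction_factor({**MIDPOINTS_VENTILATION, "a": 11.0})
    with pytest.raises(ValueError):
        FactorRange("a", 3.0, 1.0)
    with pytest.raises(ValueError):
        FactorRange("a", 0.0, 5.0, mode=7.0)
    with pytest.raises(ValueError, match="sum to 1"):
        mr.ModelCoefficients(org_weights=(0.5, 0.6, 0.2))


@given(
    base=st.dictionaries(
        st.sampled_from(FACTORS),
        st.floats(0.0, 9.0),
        min_size=len(FACTORS),
        max_size=len(FACTORS),
    ).filter(lambda d: len(d) == len(FACTORS)),
    factor=st.sampled_from(FACTORS),
    delta=st.floats(0.01, 1.0),
)
def test_strictly_decreasing_in_each_factor(base, factor, delta):
    """Worse (larger) scores always shrink F."""
    bumped = {**base, factor: base[factor] + delta}
    assert mr.correction_factor(bumped) < mr.correction_factor(base)


@given(
    values=st.lists(st.floats(0.0, 10.0), min_size=8, max_size=8).map(
        lambda v: dict(zip(FACTORS, v))
    )
)
def test_factor_range_bounds(values):
    """With default coefficients, F always lies in [0.999, 1.5]."""
    F = mr.correction_factor(values)
    assert 0.999 - 1e-12 <= F <= 1.5 + 1e-12


def test_sample_factors_moments_and_determinism(config):
    profile = config.working_types["ventilation"].profile
    s1 = mr.sample_factors(profile, 100_000, seed=3)
    s2 = mr.sample_factors(profile, 100_000, seed=3)
    for f in FACTORS:
        np.testing.assert_array_equal(s1.values[f], s2.values[f])
        r = profile.ranges[f]
        assert s1.values[f].min() >= r.lower and s1.values[f].max() <= r.upper
    # symmetric triangular on [3, 10] has mean 6.5
    assert s1.values["c"].mean() == pytest.approx(6.5, abs=0.05)
    # linearity: the MC mean of F matches F at the triangular means within 3 SE
    F = s1.correction_factors()
    se = F.std(ddof=1) / np.sqrt(F.size)
    assert abs(F.mean() - mr.correction_factor_mean(profile)) < 3 * se


def test_sample_factors_point_mass_and_errors():
    samples = mr.sample_factors(_point_profile(2.5), 100, seed=0)
    for f in FACTORS:
        assert np.all(samples.values[f] == 2.5)
    with pytest.raises(ValueError):
        mr.sample_factors(_point_profile(1.0), 0, seed=0)


@pytest.mark.parametrize(
    "p_raw, F, expected",
    [
        (0.16, 1.3756, 0.22),
        (0.105, 1.3906, 0.15),
        (0.3, 1.0, 0.30),  # identity factor
    ],
)
def test_revised_probability_rounds_to_printed(p_raw, F, expected):
    assert round(mr.revised_probability(p_raw, F), 2) == expected


def test_revised_probability_clamps_and_validates():
    with warnings.catch_warnings(record=True) as w:
        warnings.simplefilter("always")
        assert mr.revised_probability(0.9, 1.4) == 1.0
        assert any("clamped" in str(x.message) for x in w)
    with pytest.raises(ValueError):
        mr.revised_probability(-0.1, 1.2)
    with pytest.raises(ValueError):
        mr.revised_probability(0.5, 0.0)
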
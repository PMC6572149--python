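"""Monte Carlo risk engine: oracles, summaries, fitting, totals."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import minerisk as mr
from minerisk.correction import FACTORS, FactorRange

from conftest import analytic_moments


def _unit_profile() -> mr.FactorProfile:
    # all-zero scores with intercept 1 and slope 0 give F identically 1
    return mr.FactorProfile(
        "ventilation", {f: FactorRange(f, 0.0, 0.0) for f in FACTORS}
    )


UNIT_COEFFS = mr.ModelCoefficients(org_weights=(0.2, 0.6, 0.2), slope=0.0, intercept=1.0)


def test_degenerate_inputs_give_exact_risk():
    """Point-mass factors with F=1 and sd(I)=0 make every iterate p*mu."""
    spec = mr.HazardIndexSpec("ventilation", "OIW", 2.0, 0.0)
    cfg = mr.SimulationConfig(iterations=64, seed=0, coefficients=UNIT_COEFFS)
    x = mr.simulate_behavior_risk(0.16, _unit_profile(), spec, cfg)
    np.testing.assert_allclose(x, 0.16 * 2.0)


def test_ventilation_oiw_matches_analytic_oracle(study_inputs):
    p_raw, profile, specs = study_inputs["ventilation"]
    cfg = mr.SimulationConfig(iterations=10_000, seed=1)
    x = mr.simulate_behavior_risk(p_raw["OIW"], profile, specs["OIW"], cfg)
    mean, sd = analytic_moments(p_raw["OIW"], profile, specs["OIW"])
    assert mean == pytest.approx(0.4402, abs=5e-4)  # p*F_bar*mu = 0.16*1.3756*2
    assert sd == pytest.approx(0.264, rel=0.01)
    assert x.mean() == pytest.approx(mean, abs=3 * sd / np.sqrt(x.size))
    assert x.std(ddof=1) == pytest.approx(sd, rel=0.05)


def test_all_reference_cells_match_moment_propagation(study_inputs):
    """Every (type, behavior) cell's simulated moments track the closed form."""
    cfg = mr.SimulationConfig(iterations=10_000, seed=3)
    for wt, (p_raw, profile, specs) in study_inputs.items():
        samples = mr.simulate_working_type(p_raw, profile, specs, cfg)
        for code, x in samples.items():
            mean, sd = analytic_moments(p_raw[code], profile, specs[code])
            assert x.mean() == pytest.approx(mean, abs=4 * sd / np.sqrt(x.size)), (wt, code)
            assert x.std(ddof=1) == pytest.approx(sd, rel=0.06), (wt, code)


def test_seed_determinism_and_batching_invariance(study_inputs):
    p_raw, profile, specs = study_inputs["ventilation"]
    cfg = mr.SimulationConfig(iterations=2_000, seed=11)
    a = mr.simulate_working_type(p_raw, profile, specs, cfg)
    b = mr.simulate_working_type(p_raw, profile, specs, cfg)
    for code in specs:
        np.testing.assert_array_equal(a[code], b[code])


def test_hazard_scale_equivariance(study_inputs):
    """Scaling a cell's hazard distribution by k scales its risk samples by k."""
    p_raw, profile, specs = study_inputs["ventilation"]
    spec = specs["OIW"]
    cfg = mr.SimulationConfig(iterations=2_000, seed=4)
    base = mr.simulate_behavior_risk(p_raw["OIW"], profile, spec, cfg)
    scaled_spec = mr.HazardIndexSpec(
        spec.working_type, spec.behavior, 3.0 * spec.mean, 3.0 * spec.sd
    )
    scaled = mr.simulate_behavior_risk(p_raw["OIW"], profile, scaled_spec, cfg)
    np.testing.assert_allclose(scaled, 3.0 * base, rtol=1e-12)


def test_summarize_contract():
    x = np.array([1.0, 1.0, 1.0])
    s = mr.summarize(x)
    assert s.sd == 0.0
    assert len({v for v in s.quantiles.values()}) == 1
    assert s.fit_family is None  # degenerate: no fit attempted
    with pytest.raises(ValueError):
        mr.summarize([1.0])
    rng = np.random.default_rng(0)
    s2 = mr.summarize(rng.lognormal(0, 0.5, 5000), confidence=0.9)
    q = s2.quantiles
    assert (
        q["min"] <= q["ci_low"] <= q["q25"] <= q["q50"]
        <= q["q75"] <= q["ci_high"] <= q["max"]
    )


@pytest.mark.parametrize(
    "draw, expected",
    [
        (lambda rng: rng.lognormal(-1.0, 0.8, 10_000), "lognormal"),
        (lambda rng: 2.0 + 1.2 * rng.standard_normal(10_000), "normal"),
        (lambda rng: rng.uniform(1.0, 3.0, 10_000), "uniform"),
        (lambda rng: rng.triangular(0.0, 1.0, 2.0, 10_000), "triangular"),
    ],
)
def test_fit_distribution_self_consistency(draw, expected):
    """The KS-selected family recovers the generating family."""
    family, params = mr.fit_distribution(draw(np.random.default_rng(42)))
    assert family == expected
    assert params["mean"] == pytest.approx(
        {"lognormal": np.exp(-1 + 0.32), "normal": 2.0, "uniform": 2.0, "triangular": 1.0}[expected],
        rel=0.05,
    )


def test_fit_distribution_skips_positive_support_and_validates():
    rng = np.random.default_rng(0)
    x = rng.standard_normal(1000)  # contains non-positive values
    family, _ = mr.fit_distribution(x)
    assert family != "lognormal"
    with pytest.raises(ValueError):
        mr.fit_distribution(x[:40])
    with pytest.raises(ValueError, match="unknown candidate"):
        mr.fit_distribution(x, candidates=("weibull",))


def test_total_risk_single_behavior_identical_in_both_modes():
    rng = np.random.default_rng(1)
    x = rng.lognormal(0, 0.4, 4000)
    ref = mr.summarize(x)
    for mode in ("comonotonic", "independent"):
        t = mr.total_risk({"OIW": x}, mode=mode)
        assert t.mean == pytest.approx(ref.mean)
        assert t.sd == pytest.approx(ref.sd)


def test_total_risk_errors():
    with pytest.raises(ValueError, match="length"):
        mr.total_risk({"a": np.ones(5), "b": np.ones(6)})
    with pytest.raises(ValueError, match="mode"):
        mr.total_risk({"a": np.ones(5)}, mode="antithetic")


def test_comonotonic_total_sd_is_sum_of_component_sds():
    rng = np.random.default_rng(3)
    parts = {c: rng.lognormal(0, 0.5, 20_000) for c in "abc"}
    t = mr.total_risk(parts, mode="comonotonic")
    assert t.sd == pytest.approx(
        sum(np.std(v, ddof=1) for v in parts.values()), rel=0.01
    )


@given(seed=st.integers(0, 10_000), k=st.integers(2, 5))
def test_independent_sd_never_exceeds_comonotonic_sd(seed, k):
    rng = np.random.default_rng(seed)
    parts = {f"b{i}": rng.gamma(2.0, 1.0, 500) for i in range(k)}
    sd_com = mr.total_risk(parts, mode="comonotonic").sd
    sd_ind = mr.total_risk(parts, mode="independent", seed=seed).sd
    assert sd_ind <= sd_com + 1e-9
    # both couplings preserve the marginals, hence the mean
    mean = sum(v.mean() for v in parts.values())
    assert mr.total_risk(parts, mode="independent", seed=seed).mean == pytest.approx(mean)
    assert mr.total_risk(parts, mode="comonotonic").mean == pytest.approx(mean)


def test_working_type_ordering_every_seed(study_inputs):
    """Total mean risk ranks ventilation > blasting > gas prevention > electrician."""
    for seed in range(5):
        cfg = mr.SimulationConfig(iterations=4_000, seed=seed)
        means = {}
        for wt, (p_raw, profile, specs) in study_inputs.items():
            report = mr.assess_working_type(wt, p_raw, profile, specs, cfg)
            means[wt] = report.total.mean
            assert report.total.mean == pytest.approx(
                sum(s.mean for s in report.per_behavior.values()), rel=1e-9
            )
        assert (
            means["ventilation"] > means["blasting"]
            > means["gas_prevention_fire"] > means["electrician"]
        ), seed


def test_config_validation():
    with pytest.raises(ValueError):
        mr.SimulationConfig(iterations=0)
    with pytest.raises(ValueError):
        mr.SimulationConfig(confidence=1.0)
    with pytest.raises(ValueError):
        mr.SimulationConfig(total_mode="sorted")
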
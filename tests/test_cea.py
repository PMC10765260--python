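"""Incremental comparison, sensitivity analyses, and PSA machinery."""

import math

import numpy as np
import pytest

from olaparib_cea import (
    NoCrossingError,
    StrategyTotals,
    compare_strategies,
    evaluate_pair,
    fit_distribution,
    one_way_sa,
    run_psa,
    threshold_search,
)
from olaparib_cea.cea import DEFAULT_OWSA_RANGES, DistributionSpec, default_psa_specs


def _totals(label, cost, qalys, ly=None):
    return StrategyTotals(label, cost, qalys if ly is None else ly, qalys)


# ---------------------------------------------------------------------------
# compare_strategies


def test_identical_strategies_have_undefined_icer():
    a = _totals("a", 100.0, 1.0)
    res = compare_strategies(a, a)
    assert res.incremental_cost == 0.0
    assert res.icer_per_qaly is None
    assert res.dominance == ""


def test_icer_simple_arithmetic():
    res = compare_strategies(_totals("a", 300.0, 2.0), _totals("b", 100.0, 1.0))
    assert res.icer_per_qaly == pytest.approx(200.0)
    assert res.dominance == ""


def test_dominance_flags():
    better_cheaper = compare_strategies(
        _totals("a", 50.0, 2.0), _totals("b", 100.0, 1.0)
    )
    assert better_cheaper.dominance == "intervention_dominant"
    worse_costlier = compare_strategies(
        _totals("a", 200.0, 1.0), _totals("b", 100.0, 2.0)
    )
    assert worse_costlier.dominance == "intervention_dominated"
    assert worse_costlier.icer_per_qaly is None  # dQALY < 0: flagged, no division


# ---------------------------------------------------------------------------
# one-way sensitivity


def test_degenerate_range_gives_zero_width(calibrated_pair, bundled_lt):
    base_drug = calibrated_pair.olaparib.monthly_drug_cost
    entries = one_way_sa(
        calibrated_pair, bundled_lt, {"monthly_drug_cost": (base_drug, base_drug)}
    )
    assert entries[0].width == pytest.approx(0.0, abs=1e-6)


def test_unknown_parameter_rejected(calibrated_pair, bundled_lt):
    with pytest.raises(KeyError):
        one_way_sa(calibrated_pair, bundled_lt, {"nonexistent": (0.0, 1.0)})


def test_icer_strictly_increases_with_drug_cost(calibrated_pair, bundled_lt):
    icers = []
    for cost in (10_000.0, 14_523.0, 18_154.0):
        res = evaluate_pair(
            calibrated_pair.with_param("monthly_drug_cost", cost), bundled_lt
        )
        icers.append(res.icer_per_qaly)
    assert icers[0] < icers[1] < icers[2]


def test_threshold_value_plugs_back_to_wtp(calibrated_pair, bundled_lt):
    wtp = 150_000.0
    value = threshold_search(
        "monthly_drug_cost", wtp, (10_892.0, 40_000.0), calibrated_pair, bundled_lt
    )
    res = evaluate_pair(
        calibrated_pair.with_param("monthly_drug_cost", value), bundled_lt
    )
    assert res.icer_per_qaly == pytest.approx(wtp, abs=1.0)


def test_threshold_no_crossing_raises(calibrated_pair, bundled_lt):
    with pytest.raises(NoCrossingError):
        threshold_search(
            "imaging_cost", 150_000.0, (405.0, 675.0), calibrated_pair, bundled_lt
        )


# ---------------------------------------------------------------------------
# distribution fitting


def test_lognormal_hr_matches_printed_confidence_interval():
    spec = fit_distribution(0.61, 0.48, 0.77, "lognormal", name="hazard_ratio")
    assert spec.params["mu"] == pytest.approx(math.log(0.61), rel=1e-9)
    assert spec.params["sigma"] == pytest.approx(0.12056, abs=2e-4)
    lo = math.exp(spec.params["mu"] - 1.96 * spec.params["sigma"])
    hi = math.exp(spec.params["mu"] + 1.96 * spec.params["sigma"])
    assert lo == pytest.approx(0.482, abs=0.002)
    assert hi == pytest.approx(0.773, abs=0.002)


def test_beta_metastatic_utility_moments():
    spec = fit_distribution(0.55, 0.413, 0.688, "beta", name="utility_metastatic")
    a, b = spec.params["a"], spec.params["b"]
    mean = a / (a + b)
    se = math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))
    assert mean == pytest.approx(0.55, rel=1e-9)
    assert se == pytest.approx((0.55 - 0.413) / 1.96, rel=1e-9)


def test_degenerate_range_collapses_to_point_mass():
    spec = fit_distribution(100.0, 100.0, 100.0, "gamma")
    assert spec.family == "point"
    rng = np.random.default_rng(0)
    assert np.all(spec.sample(rng, 10) == 100.0)


def test_fit_distribution_rejects_bad_ordering():
    with pytest.raises(ValueError):
        fit_distribution(0.5, 0.6, 0.7, "beta")
    with pytest.raises(ValueError):
        fit_distribution(0.5, 0.4, 0.6, "triangular")


def test_fitted_sample_means_match_base_case(calibrated_pair):
    """Monte Carlo means of every fitted PSA distribution sit within 1% of
    the base-case value (lognormal carries its exp(sigma^2/2) factor)."""
    specs = default_psa_specs(calibrated_pair)
    rng = np.random.default_rng(42)
    for name, spec in specs.items():
        draws = spec.sample(rng, 200_000)
        target = spec.mean()
        assert np.mean(draws) == pytest.approx(target, rel=0.01), name
        if spec.family != "lognormal":
            assert target == pytest.approx(spec.base, rel=0.02), name


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis


def test_degenerate_psa_reproduces_base_case(calibrated_pair, bundled_lt):
    # the PSA derives the treated arm from placebo rates x hazard ratio, so
    # its point-mass limit is the HR-rebuilt pair, not the independently
    # calibrated treated arm
    base = evaluate_pair(
        calibrated_pair.with_param("hazard_ratio", 0.61), bundled_lt
    )
    specs = {
        name: DistributionSpec(name, "point", s.base, s.base, s.base)
        for name, s in default_psa_specs(calibrated_pair).items()
    }
    psa = run_psa(calibrated_pair, bundled_lt, n=8, seed=0, specs=specs)
    assert np.allclose(psa.draws["d_cost"], base.incremental_cost, rtol=1e-9)
    assert np.allclose(psa.draws["d_qaly"], base.incremental_qalys, rtol=1e-9)


def test_psa_fixed_seed_is_bit_reproducible(calibrated_pair, bundled_lt):
    a = run_psa(calibrated_pair, bundled_lt, n=40, seed=7)
    b = run_psa(calibrated_pair, bundled_lt, n=40, seed=7)
    assert a.draws.equals(b.draws)
    assert np.array_equal(a.prop_olaparib, b.prop_olaparib)


def test_psa_seed_changes_draws(calibrated_pair, bundled_lt):
    a = run_psa(calibrated_pair, bundled_lt, n=40, seed=7)
    b = run_psa(calibrated_pair, bundled_lt, n=40, seed=8)
    assert not a.draws.equals(b.draws)


def test_ceac_proportions_complementary_and_monotone(calibrated_pair, bundled_lt):
    # vary costs only: every draw keeps dQALY > 0, so the CEAC must be
    # nondecreasing in WTP and the two strategies' curves sum to one
    specs = default_psa_specs(calibrated_pair)
    cost_only = {
        name: (s if "cost" in name
               else DistributionSpec(name, "point", s.base, s.base, s.base))
        for name, s in specs.items()
    }
    psa = run_psa(calibrated_pair, bundled_lt, n=300, seed=3, specs=cost_only)
    assert np.all(psa.draws["d_qaly"] > 0)
    assert np.all(np.diff(psa.prop_olaparib) >= 0)
    assert np.allclose(psa.prop_olaparib + psa.prop_no_olaparib, 1.0)


def test_ceac_zero_wtp_prefers_cheaper_strategy(calibrated_pair, bundled_lt):
    psa = run_psa(calibrated_pair, bundled_lt, n=200, seed=5)
    assert psa.prop_olaparib[0] == pytest.approx(0.0, abs=0.01)


def test_across_seed_stability_of_acceptability(calibrated_pair, bundled_lt):
    props = [
        run_psa(calibrated_pair, bundled_lt, n=2_000, seed=s).acceptability_at(150_000)
        for s in (11, 12)
    ]
    assert abs(props[0] - props[1]) < 0.04  # ~4 binomial SEs at n=2000


def test_psa_rejects_invalid_inputs(calibrated_pair, bundled_lt):
    with pytest.raises(ValueError):
        run_psa(calibrated_pair, bundled_lt, n=0, seed=1)
    bad = {"not_a_param": DistributionSpec("not_a_param", "point", 1.0, 1.0, 1.0)}
    with pytest.raises(KeyError):
        run_psa(calibrated_pair, bundled_lt, n=2, seed=1, specs=bad)


def test_confidence_ellipse_geometry(calibrated_pair, bundled_lt):
    psa = run_psa(calibrated_pair, bundled_lt, n=200, seed=9)
    ell = psa.confidence_ellipse()
    assert len(ell["semi_axes"]) == 2
    assert ell["semi_axes"][0] >= ell["semi_axes"][1] > 0


def test_owsa_ranges_cover_every_psa_family():
    assert set(DEFAULT_OWSA_RANGES) >= {
        "hazard_ratio", "utility_no_recurrence", "monthly_drug_cost",
        "monthly_metastatic_cost", "monthly_metastatic_death_rate",
    }
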
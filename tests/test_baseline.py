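"""ICER arithmetic, efficacy test and one-way sensitivity analyses."""

import numpy as np
import pytest

from hs2econ import (
    HypoglycaemiaCEModel,
    default_scenarios,
    efficacy_test,
    icer,
    one_way_sensitivity,
    relative_risk_reduction,
)
from hs2econ.baseline import SensitivityScenario
from hs2econ.params import ValidationError


# ---------------------------------------------------------------------------
# ICER


def test_icer_of_reported_rounded_differences():
    # the reported table entries divide to 309.67 at 2 dp
    assert icer(9.29, 0.030).value == pytest.approx(309.67, abs=0.005)


def test_icer_zero_cost_difference():
    assert icer(0.0, 0.1).value == 0.0


def test_icer_dominance_flags():
    assert icer(-1.0, 0.1).dominance == "hs2_dominant"
    assert icer(5.0, -0.1).dominance == "hs2_dominated"
    assert icer(5.0, 0.1).dominance == "none"


def test_icer_undefined_at_zero_effect():
    res = icer(5.0, 0.0)
    assert res.value is None
    assert res.dominance == "undefined"


def test_icer_scales_with_currency_unit():
    base = icer(9.29, 0.03).value
    assert icer(9.29 * 1.17, 0.03).value == pytest.approx(base * 1.17)


# ---------------------------------------------------------------------------
# relative risk reduction


@pytest.mark.parametrize(
    "p_hs2, p_sc, expected",
    [(0.42404, 0.394, 7.6), (0.5, 0.5, 0.0), (0.5, 0.4, 25.0)],
)
def test_relative_risk_reduction(p_hs2, p_sc, expected):
    assert round(100 * relative_risk_reduction(p_hs2, p_sc), 1) == expected


def test_relative_risk_reduction_requires_positive_comparator():
    with pytest.raises(ValidationError):
        relative_risk_reduction(0.4, 0.0)


# ---------------------------------------------------------------------------
# efficacy test


def test_trial_primary_outcome_p_value():
    _, p = efficacy_test(32, 707, 92, 1674)
    assert round(p, 2) == 0.33


def test_equal_proportions_give_p_one():
    _, p = efficacy_test(10, 100, 10, 100)
    assert p == pytest.approx(1.0)


def test_extreme_difference_is_overwhelming():
    z, p = efficacy_test(0, 100, 50, 100)
    assert abs(z) > 8
    assert p < 1e-10


def test_invalid_counts_rejected():
    with pytest.raises(ValidationError):
        efficacy_test(5, 0, 1, 10)
    with pytest.raises(ValidationError):
        efficacy_test(11, 10, 1, 10)


def test_efficacy_test_agrees_with_binomial_resampling_oracle():
    """The asymptotic z-test p-value matches a pooled-null Monte-Carlo
    two-sided p-value at trial-sized counts."""
    e1, n1, e2, n2 = 32, 707, 92, 1674
    _, p_z = efficacy_test(e1, n1, e2, n2)
    rng = np.random.default_rng(20230316)
    pooled = (e1 + e2) / (n1 + n2)
    b = 40_000
    d_obs = abs(e1 / n1 - e2 / n2)
    d_sim = np.abs(rng.binomial(n1, pooled, b) / n1 - rng.binomial(n2, pooled, b) / n2)
    p_mc = float((d_sim >= d_obs - 1e-12).mean())
    mc_se = np.sqrt(p_mc * (1 - p_mc) / b)
    assert abs(p_mc - p_z) < 3 * mc_se + 0.01  # MC error plus normal-approx slack


# ---------------------------------------------------------------------------
# one-way sensitivity


def test_default_scenarios_bracket_their_baselines():
    by_param = {s.parameter: s for s in default_scenarios()}
    assert by_param["intervention_cost"].low < 9.95 < by_param["intervention_cost"].high
    assert by_param["r_hs2"].low < 0.75 <= by_param["r_hs2"].high
    assert by_param["hs2_repeat_rate"].low < 0.045 < by_param["hs2_repeat_rate"].high


def test_null_scenario_leaves_icer_unchanged(params, results):
    df = one_way_sensitivity(params, [
        SensitivityScenario("null", "intervention_cost", 9.95, 9.95)])
    base = results.icer.value
    assert df.loc[0, "icer_low"] == pytest.approx(base, rel=1e-12)
    assert df.loc[0, "icer_high"] == pytest.approx(base, rel=1e-12)


def test_intervention_cost_moves_icer_monotonically(params, results):
    df = one_way_sensitivity(params).set_index("parameter")
    base = results.icer.value
    row = df.loc["intervention_cost"]
    assert row["icer_low"] < base < row["icer_high"]


def test_severe_rate_moves_icer_monotonically(params, results):
    df = one_way_sensitivity(params).set_index("parameter")
    row = df.loc["hs2_repeat_rate"]
    assert row["icer_low"] < results.icer.value < row["icer_high"]


def test_halved_recurrence_rate_probability():
    # the low r_hs2 scenario halves the read+action recurrence probability input
    from hs2econ import rate_to_probability

    assert rate_to_probability(0.375) == pytest.approx(0.3127, abs=5e-5)


def test_infeasible_scenario_is_flagged_not_fatal(params):
    df = one_way_sensitivity(params, [
        SensitivityScenario("impossible", "hs2_repeat_rate", 0.9, 0.95),
        SensitivityScenario("fine", "intervention_cost", 5.0, 15.0),
    ])
    by_name = df.set_index("scenario")
    assert by_name.loc["impossible", "error"] is not None
    assert by_name.loc["fine", "error"] is None
    assert np.isfinite(by_name.loc["fine", "width"])


def test_tornado_is_sorted_by_range_width(params):
    df = one_way_sensitivity(params)
    widths = df["width"].to_numpy()
    assert all(widths[i] >= widths[i + 1] for i in range(len(widths) - 1))
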
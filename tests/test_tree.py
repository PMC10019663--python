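"""Decision-tree structure, calibration and the two-evaluator agreement."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from hs2econ import (
    TransitionParameters,
    build_arm,
    calibrate_severity_probability,
    default_parameters,
    rate_to_probability,
    recursive_arm_value,
)
from hs2econ.params import StateCost, StateCosts, probability_to_rate
from hs2econ.tree import HS2, SC, CalibrationError, call_mass, patient_types


# ---------------------------------------------------------------------------
# independent closed-form oracle: expected arm cost written as one algebraic
# expression over the branch structure, with no tree code involved


def oracle_arm_cost(arm_name, t, costs, severity):
    c = costs.cost
    stage3 = t.p5 * (t.p6 * (c("stc") + c("ed_ha")) + (1 - t.p6) * (c("stc") + c("ed"))) \
        + (1 - t.p5) * c("str")
    via_999 = c("call_999") + severity * stage3 + (1 - severity) * c("htr")
    via_111 = c("call_111") + severity * (c("redirect_999") + stage3) \
        + (1 - severity) * c("pathways_111")
    total = 0.0
    for pt in patient_types(arm_name, t):
        stage1 = sum(c(s) for s in pt.stage1_states)
        manage = pt.p31 * via_999 + pt.p32 * via_111 + pt.p_self * c(pt.self_manage_state)
        total += pt.stage1_prob * (stage1 + pt.p2 * manage)
    return total


@st.composite
def random_transitions(draw):
    p11 = draw(st.floats(0.05, 0.6))
    p12 = draw(st.floats(0.05, 0.9 - p11))
    q1 = draw(st.floats(0.05, 0.9))
    p31_ra = draw(st.floats(0.1, 0.6))
    p32_ra = draw(st.floats(0.1, 0.9 - p31_ra))
    p31 = draw(st.floats(0.1, 0.6))
    p32 = draw(st.floats(0.1, 0.9 - p31))
    q31 = draw(st.floats(0.1, 0.6))
    q32 = draw(st.floats(0.1, 0.9 - q31))
    return TransitionParameters(
        p11=p11, p12=p12, q1=q1,
        r_hs2=draw(st.floats(0.3, 1.6)),
        r_hs2e=draw(st.floats(0.3, 1.6)),
        r_na=draw(st.floats(0.3, 1.6)),
        p31_read_action=p31_ra, p32_read_action=p32_ra,
        p31_other=p31, p32_other=p32, q31=q31, q32=q32,
        hs2_repeat_rate=draw(st.floats(0.0, 0.05)),
        sc_repeat_rate=draw(st.floats(0.0, 0.05)),
        p5=draw(st.floats(0.0, 1.0)),
        p6=draw(st.floats(0.0, 1.0)),
    )


# ---------------------------------------------------------------------------
# structure


def test_pathway_counts_per_arm(params):
    hs2 = build_arm(HS2, params.transitions, params.state_costs)
    sc = build_arm(SC, params.transitions, params.state_costs)
    assert len(hs2.pathways) == 30
    assert len(sc.pathways) == 20
    assert sum(p.outcome == "HypoS" for p in hs2.pathways) == 18
    assert sum(p.outcome == "HypoS" for p in sc.pathways) == 12


def test_severe_pathways_are_exactly_the_ems_attendance_pathways(params):
    arm = build_arm(HS2, params.transitions, params.state_costs)
    for p in arm.pathways:
        assert (p.outcome == "HypoS") == ("hypos_attend" in p.states)


def test_unknown_arm_is_an_error(params):
    with pytest.raises(ValueError):
        build_arm("placebo", params.transitions, params.state_costs)


def test_missing_state_cost_is_an_error(params):
    states = dict(params.state_costs.states)
    states.pop("htr")
    from hs2econ.params import ValidationError

    with pytest.raises(ValidationError):
        StateCosts(states)


# ---------------------------------------------------------------------------
# calibration


def test_calibration_reproduces_tabulated_severity(params):
    t = params.transitions
    assert round(call_mass(patient_types(HS2, t)), 4) == 0.3993
    p4 = calibrate_severity_probability(0.045, patient_types(HS2, t))
    q4 = calibrate_severity_probability(0.055, patient_types(SC, t))
    assert round(p4, 3) == 0.113
    assert round(q4, 3) == 0.121


def test_calibration_with_two_decimal_recurrence_probabilities(params):
    # same derivation using the tabulated 2-dp recurrence probabilities
    t = params.transitions.replace(
        r_hs2=probability_to_rate(0.53),
        r_hs2e=probability_to_rate(0.59),
        r_na=probability_to_rate(0.63),
    )
    mass = call_mass(patient_types(HS2, t))
    assert round(mass, 4) == 0.3986
    assert round(0.045 / mass, 3) == 0.113


def test_calibration_zero_rate_gives_zero_severity(params):
    assert calibrate_severity_probability(0.0, patient_types(HS2, params.transitions)) == 0.0


def test_calibration_infeasible_rate_raises(params):
    with pytest.raises(CalibrationError):
        calibrate_severity_probability(0.9, patient_types(HS2, params.transitions))


@given(random_transitions())
def test_calibration_round_trip_recovers_observed_rate(params, t):
    for arm_name, rate in ((HS2, t.hs2_repeat_rate), (SC, t.sc_repeat_rate)):
        arm = build_arm(arm_name, t, params.state_costs)
        assert arm.attendance_probability() == pytest.approx(rate, abs=1e-12)


# ---------------------------------------------------------------------------
# probabilities and outcome distribution


@given(random_transitions())
def test_pathway_probabilities_sum_to_one(params, t):
    for arm_name in (HS2, SC):
        arm = build_arm(arm_name, t, params.state_costs)
        assert arm.probability_total() == pytest.approx(1.0, abs=1e-9)


def test_baseline_outcome_distributions(params):
    hs2 = build_arm(HS2, params.transitions, params.state_costs)
    sc = build_arm(SC, params.transitions, params.state_costs)
    assert [round(x, 3) for x in hs2.outcome_distribution().as_tuple()] == [0.424, 0.531, 0.045]
    assert [round(x, 3) for x in sc.outcome_distribution().as_tuple()] == [0.394, 0.551, 0.055]


def test_zero_rates_mean_no_recurrence(params):
    t = params.transitions.replace(r_hs2=0.0, r_hs2e=0.0, r_na=0.0,
                                   hs2_repeat_rate=0.0, sc_repeat_rate=0.0)
    arm = build_arm(HS2, t, params.state_costs)
    assert arm.outcome_distribution().as_tuple() == (1.0, 0.0, 0.0)


def test_increasing_a_rate_strictly_decreases_no_recurrence(params):
    base = build_arm(HS2, params.transitions, params.state_costs).outcome_distribution().p_none
    t = params.transitions.replace(r_hs2e=1.2)
    assert build_arm(HS2, t, params.state_costs).outcome_distribution().p_none < base


# ---------------------------------------------------------------------------
# expected costs: two evaluators plus an algebraic oracle


def test_toy_two_pathway_expectation(params):
    # all recurrence mass self-manages at a single known cost
    t = params.transitions.replace(
        p11=0.0, p12=0.0, p31_other=0.0, p32_other=0.0, q31=0.0, q32=0.0,
        hs2_repeat_rate=0.0, sc_repeat_rate=0.0,
    )
    arm = build_arm(SC, t, params.state_costs, severity=0.0)
    # expected cost = q1*GP + P(recurrence)*self-manage cost
    sm = params.state_costs.cost("self_manage_other")
    gp = params.state_costs.cost("gp_consult")
    p2a, p2n = rate_to_probability(t.r_hs2), rate_to_probability(t.r_na)
    expected = t.q1 * (gp + p2a * sm) + (1 - t.q1) * p2n * sm
    assert arm.expected_costs()["total"] == pytest.approx(expected, abs=1e-9)


@given(random_transitions())
def test_evaluators_agree_on_cost_and_outcomes(params, t):
    for arm_name in (HS2, SC):
        arm = build_arm(arm_name, t, params.state_costs)
        enum_cost = arm.expected_costs()["total"]
        rec_cost, rec_dist = recursive_arm_value(
            arm_name, t, params.state_costs, arm.severity)
        assert enum_cost == pytest.approx(rec_cost, abs=1e-9)
        for a, b in zip(arm.outcome_distribution().as_tuple(), rec_dist.as_tuple()):
            assert a == pytest.approx(b, abs=1e-9)
        assert enum_cost == pytest.approx(
            oracle_arm_cost(arm_name, t, params.state_costs, arm.severity), abs=1e-9)


def test_total_cost_equals_sum_of_provider_components(results):
    for arm in results.arms.values():
        costs = arm.expected_costs()
        parts = sum(v for k, v in costs.items() if k != "total")
        assert costs["total"] == pytest.approx(parts, abs=1e-12)


def test_increasing_a_unit_cost_weakly_increases_total(params):
    base = build_arm(HS2, params.transitions, params.state_costs).expected_costs()["total"]
    states = dict(params.state_costs.states)
    states["htr"] = StateCost(states["htr"].cost + 10.0, states["htr"].provider)
    bumped = build_arm(HS2, params.transitions, StateCosts(states)).expected_costs()["total"]
    assert bumped >= base


def test_patient_type_costs_toy_oracle(params):
    # a type with no stage-1 cost and a single recurrence branch:
    # conditional cost = P(recurrence) x self-manage cost
    t = params.transitions.replace(q31=0.0, q32=0.0)
    arm = build_arm(SC, t, params.state_costs, severity=0.0)
    sm = params.state_costs.cost("self_manage_other")
    expected = rate_to_probability(t.r_na) * sm
    assert arm.patient_type_costs()["no action"] == pytest.approx(expected, abs=1e-9)


def test_patient_type_cost_zero_without_recurrence_or_stage1_cost(params):
    t = params.transitions.replace(r_na=0.0, sc_repeat_rate=0.0)
    arm = build_arm(SC, t, params.state_costs)
    assert arm.patient_type_costs()["no action"] == 0.0


def test_pathway_audit_table_shape(results):
    df = results.pathway_table()
    assert len(df) == 50
    assert {"arm", "patient_type", "states", "probability", "outcome",
            "total_cost"}.issubset(df.columns)
    assert (df["probability"] >= 0).all()
    assert df.groupby("arm")["probability"].sum().round(9).eq(1.0).all()
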
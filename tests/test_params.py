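"""Parameter containers, closed-form helpers and configuration round-trip."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from hs2econ import (
    CostSchedule,
    ModelParameters,
    OutcomeDistribution,
    SelfManageMix,
    TransitionParameters,
    UtilityParameters,
    default_parameters,
    eligible_population,
    fortnight_rate,
    intervention_cost,
    load_config,
    rate_to_probability,
    save_config,
    self_manage_cost,
    weighted_admin_time,
)
from hs2econ.params import (
    MIX_OTHER,
    MIX_READ_ACTION,
    PsaSettings,
    ValidationError,
    probability_to_rate,
    round_to_thousand,
)


@pytest.mark.parametrize(
    "rate, expected_2dp",
    [(0.75, 0.53), (0.0, 0.0), (0.9, 0.59), (1.0, 0.63)],
)
def test_rate_to_probability_matches_tabulated_values(rate, expected_2dp):
    assert round(rate_to_probability(rate), 2) == expected_2dp


def test_rate_to_probability_rejects_negative_rate():
    with pytest.raises(ValidationError):
        rate_to_probability(-0.1)


@given(st.floats(min_value=0.0, max_value=1.65))
def test_rate_probability_inverse_identity(r):
    assert probability_to_rate(rate_to_probability(r)) == pytest.approx(r, abs=1e-12)


@given(st.floats(min_value=0.0, max_value=10.0), st.floats(min_value=1e-6, max_value=1.0))
def test_rate_to_probability_monotone_and_bounded(r, dr):
    p = rate_to_probability(r)
    assert 0.0 <= p < 1.0
    assert rate_to_probability(r + dr) > p


@pytest.mark.parametrize(
    "annual, expected",
    [(42_890.0, 1.65), (0.0, 0.0)],
)
def test_fortnight_rate_scaling(annual, expected):
    assert round(fortnight_rate(annual), 2) == expected


def test_fortnight_rate_lower_bound_of_incidence_range():
    # 0.072 episodes per 1,000 person-years -> 2.8e-6 per person-fortnight
    assert fortnight_rate(0.072) == pytest.approx(2.8e-6, rel=0.02)


@pytest.mark.parametrize(
    "minutes, expected",
    [(2.0, 6.70), (0.0, 1.60), (6.6, 18.43)],
)
def test_intervention_cost_arithmetic(minutes, expected):
    assert intervention_cost(minutes, 2.55, 1.60) == pytest.approx(expected, abs=0.005)


@pytest.mark.parametrize(
    "share, day, night, expected",
    [(0.28, 6.6, 2.0, 3.3), (1.0, 6.6, 2.0, 6.6), (0.5, 4.0, 4.0, 4.0)],
)
def test_weighted_admin_time(share, day, night, expected):
    assert round(weighted_admin_time(share, day, night), 1) == expected


def test_weighted_admin_time_rejects_share_outside_unit_interval():
    with pytest.raises(ValidationError):
        weighted_admin_time(1.2, 6.6, 2.0)


def test_eligible_population_national_estimate():
    n = eligible_population(7.9e6, 0.006, 0.05, 0.6)
    assert n == pytest.approx(18_012.0)
    assert round_to_thousand(n) == 18_000


@pytest.mark.parametrize(
    "args, expected",
    [((1e6, 0.0, 0.05, 0.6), 0.0), ((1e6, 0.01, 0.0, 0.0), 10_000.0)],
)
def test_eligible_population_edge_cases(args, expected):
    assert eligible_population(*args) == pytest.approx(expected)


def test_self_manage_weighted_costs():
    schedule = CostSchedule()
    assert self_manage_cost(MIX_READ_ACTION, schedule) == pytest.approx(25.03, abs=0.005)
    assert self_manage_cost(MIX_OTHER, schedule) == pytest.approx(33.54, abs=0.005)
    all_self_care = SelfManageMix(0, 0, 0, 0, 1)
    assert self_manage_cost(all_self_care, schedule) == 0.0


def test_self_manage_mix_must_sum_to_one():
    with pytest.raises(ValidationError):
        SelfManageMix(0.5, 0.5, 0.5, 0, 0)


def test_averaged_utility_decrements():
    utils = UtilityParameters()
    assert utils.delta_ns == pytest.approx(0.28 * 0.004 + 0.72 * 0.007)
    assert utils.delta_s == pytest.approx(0.28 * 0.062 + 0.72 * 0.057)
    assert round(utils.delta_ns, 3) == 0.006
    assert round(utils.delta_s, 3) == 0.058


@pytest.mark.parametrize(
    "kwargs",
    [
        {"p11": 1.2},
        {"p11": 0.7, "p12": 0.5},
        {"q31": 0.8, "q32": 0.3},
        {"hs2_repeat_rate": -0.1},
        {"r_hs2": -1.0},
    ],
)
def test_transition_validation_rejects_invalid_values(kwargs):
    with pytest.raises(ValidationError):
        TransitionParameters(**kwargs)


def test_rate_ordering_check_for_deterministic_analyses():
    TransitionParameters().check_rate_ordering()
    with pytest.raises(ValidationError):
        TransitionParameters(r_hs2=1.2, r_hs2e=0.9).check_rate_ordering()


def test_outcome_distribution_must_be_a_distribution():
    OutcomeDistribution(0.4, 0.5, 0.1)
    with pytest.raises(ValidationError):
        OutcomeDistribution(0.4, 0.5, 0.3)
    with pytest.raises(ValidationError):
        OutcomeDistribution(-0.1, 1.0, 0.1)


def test_cost_schedule_lookup_and_missing_items():
    schedule = CostSchedule()
    assert schedule.cost("STR") == 209.38
    with pytest.raises(KeyError):
        schedule.cost("NOT_AN_ITEM")
    items = dict(schedule.items)
    items.pop("GP")
    with pytest.raises(ValidationError):
        CostSchedule(items)


def test_psa_settings_mode_must_lie_in_support():
    with pytest.raises(ValidationError):
        PsaSettings(tri_support=(0.0, 0.5), mode_r_na=1.0)
    # degenerate zero-width support is the deterministic-collapse switch
    PsaSettings(tri_support=(0.0, 0.0))


def test_config_round_trip(tmp_path):
    params = default_parameters()
    path = tmp_path / "config.yaml"
    save_config(params, path)
    loaded = load_config(path)
    assert loaded.to_dict() == params.to_dict()


def test_config_missing_section_is_reported(tmp_path):
    path = tmp_path / "bad.yaml"
    path.write_text("cost_schedule: {}\n")
    with pytest.raises(ValidationError):
        load_config(path)


def test_config_invalid_probability_is_rejected(tmp_path):
    params = default_parameters()
    d = params.to_dict()
    d["transitions"]["p11"] = 1.2
    import yaml

    path = tmp_path / "bad.yaml"
    path.write_text(yaml.safe_dump(d))
    with pytest.raises(ValidationError, match="p11"):
        load_config(path)
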
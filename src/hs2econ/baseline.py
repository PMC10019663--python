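"""Baseline cost-effectiveness outputs: ICER, dominance, efficacy test and
one-way sensitivity analyses."""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd
from statsmodels.stats.proportion import proportions_ztest

from .params import ModelParameters, StateCost, StateCosts, ValidationError
from .tree import HS2, SC, build_arm

__all__ = [
    "IcerResult",
    "icer",
    "relative_risk_reduction",
    "efficacy_test",
    "SensitivityScenario",
    "default_scenarios",
    "one_way_sensitivity",
]


@dataclass(frozen=True)
class IcerResult:
    """Incremental cost-effectiveness ratio with explicit sign semantics.

    ``delta_cost`` and ``delta_effect`` are intervention minus comparator
    (positive = HS2 costlier / more effective). ``value`` is None when the
    effect difference is zero (the ratio is undefined, not infinite).
    """

    delta_cost: float
    delta_effect: float
    value: float | None
    dominance: str  # "none" | "hs2_dominant" | "hs2_dominated" | "undefined"


def icer(delta_cost: float, delta_effect: float) -> IcerResult:
    """Added cost per additional unit of benefit, with dominance flags.

    HS2 dominant: cheaper and more effective. HS2 dominated: costlier and
    less effective. In either case the ratio is negative and should be read
    through the flag, not its magnitude.
    """
    if delta_effect == 0.0:
        return IcerResult(delta_cost, delta_effect, None, "undefined")
    value = delta_cost / delta_effect
    if delta_cost <= 0.0 and delta_effect > 0.0:
        dom = "hs2_dominant"
    elif delta_cost > 0.0 and delta_effect < 0.0:
        dom = "hs2_dominated"
    else:
        dom = "none"
    return IcerResult(delta_cost, delta_effect, value, dom)


def relative_risk_reduction(p0_hs2: float, p0_sc: float) -> float:
    """Relative change in the no-recurrence probability, as a proportion.

    ``(p0_hs2 - p0_sc) / p0_sc``: positive when the intervention increases
    the chance of avoiding a recurrence.
    """
    if p0_sc <= 0.0:
        raise ValidationError("comparator no-recurrence probability must be > 0")
    return (p0_hs2 - p0_sc) / p0_sc


def efficacy_test(events1: int, n1: int, events2: int, n2: int) -> tuple[float, float]:
    """Two-sided two-proportion z-test (pooled variance, no continuity correction).

    Returns ``(z, p_value)``. Arm 1 is the intervention; at the trial counts
    (32/707 vs 92/1674) the p-value is 0.33.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValidationError("arm sizes must be positive")
    if not (0 <= events1 <= n1 and 0 <= events2 <= n2):
        raise ValidationError("event counts must lie in [0, n]")
    z, p = proportions_ztest([events1, events2], [n1, n2], alternative="two-sided")
    return float(z), float(p)


# ---------------------------------------------------------------------------
# one-way sensitivity


@dataclass(frozen=True)
class SensitivityScenario:
    """One-way perturbation of a single parameter, all else at baseline."""

    name: str
    parameter: str  # "intervention_cost" | "r_hs2" | "hs2_repeat_rate"
    low: float
    high: float

    def __post_init__(self):
        if not self.low <= self.high:
            raise ValidationError(f"scenario {self.name!r}: low must be <= high")


def default_scenarios() -> list[SensitivityScenario]:
    """The three shipped scenarios of the tornado analysis.

    Intervention cost: out-of-hours (2 min referral, 6.70 GBP) to in-hours
    (6.6 min, 18.43 GBP). Recurrence rate r_hs2: halved to 0.375, up to 0.9.
    HS2 severe-recurrence rate: 3.5% to 5.5% (the standard-care rate).
    """
    return [
        SensitivityScenario("intervention cost", "intervention_cost", 6.70, 18.43),
        SensitivityScenario("recurrence rate r_hs2", "r_hs2", 0.375, 0.9),
        SensitivityScenario("HS2 severe recurrence rate", "hs2_repeat_rate", 0.035, 0.055),
    ]


def _perturbed(params: ModelParameters, parameter: str, value: float) -> ModelParameters:
    if parameter == "intervention_cost":
        states = dict(params.state_costs.states)
        states["booklet_issued"] = StateCost(value, states["booklet_issued"].provider)
        return replace(params, state_costs=StateCosts(
            states, pathways_111_split=params.state_costs.pathways_111_split))
    if parameter == "r_hs2":
        return replace(params, transitions=params.transitions.replace(r_hs2=value))
    if parameter == "hs2_repeat_rate":
        # standard care stays at its observed rate; HS2 severity recalibrates
        return replace(params, transitions=params.transitions.replace(hs2_repeat_rate=value))
    raise ValidationError(f"unknown sensitivity parameter {parameter!r}")


def _baseline_icer(params: ModelParameters) -> IcerResult:
    hs2 = build_arm(HS2, params.transitions, params.state_costs)
    sc = build_arm(SC, params.transitions, params.state_costs)
    d_cost = hs2.expected_costs()["total"] - sc.expected_costs()["total"]
    d_eff = hs2.outcome_distribution().p_none - sc.outcome_distribution().p_none
    return icer(d_cost, d_eff)


def one_way_sensitivity(
    params: ModelParameters,
    scenarios: list[SensitivityScenario] | None = None,
) -> pd.DataFrame:
    """Evaluate one-way scenarios and order them for a tornado diagram.

    Each scenario re-runs the full baseline pipeline (including severity
    recalibration where the perturbed parameter affects it) at its low and
    high value. Returns one row per scenario, sorted by descending ICER
    range width; infeasible perturbations are flagged in the ``error``
    column and do not abort the run.
    """
    scenarios = default_scenarios() if scenarios is None else scenarios
    base = _baseline_icer(params)
    rows = []
    for sc_def in scenarios:
        row = {
            "scenario": sc_def.name,
            "parameter": sc_def.parameter,
            "low": sc_def.low,
            "high": sc_def.high,
            "icer_baseline": base.value,
            "icer_low": None,
            "icer_high": None,
            "error": None,
        }
        try:
            row["icer_low"] = _baseline_icer(_perturbed(params, sc_def.parameter, sc_def.low)).value
            row["icer_high"] = _baseline_icer(_perturbed(params, sc_def.parameter, sc_def.high)).value
            lo, hi = row["icer_low"], row["icer_high"]
            row["width"] = abs(hi - lo) if (lo is not None and hi is not None) else float("nan")
        except (ValidationError, ValueError) as exc:
            row["error"] = str(exc)
            row["width"] = float("nan")
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values("width", ascending=False, ignore_index=True)
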
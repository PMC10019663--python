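"""Decision-tree construction, evaluation and severity calibration.

Each treatment arm is an enumerated tree of terminal pathways. A patient
type (stage-1 response) faces, per fortnight: no recurrence, or a recurrence
managed through one of three channels — phone 999, phone 111, or
self-manage. Dispatch desks triage severity perfectly and EMS clinicians
attend only severe recurrences, so each 999/111 contact is severe with
probability ``p4`` (``q4`` under standard care) and then maps onto the
stage-3 secondary-care outcomes (convey-and-admit, convey-only, or
discharge at scene); non-severe 999 contacts resolve remotely (HTR),
non-severe 111 contacts disposition through the "111 pathways" bundle.

That yields 10 terminal pathways per patient type: 30 in the HS2 arm
(three types) and 20 under standard care (two types), of which 18 / 12
contain an EMS attendance.

The severity probability is calibrated so that the model's total
probability of a repeat EMS attendance equals the trial-observed rate:
``p4 = rate / sum_i P_i`` where the sum runs over the probability mass
reaching a severity node (stage-1 share x recurrence probability x total
call probability).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .params import (
    PROVIDERS,
    ModelParameters,
    OutcomeDistribution,
    StateCosts,
    TransitionParameters,
    ValidationError,
    rate_to_probability,
)

__all__ = [
    "PatientType",
    "Pathway",
    "ArmModel",
    "patient_types",
    "build_arm",
    "calibrate_severity_probability",
    "recursive_arm_value",
    "CalibrationError",
]

HS2 = "HS2"
SC = "standard care"
ARMS = (HS2, SC)


class CalibrationError(ValueError):
    """Observed attendance rate cannot be reproduced by any severity probability."""


@dataclass(frozen=True)
class PatientType:
    """One stage-1 response stratum of an arm."""

    arm: str
    label: str
    stage1_prob: float
    stage1_states: tuple[str, ...]
    rate: float  # per-fortnight recurrence incident rate
    p31: float   # P(call 999 | recurrence)
    p32: float   # P(call 111 | recurrence)
    self_manage_state: str

    @property
    def p2(self) -> float:
        """Per-fortnight recurrence probability, 1 - exp(-rate)."""
        return rate_to_probability(self.rate)

    @property
    def p_self(self) -> float:
        return 1.0 - self.p31 - self.p32


def patient_types(arm: str, t: TransitionParameters) -> tuple[PatientType, ...]:
    """Stage-1 strata for an arm; stage-1 probabilities sum to 1."""
    if arm == HS2:
        return (
            PatientType(arm, "read+action", t.p11, ("booklet_issued", "gp_consult"),
                        t.r_hs2, t.p31_read_action, t.p32_read_action, "self_manage_read_action"),
            PatientType(arm, "read only", t.p12, ("booklet_issued",),
                        t.r_hs2e, t.p31_other, t.p32_other, "self_manage_other"),
            PatientType(arm, "no actions", 1.0 - t.p11 - t.p12, ("booklet_issued",),
                        t.r_na, t.p31_other, t.p32_other, "self_manage_other"),
        )
    if arm == SC:
        return (
            PatientType(arm, "action taken", t.q1, ("control", "gp_consult"),
                        t.r_hs2, t.q31, t.q32, "self_manage_other"),
            PatientType(arm, "no action", 1.0 - t.q1, ("control",),
                        t.r_na, t.q31, t.q32, "self_manage_other"),
        )
    raise ValueError(f"unknown arm {arm!r}; expected one of {ARMS}")


@dataclass(frozen=True)
class Pathway:
    """A terminal pathway: ordered state sequence with probability and costs."""

    arm: str
    patient_type: str
    states: tuple[str, ...]
    probability: float
    provider_costs: dict[str, float]
    outcome: str  # "none" | "HypoNS" | "HypoS"

    @property
    def total_cost(self) -> float:
        return sum(self.provider_costs.values())


def _pathway(arm, ptype, states, prob, costs: StateCosts, outcome) -> Pathway:
    by_provider = {p: 0.0 for p in PROVIDERS}
    for s in states:
        for provider, c in costs.provider_costs(s).items():
            by_provider[provider] += c
    return Pathway(arm, ptype.label, tuple(states), prob, by_provider, outcome)


def _stage3_branches(t: TransitionParameters) -> list[tuple[tuple[str, ...], float]]:
    """Secondary-care outcomes after an EMS attendance for a severe recurrence."""
    return [
        (("stc", "ed_ha"), t.p5 * t.p6),
        (("stc", "ed"), t.p5 * (1.0 - t.p6)),
        (("str",), 1.0 - t.p5),
    ]


def _enumerate_type(ptype: PatientType, t: TransitionParameters, costs: StateCosts,
                    severity: float) -> list[Pathway]:
    base = list(ptype.stage1_states)
    p1, p2 = ptype.stage1_prob, ptype.p2
    out: list[Pathway] = []
    out.append(_pathway(ptype.arm, ptype, base + ["no_repeat"], p1 * (1.0 - p2), costs, "none"))
    stage3 = _stage3_branches(t)
    # 999 channel: severe -> EMS attend + stage 3; non-severe -> HTR
    for s3_states, s3_prob in stage3:
        states = base + ["repeat", "call_999", "hypos_attend", *s3_states]
        out.append(_pathway(ptype.arm, ptype, states,
                            p1 * p2 * ptype.p31 * severity * s3_prob, costs, "HypoS"))
    out.append(_pathway(ptype.arm, ptype, base + ["repeat", "call_999", "htr"],
                        p1 * p2 * ptype.p31 * (1.0 - severity), costs, "HypoNS"))
    # 111 channel: severe -> redirected 999 call + EMS attend + stage 3; non-severe -> 111 pathways
    for s3_states, s3_prob in stage3:
        states = base + ["repeat", "call_111", "redirect_999", "hypos_attend", *s3_states]
        out.append(_pathway(ptype.arm, ptype, states,
                            p1 * p2 * ptype.p32 * severity * s3_prob, costs, "HypoS"))
    out.append(_pathway(ptype.arm, ptype, base + ["repeat", "call_111", "pathways_111"],
                        p1 * p2 * ptype.p32 * (1.0 - severity), costs, "HypoNS"))
    # self-manage channel (non-severe by construction)
    out.append(_pathway(ptype.arm, ptype, base + ["repeat", ptype.self_manage_state],
                        p1 * p2 * ptype.p_self, costs, "HypoNS"))
    return out


def call_mass(types: tuple[PatientType, ...]) -> float:
    """Probability mass reaching a severity node: sum of stage1 x p2 x (p31 + p32)."""
    return sum(pt.stage1_prob * pt.p2 * (pt.p31 + pt.p32) for pt in types)


def calibrate_severity_probability(observed_rate: float,
                                   types: tuple[PatientType, ...]) -> float:
    """Severity probability reproducing an observed repeat EMS-attendance rate.

    A single value applied at every 999 and 111 severity node of the arm, so
    the arm's total EMS-attendance probability is ``severity x call_mass``;
    solving for the observed rate gives ``observed_rate / call_mass``.
    """
    if not 0.0 <= observed_rate <= 1.0:
        raise ValidationError(f"observed rate must be in [0, 1], got {observed_rate!r}")
    mass = call_mass(types)
    if mass <= 0.0:
        if observed_rate == 0.0:
            return 0.0
        raise CalibrationError("no probability mass reaches a severity node")
    severity = observed_rate / mass
    if severity > 1.0:
        raise CalibrationError(
            f"observed rate {observed_rate} exceeds attainable attendance mass {mass:.6f}"
        )
    return severity


@dataclass
class ArmModel:
    """One arm of the economic model: enumerated pathways plus summaries."""

    arm: str
    types: tuple[PatientType, ...]
    severity: float
    pathways: list[Pathway] = field(repr=False)

    # -- summaries ---------------------------------------------------------
    def probability_total(self) -> float:
        return sum(p.probability for p in self.pathways)

    def outcome_distribution(self) -> OutcomeDistribution:
        p_none = sum(p.probability for p in self.pathways if p.outcome == "none")
        p_s = sum(p.probability for p in self.pathways if p.outcome == "HypoS")
        return OutcomeDistribution(p_none, 1.0 - p_none - p_s, p_s)

    def attendance_probability(self) -> float:
        """Total probability of a repeat EMS attendance (severe recurrence)."""
        return sum(p.probability for p in self.pathways if p.outcome == "HypoS")

    def expected_costs(self) -> dict[str, float]:
        """Expected per-patient cost by provider plus 'total' (GBP)."""
        out = {p: 0.0 for p in PROVIDERS}
        for pw in self.pathways:
            for provider, c in pw.provider_costs.items():
                out[provider] += pw.probability * c
        out["total"] = sum(out[p] for p in PROVIDERS)
        return out

    def patient_type_costs(self) -> dict[str, float]:
        """Expected per-patient cost conditional on patient type (GBP)."""
        out: dict[str, float] = {}
        for pt in self.types:
            total = sum(pw.probability * pw.total_cost
                        for pw in self.pathways if pw.patient_type == pt.label)
            out[pt.label] = total / pt.stage1_prob if pt.stage1_prob > 0 else 0.0
        return out

    def to_frame(self) -> pd.DataFrame:
        """Pathway audit table: one row per terminal pathway."""
        rows = []
        for pw in self.pathways:
            row = {
                "arm": pw.arm,
                "patient_type": pw.patient_type,
                "states": " > ".join(pw.states),
                "probability": pw.probability,
                "outcome": pw.outcome,
                "total_cost": pw.total_cost,
            }
            row.update({f"cost_{p}": c for p, c in pw.provider_costs.items()})
            rows.append(row)
        return pd.DataFrame(rows)


def build_arm(arm: str, transitions: TransitionParameters, costs: StateCosts,
              severity: float | None = None) -> ArmModel:
    """Construct and (if needed) calibrate one arm of the model.

    ``severity`` defaults to the value calibrated against the arm's observed
    repeat-attendance rate; pass an explicit probability to bypass
    calibration (as the probabilistic analysis does after matching simulated
    rates).
    """
    types = patient_types(arm, transitions)
    if severity is None:
        explicit = transitions.p4 if arm == HS2 else transitions.q4
        if explicit is not None:
            severity = explicit
        else:
            rate = transitions.hs2_repeat_rate if arm == HS2 else transitions.sc_repeat_rate
            severity = calibrate_severity_probability(rate, types)
    if not 0.0 <= severity <= 1.0:
        raise ValidationError(f"severity probability must be in [0, 1], got {severity!r}")
    pathways: list[Pathway] = []
    for pt in types:
        pathways.extend(_enumerate_type(pt, transitions, costs, severity))
    return ArmModel(arm, types, severity, pathways)


# ---------------------------------------------------------------------------
# independent recursive evaluator
#
# Folds expected cost and the outcome distribution over an explicit nested
# node structure (E[node] = cost + sum p_child * E[child]) instead of
# enumerating terminal pathways and summing probability products. Used as
# the second evaluator in the two-route agreement check.


@dataclass(frozen=True)
class _Node:
    state: str
    children: tuple[tuple[float, "_Node"], ...] = ()
    outcome: str | None = None  # set on terminal nodes


def _build_node_tree(pt: PatientType, t: TransitionParameters, severity: float) -> _Node:
    stage3 = tuple(
        (prob, _Node(states[0],
                     children=(((1.0, _Node(states[1], outcome="HypoS")),)
                               if len(states) > 1 else ()),
                     outcome="HypoS" if len(states) == 1 else None))
        for states, prob in _stage3_branches(t)
    )
    attend = _Node("hypos_attend", children=stage3)
    via_999 = _Node("call_999", children=(
        (severity, attend),
        (1.0 - severity, _Node("htr", outcome="HypoNS")),
    ))
    via_111 = _Node("call_111", children=(
        (severity, _Node("redirect_999", children=((1.0, attend),))),
        (1.0 - severity, _Node("pathways_111", outcome="HypoNS")),
    ))
    recur = _Node("repeat", children=(
        (pt.p31, via_999),
        (pt.p32, via_111),
        (pt.p_self, _Node(pt.self_manage_state, outcome="HypoNS")),
    ))
    stage2 = _Node(pt.stage1_states[-1], children=(
        (pt.p2, recur),
        (1.0 - pt.p2, _Node("no_repeat", outcome="none")),
    ))
    # chain any preceding stage-1 states in front
    node = stage2
    for state in reversed(pt.stage1_states[:-1]):
        node = _Node(state, children=((1.0, node),))
    return node


def _fold(node: _Node, costs: StateCosts) -> tuple[float, dict[str, float]]:
    cost = costs.cost(node.state)
    if not node.children:
        return cost, {node.outcome or "none": 1.0}
    total = cost
    outcome: dict[str, float] = {}
    for p, child in node.children:
        c_cost, c_out = _fold(child, costs)
        total += p * c_cost
        for k, v in c_out.items():
            outcome[k] = outcome.get(k, 0.0) + p * v
    if node.outcome is not None:  # interior outcome labels do not occur
        raise AssertionError("outcome label on non-terminal node")
    return total, outcome


def recursive_arm_value(arm: str, transitions: TransitionParameters, costs: StateCosts,
                        severity: float) -> tuple[float, OutcomeDistribution]:
    """Expected total cost and outcome distribution via recursive folding."""
    total = 0.0
    outcome = {"none": 0.0, "HypoNS": 0.0, "HypoS": 0.0}
    for pt in patient_types(arm, transitions):
        c, o = _fold(_build_node_tree(pt, transitions, severity), costs)
        total += pt.stage1_prob * c
        for k, v in o.items():
            outcome[k] += pt.stage1_prob * v
    return total, OutcomeDistribution(outcome["none"], outcome["HypoNS"], outcome["HypoS"])
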
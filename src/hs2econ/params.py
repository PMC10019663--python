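"""Parameter containers and closed-form helpers for the HS2 economic model.

The model evaluates the "'Hypos' can strike twice" (HS2) leaflet-based
ambulance referral intervention against standard care for recurrent
hypoglycaemia in the fortnight after an initial, at-scene-resolved attack.
Every number the model consumes lives here: the NHS unit-cost schedule
(2018-19 prices), the per-state cost assignments with service-provider
attribution, the stage transition probabilities and incident rates, and the
utility decrements used for the cost-utility analysis.

All analyses downstream are pure functions of a :class:`ModelParameters`
instance, which can be round-tripped through a YAML configuration file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from typing import Mapping

import yaml

__all__ = [
    "CostSchedule",
    "StateCost",
    "StateCosts",
    "SelfManageMix",
    "TransitionParameters",
    "UtilityParameters",
    "OutcomeDistribution",
    "PsaSettings",
    "CostMinSettings",
    "ModelParameters",
    "rate_to_probability",
    "probability_to_rate",
    "fortnight_rate",
    "intervention_cost",
    "weighted_admin_time",
    "self_manage_cost",
    "eligible_population",
    "default_parameters",
    "load_config",
    "save_config",
]

PROVIDERS = ("EMS", "IUC", "primary care", "secondary care")

#: Unit costs in GBP, 2018-19 price year (NHS reference costs and published
#: unit-cost sources). ED{1..4}{A,NA}: emergency-department attendance by
#: department type, admitted / not admitted. HTR/STC/STR: ambulance "hear,
#: treat and refer" / "see, treat and convey" / "see, treat and refer".
DEFAULT_COST_SCHEDULE = {
    "111": (7.33, "call"),
    "999": (7.33, "call"),
    "ED1A": (262.57, "attendance"),
    "ED1NA": (170.66, "attendance"),
    "ED2A": (142.26, "attendance"),
    "ED2NA": (109.92, "attendance"),
    "ED3A": (115.69, "attendance"),
    "ED3NA": (73.57, "attendance"),
    "ED4A": (44.17, "attendance"),
    "ED4NA": (45.71, "attendance"),
    "GP": (39.00, "consultation"),
    "HA": (1215.74, "episode"),
    "HS2_ADMIN": (2.55, "minute"),
    "HS2_BOOKLET": (1.60, "booklet"),
    "HTR": (47.49, "patient"),
    "STC": (257.34, "incident"),
    "STR": (209.38, "incident"),
}


class ValidationError(ValueError):
    """A parameter value violates a model invariant."""


def _check_probability(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValidationError(f"{name} must be in [0, 1], got {value!r}")


# ---------------------------------------------------------------------------
# closed-form helpers


def rate_to_probability(r: float) -> float:
    """Per-fortnight probability of an event with exponential waiting time.

    With time-to-incident exponentially distributed at per-fortnight rate
    ``r``, the probability of at least one incident within the fortnight is
    ``1 - exp(-r)``: strictly increasing in ``r`` and bounded in [0, 1).
    """
    if r < 0:
        raise ValidationError(f"incident rate must be >= 0, got {r!r}")
    return -math.expm1(-r)


def probability_to_rate(p: float) -> float:
    """Inverse of :func:`rate_to_probability` (``-log(1 - p)``)."""
    _check_probability("probability", p)
    if p == 1.0:
        raise ValidationError("probability 1 corresponds to an infinite rate")
    return -math.log1p(-p)


def fortnight_rate(annual_rate_per_1000: float) -> float:
    """Convert episodes per 1,000 person-years to episodes per person-fortnight.

    E.g. 42,890 per 1,000 person-years -> 1.65 per person per fortnight
    (26 fortnights per year).
    """
    if annual_rate_per_1000 < 0:
        raise ValidationError("annual rate must be >= 0")
    return annual_rate_per_1000 * 1e-3 / 26.0


def intervention_cost(admin_minutes: float, per_minute_cost: float, booklet_cost: float) -> float:
    """Cost of issuing the HS2 booklet: production plus crew administration time."""
    if min(admin_minutes, per_minute_cost, booklet_cost) < 0:
        raise ValidationError("intervention cost inputs must be >= 0")
    return booklet_cost + per_minute_cost * admin_minutes


def weighted_admin_time(day_share: float, day_minutes: float, night_minutes: float) -> float:
    """Day-share-weighted administration time in minutes.

    The referral takes longer in business hours (a GP appointment is
    organised) than overnight, so the average administration time weights the
    two median durations by the share of daytime episodes.
    """
    _check_probability("day_share", day_share)
    if min(day_minutes, night_minutes) < 0:
        raise ValidationError("durations must be >= 0")
    return day_share * day_minutes + (1.0 - day_share) * night_minutes


def eligible_population(
    attendances: float, hypo_rate: float, repeat_frac: float, convey_frac: float
) -> float:
    """Annual count of patients eligible for the intervention.

    Ambulance attendances x share for severe hypoglycaemia, excluding repeat
    attendances within a fortnight and episodes conveyed to ED (only patients
    resolved and discharged at scene can receive the booklet).
    """
    for name, v in (("hypo_rate", hypo_rate), ("repeat_frac", repeat_frac), ("convey_frac", convey_frac)):
        _check_probability(name, v)
    if attendances < 0:
        raise ValidationError("attendances must be >= 0")
    return attendances * hypo_rate * (1.0 - repeat_frac) * (1.0 - convey_frac)


def round_to_thousand(x: float) -> int:
    return int(round(x / 1000.0)) * 1000


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class CostSchedule:
    """Unit-cost schedule: item code -> (cost in GBP, unit of measure)."""

    items: Mapping[str, tuple[float, str]] = field(
        default_factory=lambda: dict(DEFAULT_COST_SCHEDULE)
    )

    def __post_init__(self):
        missing = set(DEFAULT_COST_SCHEDULE) - set(self.items)
        if missing:
            raise ValidationError(f"cost schedule missing items: {sorted(missing)}")
        for code, (cost, _unit) in self.items.items():
            if cost < 0:
                raise ValidationError(f"unit cost for {code} must be >= 0, got {cost!r}")

    def cost(self, code: str) -> float:
        try:
            return self.items[code][0]
        except KeyError:
            raise KeyError(f"unknown cost-schedule item {code!r}") from None


@dataclass(frozen=True)
class SelfManageMix:
    """Disposition mix of a self-managed non-severe recurrence.

    Proportions over {ED type-1..4 attendance, not admitted; self-care at
    zero NHS cost}. Patients who read the booklet and took action self-care
    more often than other patient types.
    """

    ed1na: float
    ed2na: float
    ed3na: float
    ed4na: float
    self_care: float

    def __post_init__(self):
        props = self.as_tuple()
        for p in props:
            _check_probability("self-manage proportion", p)
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValidationError(f"self-manage mix must sum to 1, got {sum(props)!r}")

    def as_tuple(self) -> tuple[float, ...]:
        return (self.ed1na, self.ed2na, self.ed3na, self.ed4na, self.self_care)


#: mix (i): HS2 booklet read and action taken
MIX_READ_ACTION = SelfManageMix(0.08125, 0.08125, 0.01875, 0.01875, 0.8)
#: mix (ii): every other patient type
MIX_OTHER = SelfManageMix(0.10625, 0.10625, 0.03125, 0.03125, 0.725)


def self_manage_cost(mix: SelfManageMix, schedule: CostSchedule) -> float:
    """Expected NHS cost of a self-managed non-severe recurrence (GBP).

    Dot product of the disposition mix with the not-admitted ED attendance
    unit costs; the self-care disposition costs nothing.
    """
    codes = ("ED1NA", "ED2NA", "ED3NA", "ED4NA")
    return sum(p * schedule.cost(c) for p, c in zip(mix.as_tuple()[:4], codes))


@dataclass(frozen=True)
class StateCost:
    cost: float
    provider: str

    def __post_init__(self):
        if self.cost < 0:
            raise ValidationError(f"state cost must be >= 0, got {self.cost!r}")
        if self.provider not in PROVIDERS:
            raise ValidationError(f"unknown provider {self.provider!r}")


@dataclass(frozen=True)
class StateCosts:
    """Assigned cost and provider attribution for every model state.

    Stage 1 covers responses to the initial attack (booklet issue, GP
    consultation); stage 2 the response channel to a recurrence (999, 111,
    self-manage) and its non-severe terminals; stage 3 the secondary-care
    outcomes after an EMS attendance for a severe recurrence.

    Provider attribution follows the service that is reimbursed: ambulance
    activity (999 call, HTR, STC, STR, the intervention itself) to EMS; 111
    activity to Integrated Urgent Care, including the onward "111 pathways"
    disposition bundle by default; GP consultations to primary care; ED
    attendance, hospital admission and self-transport to ED to secondary
    care. The 111-pathways bundle is a weighted average of ED and
    primary-care dispositions, so ``pathways_111_split`` optionally splits
    it (ED share to secondary care, remainder to primary care).
    """

    states: Mapping[str, StateCost]
    pathways_111_split: tuple[float, float] | None = None  # (ED share, primary share)

    def __post_init__(self):
        required = {
            "booklet_issued", "control", "gp_consult", "no_stage1_action",
            "no_repeat", "repeat",
            "call_999", "call_111", "redirect_999", "hypos_attend", "htr",
            "pathways_111", "self_manage_read_action", "self_manage_other",
            "stc", "str", "ed_ha", "ed",
        }
        missing = required - set(self.states)
        if missing:
            raise ValidationError(f"state costs missing states: {sorted(missing)}")
        if self.pathways_111_split is not None:
            a, b = self.pathways_111_split
            if a < 0 or b < 0 or abs(a + b - 1.0) > 1e-9:
                raise ValidationError("pathways_111_split shares must be >= 0 and sum to 1")

    def cost(self, state: str) -> float:
        try:
            return self.states[state].cost
        except KeyError:
            raise KeyError(f"no cost assigned for state {state!r}") from None

    def provider_costs(self, state: str) -> dict[str, float]:
        """Cost of one state broken down by provider (handles the 111-pathways split)."""
        sc = self.states[state]
        if state == "pathways_111" and self.pathways_111_split is not None:
            ed_share, pc_share = self.pathways_111_split
            return {
                "secondary care": sc.cost * ed_share,
                "primary care": sc.cost * pc_share,
            }
        return {sc.provider: sc.cost}


def default_state_costs(
    schedule: CostSchedule | None = None,
    booklet_cost: float | None = None,
    pathways_111_split: tuple[float, float] | None = None,
) -> StateCosts:
    """Build the default state-cost table from the unit-cost schedule.

    ``booklet_cost`` defaults to the reported per-patient intervention cost
    of 9.95 GBP (booklet production plus a 3.3-minute weighted median
    administration time). The arithmetic recomputation
    ``intervention_cost(3.3, 2.55, 1.60) = 10.02`` is deliberately not
    substituted: reported downstream results use 9.95.

    Self-manage costs are recomputed at full precision from the disposition
    mixes and the schedule (they print as 25.03 / 33.54 at 2 dp).
    """
    schedule = schedule or CostSchedule()
    call = schedule.cost("999")
    states = {
        # stage 1
        "booklet_issued": StateCost(9.95 if booklet_cost is None else booklet_cost, "EMS"),
        "control": StateCost(0.0, "EMS"),
        "gp_consult": StateCost(schedule.cost("GP"), "primary care"),
        "no_stage1_action": StateCost(0.0, "primary care"),
        # stage 2
        "no_repeat": StateCost(0.0, "EMS"),
        "repeat": StateCost(0.0, "EMS"),
        "call_999": StateCost(call, "EMS"),
        "call_111": StateCost(schedule.cost("111"), "IUC"),
        "redirect_999": StateCost(call, "IUC"),
        "hypos_attend": StateCost(0.0, "EMS"),
        "htr": StateCost(schedule.cost("HTR"), "EMS"),
        "pathways_111": StateCost(71.94, "IUC"),
        "self_manage_read_action": StateCost(
            self_manage_cost(MIX_READ_ACTION, schedule), "secondary care"
        ),
        "self_manage_other": StateCost(
            self_manage_cost(MIX_OTHER, schedule), "secondary care"
        ),
        # stage 3
        "stc": StateCost(schedule.cost("STC"), "EMS"),
        "str": StateCost(schedule.cost("STR"), "EMS"),
        "ed_ha": StateCost(1478.13, "secondary care"),
        "ed": StateCost(168.89, "secondary care"),
    }
    return StateCosts(states, pathways_111_split=pathways_111_split)


@dataclass(frozen=True)
class TransitionParameters:
    """Branch probabilities and incident rates of the decision tree.

    Stage 1: in the HS2 arm patients split into booklet read + action taken
    (``p11``), booklet read only (``p12``) and no actions (residual); under
    standard care into action taken (``q1``) and no action. Recurrence
    probabilities follow from per-fortnight incident rates via
    ``1 - exp(-r)``: ``r_hs2`` for full intervention success (also assigned
    to standard-care action-takers), ``r_hs2e`` for partial success (read
    only) and ``r_na`` for no action. Stage 2 call probabilities (999 /
    111, residual self-manage) differ only for the read+action type. The
    severity probabilities ``p4``/``q4`` (probability a 999/111 contact is a
    severe recurrence attended by EMS) are calibrated against the observed
    trial repeat-attendance rates unless supplied. Stage 3: conveyance
    ``p5`` and admission ``p6``, shared across arms.
    """

    # stage 1
    p11: float = 0.4125
    p12: float = 0.3375
    q1: float = 0.25
    # incident rates, per fortnight
    r_hs2: float = 0.75
    r_hs2e: float = 0.9
    r_na: float = 1.0
    r_max: float = 1.65
    # stage 2 call probabilities
    p31_read_action: float = 0.3625
    p32_read_action: float = 0.2375
    p31_other: float = 0.4
    p32_other: float = 0.35
    q31: float = 0.4
    q32: float = 0.35
    # observed per-arm repeat EMS-attendance rates (trial primary outcome)
    hs2_repeat_rate: float = 0.045
    sc_repeat_rate: float = 0.055
    # severity probabilities; None -> calibrated from the repeat rates
    p4: float | None = None
    q4: float | None = None
    # stage 3
    p5: float = 0.6
    p6: float = 1.0 / 3.0

    def __post_init__(self):
        probs = {
            "p11": self.p11, "p12": self.p12, "q1": self.q1,
            "p31_read_action": self.p31_read_action, "p32_read_action": self.p32_read_action,
            "p31_other": self.p31_other, "p32_other": self.p32_other,
            "q31": self.q31, "q32": self.q32,
            "hs2_repeat_rate": self.hs2_repeat_rate, "sc_repeat_rate": self.sc_repeat_rate,
            "p5": self.p5, "p6": self.p6,
        }
        for name, v in probs.items():
            _check_probability(name, v)
        for name, v in (("p4", self.p4), ("q4", self.q4)):
            if v is not None:
                _check_probability(name, v)
        if self.p11 + self.p12 > 1.0 + 1e-12:
            raise ValidationError("p11 + p12 must be <= 1")
        if self.p31_read_action + self.p32_read_action > 1.0 + 1e-12:
            raise ValidationError("p31 + p32 (read+action) must be <= 1")
        if self.p31_other + self.p32_other > 1.0 + 1e-12:
            raise ValidationError("p31 + p32 must be <= 1")
        if self.q31 + self.q32 > 1.0 + 1e-12:
            raise ValidationError("q31 + q32 must be <= 1")
        for name, r in (("r_hs2", self.r_hs2), ("r_hs2e", self.r_hs2e), ("r_na", self.r_na)):
            if r < 0:
                raise ValidationError(f"{name} must be >= 0")

    def check_rate_ordering(self) -> None:
        """Deterministic analyses assume 0 < r_hs2 <= r_hs2e <= r_na < r_max."""
        if not (0.0 < self.r_hs2 <= self.r_hs2e <= self.r_na < self.r_max):
            raise ValidationError(
                "deterministic analyses require 0 < r_hs2 <= r_hs2e <= r_na < r_max; "
                f"got ({self.r_hs2}, {self.r_hs2e}, {self.r_na}, {self.r_max})"
            )

    def replace(self, **changes) -> "TransitionParameters":
        return replace(self, **changes)


@dataclass(frozen=True)
class UtilityParameters:
    """Utility pathway inputs for the cost-utility analysis.

    The patient utility ``U(t)`` stays at its baseline ``u0`` unless
    hypoglycaemia recurs at time ``T`` within the fortnight, after which it
    drops by a severity- and time-of-day-specific societal decrement with no
    recovery inside the two-week window. ``T`` is triangular on (0, 14) days
    with mode at 2 days. Decrements are averaged over the observed
    daytime/overnight episode split before entering the QALY difference.

    ``annualisation_factor`` converts the fortnight decrement expectation
    into QALYs per patient per year; the default 9/182 already folds in the
    expectation over ``T``.
    """

    u0: float = 1.0
    decrement_day_ns: float = 0.004
    decrement_night_ns: float = 0.007
    decrement_day_s: float = 0.062
    decrement_night_s: float = 0.057
    day_share: float = 0.28
    annualisation_factor: float = 9.0 / 182.0
    t_mode_days: float = 2.0
    t_max_days: float = 14.0

    def __post_init__(self):
        _check_probability("u0", self.u0)
        _check_probability("day_share", self.day_share)
        for name in ("decrement_day_ns", "decrement_night_ns", "decrement_day_s", "decrement_night_s"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name} must be in (0, 1), got {v!r}")
        if not 0.0 <= self.t_mode_days <= self.t_max_days:
            raise ValidationError("T mode must lie within its support")

    @property
    def delta_ns(self) -> float:
        """Day-share-averaged non-severe decrement (0.0058 at defaults)."""
        return self.day_share * self.decrement_day_ns + (1 - self.day_share) * self.decrement_night_ns

    @property
    def delta_s(self) -> float:
        """Day-share-averaged severe decrement (0.0584 at defaults)."""
        return self.day_share * self.decrement_day_s + (1 - self.day_share) * self.decrement_night_s


#: alternative literature decrement pair (HypoNS, HypoS); off by default
BEAUDET_DECREMENTS = (0.014, 0.047)


@dataclass(frozen=True)
class OutcomeDistribution:
    """Per-fortnight distribution of recurrence outcome (none, HypoNS, HypoS)."""

    p_none: float
    p_ns: float
    p_s: float

    def __post_init__(self):
        for name, v in (("p_none", self.p_none), ("p_ns", self.p_ns), ("p_s", self.p_s)):
            _check_probability(name, v)
        if abs(self.p_none + self.p_ns + self.p_s - 1.0) > 1e-9:
            raise ValidationError("outcome distribution must sum to 1")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.p_none, self.p_ns, self.p_s)


@dataclass(frozen=True)
class PsaSettings:
    """Sampling distributions for the probabilistic sensitivity analysis.

    Incident rates are independently triangular on (0, 1.65) with modes at
    their baseline values; repeat-attendance rates are binomial proportions
    at the trial arm sizes.
    """

    n_draws: int = 10_000
    tri_support: tuple[float, float] = (0.0, 1.65)
    mode_r_hs2: float = 0.75
    mode_r_hs2e: float = 0.9
    mode_r_na: float = 1.0
    n_hs2: int = 707
    p_hs2: float = 0.045
    n_sc: int = 1674
    p_sc: float = 0.055
    enforce_rate_ordering: bool = False

    def __post_init__(self):
        lo, hi = self.tri_support
        # a zero-width support collapses every rate to its mode (degenerate,
        # deterministic sampling used to check PSA consistency with baseline)
        if hi > lo:
            for name, m in (("mode_r_hs2", self.mode_r_hs2), ("mode_r_hs2e", self.mode_r_hs2e), ("mode_r_na", self.mode_r_na)):
                if not lo <= m <= hi:
                    raise ValidationError(f"{name} must lie within the triangular support")
        elif hi < lo:
            raise ValidationError("triangular support must have non-negative width")
        _check_probability("p_hs2", self.p_hs2)
        _check_probability("p_sc", self.p_sc)
        if self.n_hs2 <= 0 or self.n_sc <= 0 or self.n_draws <= 0:
            raise ValidationError("counts must be positive")


@dataclass(frozen=True)
class CostMinSettings:
    """Settings for the absorbing-Markov cost-minimisation extension."""

    pgp_values: tuple[float, ...] = (0.3, 0.4, 0.5)
    max_cycles: int = 6  # fortnights within the 90-day secondary horizon
    absorption_threshold: float = 0.95
    absorbed_accrual: str = "action"  # "action" (common GP-consulted cost) | "none"
    include_stage1_in_continuation: bool = False

    def __post_init__(self):
        for p in self.pgp_values:
            _check_probability("pGP", p)
        _check_probability("absorption_threshold", self.absorption_threshold)
        if self.absorbed_accrual not in ("action", "none"):
            raise ValidationError("absorbed_accrual must be 'action' or 'none'")
        if self.max_cycles < 1:
            raise ValidationError("max_cycles must be >= 1")


@dataclass(frozen=True)
class ModelParameters:
    """Full resolved parameter set: the single input to every analysis."""

    schedule: CostSchedule = field(default_factory=CostSchedule)
    state_costs: StateCosts = field(default_factory=default_state_costs)
    transitions: TransitionParameters = field(default_factory=TransitionParameters)
    utilities: UtilityParameters = field(default_factory=UtilityParameters)
    psa: PsaSettings = field(default_factory=PsaSettings)
    costmin: CostMinSettings = field(default_factory=CostMinSettings)

    def to_dict(self) -> dict:
        d = {
            "cost_schedule": {k: {"cost": c, "unit": u} for k, (c, u) in self.schedule.items.items()},
            "state_costs": {
                "states": {k: {"cost": sc.cost, "provider": sc.provider} for k, sc in self.state_costs.states.items()},
                "pathways_111_split": (
                    list(self.state_costs.pathways_111_split)
                    if self.state_costs.pathways_111_split is not None else None
                ),
            },
            "transitions": asdict(self.transitions),
            "utilities": asdict(self.utilities),
            "psa": asdict(self.psa),
            "costmin": asdict(self.costmin),
        }
        d["psa"]["tri_support"] = list(self.psa.tri_support)
        d["costmin"]["pgp_values"] = list(self.costmin.pgp_values)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelParameters":
        try:
            schedule = CostSchedule(
                {k: (v["cost"], v["unit"]) for k, v in d["cost_schedule"].items()}
            )
            split = d["state_costs"].get("pathways_111_split")
            state_costs = StateCosts(
                {k: StateCost(v["cost"], v["provider"]) for k, v in d["state_costs"]["states"].items()},
                pathways_111_split=tuple(split) if split is not None else None,
            )
            psa_d = dict(d["psa"])
            psa_d["tri_support"] = tuple(psa_d["tri_support"])
            cm_d = dict(d["costmin"])
            cm_d["pgp_values"] = tuple(cm_d["pgp_values"])
            return cls(
                schedule=schedule,
                state_costs=state_costs,
                transitions=TransitionParameters(**d["transitions"]),
                utilities=UtilityParameters(**d["utilities"]),
                psa=PsaSettings(**psa_d),
                costmin=CostMinSettings(**cm_d),
            )
        except KeyError as exc:
            raise ValidationError(f"configuration missing key: {exc}") from exc
        except TypeError as exc:
            raise ValidationError(f"configuration malformed: {exc}") from exc


def default_parameters() -> ModelParameters:
    """Baseline parameter set (2018-19 prices, trial-observed rates)."""
    return ModelParameters()


def load_config(path) -> ModelParameters:
    """Load and validate a YAML configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ValidationError(f"configuration file {path!s} is not a mapping")
    return ModelParameters.from_dict(data)


def save_config(params: ModelParameters, path) -> None:
    """Serialise a parameter set to YAML (round-trips via :func:`load_config`)."""
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)
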
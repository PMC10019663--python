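"""Absorbing-Markov cost-minimisation extension of the economic model.

The benefit of the intervention is assumed temporary: once a patient
consults their GP (the absorbing event) their ongoing management is the
same in either arm, so the comparison reduces to cost alone. Cycle 1 runs
the full economic model, with "booklet read + action taken" (HS2) and
"action taken" (standard care) entering the absorbed state immediately.
From cycle 2 each remaining transient patient type absorbs with a common
per-cycle probability pGP (incurring the once-only GP consultation cost)
or stays exposed and accrues its own first-cycle recurrence-management
expectation again; absorbed patients accrue the common GP-consulted
("action taken") management cost in both arms, so their per-patient cost is
arm-independent. Cumulative costs per arm are tracked and the first cycle
at which the HS2 accumulation is strictly below standard care is recorded;
iteration stops once absorption exceeds 95% in both arms, or at the cycle
cap (six fortnights, the 90-day secondary horizon).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import CostMinSettings, ModelParameters, PsaSettings, ValidationError
from .psa import sample_draw
from .tree import (
    HS2,
    SC,
    ArmModel,
    CalibrationError,
    build_arm,
    calibrate_severity_probability,
    patient_types,
)

__all__ = [
    "MarkovArm",
    "CycleRecord",
    "FirstCycle",
    "first_cycle_from_arms",
    "run_chain",
    "first_crossing_cycle",
    "estimate_least_cost_probability",
]


@dataclass
class MarkovArm:
    """Per-arm chain state: absorbed mass plus transient types with their
    per-cycle continuation costs."""

    arm: str
    cycle1_cost: float
    absorbed: float
    transient: list[tuple[float, float]]  # (mass, continuation cost per cycle)

    def total_mass(self) -> float:
        return self.absorbed + sum(m for m, _ in self.transient)


@dataclass(frozen=True)
class CycleRecord:
    cycle: int
    cum_cost_hs2: float
    cum_cost_sc: float
    absorbed_hs2: float
    absorbed_sc: float
    hs2_cheaper: bool  # strict inequality


@dataclass(frozen=True)
class FirstCycle:
    """Cycle-1 outputs of the economic model feeding the chains."""

    hs2: MarkovArm
    sc: MarkovArm
    absorbed_continuation_cost: float
    absorption_cost: float = 39.0  # once-only GP consultation


def first_cycle_from_arms(hs2: ArmModel, sc: ArmModel, params: ModelParameters) -> FirstCycle:
    """Assemble the chain inputs from two built (calibrated) arms."""
    settings = params.costmin
    costs = params.state_costs

    def stage1_cost(pt) -> float:
        return sum(costs.cost(s) for s in pt.stage1_states)

    def continuation(arm: ArmModel) -> dict[str, float]:
        type_costs = arm.patient_type_costs()
        if settings.include_stage1_in_continuation:
            return type_costs
        return {pt.label: type_costs[pt.label] - stage1_cost(pt) for pt in arm.types}

    cont_hs2 = continuation(hs2)
    cont_sc = continuation(sc)
    # patients who consulted their GP incur the standard-care "action taken"
    # management expectation thereafter, identically in both arms
    if settings.absorbed_accrual == "action":
        absorbed_cost = cont_sc["action taken"]
    else:
        absorbed_cost = 0.0

    hs2_types = {pt.label: pt for pt in hs2.types}
    sc_types = {pt.label: pt for pt in sc.types}
    markov_hs2 = MarkovArm(
        HS2,
        cycle1_cost=hs2.expected_costs()["total"],
        absorbed=hs2_types["read+action"].stage1_prob,
        transient=[
            (hs2_types["read only"].stage1_prob, cont_hs2["read only"]),
            (hs2_types["no actions"].stage1_prob, cont_hs2["no actions"]),
        ],
    )
    markov_sc = MarkovArm(
        SC,
        cycle1_cost=sc.expected_costs()["total"],
        absorbed=sc_types["action taken"].stage1_prob,
        transient=[(sc_types["no action"].stage1_prob, cont_sc["no action"])],
    )
    return FirstCycle(markov_hs2, markov_sc, absorbed_cost,
                      absorption_cost=costs.cost("gp_consult"))


def run_chain(first_cycle: FirstCycle, pgp: float,
              settings: CostMinSettings | None = None) -> list[CycleRecord]:
    """Iterate the paired chains and record per-cycle cumulative costs.

    Cycle 1 carries the full economic-model cost. In each later cycle a
    transient patient absorbs with probability ``pgp`` (paying the GP cost
    once plus, that cycle onward, the common absorbed accrual) or stays
    transient and accrues their type's continuation cost. Stops at the
    first cycle with > 95% absorption in both arms, else at ``max_cycles``.
    """
    if not 0.0 <= pgp <= 1.0:
        raise ValidationError(f"pGP must be in [0, 1], got {pgp!r}")
    settings = settings or CostMinSettings()

    state = {
        HS2: [first_cycle.hs2.absorbed, [list(t) for t in first_cycle.hs2.transient]],
        SC: [first_cycle.sc.absorbed, [list(t) for t in first_cycle.sc.transient]],
    }
    cum = {HS2: first_cycle.hs2.cycle1_cost, SC: first_cycle.sc.cycle1_cost}
    records = [CycleRecord(1, cum[HS2], cum[SC],
                           state[HS2][0], state[SC][0], cum[HS2] < cum[SC])]
    for cycle in range(2, settings.max_cycles + 1):
        for arm in (HS2, SC):
            absorbed, transient = state[arm]
            newly = sum(m for m, _ in transient) * pgp
            cost = newly * first_cycle.absorption_cost
            cost += (absorbed + newly) * first_cycle.absorbed_continuation_cost
            cost += sum(m * (1.0 - pgp) * c for m, c in transient)
            for t in transient:
                t[0] *= (1.0 - pgp)
            state[arm][0] = absorbed + newly
            cum[arm] += cost
        records.append(CycleRecord(cycle, cum[HS2], cum[SC],
                                   state[HS2][0], state[SC][0], cum[HS2] < cum[SC]))
        if (state[HS2][0] > settings.absorption_threshold
                and state[SC][0] > settings.absorption_threshold):
            break
    return records


def first_crossing_cycle(records: list[CycleRecord]) -> int | None:
    """First cycle at which the HS2 accumulation is strictly the cheaper."""
    for rec in records:
        if rec.hs2_cheaper:
            return rec.cycle
    return None


def estimate_least_cost_probability(
    params: ModelParameters,
    n_sims: int | None = None,
    seed: int | None = None,
    pgp_values: tuple[float, ...] | None = None,
    psa_settings: PsaSettings | None = None,
) -> pd.DataFrame:
    """Probability that HS2 has the lesser cumulative cost, by cycle and pGP.

    Each simulation draws first-cycle parameters exactly as the
    probabilistic sensitivity analysis does, rebuilds and recalibrates both
    arms, then replicates that cycle deterministically through the chains.
    Returns a frame indexed by completed cycle (1..5) with one column per
    pGP value plus their average; entries are the proportion of simulations
    whose first crossing occurs at or before that cycle (non-decreasing in
    the cycle index by construction). Attributes ``n_sims``, ``n_excluded``
    and ``seed`` are attached via ``DataFrame.attrs``.
    """
    settings = params.costmin
    psa_settings = psa_settings or params.psa
    pgp_values = pgp_values or settings.pgp_values
    n_sims = psa_settings.n_draws if n_sims is None else n_sims
    rng = np.random.default_rng(seed)
    cycles = list(range(1, min(5, settings.max_cycles) + 1))
    counts = {pgp: {c: 0 for c in cycles} for pgp in pgp_values}
    n_excluded = 0
    n_used = 0
    for _ in range(n_sims):
        draw = sample_draw(psa_settings, rng)
        t = params.transitions.replace(
            r_hs2=draw["r_hs2"], r_hs2e=draw["r_hs2e"], r_na=draw["r_na"],
            hs2_repeat_rate=draw["hs2_repeat_rate"], sc_repeat_rate=draw["sc_repeat_rate"],
            p4=None, q4=None,
        )
        try:
            p4 = calibrate_severity_probability(t.hs2_repeat_rate, patient_types(HS2, t))
            q4 = calibrate_severity_probability(t.sc_repeat_rate, patient_types(SC, t))
        except CalibrationError:
            n_excluded += 1
            continue
        hs2 = build_arm(HS2, t, params.state_costs, severity=p4)
        sc = build_arm(SC, t, params.state_costs, severity=q4)
        fc = first_cycle_from_arms(hs2, sc, params)
        n_used += 1
        for pgp in pgp_values:
            crossing = first_crossing_cycle(run_chain(fc, pgp, settings))
            if crossing is not None:
                for c in cycles:
                    if crossing <= c:
                        counts[pgp][c] += 1
    data = {
        f"pgp_{pgp:g}": [counts[pgp][c] / n_used if n_used else float("nan") for c in cycles]
        for pgp in pgp_values
    }
    df = pd.DataFrame(data, index=pd.Index(cycles, name="cycle"))
    df["average"] = df.mean(axis=1)
    df.attrs.update({"n_sims": n_sims, "n_used": n_used, "n_excluded": n_excluded, "seed": seed})
    return df
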
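"""Model/Results facade tying the analyses together.

:class:`HypoglycaemiaCEModel` is built from a parameter set (optionally
estimated from an episode-level trial table); :meth:`~HypoglycaemiaCEModel.fit`
calibrates the severity probabilities against the observed repeat-attendance
rates, evaluates both decision-tree arms and returns a
:class:`CEResults` carrying the baseline cost-effectiveness quantities, with
the sensitivity, cost-utility, probabilistic and cost-minimisation analyses
as methods of the results object.
"""

from __future__ import annotations

from dataclasses import replace

import pandas as pd

from . import baseline as _baseline
from . import costmin as _costmin
from . import psa as _psa
from . import qaly as _qaly
from .params import (
    ModelParameters,
    OutcomeDistribution,
    StateCost,
    StateCosts,
    default_parameters,
    intervention_cost,
    load_config,
)
from .reference import comparison_table
from .tree import HS2, SC, ArmModel, build_arm
from .trial import estimate_model_inputs

__all__ = ["HypoglycaemiaCEModel", "CEResults"]


class HypoglycaemiaCEModel:
    """Decision-tree cost-effectiveness model of recurrent hypoglycaemia.

    Parameters
    ----------
    params:
        Full parameter set; defaults to the baseline values (2018-19
        prices, trial-observed rates).
    trial_counts:
        ``(events_hs2, n_hs2, events_sc, n_sc)`` repeat-attendance counts
        backing the efficacy test; defaults to the trial's primary-outcome
        counts (32/707 intervention, 92/1674 standard care).
    """

    def __init__(self, params: ModelParameters | None = None,
                 trial_counts: tuple[int, int, int, int] = (32, 707, 92, 1674)):
        self.params = params or default_parameters()
        self.trial_counts = trial_counts

    @classmethod
    def from_config(cls, path) -> "HypoglycaemiaCEModel":
        return cls(load_config(path))

    @classmethod
    def from_trial(cls, table: pd.DataFrame,
                   params: ModelParameters | None = None) -> "HypoglycaemiaCEModel":
        """Parameterise the model from an episode-level trial table.

        Overrides the repeat-attendance rates, the daytime share and the
        intervention cost (booklet production plus administration time at
        the estimated weighted median added duration) with estimates from
        the table; everything else stays at the supplied or default values.
        """
        est = estimate_model_inputs(table)
        params = params or default_parameters()
        transitions = params.transitions.replace(
            hs2_repeat_rate=est.repeat_rate_hs2,
            sc_repeat_rate=est.repeat_rate_sc,
            p5=est.convey_p,
            p4=None, q4=None,
        )
        cost = intervention_cost(
            est.weighted_admin_min,
            params.schedule.cost("HS2_ADMIN"),
            params.schedule.cost("HS2_BOOKLET"),
        )
        states = dict(params.state_costs.states)
        states["booklet_issued"] = StateCost(cost, states["booklet_issued"].provider)
        params = replace(
            params,
            transitions=transitions,
            state_costs=StateCosts(states, params.state_costs.pathways_111_split),
            utilities=replace(params.utilities, day_share=est.day_share),
        )
        hs2_n = int((table["arm"] == HS2).sum())
        sc_n = int((table["arm"] == SC).sum())
        counts = (
            int(table.loc[table["arm"] == HS2, "repeat14"].sum()), hs2_n,
            int(table.loc[table["arm"] == SC, "repeat14"].sum()), sc_n,
        )
        return cls(params, trial_counts=counts)

    def fit(self) -> "CEResults":
        """Calibrate, build and evaluate both arms."""
        t = self.params.transitions
        t.check_rate_ordering()
        hs2 = build_arm(HS2, t, self.params.state_costs)
        sc = build_arm(SC, t, self.params.state_costs)
        return CEResults(self, hs2, sc)


class CEResults:
    """Fitted baseline results with the downstream analyses as methods."""

    def __init__(self, model: HypoglycaemiaCEModel, hs2: ArmModel, sc: ArmModel):
        self.model = model
        self.params = model.params
        self.arms: dict[str, ArmModel] = {HS2: hs2, SC: sc}
        self.severity = {"p4": hs2.severity, "q4": sc.severity}
        self.costs = {HS2: hs2.expected_costs(), SC: sc.expected_costs()}
        self.outcomes: dict[str, OutcomeDistribution] = {
            HS2: hs2.outcome_distribution(),
            SC: sc.outcome_distribution(),
        }

    # -- baseline ----------------------------------------------------------
    @property
    def delta_cost(self) -> float:
        """Cost difference, intervention minus standard care (GBP/patient)."""
        return self.costs[HS2]["total"] - self.costs[SC]["total"]

    @property
    def delta_effect(self) -> float:
        """Difference in the probability of no recurrence."""
        return self.outcomes[HS2].p_none - self.outcomes[SC].p_none

    @property
    def icer(self) -> _baseline.IcerResult:
        """GBP per episode of recurrent hypoglycaemia avoided."""
        return _baseline.icer(self.delta_cost, self.delta_effect)

    @property
    def relative_risk_reduction(self) -> float:
        return _baseline.relative_risk_reduction(
            self.outcomes[HS2].p_none, self.outcomes[SC].p_none)

    def efficacy(self) -> tuple[float, float]:
        """Two-proportion z-test of the trial primary outcome: (z, p-value)."""
        return _baseline.efficacy_test(*self.model.trial_counts)

    def cost_table(self) -> pd.DataFrame:
        """Baseline results frame shaped like the published summary table."""
        rows = []
        for provider in (*self.costs[HS2].keys(),):
            rows.append({
                "row": provider,
                "cost_hs2": self.costs[HS2][provider],
                "cost_sc": self.costs[SC][provider],
                "difference": self.costs[HS2][provider] - self.costs[SC][provider],
            })
        df = pd.DataFrame(rows)
        return df

    def patient_type_costs(self) -> dict[str, dict[str, float]]:
        return {arm: self.arms[arm].patient_type_costs() for arm in (HS2, SC)}

    def pathway_table(self) -> pd.DataFrame:
        """Audit table of all 50 terminal pathways across both arms."""
        return pd.concat(
            [self.arms[HS2].to_frame(), self.arms[SC].to_frame()], ignore_index=True)

    # -- cost-utility ------------------------------------------------------
    def qaly_difference(self) -> float:
        return _qaly.qaly_difference(
            self.outcomes[SC], self.outcomes[HS2], self.params.utilities)

    def cost_per_qaly(self) -> float:
        return _qaly.cost_per_qaly(self.delta_cost, self.qaly_difference())

    # -- sensitivity / simulation ------------------------------------------
    def one_way_sensitivity(self, scenarios=None) -> pd.DataFrame:
        return _baseline.one_way_sensitivity(self.params, scenarios)

    def simulate_psa(self, n_draws: int | None = None, seed: int | None = None,
                     settings=None) -> _psa.PsaResult:
        settings = settings or self.params.psa
        if n_draws is not None:
            settings = replace(settings, n_draws=n_draws)
        return _psa.run_psa(self.params, settings, seed=seed)

    def cost_minimisation(self, n_sims: int | None = None, seed: int | None = None,
                          pgp_values: tuple[float, ...] | None = None) -> pd.DataFrame:
        return _costmin.estimate_least_cost_probability(
            self.params, n_sims=n_sims, seed=seed, pgp_values=pgp_values)

    # -- reporting ---------------------------------------------------------
    def computed_values(self, psa_result: _psa.PsaResult | None = None,
                        costmin_result: pd.DataFrame | None = None,
                        sensitivity: pd.DataFrame | None = None) -> dict[str, float]:
        """This implementation's values for every reported comparison quantity."""
        type_costs = self.patient_type_costs()
        out = {
            "cost_hs2_total": self.costs[HS2]["total"],
            "cost_sc_total": self.costs[SC]["total"],
            "cost_difference": self.delta_cost,
            "p0_hs2_pct": 100.0 * self.outcomes[HS2].p_none,
            "p0_sc_pct": 100.0 * self.outcomes[SC].p_none,
            "effect_difference": self.delta_effect,
            "icer": self.icer.value,
            "rrr_pct": 100.0 * self.relative_risk_reduction,
            "type_cost_read_action": type_costs[HS2]["read+action"],
            "type_cost_read_only": type_costs[HS2]["read only"],
            "type_cost_no_actions": type_costs[HS2]["no actions"],
            "type_cost_sc_action": type_costs[SC]["action taken"],
            "type_cost_sc_no_action": type_costs[SC]["no action"],
            "cost_per_qaly": self.cost_per_qaly(),
            "baseline_point_cost": 100.0 * self.delta_cost,
            "baseline_point_effect": 100.0 * self.delta_effect,
        }
        for provider in ("EMS", "IUC", "primary care", "secondary care"):
            out[f"cost_hs2_{provider}"] = self.costs[HS2][provider]
            out[f"cost_sc_{provider}"] = self.costs[SC][provider]
        if sensitivity is not None:
            by_param = sensitivity.set_index("parameter")
            out["icer_cost_low"] = by_param.loc["intervention_cost", "icer_low"]
            out["icer_cost_high"] = by_param.loc["intervention_cost", "icer_high"]
            out["icer_r_hs2_low"] = by_param.loc["r_hs2", "icer_low"]
            out["icer_severe_low"] = by_param.loc["hs2_repeat_rate", "icer_low"]
            out["icer_severe_high"] = by_param.loc["hs2_repeat_rate", "icer_high"]
        if psa_result is not None:
            out["psa_dominated_pct"] = 100.0 * psa_result.p_dominated
            out["psa_dominant_pct"] = 100.0 * psa_result.p_dominant
        if costmin_result is not None:
            for cycle in (2, 3, 4, 5):
                if cycle in costmin_result.index:
                    out[f"costmin_cycle{cycle}_pct"] = 100.0 * costmin_result.loc[cycle, "average"]
        return out

    def reference_comparison(self, **kwargs) -> pd.DataFrame:
        """Computed-versus-reported deviation table (an audit output)."""
        return comparison_table(self.computed_values(**kwargs))

    def summary(self) -> str:
        """Plain-text summary in the style of a statistical results table."""
        ic = self.icer
        z, p = self.efficacy()
        lines = [
            "Recurrent hypoglycaemia cost-effectiveness model (fortnight horizon)",
            "=" * 68,
            f"{'':30s}{'HS2':>12s}{'Standard care':>16s}",
            "-" * 68,
        ]
        for provider in ("EMS", "IUC", "primary care", "secondary care", "total"):
            lines.append(f"{'cost ' + provider + ' (GBP)':30s}"
                         f"{self.costs[HS2][provider]:12.2f}{self.costs[SC][provider]:16.2f}")
        lines += [
            f"{'P(no recurrence) (%)':30s}"
            f"{100 * self.outcomes[HS2].p_none:12.1f}{100 * self.outcomes[SC].p_none:16.1f}",
            f"{'severity probability':30s}"
            f"{self.severity['p4']:12.3f}{self.severity['q4']:16.3f}",
            "-" * 68,
            f"cost difference (GBP/patient)      {self.delta_cost:10.2f}",
            f"effect difference (probability)    {self.delta_effect:10.4f}",
            f"relative risk reduction (%)        {100 * self.relative_risk_reduction:10.1f}",
            f"ICER (GBP/recurrence avoided)      "
            + (f"{ic.value:10.2f}" if ic.value is not None else "  undefined")
            + (f"  [{ic.dominance}]" if ic.dominance != "none" else ""),
            f"QALY difference (per patient-year) {self.qaly_difference():10.3e}",
            f"cost per QALY (GBP, 2 sf)          {_qaly.round_2sf(self.cost_per_qaly()):10.0f}",
            f"efficacy z-test                    z = {z:.3f}, p = {p:.2f}",
            "=" * 68,
        ]
        return "\n".join(lines)
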
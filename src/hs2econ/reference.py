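"""Originally reported results of the HS2 economic evaluation, for comparison.

The published evaluation under-specifies the provider attribution of
composite states and its printed baseline arithmetic is inconsistent at the
penny level (the stated ICER formula 100(49.79-40.50)/(42.4-39.4) evaluates
to 309.67, not the printed 309.36), so the cost-side results cannot be
reproduced exactly from the printed structure. This module records the
reported values and tabulates the deviation of this implementation's
computed values from them; the deviations are an audit output, not an error
to be minimised.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["REPORTED", "comparison_table"]

#: reported values, on the scale they were printed
REPORTED: dict[str, float] = {
    # baseline cost-effectiveness (GBP per patient unless noted)
    "cost_hs2_total": 49.79,
    "cost_sc_total": 40.50,
    "cost_hs2_EMS": 24.60,
    "cost_sc_EMS": 16.56,
    "cost_hs2_IUC": 0.41,
    "cost_sc_IUC": 0.54,
    "cost_hs2_primary care": 13.27,
    "cost_sc_primary care": 10.19,
    "cost_hs2_secondary care": 11.51,
    "cost_sc_secondary care": 13.20,
    "cost_difference": 9.29,
    "p0_hs2_pct": 42.4,
    "p0_sc_pct": 39.4,
    "effect_difference": 0.030,
    "icer": 309.36,
    "rrr_pct": 7.6,
    # per-patient-type costs (GBP)
    "type_cost_read_action": 75.71,
    "type_cost_read_only": 46.66,
    "type_cost_no_actions": 49.05,
    "type_cost_sc_action": 72.14,
    "type_cost_sc_no_action": 39.70,
    # one-way sensitivity ICERs (GBP per recurrence avoided)
    "icer_cost_low": 201.14,
    "icer_cost_high": 591.66,
    "icer_r_hs2_low": 128.77,
    "icer_severe_high": 363.76,
    "icer_severe_low": 254.82,
    # cost-utility
    "cost_per_qaly": 270_000.0,
    # cost-effectiveness plane (per 100 patients)
    "baseline_point_cost": 929.0,
    "baseline_point_effect": 3.00,
    "psa_dominated_pct": 41.81,
    "psa_dominant_pct": 1.28,
    # cost-minimisation crossing probabilities, averaged over pGP (%)
    "costmin_cycle2_pct": 37.0,
    "costmin_cycle3_pct": 57.0,
    "costmin_cycle4_pct": 65.0,
    "costmin_cycle5_pct": 68.0,
}


def comparison_table(computed: dict[str, float]) -> pd.DataFrame:
    """Tabulate computed values against the reported ones.

    ``computed`` maps keys of :data:`REPORTED` to this implementation's
    values (missing keys are skipped). Deviations are computed minus
    reported, with a relative column where the reported value is non-zero.
    """
    rows = []
    for key, reported in REPORTED.items():
        if key not in computed:
            continue
        value = computed[key]
        rows.append({
            "quantity": key,
            "computed": value,
            "reported": reported,
            "deviation": value - reported,
            "relative_deviation": (value - reported) / reported if reported else float("nan"),
        })
    return pd.DataFrame(rows)
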
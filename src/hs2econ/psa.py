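"""Probabilistic sensitivity analysis on the cost-effectiveness plane.

Each draw samples the three recurrence incident rates from independent
triangular distributions and the two repeat-attendance rates from binomial
proportions at the trial arm sizes, rebuilds both arms, recalibrates the
severity probabilities against the drawn rates, and records the cost and
effect differences per 100 patients. All other parameters stay at baseline.

Quadrants of the plane (x: recurrent cases avoided, y: added cost):
upper-left (costlier, less effective) is where standard care dominates the
intervention; lower-right is where the intervention dominates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import ModelParameters, PsaSettings
from .tree import HS2, SC, CalibrationError, build_arm, calibrate_severity_probability, patient_types

__all__ = ["PsaResult", "sample_draw", "run_psa", "quadrant"]

QUADRANTS = ("NE", "NW", "SE", "SW")


def _triangular(rng: np.random.Generator, left: float, mode: float, right: float) -> float:
    if right - left <= 0.0:  # degenerate support collapses to the mode
        return mode
    return float(rng.triangular(left, mode, right))


def sample_draw(settings: PsaSettings, rng: np.random.Generator) -> dict[str, float]:
    """One parameter draw: three incident rates and two repeat rates.

    Rates are drawn independently (no ordering constraint) unless
    ``settings.enforce_rate_ordering`` asks for rejection sampling of
    r_hs2 < r_hs2e < r_na. Binomial counts are converted to proportions.
    """
    lo, hi = settings.tri_support
    while True:
        r_hs2 = _triangular(rng, lo, settings.mode_r_hs2, hi)
        r_hs2e = _triangular(rng, lo, settings.mode_r_hs2e, hi)
        r_na = _triangular(rng, lo, settings.mode_r_na, hi)
        if not settings.enforce_rate_ordering or r_hs2 < r_hs2e < r_na:
            break
    return {
        "r_hs2": r_hs2,
        "r_hs2e": r_hs2e,
        "r_na": r_na,
        "hs2_repeat_rate": rng.binomial(settings.n_hs2, settings.p_hs2) / settings.n_hs2,
        "sc_repeat_rate": rng.binomial(settings.n_sc, settings.p_sc) / settings.n_sc,
    }


def quadrant(delta_cost: float, delta_effect: float) -> str:
    """Quadrant label; boundary points go to the east/north side."""
    ns = "N" if delta_cost >= 0.0 else "S"
    ew = "E" if delta_effect >= 0.0 else "W"
    return ns + ew


@dataclass
class PsaResult:
    """Cost-effectiveness plane draws and quadrant summary."""

    points: pd.DataFrame  # draw, delta_cost_100, delta_effect_100, quadrant
    n_excluded: int
    seed: int | None
    baseline_point: tuple[float, float]  # (delta_cost_100, delta_effect_100)

    def quadrant_summary(self) -> pd.DataFrame:
        """Proportion of draws per quadrant with Monte-Carlo standard errors."""
        n = len(self.points)
        rows = []
        for q in QUADRANTS:
            p = float((self.points["quadrant"] == q).mean()) if n else float("nan")
            se = float(np.sqrt(p * (1 - p) / n)) if n else float("nan")
            rows.append({"quadrant": q, "proportion": p, "mc_se": se})
        return pd.DataFrame(rows)

    @property
    def p_dominated(self) -> float:
        """Share of draws where standard care dominates (upper-left, NW)."""
        return float((self.points["quadrant"] == "NW").mean())

    @property
    def p_dominant(self) -> float:
        """Share of draws where the intervention dominates (lower-right, SE)."""
        return float((self.points["quadrant"] == "SE").mean())


def evaluate_draw(params: ModelParameters, draw: dict[str, float]) -> tuple[float, float]:
    """Cost and effect differences (per 100 patients) for one parameter draw.

    Raises :class:`CalibrationError` when the drawn repeat rate is not
    attainable under the drawn incident rates.
    """
    t = params.transitions.replace(
        r_hs2=draw["r_hs2"], r_hs2e=draw["r_hs2e"], r_na=draw["r_na"],
        hs2_repeat_rate=draw["hs2_repeat_rate"], sc_repeat_rate=draw["sc_repeat_rate"],
        p4=None, q4=None,
    )
    p4 = calibrate_severity_probability(t.hs2_repeat_rate, patient_types(HS2, t))
    q4 = calibrate_severity_probability(t.sc_repeat_rate, patient_types(SC, t))
    hs2 = build_arm(HS2, t, params.state_costs, severity=p4)
    sc = build_arm(SC, t, params.state_costs, severity=q4)
    d_cost = 100.0 * (hs2.expected_costs()["total"] - sc.expected_costs()["total"])
    d_eff = 100.0 * (hs2.outcome_distribution().p_none - sc.outcome_distribution().p_none)
    return d_cost, d_eff


def run_psa(params: ModelParameters, settings: PsaSettings | None = None,
            seed: int | None = None) -> PsaResult:
    """Run the probabilistic sensitivity analysis.

    Draws with infeasible calibration (simulated repeat rate above the
    attainable attendance mass) are excluded and counted, not silently
    dropped. A fixed seed reproduces the draw sequence bit for bit.
    """
    settings = settings or params.psa
    rng = np.random.default_rng(seed)
    records = []
    n_excluded = 0
    for i in range(settings.n_draws):
        draw = sample_draw(settings, rng)
        try:
            d_cost, d_eff = evaluate_draw(params, draw)
        except CalibrationError:
            n_excluded += 1
            continue
        records.append({
            "draw": i,
            "delta_cost_100": d_cost,
            "delta_effect_100": d_eff,
            "quadrant": quadrant(d_cost, d_eff),
            **draw,
        })
    hs2 = build_arm(HS2, params.transitions, params.state_costs)
    sc = build_arm(SC, params.transitions, params.state_costs)
    baseline = (
        100.0 * (hs2.expected_costs()["total"] - sc.expected_costs()["total"]),
        100.0 * (hs2.outcome_distribution().p_none - sc.outcome_distribution().p_none),
    )
    return PsaResult(pd.DataFrame(records), n_excluded, seed, baseline)
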
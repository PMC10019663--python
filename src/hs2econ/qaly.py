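"""Cost-utility analysis: QALY difference from stepped utility pathways.

A recurrence at time ``T`` within the fortnight drops the patient's utility
by a severity-specific decrement for the rest of the two-week window (no
recovery inside the window), so the lost utility area is
``delta x (14 - T)`` utility-days. Averaging over the triangular
distribution of ``T`` and annualising, the QALY difference between arms is
linear in the outcome-distribution differences:

    factor x (delta_NS x (pNS_sc - pNS_hs2) + delta_S x (pS_sc - pS_hs2))

where the default factor 9/182 folds in both the expectation over ``T`` and
the annualisation. Internally the factor is decomposed as
``annual_scale x E[(14 - T) / 14]`` with ``E[(14 - T) / 14] = 13/21`` for
triangular ``T`` on (0, 14) days with mode 2, which lets a Monte-Carlo
integration over ``T`` serve as an independent check of the closed form.
"""

from __future__ import annotations

import math

import numpy as np

from .params import OutcomeDistribution, UtilityParameters, ValidationError

__all__ = [
    "expected_decrement_fraction",
    "qaly_difference",
    "qaly_difference_mc",
    "cost_per_qaly",
    "round_2sf",
]


def expected_decrement_fraction(utils: UtilityParameters) -> float:
    """E[(t_max - T) / t_max]: expected fraction of the fortnight spent at
    decremented utility, for triangular T on (0, t_max) with the given mode.

    Closed form via E[T] = (0 + mode + t_max) / 3; equals 13/21 at defaults.
    """
    e_t = (0.0 + utils.t_mode_days + utils.t_max_days) / 3.0
    return (utils.t_max_days - e_t) / utils.t_max_days


def _annual_scale(utils: UtilityParameters) -> float:
    return utils.annualisation_factor / expected_decrement_fraction(utils)


def _delta_terms(dist_sc: OutcomeDistribution, dist_hs2: OutcomeDistribution,
                 utils: UtilityParameters) -> float:
    return (utils.delta_ns * (dist_sc.p_ns - dist_hs2.p_ns)
            + utils.delta_s * (dist_sc.p_s - dist_hs2.p_s))


def qaly_difference(dist_sc: OutcomeDistribution, dist_hs2: OutcomeDistribution,
                    utils: UtilityParameters) -> float:
    """Annualised QALY gain of the intervention over the comparator.

    Positive when the intervention shifts probability mass from (severe)
    recurrence to no recurrence; zero when the distributions coincide;
    antisymmetric under swapping the two distributions.
    """
    return utils.annualisation_factor * _delta_terms(dist_sc, dist_hs2, utils)


def qaly_difference_mc(dist_sc: OutcomeDistribution, dist_hs2: OutcomeDistribution,
                       utils: UtilityParameters, n_draws: int = 1_000_000,
                       rng: np.random.Generator | None = None) -> tuple[float, float]:
    """Monte-Carlo counterpart of :func:`qaly_difference`.

    Draws recurrence times from the triangular distribution, computes each
    stepped pathway's decremented fraction of the fortnight directly, and
    applies the same annualisation scale. Returns ``(estimate, std_error)``.
    """
    rng = np.random.default_rng() if rng is None else rng
    t = rng.triangular(0.0, utils.t_mode_days, utils.t_max_days, size=n_draws)
    w = (utils.t_max_days - t) / utils.t_max_days
    scale = _annual_scale(utils) * _delta_terms(dist_sc, dist_hs2, utils)
    est = scale * float(np.mean(w))
    se = abs(scale) * float(np.std(w, ddof=1)) / math.sqrt(n_draws)
    return est, se


def cost_per_qaly(delta_cost: float, qaly_diff: float) -> float:
    """Cost-utility ICER in GBP per QALY; undefined at zero QALY difference."""
    if qaly_diff == 0.0:
        raise ValidationError("QALY difference is zero; cost per QALY is undefined")
    return delta_cost / qaly_diff


def round_2sf(x: float) -> float:
    """Round to 2 significant figures (reporting convention for GBP/QALY)."""
    if x == 0.0:
        return 0.0
    exponent = math.floor(math.log10(abs(x)))
    return round(x, -int(exponent) + 1)
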
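"""Synthetic episode-level trial data with the structure the model consumes.

The economic model is parameterised from a handful of trial aggregates:
per-arm repeat-attendance proportions, the daytime/overnight episode split,
the conveyance rate, and the arm difference in median at-scene durations by
time-of-day stratum (which prices the intervention's administration time).
This generator emulates exactly those aggregates at episode level —
per-arm Bernoulli repeat flags, Bernoulli stratum and conveyance flags, and
right-skewed at-scene durations whose medians are shifted additively by arm
and stratum — so the whole estimation-to-model pipeline is testable
without any external data. It reproduces no patient-identifiable or
calendar structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import ValidationError, weighted_admin_time
from .tree import HS2, SC

__all__ = ["simulate_trial", "TrialEstimates", "estimate_model_inputs"]


def simulate_trial(
    n_hs2: int = 707,
    p_hs2: float = 0.045,
    n_sc: int = 1674,
    p_sc: float = 0.055,
    day_share: float = 0.28,
    convey_p: float = 0.6,
    base_median_min: float = 35.0,
    added_day_min: float = 6.6,
    added_night_min: float = 2.0,
    sigma: float = 0.45,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate an episode-level trial table.

    Durations are log-normal around ``base_median_min`` (a realistic at-scene
    time for an EMS hypoglycaemia episode resolved at scene) with the
    intervention arm's median shifted by ``added_day_min`` in the 8am-8pm
    stratum and ``added_night_min`` overnight, so the arm difference in
    median duration is exact in expectation. Columns: ``arm``,
    ``repeat14``, ``daytime``, ``conveyed``, ``duration_min``.
    """
    for name, p in (("p_hs2", p_hs2), ("p_sc", p_sc), ("day_share", day_share), ("convey_p", convey_p)):
        if not 0.0 <= p <= 1.0:
            raise ValidationError(f"{name} must be in [0, 1], got {p!r}")
    if n_hs2 <= 0 or n_sc <= 0:
        raise ValidationError("arm sizes must be positive")
    if base_median_min <= 0 or sigma <= 0:
        raise ValidationError("duration model requires positive median and sigma")
    rng = np.random.default_rng(seed) if rng is None else rng

    frames = []
    for arm, n, p_rep in ((HS2, n_hs2, p_hs2), (SC, n_sc, p_sc)):
        daytime = rng.random(n) < day_share
        base = rng.lognormal(mean=np.log(base_median_min), sigma=sigma, size=n)
        shift = np.zeros(n)
        if arm == HS2:
            shift = np.where(daytime, added_day_min, added_night_min)
        frames.append(pd.DataFrame({
            "arm": arm,
            "repeat14": rng.random(n) < p_rep,
            "daytime": daytime,
            "conveyed": rng.random(n) < convey_p,
            "duration_min": base + shift,
        }))
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class TrialEstimates:
    """Model inputs estimated from an episode-level table."""

    repeat_rate_hs2: float
    repeat_rate_sc: float
    convey_p: float
    day_share: float  # share of daytime episodes in the intervention arm
    median_diff_day_min: float
    median_diff_night_min: float
    weighted_admin_min: float


def estimate_model_inputs(table: pd.DataFrame) -> TrialEstimates:
    """Estimate the aggregates the economic model consumes.

    Repeat-attendance proportions per arm, conveyance rate, daytime share
    (intervention arm, as the administration-time weighting uses it), the
    per-stratum arm difference in median at-scene duration, and the
    day-share-weighted administration time bridging to the intervention
    cost.
    """
    for arm in (HS2, SC):
        if not (table["arm"] == arm).any():
            raise ValidationError(f"trial table has no episodes in arm {arm!r}")
    hs2 = table[table["arm"] == HS2]
    sc = table[table["arm"] == SC]

    def median_diff(daytime: bool) -> float:
        a = hs2.loc[hs2["daytime"] == daytime, "duration_min"]
        b = sc.loc[sc["daytime"] == daytime, "duration_min"]
        if a.empty or b.empty:
            return float("nan")
        return float(a.median() - b.median())

    day_share = float(hs2["daytime"].mean())
    diff_day = median_diff(True)
    diff_night = median_diff(False)
    if np.isnan(diff_day) and np.isnan(diff_night):
        raise ValidationError("no stratum with episodes in both arms")
    # single-stratum tables: the weighted time is that stratum's difference
    if np.isnan(diff_day):
        weighted = diff_night
    elif np.isnan(diff_night):
        weighted = diff_day
    else:
        weighted = weighted_admin_time(day_share, diff_day, diff_night)
    return TrialEstimates(
        repeat_rate_hs2=float(hs2["repeat14"].mean()),
        repeat_rate_sc=float(sc["repeat14"].mean()),
        convey_p=float(table["conveyed"].mean()),
        day_share=day_share,
        median_diff_day_min=diff_day,
        median_diff_night_min=diff_night,
        weighted_admin_min=weighted,
    )
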
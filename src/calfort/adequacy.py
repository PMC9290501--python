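"""Effectiveness and safety metrics for a usual-intake distribution.

Effectiveness uses the EAR cut-point method: the prevalence of inadequate
intake in a life-stage group is the (weighted) share of the usual-intake
distribution strictly below the group's EAR.  Safety is the share strictly
above the UL.  Values exactly at a threshold count as adequate and safe.

The *initial gap* is the planning quantity for choosing a fortification
level: pick a target prevalence of inadequacy from the baseline prevalence
(50% when baseline is above 50%, 10% when between 10% and 50% inclusive,
0% when below 10%), then measure how many mg/day separate the EAR from the
usual intake at that target percentile.  Dividing the gap by the group's
mean flour intake (per 100 g) converts it to a candidate fortificant
level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reference_values import DRIEntry
from .usual_intake import UsualIntakeDistribution

__all__ = [
    "AdequacySummary",
    "GapResult",
    "prevalence",
    "target_prevalence",
    "initial_gap",
    "gap_to_level",
]


@dataclass(frozen=True)
class AdequacySummary:
    """Weighted prevalence below the EAR / above the UL plus mean and SD."""

    pct_below_ear: float
    pct_above_ul: float
    mean_mg: float
    sd_mg: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.pct_below_ear <= 100.0 and 0.0 <= self.pct_above_ul <= 100.0):
            raise ValueError("percentages must lie in [0, 100]")


@dataclass(frozen=True)
class GapResult:
    """Target prevalence (0/10/50 %) and the mg/day gap to reach it."""

    target_prevalence: float
    initial_gap_mg: float

    def __post_init__(self) -> None:
        if self.initial_gap_mg < 0:
            raise ValueError("gap must be non-negative")


def prevalence(dist: UsualIntakeDistribution, entry: DRIEntry) -> AdequacySummary:
    """EAR cut-point prevalence and UL exceedance for one group.

    Comparisons are strict: a usual intake exactly at the EAR is adequate,
    exactly at the UL is safe.
    """
    v = dist.values_mg
    w = dist.weights / dist.weights.sum()
    below = float(np.clip(w[v < entry.ear_mg].sum() * 100.0, 0.0, 100.0))
    above = float(np.clip(w[v > entry.ul_mg].sum() * 100.0, 0.0, 100.0))
    mean, sd = dist.mean_sd()
    return AdequacySummary(
        pct_below_ear=below, pct_above_ul=above, mean_mg=mean, sd_mg=sd
    )


def target_prevalence(current_pct_below_ear: float) -> float:
    """Step rule mapping baseline inadequacy to a planning target.

    Above 50% -> 50; between 10% and 50% (both inclusive) -> 10; below
    10% -> 0.  Returns one of {0.0, 10.0, 50.0}.
    """
    if not 0.0 <= current_pct_below_ear <= 100.0:
        raise ValueError("prevalence must lie in [0, 100]")
    if current_pct_below_ear > 50.0:
        return 50.0
    if current_pct_below_ear >= 10.0:
        return 10.0
    return 0.0


def initial_gap(dist: UsualIntakeDistribution, entry: DRIEntry) -> GapResult:
    """mg/day between the EAR and the usual intake at the target percentile.

    The target prevalence is derived from the group's baseline prevalence;
    the gap is ``max(0, EAR - percentile(dist, target))`` -- the amount by
    which the distribution would have to shift upward so that only the
    target share remains below the EAR.
    """
    base = prevalence(dist, entry)
    target = target_prevalence(base.pct_below_ear)
    at_target = dist.percentile(target)
    gap = max(0.0, entry.ear_mg - at_target)
    return GapResult(target_prevalence=target, initial_gap_mg=gap)


def gap_to_level(gap_mg: float, mean_flour_g: float) -> float:
    """Convert a mg/day gap into a fortificant level (mg per 100 g flour).

    Returns ``inf`` for a group that eats no flour: no level closes its gap.
    """
    if gap_mg < 0:
        raise ValueError("gap must be non-negative")
    if mean_flour_g <= 0:
        return float("inf") if gap_mg > 0 else 0.0
    return gap_mg / mean_flour_g * 100.0
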
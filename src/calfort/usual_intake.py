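"""Usual (habitual) intake estimation from single-day dietary recalls.

A single 24-h recall observes usual intake plus within-person day-to-day
noise, so the one-day intake distribution is wider than the usual-intake
distribution and overstates the tails -- exactly the tails the EAR/UL
cut-points measure.  The classical remedy is a measurement-error
deconvolution: transform daily intakes toward symmetry, estimate the
within- and between-person variance components from repeated recalls (or
take their ratio from an external source), shrink each subject's day-1
value toward the group mean by ``sqrt(1 / (1 + ratio))`` where ``ratio =
within_var / between_var``, and back-transform.

On the log scale, usual intake defined as each subject's long-run *mean*
daily intake sits half a within-variance above the subject's mean log
intake (Jensen's gap for multiplicative noise).  The back-transform
therefore adds ``within_var / 2`` before exponentiating by default
(``bias_correction=True``); disable it to reproduce the plain shrinkage
estimate, which preserves the transformed-scale mean exactly.

Survey weights enter every mean, variance, and percentile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .reference_values import LifeStageGroup

__all__ = [
    "VarianceComponents",
    "VarianceRatioSpec",
    "UsualIntakeDistribution",
    "UsualIntakeError",
    "estimate_variance_components",
    "adjust_distribution",
    "weighted_percentile",
    "DEFAULT_EXTERNAL_RATIO",
]

#: Placeholder external within:between variance ratio on the log scale.
#: Any real analysis without repeat recalls must supply a ratio estimated
#: from a comparable survey; a warning is emitted whenever this default is
#: used.
DEFAULT_EXTERNAL_RATIO = 2.0

#: Offset added before taking logs so that zero intakes are transformable.
DEFAULT_LOG_OFFSET = 1.0


class UsualIntakeError(ValueError):
    """Estimation is impossible with the given data/configuration."""


@dataclass(frozen=True)
class VarianceComponents:
    """Within- and between-person variance on the transformed scale."""

    between_var: float
    within_var: float
    n_subjects: int
    n_repeat_subjects: int

    @property
    def ratio(self) -> float:
        """within:between variance ratio (inf when between_var == 0)."""
        if self.between_var == 0.0:
            return float("inf")
        return self.within_var / self.between_var


@dataclass(frozen=True)
class VarianceRatioSpec:
    """How to obtain the within:between variance ratio.

    ``internal``: estimate both components from repeated recalls in the
    data at hand.  ``external``: use ``ratio`` taken from another survey
    of the same nutrient (needed when every subject has a single recall).
    """

    mode: str = "internal"
    ratio: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("internal", "external"):
            raise UsualIntakeError(f"unknown variance mode {self.mode!r}")
        if self.mode == "external" and self.ratio is not None and self.ratio <= 0:
            raise UsualIntakeError("external variance ratio must be > 0")

    def resolve_ratio(self) -> float:
        if self.mode != "external":
            raise UsualIntakeError("resolve_ratio is only valid in external mode")
        if self.ratio is None:
            warnings.warn(
                "external variance mode with no ratio supplied: using the "
                f"placeholder default {DEFAULT_EXTERNAL_RATIO}; set a "
                "survey-specific ratio for any real analysis",
                stacklevel=2,
            )
            return DEFAULT_EXTERNAL_RATIO
        return self.ratio


@dataclass
class UsualIntakeDistribution:
    """A group's estimated usual-intake values, one per subject, with weights."""

    group: LifeStageGroup | None
    values_mg: np.ndarray
    weights: np.ndarray
    subject_ids: list[str] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values_mg = np.asarray(self.values_mg, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.values_mg.shape != self.weights.shape:
            raise UsualIntakeError("values and weights must have the same length")
        if np.any(self.weights <= 0):
            raise UsualIntakeError("weights must be positive")
        if np.any(self.values_mg < 0):
            raise UsualIntakeError("usual intakes must be non-negative")

    def __len__(self) -> int:
        return len(self.values_mg)

    def mean_sd(self) -> tuple[float, float]:
        w = self.weights / self.weights.sum()
        mean = float(np.dot(w, self.values_mg))
        sd = float(np.sqrt(np.dot(w, (self.values_mg - mean) ** 2)))
        return mean, sd

    def percentile(self, p: float) -> float:
        return weighted_percentile(self.values_mg, self.weights, p)


def _transform(x: np.ndarray, transformation: str, offset: float) -> np.ndarray:
    if transformation == "log":
        return np.log(np.asarray(x, dtype=float) + offset)
    if transformation == "identity":
        return np.asarray(x, dtype=float)
    raise UsualIntakeError(f"unknown transformation {transformation!r}")


def _back_transform(t: np.ndarray, transformation: str, offset: float) -> np.ndarray:
    if transformation == "log":
        return np.maximum(np.exp(t) - offset, 0.0)
    return np.maximum(np.asarray(t, dtype=float), 0.0)


def _weighted_var(x: np.ndarray, w: np.ndarray) -> float:
    """Unbiased weighted variance (reliability weights); equals the
    ddof=1 sample variance for uniform weights."""
    w = np.asarray(w, dtype=float)
    x = np.asarray(x, dtype=float)
    sw = w.sum()
    mean = np.dot(w, x) / sw
    denom = sw - np.dot(w, w) / sw
    if denom <= 0:
        return 0.0
    return float(np.dot(w, (x - mean) ** 2) / denom)


def estimate_variance_components(
    per_subject: Sequence[np.ndarray],
    weights: Sequence[float] | None = None,
) -> VarianceComponents:
    """One-way random-effects decomposition on the transformed scale.

    ``per_subject`` holds each subject's transformed daily intakes (length
    = number of recall days).  The within-person variance is the (weighted)
    mean over subjects with >= 2 days of the per-subject sample variance;
    the between-person variance is the variance of subject means minus the
    within-variance share attributable to day-level noise,
    ``within_var / mean_days``, floored at zero.

    Raises :class:`UsualIntakeError` when no subject has repeated days
    (use an external variance ratio instead).
    """
    per_subject = [np.asarray(d, dtype=float) for d in per_subject]
    n = len(per_subject)
    if n < 2:
        raise UsualIntakeError("need at least 2 subjects to estimate variances")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
    repeat = [i for i, d in enumerate(per_subject) if len(d) >= 2]
    if not repeat:
        raise UsualIntakeError(
            "no subject has repeated recall days; use VarianceRatioSpec("
            "mode='external', ratio=...) with an external variance ratio"
        )
    sub_vars = np.array([np.var(per_subject[i], ddof=1) for i in repeat])
    wr = w[repeat]
    within = float(np.dot(wr, sub_vars) / wr.sum())
    means = np.array([d.mean() for d in per_subject])
    mean_days = float(np.dot(w, [len(d) for d in per_subject]) / w.sum())
    between = max(0.0, _weighted_var(means, w) - within / mean_days)
    return VarianceComponents(
        between_var=between,
        within_var=within,
        n_subjects=n,
        n_repeat_subjects=len(repeat),
    )


def adjust_distribution(
    day1_mg: Sequence[float],
    weights: Sequence[float] | None = None,
    spec: VarianceRatioSpec | None = None,
    components: VarianceComponents | None = None,
    *,
    group: LifeStageGroup | None = None,
    subject_ids: Sequence[str] | None = None,
    transformation: str = "log",
    offset: float = DEFAULT_LOG_OFFSET,
    bias_correction: bool = True,
) -> UsualIntakeDistribution:
    """Shrink a one-day intake distribution into a usual-intake estimate.

    On the transformed scale each value moves toward the weighted group
    mean: ``t' = m + (t - m) * sqrt(1 / (1 + ratio))``.  In ``internal``
    mode the ratio comes from ``components``; in ``external`` mode from
    ``spec.ratio``.  With ``bias_correction`` (default) the back-transform
    adds half the estimated within-person variance on the log scale so the
    result estimates each subject's raw-scale long-run mean intake.

    A zero between-person variance in internal mode collapses the whole
    group to its mean (a degenerate but well-defined distribution); a
    warning is emitted.
    """
    x = np.asarray(day1_mg, dtype=float)
    if x.size == 0:
        raise UsualIntakeError("empty intake list")
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    spec = spec or VarianceRatioSpec(mode="internal")

    t = _transform(x, transformation, offset)
    wn = w / w.sum()
    m = float(np.dot(wn, t))
    day1_var = _weighted_var(t, w)

    if spec.mode == "internal":
        if components is None:
            raise UsualIntakeError("internal mode requires variance components")
        if components.between_var == 0.0:
            warnings.warn(
                "between-person variance is 0: usual-intake distribution is "
                "degenerate at the group mean",
                stacklevel=2,
            )
            shrink = 0.0
            within = components.within_var
        else:
            ratio = components.ratio
            shrink = float(np.sqrt(1.0 / (1.0 + ratio)))
            within = components.within_var
    else:
        ratio = spec.resolve_ratio()
        shrink = float(np.sqrt(1.0 / (1.0 + ratio)))
        # split the observed day-1 variance according to the external ratio
        within = day1_var * ratio / (1.0 + ratio)

    t_adj = m + (t - m) * shrink
    correction = 0.0
    if bias_correction and transformation == "log":
        correction = within / 2.0
        t_adj = t_adj + correction

    values = _back_transform(t_adj, transformation, offset)
    return UsualIntakeDistribution(
        group=group,
        values_mg=values,
        weights=w,
        subject_ids=list(subject_ids) if subject_ids is not None else None,
        metadata={
            "transformation": transformation,
            "offset": offset,
            "mode": spec.mode,
            "shrink_factor": shrink,
            "within_var": within,
            "bias_correction": correction,
            "transformed_mean": m,
        },
    )


def weighted_percentile(
    values: Sequence[float], weights: Sequence[float], p: float
) -> float:
    """Weighted percentile with linear interpolation.

    The rule generalises the standard linear-interpolation sample
    percentile so that positive-integer weights reproduce ``np.percentile``
    of the weight-expanded sample exactly: the continuous rank is
    ``h = (W - 1) * p / 100`` with ``W`` the total weight, and the value is
    interpolated between the expanded-sample positions ``floor(h)`` and
    ``ceil(h)``.  Weights should therefore be on a count-like scale (survey
    weights are).  ``p=0`` returns the minimum, ``p=100`` the maximum, and
    the result is monotone in ``p``.
    """
    if not 0.0 <= p <= 100.0:
        raise ValueError(f"percentile p={p} outside [0, 100]")
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise ValueError("empty distribution")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    order = np.argsort(v, kind="stable")
    v = v[order]
    w = w[order]
    if p == 0.0:
        return float(v[0])
    if p == 100.0:
        return float(v[-1])
    cw = np.cumsum(w)
    W = cw[-1]
    h = max(0.0, (W - 1.0)) * p / 100.0
    j0 = np.floor(h)
    j1 = np.ceil(h)
    # value at expanded position j: first k with cumulative weight > j
    k0 = int(np.searchsorted(cw, j0, side="right"))
    k1 = int(np.searchsorted(cw, j1, side="right"))
    k0 = min(k0, v.size - 1)
    k1 = min(k1, v.size - 1)
    if k0 == k1:
        return float(v[k0])
    return float(v[k0] + (h - j0) * (v[k1] - v[k0]))
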
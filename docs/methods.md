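# Methods

## Problem and model

`calfort` estimates what mandatory calcium fortification of flour would do
to a population's calcium intake. The inputs are individual-level 24-h
dietary recalls (or food records): per subject, day, and food item, the
amount eaten (g) and its calcium content (mg), plus demographics, survey
weights, and a map from food codes to flour content. The outputs are, per
IOM life-stage group, the estimated usual-intake distribution before and
after fortification and two tail quantities: the prevalence of inadequate
intake (share of the group below the EAR, the cut-point method) and the
share at risk of excess (above the UL).

The analysis chain is:

1. **Daily totals.** Per subject-day, calcium is summed over all items
   (supplements included); fortifiable flour is summed as
   `amount_g x flour_fraction` over non-tablet items. Tablet/pill
   supplements may contain starch but would never be fortified, so they
   contribute calcium but no flour. A food's flour fraction is the sum
   over its flour types (bread with 30% rice flour and 40% wheat flour is
   70% flour); by default all flour types are fortified jointly, and a
   `flour_types` filter restricts fortification to a subset (e.g.
   wheat-only programmes).

2. **Usual-intake adjustment.** A single day's intake is usual intake plus
   within-person day-to-day noise; using one-day intakes directly
   overstates both tails. On a transformed scale (natural log with offset,
   see below) each subject's day-1 value is shrunk toward the weighted
   group mean:

   `t_i' = m + (t_i - m) * sqrt(1 / (1 + r))`,   `r = s2_within / s2_between`.

   With repeated recalls (`internal` mode) the variance components come
   from a one-way random-effects decomposition by the method of moments:
   the within-person variance is the weighted mean of per-subject sample
   variances over subjects with at least two days; the between-person
   variance is the variance of subject means minus `s2_within / mean
   days`, floored at zero. Any two distinct day indices count as a repeat
   (nonconsecutive-day correlation corrections are out of scope). Without
   repeats (`external` mode) the ratio `r` must be supplied from a
   comparable survey; the shipped default of 2.0 is a placeholder and
   triggers a warning whenever it is used.

3. **Back-transformation.** Usual intake is defined as a subject's
   long-run *mean* daily intake on the raw scale. Under multiplicative
   noise the mean log intake sits half a within-variance below the log of
   that mean (Jensen's gap), so the default back-transform adds
   `s2_within / 2` on the log scale before exponentiating. Without this
   correction the estimated distribution is systematically shifted low by
   `exp(-s2_within/2)` and the cut-point prevalence is biased (about
   1.4 points at the default within-person log-SD of 0.5 for a group with
   ~97% baseline inadequacy; enough to break parameter recovery at
   n = 1000). Setting `bias_correction=False` reproduces the plain
   shrinkage estimate, which preserves the transformed-scale weighted mean
   exactly; with the correction on, the transformed mean shifts by exactly
   `s2_within / 2`. In external mode `s2_within` is inferred by splitting
   the observed day-1 variance according to the external ratio.

4. **Fortification scenario.** Fortifying at level `L` mg per 100 g adds
   `flour_g x L / 100` mg to each subject-day (default 156 mg/100 g, the
   UK mandatory ceiling for calcium in white wheat flour). The adjustment
   is re-run on the fortified daily intakes with the same variance
   configuration: fortification adds a deterministic per-day amount, so
   re-estimating components on shifted data would change nothing
   meaningful on the raw scale.

5. **Adequacy metrics and planning gap.** Prevalences use strict
   comparisons (exactly at the EAR is adequate, exactly at the UL is
   safe). The target prevalence of inadequacy is a step rule on baseline
   prevalence: above 50% -> 50%; between 10% and 50% -> 10%; below
   10% -> 0%. Both boundaries are conventions documented in code: exactly
   50% maps to 10 ("above 50%" read strictly) and exactly 10% maps to 10
   ("between" read inclusively). The initial gap is
   `max(0, EAR - percentile(usual, target))`, the mg/day shift needed so
   that only the target share remains below the EAR; dividing by the
   group's mean flour intake (per 100 g) converts it to a candidate
   fortificant level.

Survey weights enter every mean, variance, percentile, and prevalence.
Point estimates only; no uncertainty intervals around prevalences.

## Reference values

The shipped table covers calcium for 18 IOM life-stage groups: pooled-sex
children (0.5-1: EAR 270/UL 1500; 1-4: 400/2500; 4-9: 640/2500), females
and males 9+ (six age bands each), and pregnant women (14-19: 1100/3000;
19-31 and 31-51: 800/2500). Age intervals are half-open `[min, max)`,
matching the "a <= age < b" group labels; pregnant women younger than 19
are classified by their own age row, not forced into adult rows. The
table is a data file (CSV) so other nutrients or country-specific
references can be swapped in; lactation groups and infants under 6 months
are not covered. Classification errors (pregnant male, age < 0.5, a
pregnant woman outside 14-51) name the subject.

## Numerical choices

* **Transformation.** Natural log with offset 1.0 mg, `t = ln(x + 1)`.
  Zero daily calcium is biologically implausible but can occur in sparse
  recalls; the offset keeps zeros transformable and is negligible at
  typical intakes (~150-1000 mg). The transformation is pluggable
  (`log` | `identity`) and recorded in output metadata.
* **Weighted percentile.** Linear interpolation at continuous rank
  `h = (W - 1) p / 100` over the weight-expanded order; for
  positive-integer weights this reproduces `np.percentile` of the
  expanded sample exactly, so weights should be on a count-like scale
  (survey weights are). `p=0`/`p=100` return min/max.
* **Weighted SDs.** Reported summary SDs are population-style (divide by
  total weight); variance *estimation* uses the unbiased reliability-
  weights form (equals ddof=1 for uniform weights).
* **Degenerate cases.** Zero between-variance collapses the group to its
  mean with a warning; groups smaller than `min_n` (default 10) are
  analysed but flagged; unmapped food codes count as flour-free and are
  tallied in the run warnings.
* **Tie-breaks.** Values exactly at a cut-point never count in a tail;
  the first recall day is the lowest day index.

The % of a group consuming flour and the mean/SD flour intake use each
subject's **first recall day only**, zeros included — the day-1 convention
keeps the statistic comparable between subjects with one and two recall
days.

## Synthetic surveys and what they do (not) show

`calfort.synthetic` generates seeded surveys with known ground truth:
usual intake `U_i ~ LogNormal(mu, sigma)` per group; daily intake
`D_ij = U_i exp(e_ij - s2_w/2)`, `e_ij ~ N(0, s2_w)` so `E[D|U] = U`;
flour-consumer status Bernoulli per subject with Gamma daily grams for
consumers; days split into 2-5 food items with flour carried by an item
of known fraction; uniform or log-normal weights. True `%<EAR`, `%>UL`,
and the mean come from the log-normal CDF, not from sampling.

Seven presets (`argentina-like` ... `zambia-like`) moment-match the group
sizes, flour-consumer shares (6% in the Bangladesh-like survey to ~100%
in the Zambia-like one), and calcium/flour means/SDs published in summary
tables of seven national dietary surveys. The
Argentina-like preset has a single recall day (external-ratio mode); the
others have two days for every subject — the real surveys' smaller
second-round subsets are not emulated. The within-person log-SD is not
recoverable from the published tables and is fixed at 0.5 (daily CV
~53%, a typical magnitude for calcium) for all presets.

Passing tests on these cohorts show that the estimator chain is
internally consistent and recovers known log-normal truths; they do not
show agreement with the published country tables, which would require the
original survey microdata and the internals of the adjustment software
used to produce them (its transformation family and within-person
variance model are not public). The worked-example check used here is the
additivity identity on group means, which holds to <0.5% on the Argentina
rows independent of adjustment details.

## Problem sizes

The test suite and the acceptance script use: 1000 random cut-point
instances of up to 10^4 points (tests; 200 in the script), 200 replicates
of n = 1000 subjects x 2 days for parameter recovery, 50 random cohorts
of 40-120 subjects for monotonicity, n = 10^5 for generator-truth
convergence, and full-size presets (up to ~22,000 subjects for the
Argentina-like survey) for end-to-end runs.

## Known limitations

* The adjustment is a single log-scale shrinkage (the simplest member of
  the ISU family); it does not model episodic consumption (two-part /
  NCI), covariates, or heterogeneous within-person variance, and it
  assumes the transformed day-1 distribution is approximately normal.
* The external-ratio default (2.0) is a placeholder, not an estimate.
* Flour-content mapping quality is the user's responsibility; unmapped
  codes silently contribute no flour (with a logged count).
* No bioavailability/absorption modelling, nutrient interactions, or
  cost considerations: the simulation is purely about intake shifts.
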
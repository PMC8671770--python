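# Methods

`edmood` implements a complete, reproducible version of a survey-analysis
workflow used in college mental-health research: respondents screened for
anxiety (GAD-7) and depression (PHQ-2) are clustered into severity tiers, and
disordered-eating concerns, behaviors and a composite severity score (EDE-Q)
are contrasted across the tiers. This note documents the statistical choices,
the synthetic-data model behind the tests, and the known limitations.

## Instrument scoring

GAD-7 (7 items, 0–3) and PHQ-2 (2 items, 0–3) totals are plain item sums
(ranges 0–21 and 0–6; diagnostic cutoffs 10 and 3). The four averaged EDE-Q
subscales (restraint 5 items, eating concern 4, shape concern 8, weight
concern 5) are arithmetic means of 0–6 day-frequency categories. Binge eating
is a single 28-day episode count (0–41) used as-is.

The three purging behaviors are 28-day counts recoded onto clinically
weighted 0–6 bins before summing into the 0–18 purging score. Vomiting and
laxative use: 0 → 0, 1–5 → the count itself, 6+ → 6. Excessive exercise:
0 → 0, then quintile-width bins (1–5 → 1, 6–10 → 2, 11–15 → 3, 16–20 → 4,
21–25 → 5, >25 → 6). On both codings a recoded value of 4+ marks the
frequency at which the behavior is considered clinically significant. An
alternative 1–7 presentation of the same bins exists in some reports; it is a
constant offset and is not used in scoring.

Missing items are never imputed or prorated: a record with any missing scored
item is flagged incomplete and removed by the cohort filter, mirroring how
non-finishers are handled in practice.

Cronbach's alpha uses `k/(k-1) * (1 - Σ var(item) / var(total))` with the
population-variance convention in numerator and denominator; the ratio, and
hence alpha, is identical under the sample convention.

## Cohort filter

Exclusions are applied in a fixed order with first-match attribution —
duplicate id (keep first), incomplete, age outside 18–25, no US high school,
graduate student — so each record lands in exactly one bucket and
`n_final = n_started − Σ exclusions` always holds. Both age bounds are
enforced under the single age rule. Precedence matters only for records
failing several rules; the chosen order follows the natural narrative order
of survey-intake cleaning.

## Severity composite

Each of six subscales (four averaged EDE-Q subscales, binge, purging) is
recoded against the 75th/90th percentiles of the analytic sample itself:
0 below p75, 1 in [p75, p90] (both boundaries inclusive), 2 above p90;
categories sum to 0–12. Percentiles use linear interpolation between order
statistics (`numpy.percentile(..., method="linear")`), fixed so cutoffs are
bit-reproducible. The boundary-tie rule is a documented choice; with
continuous tie-free scores the expected category shares are 75/15/10% and the
tie rule is irrelevant. With heavily tied count-derived subscales (purging,
binge) the shares deviate substantially from 75/15/10 — an intrinsic property
of percentile recoding on discrete data, not an implementation artifact.
Cutoffs are always recomputed from the supplied sample; there are no norm
tables.

## Two-stage clustering

Clustering operates on the raw (GAD-7 total, PHQ-2 total) pairs without
standardization; GAD-7's larger range dominates the Euclidean metric, which
is consistent with the near-total anxiety separation such cohorts exhibit
(anxiety partial η² ≈ 0.94 vs depression ≈ 0.4–0.5).

**Ward schedule.** Stage one is Ward minimum-variance agglomeration
(`scipy.cluster.hierarchy.linkage`, exact O(n²) at desk scale, no
approximation). The schedule coefficient at stage *s* is the cumulative
within-cluster sum of squares after the merge — scipy's Ward height *h*
satisfies *h² = 2·ΔESS*, so coefficients are `cumsum(h²/2)`. Two invariants
are enforced by tests: coefficients are non-decreasing and the final
coefficient equals the total SS about the grand mean.

**Elbow rule.** The number of clusters is read off the schedule as
`k = n − s*`, where *s** is the stage after which the coefficient difference
"takes off". The default criterion is a scale-free explained-variance rule:
*s** is the first stage whose following merge consumes more than 5% of the
total sum of squares. The rationale: in any nested group structure the final
(2→1) merge has the globally largest absolute jump, so "largest first
difference" would return k = 2 regardless of the real number of groups; what
identifies the elbow is the *first* merge expensive enough to be structural.
On four-tier anxiety/depression cohorts of this shape, the merge from 5 to 4
clusters consumes ~2–3% of total SS and the merge from 4 to 3 consumes ~9%,
so the rule lands on k = 4 with margin on both sides. The literal
largest-jump criterion is available as `criterion="absolute"` (searched over
a candidate window k ∈ 2..15, earliest stage on ties). The 5% share is a
conventional scree-style variance cutoff chosen a priori; it presumes a
handful of clusters each carrying a non-trivial variance share and will
under-count many small equally sized clusters.

**K-means.** Stage two is seeded Lloyd's K-means (`sklearn.cluster.KMeans`)
at the elbow k: k-means++ initialization, 10 restarts by default, best
inertia kept; a `ward_means` mode instead seeds centroids from the Ward
k-cluster means (the classic two-stage convention). Final centroids are
recomputed as exact means of assigned points. Every seed is recorded in the
run manifest.

**Labels.** Clusters are ordered by ascending mean GAD-7. With k = 4 and a
cutoff pattern matching the four-tier narrative — clusters 1–2 below both
diagnostic cutoffs, cluster 3 at/above the GAD-7 cutoff, cluster 4 at/above
both — the canonical labels are applied (not depressed/anxious, mixed
(subclinical), moderate, high). The moderate tier deliberately requires only
the anxiety cutoff: in cohorts of this shape the third cluster's PHQ-2 mean
sits just under 3 while its GAD-7 mean is well above 10. Any other pattern,
or k ≠ 4, yields rank labels plus an explicit inconsistency warning — the
pipeline never silently names a configuration that contradicts the cutoffs.

## Group statistics

Per-cluster summaries are sample mean, sample SD (n−1), and t-based 95% CIs
(`mean ± t(0.975, n−1)·sd/√n`; z-based CIs differ negligibly at these n).
One-way ANOVA is computed from group summary triples (n, mean, sd) —
`SSB = Σ nᵢ(mᵢ−m̄)²`, `SSW = Σ (nᵢ−1)sᵢ²` — and the raw-data route simply
summarizes and delegates, so the two routes agree to machine precision (a
property-tested identity). Partial η² = SSB/(SSB+SSW), classified
below-small/small/medium/large at 0.01/0.06/0.14. Post hoc contrasts use
Tukey–Kramer for unequal group sizes with adjusted p-values from scipy's
studentized-range distribution on (k, N−k); significant pairs (p < .05) are
emitted as the conventional letter set (a = 1v2 … f = 3v4). Main-effect and
post hoc thresholds default to .01/.05 and are arguments. Within-group df is
N−k throughout (1788 for four groups of 609/567/371/245, even where reports
print 1789).

## Synthetic cohort generator

The generator's defaults emulate a four-cluster college cohort of n = 1792
(609/567/371/245) with published cluster-level moments: GAD-7 means
1.84/6.61/12.30/18.89, PHQ-2 means 0.56/1.45/2.42/3.49, per-cluster EDE-Q
subscale means/SDs, overdispersed binge counts, rare vomiting/laxative use,
and exercise on the recoded scale. Mechanics, per group:

* **Totals.** GAD-7 and PHQ-2 totals, and the four averaged subscales, are
  drawn from normals truncated to their scale ranges. The parent location is
  solved (Brent's method) so the *truncated* mean equals the target —
  without this, truncating e.g. mean 18.89, SD 1.92 at 21 would bias the
  realized mean down by ≈ 0.5. SD shrinkage from truncation and rounding is
  unavoidable and is reported (target vs realized) in the generator
  manifest, never hidden.
* **Items.** Each total is decomposed into item responses by randomly
  allocating unit increments across items under the per-item caps (0–3 for
  GAD/PHQ items, 0–6 for EDE-Q items), so item sums reproduce the drawn
  totals exactly and subscale means land within half a unit per item of the
  drawn target.
* **Counts.** Binge: negative binomial moment-matched to (mean, sd) —
  published SDs exceed means throughout — truncated at 41. Vomiting and
  laxatives: zero-inflated geometric with positive-part mean 1.5, occupancy
  set by the target mean. Exercise: the recoded 0–6 value is drawn
  (mean-matched truncated normal, rounded) and inverted to a raw count
  uniform within its bin, so the recode reproduces the drawn value exactly.
* **Intake.** `generate_intake` wraps the cohort with configured numbers of
  duplicate-id copies, item-deleted incompletes, over-age, foreign-high-school
  and graduate records — each engineered to trip exactly one exclusion rule —
  and shuffles deterministically. The defaults reproduce the canonical
  2564 → 1792 intake arithmetic (150 duplicates, 405 incompletes, 81
  over-age, 126 foreign high school, 10 graduate students).

All draws flow from one `numpy` Generator seeded by the config, so output is
byte-identical across re-runs.

**What the generator does not model.** Within-group draws are independent
across scales: no GAD/PHQ/EDE-Q correlation beyond what the shared group
induces, no item-level response model (IRT), no demographic covariates
beyond the eligibility fields. Consequently the severity composite's
per-cluster means are lower than a real cohort's (where subscale elevations
co-occur within person), although their monotone increase across clusters is
preserved. Passing tests therefore demonstrate that the *pipeline* recovers
the structure it assumes, not that real data would show these exact values.

## Problem sizes in the test suite

Unit tests run on scaled-down cohorts (4 × 40 respondents); the
parameter-recovery suite runs the full n = 1792 design over 20 seeds
(~15 s), chosen to estimate the elbow hit-rate and cluster-mean recovery
with reasonable Monte-Carlo resolution; the percentile-calibration check
uses 10⁵ tie-free draws.

## Known limitations

* The elbow rule's 5% variance share is tuned to "few clusters, each
  substantial"; it is not a general model-selection procedure (no silhouette
  or gap statistic is provided, by design).
* Percentile-based severity categories are unstable on heavily tied discrete
  subscales (see above).
* ANOVA assumes homoscedasticity; no Welch or Games–Howell variants.
* Recomputation of published tables from printed summaries inherits the
  rounding of those summaries (CI bounds can move by ±0.005, letter patterns
  near p = .05 can flip).
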
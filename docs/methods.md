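# Methods

This note documents the models, rules and numerical choices behind
`prolight`, and what the synthetic-data tests do and do not demonstrate.

## Instruments and scoring

Two instruments ship in the registry (`src/prolight/data/scales.yaml`):

* **EORTC QLQ-C30 subset** — the scales fed back to patients: physical
  (5 items), emotional (4), cognitive (2) and social (2) functioning,
  global health status/QoL (2 items coded 1–7), fatigue (3 items), plus a
  single-item neuropathy symptom ("tingling in hands or feet") modelled as
  an ordinary symptom scale. Items are coded 1–4 (global 1–7). The raw
  score is the mean of the answered items; the linear transform maps it to
  0–100: functioning scales use S = (1 − (raw − min)/range)·100 so that the
  favorable extreme scores 100, symptom scales and the global scale use
  S = ((raw − min)/range)·100 (global range 6).
* **HADS** — anxiety and depression subscales of exactly 7 items each,
  coded 0–3, scored by summation to 0–21, higher meaning more symptoms.

A note on coding conventions: questionnaires are sometimes described with
five verbal anchors "0 (not at all) to 4 (very much)", but the published
scoring algorithm that yields the 0–100 range assumes the 4-point 1–4
coding used here. The registry carries explicit `response_min`/`max` per
item, so a deployment that codes differently configures it there; the
transform adapts automatically.

Missing data follow the instruments' standard conventions, exposed as
parameters on `ScaleDefinition`: EORTC scales are scored when at least half
of the items are answered (`min_answered_fraction = 0.5`), using the mean
of the answered items; HADS subscales tolerate at most one missing item
(`hads_max_missing = 1`), prorating the 6-item sum by 7/6. Anything beyond
that yields a missing scale score, which downstream modules surface as an
explanatory note rather than a number.

Transformed scores are kept at full floating precision internally; rounding
to one decimal happens only in rendered documents.

## Reference norms and age bands

Scores are interpreted against `NormTable` cells keyed by (comparator,
scale, sex, age band). The default age-band scheme is 18–30, 31–45, 46–60,
61–75, >75 — bands of 10–15 years from age 18 with an open-ended last band.
The middle band edges are a design choice here (only the first and last
bands are pinned by the deployment this mirrors) and the scheme is fully
configurable. Band bounds are inclusive integers; a fractional age between
two bands (e.g. 30.5) falls in the lower band.

Lookup resolves in order: exact (sex, band) cell → pooled-sex cell for the
band → all-ages cells. A miss raises a typed `NormUnavailableError`; there
is deliberately no silent default, because "no norm" is meaningful (the
packaged table has no general-population norm for tingling, and the report
module degrades that comparison to an own-score chart with a note).

The packaged `norms_reference.csv` is a **demonstration fixture**: it
carries published pooled summaries of a lymphoma reference cohort (n = 876)
and a general-population normative cohort (n = 1852) as pooled-sex,
all-ages cells. Sex- and age-stratified reference statistics for these
cohorts are not published at cell level, so sex/age lookups resolve through
the pooled fallback. Production deployments supply fully stratified tables
through the same CSV/JSON interface.

## Clinically relevant differences

The traffic-light half-width d is the per-scale *minimal medium clinically
relevant difference* from the EORTC interpretation guidelines. The
guideline values themselves are an external resource, so
`data/thresholds.yaml` ships round defaults in the spirit of the guideline
magnitudes (10 points for the 0–100 scales, 3 points for HADS) with the
explicit intent that deployments edit them; all package behaviour is
parameterized over the configured d. The same file configures the ordered
|difference| cutoffs mapping a group mean difference to
no / trivial / small / medium / large.

## Traffic-light classification

Against a norm mean m with half-width d, the score bands are
(−∞, m−d] / (m−d, m+d) / [m+d, ∞) intersected with the score range:
amber within d of the mean, the extreme colors otherwise, oriented by scale
polarity. Two boundary conventions matter:

* A score exactly at m ± d takes the extreme color ("as much as or more
  than" the minimal difference); the amber interval is open at both ends.
  Segments record open/closed endpoints so each score belongs to exactly
  one segment.
* When m + d exceeds the scale maximum (or m − d falls below the minimum)
  the clipped extreme segment is empty and dropped from the chart geometry;
  the classification rule is unchanged.

HADS subscales are classified on absolute severity cutoffs (0–7 green,
8–10 amber, ≥ 11 red) regardless of the chosen comparator; comparator
norms for HADS remain available to the statistics module. Whether the
original feedback system additionally painted HADS charts with norm-based
bands is not documented; this package uses the cutoff bands for the chart.

GP advice defaults to red **symptom** scores only (EORTC symptom scales
and HADS); `advise_functioning=True` extends it to functioning scales, an
extension explicitly requested by patients.

## Feedback reports

Generation is strictly opt-in: a declined selection produces a
`FeedbackReport` with `generated=False` and no sections. Topics map 1:1 to
scales (nine topics in total; "all" expands to all nine). Comparator
choices are own-scores-only, lymphoma cohort, general population, or both
cohorts; own-only renders a single uncolored bar with the dotted score
line. Narrative text is assembled from a YAML registry — scale
description, one interpretation sentence per comparator chosen purely by
(scale family, comparator, color), a contextual paragraph, and the GP
callout — so localization is a file swap. "Yellow" and "amber" are one
category with one token.

Charts are SVG assembled by deterministic string formatting: colored
rectangles matching the segment geometry (adjacent integer HADS bands meet
at the half-integer so the bar is gapless) and a dotted purple line at the
patient's score — bar chart, traffic colors and dotted line being the
design patients preferred. Identical inputs produce byte-identical SVG,
HTML and JSON, which the end-to-end determinism test exploits.

## Statistics

* **Exact tests.** Fisher's exact test and the Freeman–Halton r × c
  generalization are computed by complete enumeration of all tables with
  the observed margins (depth-first over bounded row compositions). The
  two-sided p-value uses probability-mass ordering: the sum of
  probabilities of tables whose probability does not exceed the observed
  table's, compared with relative tolerance 1e−7 so that tables with
  mathematically equal probability (which arise whenever two row margins
  coincide) are never excluded by floating-point rounding. Probabilities
  are computed in log space via `gammaln`. Enumeration is guarded by a
  configurable cap (default 2·10⁶ tables); beyond it a Monte-Carlo mode
  samples margin-fixed tables with Patefield's algorithm. The 2×2 case is
  the same code path. Validity (P(p ≤ α) ≤ α under the margin-fixed null)
  is verified in the tests against the complete null distribution rather
  than by sampling.
* **t tests.** Two-sided two-sample t, pooled (Student) by default — the
  plain "t test" convention — with Welch by flag; raw-sample and
  summary-statistic entry points agree exactly. Zero variance in both
  groups with equal means returns p = 1 by convention; with unequal means
  it is a domain error.
* **ANCOVA.** OLS of score on intercept + group (0/1) + age (years,
  untransformed) + sex (0/1). The group coefficient is the adjusted mean
  difference; adjusted group means are evaluated at the overall covariate
  means, so they differ exactly by the coefficient. Rank-deficient designs
  raise an error naming the collinear column(s).

## Synthetic cohorts

The generator emulates the study conditions at scale-summary level. Its
defaults are the study's: n = 45 patients, 58% male, age ~ N(60.7, 13.6²)
truncated to [18, 95]; per-scale targets equal to the published lymphoma
reference cohort means/SDs; opt-in probability 0.80; per-topic viewing
probabilities from the published uptake table (1.00 down to 0.81); and
comparator-set probabilities own-only 2/36, lymphoma-only 11/36, both
cohorts 23/36 (the published marginals — 34/36 cohort viewers, 23/36
population viewers, 2/36 own-only — imply the population viewers are a
subset of the cohort viewers).

Per patient and scale a latent score is drawn from a normal distribution
truncated to the score range and rounded to the nearest score the items can
realize; the sub-item remainder is spread over items by randomized
rounding. Because truncation and grid rounding pull the realized mean
toward the middle of the range (several published means sit close to the
ceiling — e.g. a nominal N(82.4, 23²) truncated to [0, 100] has mean
≈ 73.6), the latent location is calibrated per scale: the expectation of
the rounded, truncated draw has a closed form over the achievable-score
grid, and the location is root-solved (Brent) so that the *expected scored
value equals the target mean exactly*. The realized SD is consequently
smaller than the nominal target SD (truncation removes tail mass); only
the mean is guaranteed. A single root seed spawns independent substreams
for demographics, scores, selections and missingness, so each piece
regenerates identically on its own.

What the generator does **not** emulate — and therefore what passing tests
do not show about real data: item-level response structure within a scale
(generated items are maximally homogeneous, real items correlate
imperfectly), the skew and ceiling clumping of real HRQoL distributions
beyond what truncation induces, correlations between scales, and any
coupling of demographics or clinical covariates to outcomes (the
microdata generator injects linear age/sex/group effects only where a test
asks for them).

`simulate_norm_microdata` generates subject-level scores from an explicit
linear model (baseline + group effect + age effect + sex effect + normal
noise, optionally with an age-shifted group for confounding constructions)
for ANCOVA calibration and recovery tests.

## Problem sizes and numerical tolerances in the test suite

Monte-Carlo assertions use 3-standard-error bounds under fixed seeds:
cohort target recovery at n = 5000 patients; ANCOVA null calibration over
200 replicates of 40 + 40 subjects plus effect recovery at 500 + 500;
exact-test validity over the complete enumerated null distribution of two
small margin sets; tail-mass checks for the color tabulation at n = 1000.
Exact-test probability sums are asserted to 1e−9; least-squares oracles to
relative 1e−10; serialization round-trips must be bit-exact.

## Known limitations

* The packaged norms are pooled, not stratified; age/sex matching is
  structural until a deployment supplies stratified tables.
* Longitudinal feedback (tracking scores over time), PDF export and
  interactive delivery are out of scope.
* The shipped d values and size-class bounds are editable defaults, not
  the guideline values themselves; analyses that depend on specific
  thresholds must configure them.
* Narrative text ships in English only (the registry is the localization
  point).
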
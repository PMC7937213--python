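# Methods

## Problem

Continuous patient-reported outcomes (a 0–100 mm pain VAS, the 0–100
Constant–Murley score, the 0–12 Simple Shoulder Test) are hard to act on
without two interpretation thresholds:

* **MID** (minimal important difference): the smallest *change* from
  baseline that patients perceive as important — "feeling better".
* **PASS** (patient acceptable symptom state): the *follow-up score* at
  which patients consider themselves well — "feeling good".

Both are estimated against an external transition anchor: a five-level
global rating of change (GRC), 1 = very satisfied / healed completely …
5 = worse.  This package implements the full anchor-based estimation
pipeline for a shoulder-trial design (three treatment arms, pain measured
at 6/12/24 months, function instruments at 6/24 months), together with a
synthetic cohort generator, because the motivating trial's data are not
publicly available.

## Data contract

Long format, one row per patient × timepoint × instrument, with baseline
score, post score, and GRC.  Change scores are stored signed
(post − baseline) but every estimator consumes the *improvement
magnitude* (sign flipped for pain instruments), so pain and function
share one code path and all MIDs print as positive numbers.  Missing
items are handled by pairwise deletion per analysis — no imputation —
which is what makes the analysable pair counts differ across instruments
and timepoints.  Pooling across timepoints concatenates rows: the unit of
the pooled analyses is the GRC-outcome pair, not the patient (a
patient-level bootstrap is available as a sensitivity option, off by
default, since the motivating analysis pooled pairs without clustering
adjustment).

## MID estimators

The anchor is dichotomized to improved (GRC 1–3) vs no change (GRC 4);
worseners (GRC 5) are excluded from the ROC analysis only.  MIDs for
deterioration are not estimated (too few worseners in the design this
emulates).

* **ROC.** Candidate cutoffs are midpoints between consecutive distinct
  observed improvements, plus sentinels below the minimum and above the
  maximum.  Midpoints are deliberate: they produce non-observed
  thresholds such as 1.5 on the integer SST scale.  The reported cutoff
  minimises the Euclidean distance to the (sensitivity = 1,
  specificity = 1) corner, unweighted; ties break toward higher
  sensitivity, then higher specificity, then the smaller cutoff.  The
  engine reports full-precision cutoffs; reporting can round for
  presentation.
* **MDoC.** Mean improvement of GRC 3 ("somewhat satisfied") minus mean
  improvement of GRC 4.
* **MC.** Mean improvement of GRC 3.  By construction
  MDoC = MC − mean(GRC 4 improvement), an identity the tests exercise.

## PASS estimators

PASS is estimated on post scores, pooled across timepoints, under two
anchor definitions — satisfied = {GRC 1} (conservative) or {GRC 1, 2} —
with nobody excluded.  The ROC method mirrors the MID one
(lower-predicts-satisfied for pain, higher for function).  The percentile
method takes the 75th percentile of the satisfied group's post scores for
pain instruments and the 25th for function instruments.  All quantiles in
the package (percentile method, bootstrap intervals) use linear
interpolation between order statistics; one definition everywhere.
Integer SST thresholds remain reachable because SST posts are integers.

## AUC and its confidence interval

The AUC is the Mann–Whitney probability that a random improved patient
out-scores a random not-improved one, ties ½ — computed from midranks,
and identical to O(n²) pair counting (property-tested).  Its variance
uses DeLong's structural components: per-observation placement values
obtained from midranks in O(n log n), sample variances with ddof = 1, and
a Wald interval on the AUC scale clipped to [0, 1].  No logit transform —
the choice is documented and switchable in principle; near-degenerate
data therefore produce clipped, possibly degenerate intervals ([1, 1]
under perfect separation), which is the honest behaviour of the plain
Wald form.  DeLong needs at least two observations per class.

## Bootstrap

Percentile intervals (not BCa): 1000 resamples by default, resampling
rows (GRC-outcome pairs) with replacement; the patient-level variant
resamples patient identities and keeps their rows together.  Replicates
where the statistic is undefined (a resample that lost an entire GRC
group) are dropped and counted; more than 50 % undefined aborts with a
diagnostic.  All streams derive from a single user seed via
`numpy.random.SeedSequence`, so every table cell is bit-reproducible
under (input, seed).

## Anchor validation

Spearman correlations (midrank ties) of the anchor with baseline, post
and change scores, with bootstrap CIs.  The GRC is reversed to a
satisfaction score (6 − GRC) before correlating; in the default
"aligned" mode outcome values are also oriented so that larger = better,
making an informative anchor correlate positively everywhere.  A
"paper-sign" mode keeps raw signed scores, reproducing the sign pattern
trial reports print (negative correlations for pain).  Flags:
`adequate_change_correlation` (|rho_change| ≥ 0.3 by default — the
numeric cut is ours, configurable; reports call the anchor "adequate" or
"very low" without one), `near_zero_baseline` (|rho_baseline| < 0.2),
and `change_exceeds_post`, whose failure is the recall-bias signature.
An inadequate change correlation marks the instrument's MID as
unreliable downstream.

## Synthetic cohort generator

A latent-variable ordinal-anchor model — the simplest mechanism we found
that reproduces every qualitative finding the pipeline must detect:

* A standard-normal latent recovery `u` per patient × timepoint
  (within-patient correlation 0.5 across visits).
* Baselines are normal per instrument, clipped to scale, rounded for
  SST, and share a patient-level severity factor across instruments
  (wellbeing-aligned correlation 0.6): severe patients have more pain
  *and* worse function at baseline.
* True improvement per instrument = `effect_mean + effect_sd ×
  (κ·u + √(1−κ²)·v) + measurement noise`, with `v` an
  instrument-specific recovery component.  The coupling κ is 1 for pain
  on activity, CS and SST and 0.5 for pain at rest: rest pain is rarely
  the symptom that drives satisfaction, which is what makes its anchor
  weak.
* Post = baseline ± improvement, clipped to the scale (SST rounded).
* GRC = ordinal cut of `z = (1−w)·u + w·(standardised wellbeing post) +
  anchor noise` at thresholds (0.84, 0, −0.67, −1.64), giving roughly
  20/30/25/20/5 % in categories 1–5.  The recall-bias weight `w`
  operationalises patients rating their current state instead of their
  change; at `w > 0` the GRC-post correlation overtakes the GRC-change
  correlation, exactly the diagnostic pattern.
* Item-level missingness (3 % post, 2 % GRC, 1 % baseline) produces the
  unequal pair counts a real trial reports.

Default numeric parameters (baseline 35/70/52/6, SD 18/15/13/2.5; effect
15/30/22/3.2, SD 16/20/14/2.6; noise 24/9/5/1; anchor noise 0.25) are
**synthetic**: chosen once to be clinically plausible for subacromial
pain and calibrated so the default scenario reproduces the qualitative
pattern of the motivating analysis — discrimination AUC ≈ 0.90–0.94 for
activity pain/CS/SST, a weak rest-pain anchor, ROC MIDs below MC MIDs —
not to equal the original trial's (non-public) distributions.

Because the generator knows `u` and the cuts, it reports implied true
thresholds: at `w = 0` and κ = 1 the planted MID on the instrument scale
is `effect_mean + effect_sd × τ₃`; at `w = 1` with a single-instrument
anchor the planted PASS post cut is exact.  Scenario library:
`fimpact-like` (defaults), `perfect-anchor` (noise-free, parameters kept
clear of scale boundaries so floor/ceiling censoring cannot blur the
planted cuts), `worthless-anchor` (anchor independent of outcomes, cuts
scaled with the noise to keep category proportions), `recall-biased`
(w = 0.7), `planted-pass` (w = 1, anchor driven by activity-pain post
only).

## Validation strategy and problem sizes

* Exact oracles: AUC vs brute-force pair counting and corner selection vs
  exhaustive minimisation on 200 tie-rich random datasets; the DeLong
  variance against a hand-computed 4-observation placement-value fixture.
* Parameter recovery: the noise-free scenario recovers planted MIDs to
  midpoint resolution with AUC 1.0.  Under the default noise the
  closest-to-corner estimand is *not* the planted cut but the
  population-optimal corner cutoff (noise shifts it upward — e.g. 21.8
  vs a planted 16.6 for activity pain); the recovery test therefore
  compares the median over 200 trial-size seeds against that estimand,
  frozen from a single n = 40 000 oracle run, with a ±3-unit tolerance
  (±0.5 on SST, one midpoint step).
* Bootstrap calibration: 500 Monte-Carlo simulations of a nominal-95 %
  interval for a mean at n = 200, coverage required within 95 ± 2.5 %.
* Qualitative patterns asserted on generated cohorts: ROC MID ≤ MC MID
  (at n = 2000, where sampling noise cannot mask the ≈2-unit population
  gap), recall bias flipping the post/change correlation order, the
  weak rest-pain anchor flagged inadequate, percentile-PASS ≈ ROC-PASS
  (within 5 units on 0–100 scales, 1 on SST) for the adequately
  anchored instruments.

Problem sizes (200 seeds at the trial's n = 193; 500 × 1000 bootstrap
simulations; n = 2000–40 000 single cohorts for population checks) were
chosen to make these assertions stable at a few minutes of runtime on one
CPU.

## What passing tests do and do not show

The generator emulates structure (scales, visit schedule, shared anchor,
missingness) and qualitative anchor behaviour, not the original trial's
joint distributions: treatment arms have identical effect distributions,
missingness is completely at random, latents are normal with clipping,
and baselines are cross-sectionally but not longitudinally refined.
Passing tests show the estimators do what they claim on data with known
truth — they do not certify the original published threshold values.
Known limitations: under the weak-coupling rest-pain mechanism the MC
estimate deflates and the percentile- and ROC-PASS can genuinely diverge
for rest pain (the motivating data agreed there via a different
mechanism — satisfied patients having near-zero rest pain); MDoC sits
below the ROC cutoff in the generator because the "no change" band still
improves ≈10 units on average, whereas trial reports often find
MDoC ≈ MC; and a single-latent ordinal anchor cannot jointly reproduce a
rest-pain change correlation of ≈0.25 and a rest-pain AUC of ≈0.72 —
this generator yields ≈0.6, preserving the qualitative "does not
discriminate well" finding.
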
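# Methods

## Instrument model and recoding

The ADI-R is modelled as 93 items answered with raw codes 0–3 plus the
exception codes 7 ("definite abnormality, but not of the type specified"),
8 ("not applicable") and 9 ("not known / not asked"). Scoring collapses
3 → 2 and every exception code → 0, giving an ordinal 0–2 scale; recoding
is idempotent on its image and applied elementwise when a cohort is
assembled into the subjects × items matrix. Class labels are fixed as
autism = −1 and non-spectrum = +1 so that the ADTree's sign convention
(negative score ⇒ autism) holds by construction rather than by a
post-hoc flip.

Items are dropped before learning when a *strict* majority of their raw
answers are exception codes (fraction > 0.5, threshold configurable); an
instrument version may additionally force-exclude items (special isolated
skills, optional hand-written answers). Exclusion depends only on
per-item answer marginals, so it is invariant to subject order.

The diagnostic algorithm sums recoded scores within three behavioural
domains and classifies autism when all three totals *meet or exceed*
their cutoffs — 10 (social), 8 verbal / 7 nonverbal (communication),
3 (restricted/repetitive behaviour). "Meets-or-exceeds" is the standard
convention; a strict inequality would make the published cutoff values
themselves unreachable at the boundary. The canonical item→domain
assignment is licensed and not distributed here; the shipped default
mapping (15 social, 13 communication, 8 RRB items) is synthetic, clearly
labelled non-canonical, and only used by the simulators and examples. The
age-of-onset criterion of the instrument is out of scope. Ages are stored
as integer months; year-valued filters convert by /12 and use half-open
intervals, so the training window "5 to under 17 years" is [60, 204)
months and the under-5 subgroup is a max-only filter.

## ADTree learner

Real-valued boosting in the standard formulation: weights start at 1, the
root contributes ½ ln((W₊+ε)/(W₋+ε)), and each of T rounds adds under an
existing prediction node c₁ the base condition c₂ = (item < threshold)
minimising Z(c₁,c₂) = 2[√(W₊(c₁∧c₂)W₋(c₁∧c₂)) + √(W₊(c₁∧¬c₂)W₋(c₁∧¬c₂))]
+ W(¬c₁), with child values ½ ln((W₊+ε)/(W₋+ε)) on their partitions and
the weight update wᵢ ← wᵢ exp(−yᵢ rₜ(xᵢ)). Numerical choices:

* **T = 10** boosting rounds by default — the common toolkit default,
  and the regime in which a shortened questionnaire (≤ 10 splits, items
  reused) emerges. **ε = 1** smoothing in every ½ ln ratio guards empty
  partitions.
* Item scores are treated as ordinal numerics; candidate thresholds are
  midpoints between consecutive observed values of an item *within the
  records reaching the precondition* (so at most 0.5 and 1.5 on the 0–2
  scale).
* The search expands **all** existing prediction nodes as preconditions,
  not only the last-added path.
* Ties in Z break deterministically: lowest item id, then lowest
  threshold, then earliest-created node. Z values within a 1e−9 relative
  band are treated as tied, which makes the fitted model invariant to
  record order despite floating-point summation-order noise.
* A single-class training set yields a warning and a root-only model;
  boosting stops early if no node has a splittable item left.
* The exponential loss Σ exp(−yᵢF(xᵢ)) equals the total weight after each
  update and is recorded per iteration; it is non-increasing by
  construction of the node values.

Scoring sums every reached prediction node (parallel splitters under one
node all contribute). `classify_score` maps sign → label with score 0
classified non-spectrum (and always flagged); |score| is the confidence
and values below a configurable band (default 0.5, chosen so that a
score like 0.18 counts as low-confidence while typical well-classified
sheets score |F| ≫ 1) are flagged for further behavioural assessment.
Models serialise to JSON with repr-precision floats, so a round trip
reproduces scores bit-exactly.

The published seven-item subset (compsl5, conver5, play5, peerpl5,
gaze5, grplay5, ageabn) ships as a named constant for
questionnaire-shortening use; the original study never printed its tree's
thresholds or node values, so scoring models are always trained fresh.

## Baselines

DecisionStump exhaustively minimises training misclassifications over
(item, threshold, side-label) triples, with the constant majority stump in
the search space; OneR maps each observed value of each item to its
majority label and keeps the item with fewest errors. Ties break to the
lowest item id then threshold; a tied value-level majority resolves to
autism, since a screening instrument's false negatives are costlier than
its false positives. Both emit constant confidence 1 so the evaluation
layer treats all classifiers uniformly.

## Evaluation

Autism is the positive class. Cross-validation is a single stratified
k-fold (default k = 10) with seeded shuffling — with 891 cases vs 75
controls an unstratified split occasionally leaves a fold control-free,
which would corrupt the FPR; if a class has fewer than k members the
split falls back to unstratified with a warning. Each record is scored
exactly once by a model not trained on it, and pooled out-of-fold
predictions feed the confusion metrics. Undefined ratios (zero
denominator) are reported as NA, never coerced. Presentation rounding
mimics the field's reporting style: rates to 3 decimals, accuracies as
percentages. The comparison table appends externally computed
(FPR, TPR, accuracy) rows verbatim so published algorithm results can sit
beside in-package learners; the score-vs-age profile emits one row per
subject (age in years, signed score, labels, low-confidence flag) for
scatter plotting with any tool.

## Synthetic data

`generate_cohort` emulates the shape of the restricted repositories:

* **Sizes** 891 cases / 75 controls (the training repository's shape).
* **Planted signal**: the seven published items score 2 with probability
  0.9 in cases and 0.05 in controls, 0 otherwise. All other items share
  one background distribution P(0,1,2) = (0.55, 0.30, 0.15) in *both*
  classes, so non-planted items are label-independent up to the
  accept/reject step below. The background mean (0.6 per item) was chosen
  so that planted-plus-background domain totals clear the cutoffs for
  most case draws (predicted per-sheet rejection ≈30%) while controls
  almost always fail at least one domain (≈3%).
* **Constraint**: each case sheet is redrawn (bounded retries) until it
  satisfies, and each control until it fails, the diagnostic algorithm
  under the configured mapping — so generated labels agree with the
  independently implemented algorithm on every sheet.
* **Raw-code realism**: a recoded 2 is written as raw severity 3 with
  probability 0.1; every cell receives an exception code at rate 0.02;
  three designated items (outside the domains and the planted set) get
  exception codes at rate 0.7, exercising the majority-exception
  exclusion end to end.
* **Ages**: log-normal fitted to the target quartiles (cases
  6.44 / 8.06 / 10.84 years, controls 6.38 / 9.24 / 11.88) via the median
  and log-IQR, truncated to [5, 17) by resampling and stored as integer
  months. Truncation biases the quartiles by ≈0.3 y, within the ±0.75 y
  tolerance the tests assert. 80% of subjects are verbal.

`resample_controls` draws each item independently and uniformly with
replacement from the observed control pool's per-item multiset, so output
marginals match the pool; whole-row copying is available as a
sensitivity-analysis mode. `simulate_near_cutoff_controls` draws each
domain total uniformly from [max(0, cutoff−δ), cutoff−1] (δ = 3 by
default — "close to" is not quantified in the source analyses — and
configurable to stress specificity), allocates it across the domain's
items uniformly over all {0,1,2} compositions via exact
dynamic-programming counts, and fills non-domain items from a low
background. Sheets are verbal by default so the communication range is a
single interval. All generators are pure functions of (config, seed).

## What the synthetic cohort does and does not show

Passing tests on the planted cohort demonstrate that the pipeline
recovers a small informative subset, achieves near-perfect
cross-validated sensitivity under heavy class imbalance, and that the
simulators satisfy their stated constraints. Two deliberate departures
from real instrument data matter when interpreting results:

* Real ADI-R items are strongly inter-correlated (they probe related
  behaviours); synthetic items are independent given the class. After the
  planted signal separates the classes (by ~7 boosting rounds the
  exponential loss has fallen two orders of magnitude), the remaining
  rounds may latch onto chance correlations among the ~83 background
  items, so fitted trees often contain one or two non-planted items in
  their late splits. On correlated real data the residual signal stays
  inside the informative subset, which is why a fixed T = 10 can yield a
  tree of exactly seven distinct items there.
* Near-cutoff controls spread their domain totals uniformly across
  domain items *including* the planted ones, so roughly half of them
  present autism-like patterns on the few items a fresh synthetic-trained
  tree uses, and its specificity on this set (~0.5) is far below what a
  tree trained on real data shows on the analogous simulation. The set
  functions as a worst-case stress test of borderline phenotypes rather
  than a calibrated specificity estimate.

## Reported problem sizes

The acceptance script and tests run the full 966-subject cohort, 10-fold
cross-validation, 1000-sheet simulated-control sets (10 000 for the
uniformity check), and 20 generator seeds for the recovery sweep — the
sizes at which the statistical assertions (chi-square at α = 0.01,
quartile tolerances, ±3σ composition frequencies) are well calibrated.
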
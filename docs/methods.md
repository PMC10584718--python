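# Methods

`vowelmap` implements a two-arm pipeline for predicting how listeners of a
five-vowel language (Cypriot Greek, /i ε ɐ ɔ u/) perceive and discriminate
the twelve Dutch monophthongs, and for checking both arms against observed
AXB discrimination accuracy.  This note records the models, the defaults,
and the design choices that were genuinely open.

## The acoustic arm

**Speaker normalization.**  Raw formant measurements (F1–F3, Hz) are
z-scored within speaker (Lobanov normalization) using the sample SD
(n − 1), which removes vocal-tract-length differences while preserving
relative vowel positions.  Each speaker must contribute ≥ 2 tokens with
non-zero spread per formant; violations are hard errors naming the
speaker.  Duration (ms) is never normalized — only the three formants
carry speaker anatomy.

**Pseudo-Hz rescaling.**  z-scores are mapped back to a Hz-like scale by
`F = 250 + 500 · (z − z_min)/(z_max − z_min)`, with `z_min`/`z_max`
pooled per formant over the normalized dataset.  The constants live in
one place (`acoustics.RESCALE_OFFSET/RESCALE_SPAN`) so an alternative
scaling can be substituted without touching anything else.  Because each
formant is rescaled independently, the physical ordering F1 < F2 < F3
need not survive rescaling; the token validator therefore enforces that
ordering only for raw (`normalized=False`) tokens.  Applying a frozen
normalization state to new data can produce z values outside the stored
range; these are clamped with a warning rather than extrapolated.

**Acoustic similarity.**  Similarity between an L1 vowel and a Dutch
vowel is the Euclidean distance `d = √(Σ (xᵢ − yᵢ)²)` between inventory
mean vectors, by default in the F1 × F2 plane (the plane in which the
reference distances are defined); F3 and duration can be included via
the feature-set argument.  Distances are reported half-up-rounded to the
nearest integer for comparison with printed values, while the raw float
is retained internally.

**LDA classification.**  The classifier is a pooled-covariance Gaussian
("classical" LDA): per-category sample means, a pooled within-class
covariance `S = W/(n − k)`, and uniform priors over the five L1
categories (the training design is balanced: 12 speakers × 4 repetitions
per vowel).  Posteriors are the softmax of the linear discriminant
scores; classification is hard argmax, with ties broken by the canonical
category order (i, ε, ɐ, ɔ, u) and flagged.  The model consumes
token-level data, not inventory means — a 5-point training set would
leave a 4-feature covariance undefined.  Cross-validation is
leave-one-out: deterministic, and the convention of the classical
implementations of this analysis.  Tests cross-check predictions against
an explicit Gaussian-density Bayes oracle and against scikit-learn.

**Wilks'-lambda stepwise selection.**  Feature relevance is assessed by
pure forward selection on Wilks' Λ = det(W)/det(T).  At each step the
candidate minimizing the partial Λ enters if its F-to-enter
(`F = (df2/df1)·(1 − Λ_ratio)/Λ_ratio`, df1 = k − 1, df2 = n − k − p,
p = features already entered) is significant at α = 0.05.  Candidates
collinear with the selected set yield a singular scatter and are skipped;
no removal steps are performed.  The trace records Λ, F, p, and the LOO
accuracy of the model at every step.  On synthetic Cypriot Greek data F2
enters first — the five vowels are spread primarily along the
front–back/rounding axis — followed by F1; F3 and duration add little.

**From machine classification to UPM.**  Feeding Dutch tokens to the L1
model yields an "acoustic" confusion matrix that is analyzed exactly
like a listener confusion matrix (below).  For contrasts whose members
completely overlap under the full model, single-feature confusion
matrices (one per stepwise-entered feature) provide an escape hatch:
if the members separate on an individual measure, listeners attending to
that cue may still discriminate them, so the predicted tier is upgraded
from poor to moderate-to-good.  This mirrors the cue-weighting argument
the stepwise analysis exists to support.

## The perceptual arm (UPM)

The chance score is 1/k for k response categories (0.20 for the
five-vowel L1).  The above-chance threshold is **inclusive** (≥), and a
row's above-chance set is the set of categories meeting it.  Degrees:
complete (equal sets), partial (overlapping but unequal), none
(disjoint).  An empty set is reported as a distinct "uncategorized"
outcome rather than being forced into the lattice.

The **overlap score** sums, over every shared L1 category, the smaller
of the two members' classification percentages — including below-chance
cells, since the defining worked example (89/11 vs 37/59 → 48%) counts
the 11% cell.  It is symmetric, 100 iff the rows are identical, 0 iff
their supports are disjoint.

The **perceived-distance test** is a pooled-variance (Student) two-sample
t-test on goodness ratings (df = n₁ + n₂ − 2), restricted to trials in
which the shared above-chance category was chosen; when the members share
more than one category, the one with the largest min-proportion carries
the test.  Degenerate inputs: zero pooled variance with equal means is a
null result (t = 0); with unequal means it is reported significant with
an infinite-t sentinel and a warning.

**Tier prediction**: none → good; partial → moderate-to-good;
complete → poor, upgraded to moderate-to-good when the perceived-distance
test is significant (perceptual arm) or when a single-feature matrix
shows partial/no overlap (acoustic arm).  A complete-overlap contrast
without rating data is an error, not a silent "poor".

## Observed discrimination

AXB correctness is recomputed from configuration × response (the middle
letter of AAB/ABB/BBA/BAA identifies X); the log's own correctness column,
if any, is ignored.  Per contrast we report the pooled accuracy, the
per-listener accuracies, and a one-sample t-test of the per-listener
accuracies against the 0.5 chance level (df = n_listeners − 1) — the
per-listener convention is implied by the reference dfs (20 and 9).
Observed accuracy maps to tiers through configurable bands, default
poor ≤ 0.60 < moderate-to-good ≤ 0.80 < good; the cut points are exposed
because "moderate" is a reporting convention, not a theoretical constant
(67–71.3% is described as moderate, control-group ceiling performance as
good).  An arm "agrees" on a contrast when its predicted tier equals the
observed tier; accuracies within 0.02 of a band edge are flagged as
near-boundary.

## The synthetic-data generator

The generator emulates the study's data-generating assumptions so every
stage runs without recorded audio:

* **Tokens** — per vowel, independent Gaussians per feature with the
  published inventory means/SDs (5 CG vowels, 12 Dutch vowels; F1–F3 in
  normalized pseudo-Hz, duration in ms).  Sample sizes follow the study:
  CG 12 speakers × 4 repetitions (48/vowel, 240 total), Dutch
  20 speakers × 1 (240 total).  Draws violating F1 < F2 < F3 are redrawn
  (≤ 100 retries).  Features are generated independently — real formant
  data are correlated within vowel, so the synthetic covariance structure
  is optimistic; passing tests demonstrate the pipeline's correctness
  under the stated marginals, not robustness to real covariance.
  Likewise there are no true speaker effects: speakers are exchangeable
  labels, which makes Lobanov normalization a near no-op on synthetic
  data rather than the substantive correction it is on real recordings.
* **Classification responses** — 21 listeners × 12 vowels × 3
  repetitions; each trial's category is drawn from a per-stimulus
  confusion-probability row, and a goodness rating from a
  per-(stimulus, category) Gaussian (SD 1.0), rounded and clamped to
  1–5.  The /i/ and /ɪ/ rows are the published proportions; all other
  rows were pinned once so the full table jointly satisfies the published
  constraints (modal categories, which vowels are single- vs
  multi-category above chance, overlap scores 48/67/32 for
  /i–ɪ/, /ɔ–o/, /ø–y/, rating means 3.85/3.16 for the /ɛ–ʏ/ test).
  Rounding/clamping shrinks realized rating means slightly toward 3.
* **AXB trials** — per listener, 4 contrasts × 4 configurations × 4
  repetitions; correctness is Bernoulli at a per-contrast probability
  (experimental group inside the published 67–71.3% moderate band,
  control group 0.95), and the button response is derived from the
  configuration.

Randomness is split counter-style: every (vowel, speaker) or listener
unit gets `default_rng([seed, stream, index])`, so output is
byte-identical under a fixed seed and subsets are stable when sample
sizes change.

## Numerical choices

* Sample SDs (n − 1) throughout.
* Above-chance comparison uses a 1e-9 absolute tolerance so count-derived
  proportions at the boundary (e.g. 12/60 vs 0.20) behave inclusively.
* Argmax ties in classification are detected at 1e-9 score tolerance,
  broken by canonical category order, and flagged on the confusion row.
* Confusion rows validate to 1 within 1e-6; posteriors within 1e-9.
* Singular covariances (collinear features) are hard errors for training
  and silent skips for stepwise candidates.

## Problem sizes

Tests and the acceptance script run the study at its native sizes
(240 + 240 tokens, 756 classification trials, 1,344 + 640 AXB trials);
the cross-validation replication averages 20 independently seeded
training sets.  Monte-Carlo recovery tests scale listener counts up to a
few hundred where a tighter empirical tolerance is being checked.

## Known limitations

* The pinned pseudo-Hz map (250/500 with pooled z min/max) is one member
  of a family of published scalings; distances computed after rescaling
  depend on the choice, which is why reference distances are computed
  directly from the published summary tables.
* Whether rescaling ranges should be pooled over speakers jointly or per
  speaker is undetermined by the sources; pooled-jointly is implemented.
* The stepwise F-to-enter uses the single-root approximation appropriate
  for adding one variable; exact small-sample behaviour with many
  categories and few tokens is not guaranteed.
* The binomial logistic mixed-effects modelling and post-hoc group
  comparisons of the original analysis are out of scope; group contrasts
  are reported descriptively only.
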
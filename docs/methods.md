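# Methods

## Problem and data model

A pure-tone audiometry result for one ear is a pair of threshold curves in
dB HL over octave frequencies: air conduction (AC) at 125, 250, 500, 1000,
2000, 4000, 8000 Hz and bone conduction (BC) at 250–4000 Hz (the extremes
are not measured by bone).  125 Hz AC and 250 Hz BC are optional in
practice; a record is *complete* when AC is present at 250–8000 Hz and BC
at 500–4000 Hz.  Thresholds are stored exactly as read — absent points stay
absent, never imputed at the IO layer.

## Validity screening

Records are screened by five independent, pure checks before diagnostic
use: completeness; AC within −10..110 dB HL with a 90 dB ceiling at low
frequencies (audiometer output is limited there); adjacent-octave AC steps
within ±30 dB; BC within −10..60 dB HL with a 40 dB ceiling at 250 Hz; and
the signed per-frequency difference AC − BC within −10..50 dB (a gap above
50 dB exceeds what middle-ear pathology produces; bone more than 10 dB
worse than air is physically inconsistent beyond test–retest error).  All
bounds are inclusive.

Two of these rules are stated ambiguously in the audiology literature and
are therefore configuration options with documented defaults:

* whether the stricter AC/BC ceiling applies **at or below** 250 Hz
  (default) or above it.  The default follows instrument physics: maximum
  output is lower at low frequencies.
* whether the 30-dB octave-step rule is one-sided or **symmetric**
  (default).  A strictly one-sided reading (only rises within 0–30 dB
  allowed) would reject every rising audiogram and hence essentially every
  conductive loss, so the symmetric |Δ| ≤ 30 dB reading is the default;
  the bounds are exposed as a signed (lo, hi) pair.

## Diagnostic rule engine

Summaries per ear: air and bone PTA₄ (unrounded means over 0.5/1/2/4 kHz),
the air high-frequency mean over the grid octaves in 4–8 kHz (4000 and
8000 Hz), the bone high-frequency mean over the grid octaves in 4–6 kHz —
which on the standard bone grid is 4000 Hz alone, since 6000 Hz bone is
never measured — and the gap-presence predicate (≥ 10 dB at ≥ 3 of the four
frequencies, or ≥ 15 dB at one; inclusive).  The four class predicates
(table in the README) are mutually exclusive by construction; combinations
matched by no row (e.g. normal PTA with a large gap, or an air loss over a
normal bone curve without a gap) return `indeterminate` rather than being
forced into a class.  Expert-labelled clinical data has no such residual
category — human labellers resolve edge cases by judgement — so an
automatic engine must surface them explicitly; `indeterminate` records are
excluded from training.  All comparisons use unrounded means; there is no
rounding before cutoff comparison.

## Synthetic data generator

Clinical audiometry datasets are confidential, so experiments run on
synthetic audiograms.  The generator draws a bone-level curve
`base + slope·octave + N(0, 2.5 dB)` and a gap curve
`gap_base + N(0, 2 dB)` from class-specific priors (dB HL; dB/octave):

| class | bone base | slope | gap |
|---|---|---|---|
| normal | −5..12 | −1..2 | 0..7 |
| conductive | −5..12 | −1..2 | 15..40 |
| mixed | 25..50 | −1..4 | 15..40 |
| sensorineural | 25..58 | 0..5 | 0..7 |

AC = bone + gap and BC are quantised to 5-dB steps (clinical practice;
configurable down to 1 dB for boundary stress tests) and clipped to the
instrument limits.  The sensorineural slope prior is biased positive
because such losses typically worsen toward high frequencies.  Candidates
are rejection-sampled against the QC screen and the rule engine until the
intended label is produced exactly, so label correctness is guaranteed by
the oracle, not by the prior; acceptance rates are high (≫ 10%) and a
1000-attempt cap guards against misconfiguration.  Optional points are
included stochastically (125 Hz AC with p = 0.8, 250 Hz BC with p = 0.5).
Class membership is multinomial at configurable proportions; the default is
the class mix of a large clinical population, 2584/657/4028/7777 ears over
15,046 (≈ 17.17/4.37/26.77/51.69%).  One `numpy` generator seeded from the
config drives everything; no global random state.

What the generator does **not** emulate: patient age/sex structure,
measurement noise and test–retest variability, bilateral correlation
between ears, and audiogram shape families beyond base-plus-slope (notches,
corner audiograms).  Passing tests therefore demonstrate that the models
recover a deterministic labelling rule from rule-consistent curves — a
learnability and correctness statement about the pipeline, not a clinical
performance claim.

## Feature encoding and scaling

Each audiogram becomes a 7-step sequence ordered by the air grid, two
features per step (AC, BC) plus a bone-presence flag.  Absent bone values
stay NaN through scaling and are filled with 0 *after* normalisation (the
channel centre under z-scoring), so they never contaminate fitted
statistics; the flags are available as an optional third input channel
(default off, matching the two-feature design).  A missing optional 125 Hz
AC falls back to the 250 Hz value so the air channel is fully numeric.

Four scalers are implemented per channel (pooled fitting available):
z-score (population σ, ddof = 0), min–max, robust (median/IQR, quartiles by
linear interpolation) and max-abs.  Scalers are fitted per CV fold on the
training split only — fold-local fitting avoids train/test leakage.
Degenerate (constant) channels raise by default; a unit-scale fallback is
available.

Class imbalance is handled with loss weights w_c = N/(K·n_c) (K = 4), the
standard balanced heuristic, satisfying Σ n_c·w_c = N; custom weights can
be passed instead.

## Sequence classifiers

The proposed classifier is: bidirectional LSTM (64 units per direction,
first layer only) → dropout 0.2 → LSTM (32 units, last hidden state) →
dropout 0.2 → dense softmax over the four classes.  The initial variant
replaces the Bi-LSTM with a plain LSTM.  No deep-learning framework is
required: the network is implemented in numpy with explicit
backpropagation-through-time, verified against numerical gradients in the
test suite.

Training minimises class-weighted cross-entropy with Adam (lr 1e-3,
β = 0.9/0.999), mini-batches of 32, up to 150 epochs with early stopping
(patience 10) on the loss of a stratified 10% validation split, restoring
the best weights.  Layer sizes, dropout rates, optimiser settings, batch
size and epoch budget are conventional choices for a 7-step, 2-channel
sequence and are all exposed in `ModelConfig`.  Determinism: with a fixed
(data, config, seed) triple all stochastic elements — initialisation,
shuffling, dropout masks, the validation split — come from one seeded
generator, giving bit-identical predictions on one machine; across BLAS
builds results are statistically equivalent.  Argmax ties at prediction
resolve in the fixed class order (normal, conductive, mixed,
sensorineural).

## Decision-tree baseline

The comparison baseline is a C4.5-style gain-ratio tree over the flat
12-dimensional threshold vector (7 AC + 5 BC; an absent bone threshold
falls back to its paired air value, a zero-gap sentinel, configurable).
Splits are binary thresholds at midpoints of sorted distinct values,
chosen to maximise information gain divided by split information, with
splits of non-positive gain discarded; leaves take the majority label with
ties in fixed class order; minimum leaf size 2, unlimited depth.
Error-based (pessimistic) pruning is deliberately omitted — a `max_depth`
hook is provided instead — because on rule-consistent synthetic data
pruning mainly trades a little accuracy for size, which is irrelevant to
its role as a paired-comparison baseline.

## Evaluation protocol

Stratified K-fold CV (default K = 10): within each class, indices are
shuffled once (seeded) and dealt round-robin, so per-class fold counts
differ by ≤ 1.  Per fold, the scaler and class weights are fitted on the
training split, the model trained, and the held-out fold scored.  Per-class
one-vs-rest precision/recall/F1 use the conventions F1 = 0 when
precision + recall = 0; aggregates are support-weighted by default (macro
via config), and overall accuracy is trace/total.  CV summaries are
arithmetic mean ± population sd (ddof = 0); percentages print at 2 dp while
internal values stay unrounded.  Confusion matrices are pooled over folds
for single-matrix reporting.

Multiclass AUC is micro-averaged one-vs-rest: the four binary
(indicator, score) problems are pooled and AUC computed as the normalised
Mann–Whitney rank statistic with ties counting ½ (equal to trapezoidal ROC
integration; cross-checked against exhaustive pair counting and
scikit-learn in the tests).  Classifier pairs are compared with McNemar's
test on discordant errors, χ² = (|n01 − n10| − 1)²/(n01 + n10) with
continuity correction by default (the uncorrected variant is a flag); with
no discordant pairs the result is statistic 0, p = 1, flagged rather than
raised.

## Problem sizes

The shipped experiments generate 10,000 ears (≈ 8,000 train / 2,000 test
after a stratified 80/20 split) for the end-to-end runs, 131,072 grid
points for the rule-engine truth table, and 50,000 draws for the
law-of-large-numbers check on class proportions — sizes at which every
stochastic acceptance margin (3 binomial sd; the ≥ 98% held-out accuracy
bound) is comfortably resolved on a single CPU.

## Known limitations

* Synthetic curves are rule-consistent by construction; real audiograms
  contain measurement noise, vendor-specific quirks and shapes outside the
  parametric family, so reported accuracies do not transfer to clinical
  data.
* The rule engine implements the published criteria literally; expert
  labellers deviate from mechanical rule application in edge cases, and
  such disagreement is unobservable here.
* Severity grading, audiogram-shape configuration, inter-ear symmetry and
  image-based audiogram parsing are out of scope.
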
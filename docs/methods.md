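# Methods

## The model

`ldometa` treats orthology meta-prediction as binary classification over call
signatures. For a directed species pair (query species → target species), the
candidate pool is the union of all gene pairs predicted by K constituent
algorithms; each pooled pair carries the K-bit signature of who called it.
A linear decision rule

    raw(c) = w · x^c − b

is fit to the pairs that the reference LDO set can label: positives are pairs
present in the reference, negatives are pairs in which the query or the
target gene has a *different* reference partner. Pairs touching no reference
gene are unclassified; they are scored at prediction time but never trained
on. The rule is the soft-margin linear SVM (hinge loss, quadratic
regularization, unnormalized penalty C·Σ hinge), which makes the model a
weighted voting scheme: unit weights and zero offset reduce it exactly to the
vote count.

Assumptions worth stating explicitly:

- The reference set is *conservative but trustworthy*: its pairs are
  near-certainly true LDOs, but it misses many true LDOs. Training therefore
  learns a "reference-like" signature, and the interesting output is the
  high-scoring pairs *outside* the reference.
- Constituent calls are informative in aggregate even when individually noisy
  or mutually correlated; the SVM handles redundancy by down-weighting
  correlated inputs, which plain voting cannot.
- Gene identifiers are opaque strings shared across input files; any ID
  mapping happens upstream.

## Model selection and evaluation

The penalty C is chosen from the logarithmic grid {4⁻², 4⁻¹, 1, 4, 4²} by
nested cross-validation: an outer 10-fold split estimates generalization, and
within each outer training portion an inner 10-fold split picks the C with
the highest mean held-out accuracy (ties go to the smallest C, i.e. the
strongest regularization). Folds are built with two constraints taken
together: all pairs sharing a query gene land in one fold (a gene's
candidates are not independent), and per-fold class proportions track the
global proportions as closely as the grouping allows (validated at ±20%
relative tolerance; grouping makes exact stratification impossible).
Grouping is by query gene for the forward model and by target gene for the
reverse model — the only difference between the two directed models, since
the features themselves are direction-free. Precision, recall and F are
reported as mean ± SEM over the outer folds; every labeled pair receives
exactly one out-of-fold raw score.

Implementation notes: fits go through liblinear (hinge loss, dual coordinate
descent, tolerance 1e-6, fixed random state), with duplicate signature rows
collapsed into sample weights — an exact reformulation that speeds up the
~10³ fits of a nested CV by an order of magnitude. Features are left as raw
0/1 calls: standardizing them would destroy the voting-equivalence identity.
Class imbalance is handled only by stratified partitioning, matching the
method's design; `class_weight="balanced"` exists as an explicit opt-in.

## Confidence calibration

Raw scores are species-pair specific, so they are rescaled onto a common
[0, 1] confidence scale tied to classifier performance. For each
β ∈ {0.125, 0.25, 0.5, 1, 2, 4, 8}, the raw threshold T_β maximizing
F_β = (1+β²)PR/(β²P+R) (predicted = score ≥ T; ties broken toward the lower
threshold, favoring recall) is pinned to the confidence 1 − β/2 for β ≤ 1 and
1/(2β) for β ≥ 1 — i.e. 0.9375, 0.875, 0.75, 0.5, 0.25, 0.125, 0.0625 —
so that doubling β halves the remaining distance to the scale's edge and the
balanced-F threshold always sits at 0.5. Between anchors the map is the
monotone cubic Hermite interpolant with Fritsch–Carlson-type tangents
(scipy's PCHIP); outside the observed score range it clamps to 0/1, keeping
the probability-like semantics rather than extrapolating.

Three deliberate choices where the scheme needed completing:

- **Anchors come from out-of-fold scores.** Calibrating on training scores
  would be optimistic; the nested CV already produces an unbiased raw score
  for every labeled pair, and those are what the anchor search sees.
- **Degenerate anchors.** Heavily tied scores (vote counts especially) make
  several betas share one maximizing threshold. Tied anchors collapse to a
  single anchor at the mean of their confidences; any anchor still breaking
  strict joint monotonicity is dropped, scanning outward from the β = 1
  anchor. Fewer than two surviving anchors is an error — such a score set
  carries too little structure to calibrate.
- **Endpoints.** The minimum and maximum observed raw scores anchor
  confidences 0 and 1 (nudged outward by machine-epsilon scale on collision),
  making the scale exhaust [0, 1] over the observed score range.
- **Recall denominators.** Reference pairs that no constituent algorithm
  pooled cannot be scored, but they remain false negatives: they are counted
  in the recall denominator of the anchor search and of reported PR curves.

Each direction's raw scores pass through that direction's scaler, and the
final confidence of a pair is the arithmetic mean of the two scaled
directions (averaging on the calibrated scale keeps the 0.5 ↔ balanced-F
semantics; the vote score needs no averaging since the count is
direction-free).

## Call-set extraction

- Thresholding keeps pairs with confidence ≥ t (inclusive; default 0.5).
- A reciprocal best hit additionally requires the pair's confidence to be
  maximal among both genes' partners. "Maximal" compares confidences rounded
  to 6 decimals: genuine ties (identical signatures) are exactly equal and
  are all retained, while float noise cannot fabricate or break a tie.
- Overlap summaries report the fractions of the reference reproduced and of
  novel (reference-absent) calls, the method's headline quantities.

## The synthetic benchmark

The generator plants cross-species gene families (per-side family sizes
drawn from {1: 0.60, 2: 0.25, 3: 0.10, 4: 0.05}), designates at most one
true LDO pair per family (probability 0.9), and forms candidates from all
within-family cross pairs plus Poisson background pairs (rate 0.5 per
family). Algorithm k calls a candidate with probability
logistic(a_k + b_k·[true LDO] + 2.0·[same-family non-LDO] + z), where
z ~ N(0, latent_sd²) is shared across algorithms for a pair, inducing the
inter-algorithm correlation real databases show. The reference keeps 80% of
true LDOs and swaps 2% of its entries to a same-family partner, emulating a
conservative reference with rare errors.

The default "heterogeneous-17" regime uses K = 17, baseline call rates
logistic(a_k) spanning ≈0.001–0.05 and reliabilities b_k set so true-LDO
recall spans ≈0.3–0.95, with a fixed interleaving decoupling reliability from
call volume, latent_sd = 1, and 3000 genes per species (≈1900 families) —
sizes chosen so a full nested CV runs in seconds on one core while leaving
per-fold counts in the hundreds. On this regime the nested-CV SVM beats
voting on held-out max-F in 10/10 seeds and the learned weights rank the
algorithms by their planted discriminability (median Spearman ρ ≈ 0.97).

What the simulation does *not* emulate: real gene-family topology (it has no
shared ancestry across families), database-specific biases that correlate
with sequence properties rather than a generic latent, many-to-many reference
structures, and ID-mapping noise. Passing tests therefore demonstrate the
correctness and calibration of the machinery under the method's stated
assumptions, not performance figures transferable to any specific species
pair.

## Numerical and degenerate-input conventions

- Precision (recall) is defined as 0 when its denominator is 0; F_β is 0
  when P = R = 0. Threshold scans then stay well defined on all-negative
  prediction sets.
- PR curves place one point per distinct score; recall is non-increasing in
  the threshold by construction.
- The Jaccard agreement of two empty prediction sets, a zero-variance weight
  vector in a Pearson correlation, a non-one-to-one reference, and a
  single-class training set are all errors, not silent defaults.
- All randomness flows from explicit integer seeds (NumPy Generator or
  scikit-learn random_state); identical inputs and seed give byte-identical
  artifacts, which the test suite asserts end to end.

## Known limitations

- The linear kernel is a design commitment (the decision rule *is* the
  published weighted-voting form); nonlinear kernels and probability
  calibration (Platt, isotonic) are out of scope.
- Scores deployed on unclassified pairs come from a single production model
  per direction (C re-selected by one full 10-fold CV on all labeled data,
  refit on all of it) while anchors come from out-of-fold scores; a
  fold-ensemble average would be an alternative with slightly different
  variance properties.
- Intercept handling follows liblinear's convention of regularizing the
  offset; on the near-separable pools this package targets, the effect on
  the decision boundary is below the solver tolerance's practical impact.
- One species pair per run; multi-species matrices are loops over runs.
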
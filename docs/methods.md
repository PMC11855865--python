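# Methods

## Problem

`ehrisk` models the 3-month risk of psychosis onset (or first antipsychotic
order) in patients already diagnosed with Alzheimer's disease, from
longitudinal EHR streams, and then asks the interpretive question: which
diagnoses, medications and abnormal lab results move that risk, and in
which direction? The answer is a perturbation-based *relative contribution*
(RC) per feature, with RC > 1 read as risk-associated and RC < 1 as
protective, plus a drug→protein-target layer that supports repurposing-style
questions at the target level.

## Cohort definition

A patient's timeline is a dated stream of `(code_type, code)` events.
Cohort rules:

* **Index date** — the anchor encounter. Inputs come from the half-open
  look-back `[index − 365 d, index)`; the outcome is sought in
  `(index, index + 90 d]`. Events on the index date belong to neither
  window, so the anchoring encounter cannot leak its own label. "Three
  months" is fixed at 90 days and "one year" at 365 days; calendar-month
  arithmetic was rejected as ambiguous and untestable.
* **Case** — the latest encounter that follows an AD diagnosis, has a full
  year of record behind it, has no psychosis/antipsychotic event on or
  before it, and is followed by the patient's first such outcome event
  within 90 days.
* **Control** — the latest encounter satisfying the same inclusion rules
  with no outcome in the 90-day window. A patient whose outcome falls more
  than 90 days after every eligible encounter is a control at their latest
  eligible encounter.
* **Exclusions** are machine-readable: `NO_AD`, `INSUFFICIENT_HISTORY`,
  `PRIOR_PSYCHOSIS`, `PRIOR_ANTIPSYCHOTIC`, `NO_ELIGIBLE_ENCOUNTER`.
* **Delirium masking** — psychosis diagnoses sharing a calendar day with a
  delirium diagnosis are removed before labeling (transient
  delirium-driven psychosis is not the outcome of interest). Only
  exact-date co-occurrence masks; a next-day psychosis survives.
* **Augmentation** — each case may contribute additional samples anchored
  at distinct earlier encounters that independently satisfy every case
  criterion, capped per case, taken latest-first (closest to the outcome).
  No events are fabricated and controls are never augmented. Splitting is
  by patient (8:1:1), so augmented copies can never straddle a split.

## Encoding

Tokens are `(code_type, code)` pairs. Abnormal labs are binary flags keyed
by test ID (normal results are not tokens); labs are capped to the top 89
most frequent by patient count; diagnoses may be collapsed to 3-character
ICD-10 groups through an ICD-9→ICD-10 lookup; the overall vocabulary is
capped at 30,000 with index 0 reserved for out-of-vocabulary tokens, which
are kept as a shared token rather than dropped so visit structure is
preserved. The vocabulary is built from training-split patients only.
A sample encodes as one element per encounter date — a deduplicated index
set plus the integer day gap to the previous encounter.

## Models

Four families share one training/evaluation contract:

* **LR** — scikit-learn logistic regression on the binary
  presence-of-code bag. Order- and time-blind by construction.
* **RNN** — stacked tanh recurrent network over visit embeddings.
* **TLSTM** — LSTM whose long-term memory is discounted before each step
  by `g(Δt) = 1/log(e + Δt)` of the elapsed days; `g(0) = 1`, strictly
  decreasing, always positive. The memory decomposition weights start at
  zero (the cell begins as a plain LSTM and learns what should decay) and
  the forget-gate bias starts at +1, both standard retention-friendly
  initialisations.
* **RETAIN** — two-level attention: visit-level α (softmax over visits)
  and dimension-level β (tanh), both produced by recurrent networks run in
  reverse time; the context vector Σ αᵢ βᵢ ⊙ vᵢ feeds a linear head.
  Contribution analysis still uses perturbation, not RETAIN's native
  attention weights, so all model families are attributed identically.

The neural models run on a small reverse-mode autodiff engine written for
this package (NumPy arrays, dynamic tape, finite-difference-verified);
training is Adam with decoupled (AdamW-style) weight decay, binary
cross-entropy on logits, dropout on the embedding layer, and early
stopping on validation AUROC with a patience of 3 by default, restoring
the best-validation weights. Weight decay (default 1e-2) matters: at
desk-scale n the sequence models otherwise memorise the training split and
downstream attributions inherit the fit noise. The classification
threshold for precision/recall/F1 is the max-F1 point on the validation
split, frozen before the test split is touched. Defaults follow common
EHR practice (embedding 128, hidden 128, dropout 0.2, two layers,
vocabulary cap 30,000); the bundled studies use smaller dimensions, noted
below.

## Feature contributions and RC

* **Occlusion FC** — the contribution of one token occurrence is
  `p(full sequence) − p(sequence with that single occurrence removed)`,
  each occurrence occluded independently from the intact sequence; a
  patient's FC for a feature is the sum over its occurrences. Under a
  logistic bag model a single occurrence gives exactly σ(z) − σ(z−w).
  Because the LR featurizer is presence-based, removing one of several
  occurrences leaves its bag unchanged — a duplicate occurrence
  contributes 0 under LR; sequence models see every occurrence.
* **Normalization** — each patient's FCs are divided by the patient's
  total |FC|, so Σ|normalized FC| = 1 per patient. This is the
  visit-frequency scaling: heavily-utilising patients otherwise dominate
  the group statistics. All-zero patients keep zeros and are flagged.
* **RC** — `median(FC | event patients) / median(FC | non-event
  patients)`. Medians, not means: FC distributions are heavy-tailed.
  Both group vectors are taken over *all* patients in the analyzed cohort,
  with unexposed patients entering as exact zeros — differential exposure
  between events and non-events is part of the association being measured,
  and balanced positive/negative planted effects are provably invisible to
  exposed-only medians. A zero non-event median leaves RC undefined
  (`UNDEFINED` flag, never a silent drop); a negative ratio is flagged
  `INDETERMINATE_SIGN`.
* **Significance** — two-sided Wilcoxon rank-sum on the same two vectors
  (exact enumeration when n ≤ 12 and tie-free, tie-corrected normal
  approximation otherwise), Benjamini–Hochberg FDR at 0.05 as the
  reporting cutoff, Bonferroni reported alongside. The multiplicity family
  is the set of features tested in one analysis run; drug-level and
  target-level analyses are corrected separately. Features with fewer than
  `min_support` (default 10) exposed patients in either group are reported
  as skipped.
* **Cross-fitting** — contributions are computed by models that never saw
  the scored patient: patients are split into folds and each fold is
  scored by models trained on the others, optionally ensembled over
  several initialisations per fold. Perturbing a model on its own training
  patients leaks fit noise into the FC signs (the sign tracks the training
  label), which at n ≈ 2000 inflated the null false-flag rate an order of
  magnitude; cross-fitting restores nominal calibration. On very large
  cohorts this bias shrinks and single-model attribution becomes
  acceptable, but cross-fitting is the package default.

## Drug→target layer

Two complementary analyses, selected by `--method {drug,target}`:

* **Drug-focused** — contributions are computed on drug tokens; per-patient
  drug FCs are then summed onto each protein whose drugs the patient was
  exposed to. Additive pooling is the only aggregation that makes a
  one-to-one drug↔target map an exact identity (pooled RCs equal drug
  RCs bit-for-bit), which the tests assert.
* **Target-focused** — mapped medication tokens are replaced by their
  protein-target token sets *before* vocabulary construction, pooling
  patients across drugs that share a target and raising per-feature
  support; unmapped drugs pass through. Direction of modulation
  (agonist/antagonist) is deliberately ignored.

## Synthetic cohorts

The generator emulates the shape of a de-identified EMR extract: per
patient, a Poisson number of encounter dates (floor 2, spread over an
observation period of 540 days by default, always spanning the look-back),
per-visit independent code draws at configurable prevalences, an AD
diagnosis planted at the first encounter, and a binary outcome drawn from
a logistic model over the codes present in the one-year look-back before
the patient's latest eligible encounter. Cases get a psychosis-diagnosis
or antipsychotic-order event appended uniformly within the 90-day window,
so the cohort rules can re-derive every label from the stream alone.
Exposure is presence-based (a code counts once however often it occurs),
matching the binary token view the models consume. An optional
order-effect term adds to the logit when one code's first occurrence
precedes another's — the only mechanism here that sequence models can see
and a presence bag cannot.

Anchoring the outcome draw at the *latest* eligible encounter (rather than
a random one) makes the generative look-back window coincide with the
window the cohort builder extracts, so the planted logistic model is
exactly the model a perfect learner could recover. With a random anchor
the two windows differ by up to the outcome delay and every learner is
attenuated by exposure misclassification.

What the generator does not emulate: real ICD semantics, lab values
(only abnormal flags), visit-type structure, demographic confounding,
code co-occurrence correlations, or time-varying prevalence. Passing the
bundled studies therefore demonstrates the statistical machinery under a
known data-generating process, not clinical performance.

## Bundled studies (problem sizes and conditions)

All studies run on one CPU; conditions were fixed once, as follows:

* **Planted-effect recovery** — n = 2000 patients, 30 codes at per-visit
  prevalence 0.17 (≈70% look-back exposure, which keeps group medians off
  the zero block), three codes at β = +1, three at β = −1, baseline logit
  −1.1 (≈30% case share, the case-enriched regime typical of risk-model
  development cohorts). Scoring model: RETAIN, embedding/hidden 16,
  dropout 0.2, lr 3e-3, weight decay 3e-2, 3-fold cross-fit, 3-model
  ensembles.
* **Null calibration** — 20 cohorts of n = 1000 with all β = 0; pooled
  fraction of q ≤ 0.05 flags compared to 0.05 + 3 MC standard errors.
* **Strong-effect discrimination** — n = 5000, 60 codes all carrying
  |β| = 2 at prevalence 0.25 with ~6 visits/patient; TLSTM (dim 64,
  lr 1e-3) and RETAIN (dim 48, lr 3e-3) against the 0.85 AUROC bar. Dense
  moderate-dimensional signal is the regime where attention/recurrent
  pooling approaches the presence-bag optimum.
* **Order-signal gap** — outcome driven by which of two common codes
  appears first (β_order = 2); LR is blind to it by construction.
* **Ablation ordering** — diagnosis codes carry 70% of planted |β| mass;
  the no-diagnosis ablation should cost the most AUROC.
* **Pooling power** — ten drugs, each in ~20 of 600 patients, all β = +1,
  all mapping to one protein; target-level detection power versus the best
  single-drug test over 10 replicates (min_support lowered to 3 so the
  rare single-drug tests are run rather than skipped, keeping the
  comparison fair).

## Numerical and degenerate-input choices

Sigmoid and binary cross-entropy are computed in numerically stable forms;
the attention softmax subtracts the running maximum. Empty sequences
predict the training base rate under the neural models and σ(intercept)
under LR. Vocabulary ties break lexicographically; report ties break by
feature name; same-day ties between outcome and index candidate exclude
that candidate (the outcome must be strictly after the index date). Seeds
flow from a single declared integer through `numpy.random.SeedSequence`
spawns, so per-patient streams are reproducible byte-for-byte.

## Known limitations

The models are desk-scale NumPy implementations — faithful in form but not
tuned for GPU-scale data. RC is an association measure computed on model
attributions: it inherits model misspecification and does not adjust for
confounding by indication. Medians over cohorts with <50% feature exposure
leave RC undefined by construction. The LR occlusion semantics
(presence-based) zero out duplicate occurrences; count-based featurization
was rejected to keep the bag invariant under visit duplication.
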
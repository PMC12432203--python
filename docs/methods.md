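# Methods

`flustim` implements an analysis pipeline for verbal- and figural-fluency
behavior collected under repetitive transcranial magnetic stimulation
(rTMS), together with a synthetic-study generator that makes every stage
testable against known ground truth. This note documents the models, the
numerical choices, and what the synthetic data do and do not emulate.

## Automated clustering and switching

A semantic-fluency sequence (all responses a participant produced for one
category) is segmented using word embeddings:

1. Every response token is mapped to a vector from a word2vec-text store
   (`embeddings`). Multiword tokens use the unweighted mean of their
   in-vocabulary constituents. Out-of-vocabulary tokens are, by default,
   spliced out of the similarity chain with a logged warning (`skip`
   policy); an `error` policy aborts instead. Vectors are stored exactly as
   read — cosine similarity is scale-invariant, and not normalising
   preserves file round-trip fidelity.
2. The *switch threshold* of a category is the median cosine similarity
   over all unordered pairs of distinct words in the category's pool. By
   default the pool is the set of distinct correct, non-repeated responses
   produced for that category across the whole dataset; an external norm
   list can be substituted via configuration.
3. Walking consecutive resolvable tokens, a pair whose similarity falls
   *strictly below* the threshold opens a new cluster (one switch). A
   similarity exactly equal to the threshold stays inside the cluster, and
   identical vectors compare as exactly 1, so repeating a word can never
   create a switch. A *cluster* is a maximal run of two or more consecutive
   tokens with no internal switch; singleton runs belong to no cluster.

Only correct, non-repeated responses enter the similarity chain by default
(configurable): repetitions and intrusions are scored incorrect during
preprocessing, and treating them as forced switches would conflate error
rates with strategy. The module is fully deterministic.

## Preprocessing

Reaction times are task-specific: semantic fluency uses the inter-response
interval (onset of item *i* minus offset of item *i−1*; the first item has
no RT), figural fluency the time from blank-arrangement presentation to the
button press, picture naming the time from picture onset to naming onset.
Within each participant × session × task × item group, RTs at least three
*sample* SDs (n−1 denominator) above the group mean are removed in a single
pass — one-sided, no re-iteration; groups of fewer than three RTs pass
through untouched because an SD on so few points is unstable. For a
standard-normal group of size 90 this trims about 0.10% of rows (the
asymptotic 0.13% is approached from below at finite n).

Accuracy coding: in semantic fluency, the second and later occurrences of a
normalized response (case-folded, whitespace-trimmed; morphological
variants are *not* merged) are incorrect, as are responses outside an
optional category-membership list or on a proper-name list. In figural
fluency a design is a set of bars (unordered dot pairs); a bar-set
identical to an earlier one within the same arrangement is incorrect.

The executive composite inverts Trail-Making-Test seconds (so larger =
better), z-standardizes TMT and Digit-Symbol counts against the analysis
cohort (sample SD), and averages the two z-scores per participant.
Following the composite's definition as a plain mean, it is *not*
re-standardized afterwards, so its variance is 1 only when the two tests
correlate perfectly. Spot-the-Word is z-standardized separately.

## Condition-effect models

All factors are *simple-coded*: level *j*'s contrast column carries
(k−1)/k on level *j* and −1/k elsewhere, so each coefficient estimates
level *j* minus the reference (sham stimulation; session 1) while the
intercept stays at the grand mean over levels. Three families cover the
outcomes:

* **log RT** — Gaussian linear mixed model on natural-log RTs of correct
  trials, participant random intercept (statsmodels MixedLM, REML).
* **binary accuracy** — logistic regression with a participant random
  intercept, fitted by maximizing the marginal likelihood with 15-point
  Gauss–Hermite quadrature and L-BFGS-B; odds ratios are exp(coefficients).
* **counts** (switches, correct items) — negative-binomial (NB2,
  variance μ + αμ²) regression with log link and participant random
  intercept, same quadrature machinery; incidence-rate ratios are
  exp(coefficients). α → 0 recovers the Poisson limit (the optimizer is
  bounded at α = 10⁻⁸).

Crossed category/stimulus random intercepts are *not* fitted: category
indicators are exactly aliased with the category-difficulty regressor, so
the category variance is deliberately left to the dispersion/residual term.
The omission is declared in `FitResult.metadata`; in the balanced designs
generated here it does not bias the condition contrasts (verified by the
recovery studies below). By-participant random slopes are likewise out of
the default models. Confidence intervals are Wald on the link scale, so
exponentiating the CI endpoints gives the IRR/OR intervals exactly.
Standard errors come from the inverse observed information (numerically
differentiated at the optimum); when a variance parameter sits on its
bound, the fixed-effect block is pseudo-inverted and degenerate terms
surface as NaN p-values rather than fabricated ones.

The condition-contrast family is, by default, the three active-vs-sham
comparisons; pairs among active conditions form a separate post-hoc family.
Each family is Benjamini–Hochberg adjusted (step-up, capped at 1, input
order preserved). No stepwise model selection is performed: the configured
model is fitted as-is.

## E-field dose–response

The pipeline consumes per-participant 95th-percentile e-field summaries
(V/m) per stimulation target as data; it never computes fields from
anatomy. Each target's field in its own stimulation session is Pearson-
correlated (two-sided; a rank option exists) with every participant-level
behavior summary of that session (mean RT and accuracy per task); the BH
family is all associations computed in a run. For the dual-site session an
OLS regression uses both targets' fields as predictors; coefficients are
standardized post hoc as β·SD(x)/SD(y), which equals Pearson's r in the
single-predictor case and is invariant to affine rescaling of any variable.
Associations with constant inputs are flagged undefined and excluded from
the family. Predictors correlated beyond |r| = 0.999 are rejected as
collinear.

## Synthetic studies

The generator emulates a four-session within-subject design: 24
participants × 4 conditions (sham, IFG, preSMA, dual; order randomly
permuted per participant), 6 semantic categories per session (3 easy, 3
difficult, 90 s each), 3 figural dot arrangements per session (≤ 40
designs, 3.5 min), and 99 named pictures (2.5 s each).

*Lexicons.* Each category has 4 subclusters × 8 words in a 32-dimensional
embedding. Subcluster centroids are built with exact pairwise cosine
(Cholesky of the target Gram matrix on a random orthonormal frame) and word
noise is drawn orthogonal to the centroid span, so empirical within- and
between-subcluster similarities concentrate within ±0.05 of their targets
(defaults 0.9 / 0.1, re-tuned internally and re-checked).

*Sequences.* Items accrue lognormally in time until the 90-s window closes.
The planted switch count is NB2-distributed with rate = base rate (12) ×
condition multiplier × difficulty multiplier (0.60) ×
exp(participant + category intercepts), clipped to what the sequence length
and subcluster capacity admit; run lengths are composed uniformly at random
subject to those caps, and each run draws from a different subcluster than
its predecessor, without word replacement. Repetitions (3%) and
out-of-category intrusions (2%) are injected as extra tokens; they are what
the accuracy coder is expected to catch and do not disturb the planted
boundaries of the correct-token chain.

*Effect sizes.* Defaults are the point estimates this design reports:
semantic log-RT shifts 0.09/0.12/0.11 (IFG/preSMA/dual), switch-rate
multipliers 0.93/0.90/0.87, figural-accuracy odds 1.17/0.96/0.79, figural
log-RT shift 0.04 (the dual value is unreported and set to 0.04 as well),
difficulty effects +0.48 log-RT and ×0.60 on switch rates. Participant
intercept SDs default to 0.15 (log RT), 0.30 (switch rate), 0.40
(accuracy logits); NB dispersion α = 0.15. E-fields are Normal(90, 15) V/m
for IFG and Normal(85, 15) for preSMA, truncated at zero, with semantic
log RT coupled to the IFG field (0.01 log-units per V/m in the IFG session)
and figural accuracy to the preSMA field in the dual session (−0.02 logits
per V/m).

What the generator does *not* emulate: real lexical statistics (tokens are
synthetic labels), acoustic microstructure of speech, learning curves
beyond a fixed figural session trend, rater disagreement, or anatomy/coil
physics. Passing tests therefore demonstrate that the algorithms recover
what they claim under the stated statistical structure — not that a
particular empirical dataset will show particular effects.

## Validation studies

`flustim.validation` packages the recurring simulation studies; the
reproduction script and the acceptance tests call them at these sizes,
chosen so the full battery completes in a few minutes:

* oracle equivalence of switch counting (1,000 random sequences),
  category thresholds (200 pools) and BH-FDR (500 p-vectors) — exact;
* planted-cluster recovery on well-separated lexicons with the threshold
  calibrated between the similarity bands (0.5) — ≥ 99% of 1,000 sequences;
* switch-rate multiplier 0.85 recovered by the NB mixed model within
  [0.75, 0.95] over 200 replicates at the full design size;
* +0.10 log-RT shift recovered within ±0.03 over 100 replicates of the
  complete preprocess → trim → mixed-model path;
* null calibration of the BH-corrected active-vs-sham family ≤ 0.07
  rejection over 1,000 replicates at a reduced design (8 participants,
  2 categories, 45-s windows — calibration does not depend on size);
* e-field coupling slope recovered within ±10% over 500 replicates at
  n = 24, and the uncoupled target's dual-site coefficient within 2 SE of
  zero in ≥ 93% of replicates.

## Known limitations

* The GLMM fitter covers exactly one random-intercept factor; it is not a
  general mixed-model engine.
* The quadrature likelihood is non-adaptive; with very large intercept SDs
  (σ ≳ 3 on the link scale) more nodes would be needed.
* The median-similarity threshold is lenient by construction (it sits in
  the between-subcluster similarity band), so absolute detected switch
  counts undercount planted transitions; condition *ratios* are preserved,
  which is what the count model estimates.
* Proper-name detection is list-based only; morphological variants are not
  merged during repetition detection.
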
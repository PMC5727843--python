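# Methods

This note documents the model as implemented, the choices made where
the design was genuinely open, and what the synthetic experiments do
and do not establish.

## The diagnostic model

A subject carries up to four blocks of observations — facial landmark
geometry, body-shape measurements, sentence voice features and
questionnaire responses — plus sex, age and an expert-assigned
constitutional label (TE, SE or SY; the rare TY type is excluded
before modeling, as are subjects under 15 and records flagged as
extraction errors). Male and female subjects run through entirely
separate pipelines, since every reported result is sex-stratified.

For each sex the pipeline is:

1. **Common samples.** The integrated model is fit and evaluated only
   on subjects carrying all four blocks.
2. **Split.** A random 7:3 train/test partition stratified by type ×
   age decade (floor(floor/decade), ages 60+ pooled); per-stratum train
   counts are floor(0.7·n) with largest-remainder correction so the
   overall fraction is exact, and singleton strata go to train.
3. **Age compensation.** Each continuous feature is replaced by
   (x − m(age)) / s(age), with m and s moving statistics over same-sex
   training subjects within ±5 years (window widened symmetrically
   until ≥30 subjects). m is a local linear estimate (the feature
   regressed on age within the window, evaluated at the window
   center) rather than a plain window mean — a plain mean is biased at
   the age range's edges, which re-introduces an age correlation; s is
   the within-window residual SD, floored at 1e-8 so exactly
   deterministic features stay finite. Fitting on training subjects
   only avoids leakage; refitting on already-normalized data is a
   near-identity (checked to 0.05 at n = 5000).
4. **Component models.** Per modality, three one-vs-rest fits of the
   0/1 type indicator minimizing
   `(1/2W) Σ v_i (y_i − b0 − x_i β)² + λ‖β‖₁`
   with class weights v_i = N/(3·N_j) (each type gets total mass N/3;
   mean weight exactly 1). Features are standardized to weighted mean
   0 / SD 1 on the training data inside the fit; returned coefficients
   are mapped back to the original scale. λ runs over 100 log-spaced
   values from λ_max (smallest penalty zeroing all slopes) down to
   10⁻³·λ_max and is chosen by 10-fold CV, folds stratified by type,
   minimizing weighted MSE; ties resolve to the larger λ. Squared
   error on the indicator (not logistic loss) is deliberate: the CV
   risk is MSE, so π_ij is an uncalibrated linear score. That is
   harmless downstream — argmax classification is invariant to the
   affine scale the stacking stage absorbs — and a softmax view exists
   for reporting only. The quadratic solver is scikit-learn coordinate
   descent after sqrt-weight row scaling; the test suite pins it
   against soft-threshold and weighted normal-equations closed forms
   (1e-8) and an independent proximal-gradient solver (1e-6).
5. **Questionnaire path.** Answers are one-hot indicators per
   (question, category); unanswered questions are all-zero blocks, not
   imputed. Per-type L1 models on the indicators yield three
   continuous scores (their linear predictors — the natural reading of
   "continuous variables calculated by sparse regression"); the
   questionnaire component is then a weighted OLS of each indicator on
   those three scores, penalty-free because three well-conditioned
   regressors need no shrinkage. All-constant scores (intercept-only
   upstream models) are tolerated and predict the weighted class mass;
   non-constant but collinear scores raise, since they signal a
   degenerate L1 path.
6. **Integration.** For each type j, the same weighted-L1-with-CV
   machinery regresses the type-j indicator on the four modality
   scores (π_ij)_r, giving stacking weights w_jr and intercept b_j.
   The intercept is included although the pure weighted-sum form has
   none: the component scores have arbitrary offsets; a config flag
   restores the literal no-intercept form, and another admits all 12
   π columns per type (default off, matching the published equation).
   The earlier fixed-weight variant (one shared w_r per modality,
   user-supplied) is available for A/B comparison.
7. **Diagnosis and cutoff.** Predicted type = argmax of the three
   TSCOREs, ties broken in fixed TE < SE < SY order (logged). The
   typicality margin is top minus second TSCORE; subjects with margin
   < τ are flagged atypical. τ is not dictated by the model; the
   default is 0.1 with a sweep utility reporting retained-fraction vs
   accuracy curves. The cutoff is applied to raw TSCOREs rather than
   simplex-renormalized probabilities; under renormalization the two
   differ only by a monotone map, so the retained-set ordering is
   unchanged.
8. **Evaluation.** 3×3 confusion matrices (rows true, columns
   predicted), per-type sensitivity = diagonal/row total and accuracy
   = trace/grand total, both as percentages rounded half-up at one
   decimal in exact decimal arithmetic — the convention that
   reproduces every published cell from its raw counts, which ship as
   a JSON regression fixture.

## Feature grammar conventions

Landmark coordinates are in the image frame (x right, y down, pixels);
"horizontal"/"vertical" distances are |Δx|/|Δy|, which cancels in all
ratio features. Angles are reported in degrees; two-point angles are
the acute angle of the line against the horizontal. The suffixed
variants are implemented as configurable conventions since the source
vocabulary never defines them: `s` = signed angle in (−90°, 90°] with
the line oriented Δx ≥ 0, `i` = left-right mirrored direction (which
negates the signed and preserves the unsigned angle), `is` = both. The
parsed expression stores the flags, so a different convention swaps in
without re-parsing. `PDL_a_b_c` is read as the perpendicular distance
from point a to the line b–c — the only reading consistent with three
point arguments. The named areas `FArea02`/`FArea03` are polygon
features whose point lists are not part of the printed vocabulary;
shipped defaults are lower-face contour polygons (YAML, user-
overridable), evaluated by the shoelace rule. Degenerate geometry
(coincident points, zero-length angle arms) raises rather than
returning 0.

## Voice conventions

The reference analysis window is 2¹¹ samples at 44.1 kHz (46.4 ms).
Pitch percentiles interpolate linearly between order statistics; sFHL
is NaN when the lower half-spread vanishes (flagged, and backfilled
from the other utterance when averaging the two). HNR is the
normalized-autocorrelation form: the peak r near the pitch lag
(searched within ±20% of the nominal period, parabolic refinement)
gives 10·log₁₀(r/(1−r)) dB, capped at ±60 dB. CPP uses a Hamming
window, dB log-magnitude spectrum with a relative (−160 dB) floor,
real cepstrum, peak searched in the 60–500 Hz quefrency band, minus a
line regressed on the cepstrum from 1 ms to the band's upper edge.
MFCCs use a 26-filter triangular mel bank over 0–Nyquist and an
orthonormal DCT-II, keeping coefficients 1–12 so the vector is exactly
gain-invariant. Only sentence utterances are analyzed; vowel features
are out of scope. How the original extractor delimited sDT is not
documented; here it is the span from first to last voiced frame.

## The synthetic cohort generator

The generator produces the statistical shape the pipeline was built
for, with known ground truth; it claims no anatomical or phonetic
realism. Defaults (chosen once, all overridable):

- n = 2000 subjects, 35% male, type proportions 0.40/0.27/0.33
  (TE/SE/SY) — deliberately unbalanced so the class weighting is
  meaningfully exercised; ages 15–79 with a decade mix weighted toward
  older adults.
- Continuous blocks (face 60, body 40, voice 21 features): unit-SD
  noise equicorrelated at ρ = 0.7 within blocks of 4 features — the
  multicollinearity that motivates the L1 penalty. The first 10
  features are informative: each correlated block gets one random
  assignment of (−e/2, 0, +e/2) to the three types, e = 1.5 SD.
  Assigning shifts per block (a region moves as a unit) rather than
  per feature matters: independent per-feature patterns inside a
  correlated block would let a linear model cancel the shared noise
  and saturate single-modality accuracy at 100%, which is not the
  regime of interest. With block-level shifts, single modalities reach
  ~75–80% held-out accuracy and stacking them ~95–99%.
- Per-feature age slopes (SD 0.3 per standardized age) and sex offsets
  (SD 0.2), removed downstream by the per-sex age normalization.
- Questionnaire: 15 questions with 2–5 categories; 8 informative
  questions get class-tilted category logits (scale 1.0).
- Missingness: 10% (face, voice) and 5% (body, questionnaire) of
  subjects lack the block, so the common-sample intersection is real.
- Raw-input generators: landmark sets are the canonical template face
  deformed by a class-dependent frontal width factor (TE 1.05,
  SE 0.97) plus coordinate noise, and voice subjects get pitch tracks
  with a programmed 20 Hz SE−TE mean-pitch gap plus optional
  harmonic-plus-noise frames at a programmed HNR — these exercise the
  feature extractors end to end.
- Every stream derives from one master seed (split via SeedSequence);
  identical seeds give bit-identical cohorts.

What passing the synthetic suite shows: the pipeline recovers
programmed structure (directional effects, informative supports),
integration beats any single modality when the blocks carry partly
independent signal, null cohorts stay at chance, and the typicality
cutoff trades coverage for accuracy. What it does not show: clinical
accuracy on real constitutional data, which depends on effect sizes,
feature distributions and label noise the generator does not attempt
to reproduce.

## Numerical and bookkeeping details

- Coordinate-descent tolerance 1e-9 (well inside the 1e-7 max-change
  contract), max 200k iterations; λ = 0 solves weighted normal
  equations exactly (minimum-norm on rank deficiency).
- Weighted SDs in standardization are floored at 1e-8; constant
  questionnaire indicator columns are dropped with a log entry.
- CV at small n reduces the fold count to the smallest stratum size
  (with a warning) rather than failing.
- Multi-seed experiment sizes (20 seeds × n = 2000 for recovery/null,
  10 seeds in the acceptance script) keep replicate medians stable
  while the full suite runs in minutes on one CPU.
- Serialization: model bundles are JSON (coefficients, intercepts,
  λ*, standardization stats, age-normalizer grids, seeds); CSV floats
  are written as shortest round-trip representations and parsed with
  round-trip precision, so save/load reproduces predictions exactly.

## Known limitations

- π scores are not calibrated probabilities; only their ordering and
  affine geometry are used. Users wanting probabilities should apply
  the softmax view knowingly.
- Age normalization assumes a locally linear age trend within ±5-year
  windows; strongly nonlinear trends at the range edges are only
  approximated.
- The questionnaire path treats "continuous variables" as linear
  predictors of the indicator models; fitted-probability readings
  would differ by a monotone map per type.
- Automatic landmark detection from photographs, audio segmentation
  into sentence/vowel parts, and the historical fixed integration
  weights are out of scope (the latter is supported only as a
  user-supplied configuration variant).
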
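# Methods

## The analysis in brief

Striatal dopamine-transporter SPECT is interpreted through a small set of
visual features — overall uptake level (high/low), left–right symmetry,
and the comma-vs-dot shape that results from putamen loss relative to the
caudate — together with ROI indices: the specific binding ratio
(SBR = (striatal − background)/background mean counts), an asymmetry index,
and the putamen:caudate (PC) ratio. This package reproduces that workflow
as code: images are standardized to a 70×70 frame, three classifier
families score each visual feature from the raw pixels, and three logistic
diagnosis models built from ROI indices, the machine-learned abnormality
probability, or the per-feature probabilities plus age are compared by ROC.
Because clinical images cannot be redistributed, every stage runs on
parametric phantoms whose ground truth is known exactly, which turns the
whole pipeline into a set of checkable recovery problems.

## Phantom model

Each subject is a 21-slice, 128×128 count volume. The brain is a uniform
ellipse (half-axes 48×40 px, mildly shrinking away from the central slice)
at `background_level` = 30 expected counts/pixel. Per side, a caudate disc
(r = 5 px) and a rotated putamen ellipse (8.5×4.5 px, 25°) form the comma;
the two regions are kept disjoint with a small gap that the point-spread
blur (Gaussian, σ = 2.5 px) closes visually. The striatal footprint is
largest on the central slice and shrinks one and two slices away, so slice
selection has a unique, known argmax while the three central slices carry
full uptake inside the base footprint.

Pixel expectation inside a striatal region is
`bg · (1 + (C − 1) · t)`, where `C` is the striatal:background contrast and
`t` the template value (1 in the caudate, `putamen_attenuation` in the
putamen). The template value therefore scales the *specific* (above-
background) uptake: a dot-like phantom with attenuation 0.5 halves the
putamen's specific binding, so the background-subtracted PC ratio recovers
the attenuation factor exactly, and SBR recovers `C − 1`. Asymmetry
multiplies the worse side's contrast by `asymmetry_factor` (0.6), the worse
side chosen at random per subject. Poisson noise is applied to the blurred
expectation (`noise_scale` multiplies expectations before sampling;
`noise_scale = 0` returns the noise-free expectation).

Default contrasts are 5× background for the normal (high) class and 2× for
the low class, chosen so that the SBR scale brackets the conventional
normal/abnormal threshold of roughly 4.5. Ages are normal, clipped to
[40, 95]: 75 ± 8 y for the training-like cohort and 67 ± 15 y for the
test-like cohort. The feature-combination mixes reproduce the marginal
frequencies of a movement-disorder referral stream (training-like: low 77%,
asymmetric 60%, dot 64%, abnormal = OR of features = 79%; test-like: 46% /
37% / 47%, abnormal ≈ 57%). The diagnosis is Bernoulli with
`logit p = b₀ + b_age·age + b_low·low + b_asym·asym + b_dot·dot`, defaults
(−8, 0.1, 2, 1, 2) — a rule in which shape information (dot) and age carry
diagnostic signal beyond what mean counts provide, so the combined model has
something real to gain over the ROI-only model, and logistic fits have a
known truth to recover.

What the phantoms deliberately lack: cortical texture, ventricles and
atrophy, attenuation/scatter physics, camera- or collimator-specific
response, anatomical variability of the striatum, and any dependence of the
visual-impression label on reader behaviour (here `abnormal` is the OR of
the generated features). Passing tests therefore demonstrate that the
*pipeline machinery* is correct and self-consistent under its stated model,
not that the classifiers would reach the same accuracy on patient data.

## Standardization choices

The paper-style chain leaves several constants unstated; the defaults here
are: striatal bootstrap region for slice selection = pixels ≥ 60% of the
volume maximum; brain contour = largest connected component ≥ 10% of the
summed-image maximum, holes filled; bounding box resampled bilinearly to
100×120; 70×70 crop centred on the intensity-weighted centroid of pixels
≥ 50% of the maximum (the striatum at high contrast, the bright brain core
at low contrast — both centrally located, so centring stays
class-consistent). Argmax ties take the lowest slice index; crops touching
the border are zero-padded. The crop origin quantizes the centroid to 1e-6
before rounding so that mirroring a volume mirrors the frame exactly for
midline-symmetric images (and to within one pixel otherwise).

The group striatal mask thresholds the cohort-average of max-normalized
images at a 30% cutoff. Read literally as 30% of the average's maximum, the
cutoff floods the whole brain whenever low-uptake subjects dominate (their
max-normalized background sits near 0.5, above any 0.3 threshold), leaving
no background region to normalize against. The default mode therefore
references the cutoff to the in-brain intensity range — threshold =
median + cutoff × (max − median), the median over non-zero pixels
estimating the background plateau — which recovers the generating striatal
footprint with Dice ≈ 0.8 at default noise and reduces to the literal rule
as the plateau falls. The literal reading remains available as
`mode="absolute"`. Background normalization rescales so the mean over
(non-zero pixels ∖ mask dilated by 1 px) is exactly 0.15; classifiers train
on background-normalized images, max-normalized ones serve mask building
and display.

## ROI template

The quantitation template mirrors the phantom geometry mapped through the
standardization (the 48-px brain half-height onto the 120-px box, factor
1.25), with every region shrunk by 2.5 px so it sits strictly inside the
true uptake region — making the indices insensitive to edge interpolation
and blur. The fit translates each side to the centroid of pixels whose
excess over the frame median reaches 30% of the local maximum's excess
(median-referenced so background pixels never enter at low contrast); if
the local maximum is below 1.5× the frame median (near-background,
burst-striatum-like uptake) the base placement is kept and flagged. The
background reference is a central disc (r = 32 px) minus the striatal
regions dilated by 6 px. The asymmetry index uses the absolute symmetric
percent difference of the side SBRs; the PC ratio background-subtracts both
numerator and denominator and summarizes by the worse (minimum) side,
matching the convention that diagnosis rests on the worse side's profile.

## Classifiers and evaluation

All three families consume the flattened 4900-pixel vector directly.
Explicit defaults replace any automatic tuning: LR is L2-regularized
(C = 1); kNN uses k = 5 with Euclidean distance; GBT grows 200 depth-3
trees at learning rate 0.1 examining √4900 = 70 candidate pixels per split
(seeded, so runs are reproducible). Evaluation is stratified fourfold
cross-validation on subjects: per round, 75% of subjects — doubled by
horizontally flipped copies — train the model and the untouched 25% are
scored; augmenting validation folds would double-count and leak.
Probabilities are pooled out-of-fold. AUC is computed from midranks
(exactly the tie-aware Mann–Whitney pair-counting probability) and tested
against 0.5 two-sided (exact Mann–Whitney for small tie-free samples,
normal approximation otherwise); recall/precision/F1/accuracy use a 0.5
threshold, with undefined quantities reported as NaN rather than 0.

## Diagnosis models

All models output `p = 1/(1 + exp(−(b₀ + Σ bᵢxᵢ)))`. Logistic fits are
unpenalized maximum likelihood (statsmodels); rank-deficient designs raise
an error naming the collinear columns, and (quasi-)separated fits are
re-estimated with a light ridge penalty and flagged. Forward stepwise
selection greedily adds the candidate maximizing AUC (4-fold
cross-validated within the fitting cohort by default; in-sample
optionally), stops when the gain is ≤ 0.005, and allows at most one
probability per feature family so each visual feature contributes through
one classifier. The Youden threshold is found by exhaustive scan over
midpoints between distinct scores using integer arithmetic
(J·n₁·n₀ = TP·n₀ − FP·n₁), which avoids float ties; remaining ties resolve
toward higher specificity. Paired AUCs on the same subjects are compared
with DeLong's covariance-aware test (validated against R's `pROC::roc.test`
to five decimals).

Protocol: the feature classifiers are always trained on the training-like
cohort. The logistic layers of Models 1 and 3 (and the stepwise selection)
are, by default, fit and assessed on the test cohort
(`model_protocol="test_insample"`), matching the clinical-literature
practice of building the multivariable layer on the evaluation cohort; a
fully held-out variant (`model_protocol="two_cohort"` — logistic layers fit
on the training cohort, only scored on the test cohort) is available. Under
the held-out variant the Model 3 > Model 1 AUC ordering is preserved but
the paired test loses power (the difference shrinks by what the training
cohort's fit does not transfer). Model 2's "best method" is chosen by
training-cohort cross-validated AUC to avoid test-set selection.

## Problem sizes and numerics

Default experiment sizes are 137 training-like and 102 test-like subjects;
the feature-learning benchmark uses a 200-subject cohort; logistic recovery
uses n = 2000 label-only draws (no images needed); determinism checks run a
reduced 48/24 configuration twice. All randomness flows from a single seed
through `numpy.random.default_rng`, with child seeds below 2³¹; two runs
with the same configuration produce byte-identical CSV/JSON output
(`float_format="%.10g"`, sorted JSON keys).

## Known limitations

- 2-D, single-summed-slice quantitation; no volumetric (Tossici-Bolt-style
  volume-corrected) SBR, no partial-volume correction.
- The SBR/AI/PC oracles are exact only for noise-free, unblurred phantoms;
  with blur the eroded template keeps the bias small but nonzero.
- Mirror equivariance of the crop is exact only for midline-symmetric
  input; otherwise the crop can shift by one pixel.
- The asymmetry feature is geometrically clean in phantoms, so classifiers
  and the ROI asymmetry index both detect it far more easily than in
  clinical images, compressing the advantage of ML over ROI indices for
  that feature.
- The group-mask cutoff interpretation matters at low contrast (see above);
  results with `mode="absolute"` are only meaningful for cohorts dominated
  by high-contrast subjects.
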
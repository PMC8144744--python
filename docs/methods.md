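# Methods

This document describes the statistical model, the algorithmic conventions,
and the numerical choices implemented in `phase4d`, and what the synthetic
generators do and do not emulate.

## Data model

The central container is a long-format phase-feature table with one value per
(patient, phase, ROI, feature) cell. Phases form an ordered cyclic axis,
default `0%` … `90%` in steps of 10, where `0%` is peak inhale; index `i` has
cyclic neighbours `(i−1) mod P` and `(i+1) mod P`. Two regions of interest
(ROIs) are modelled: the tumour and the peritumoural band. Missing cells are
detected and kept missing, never imputed; operations that need a phase
exclude the affected patient-features and log the count. CSV round trips are
bit-exact (`float_precision="round_trip"` on load).

## ROI geometry

- **Peritumoural band**: all voxels within 3 mm inside or outside the gross
  tumour volume (GTV) surface, computed with Euclidean distance transforms
  using the physical voxel spacing.
- **High-density correction**: band voxels outside the GTV that belong to, or
  are 26-adjacent to, tissue above 0 HU (chest wall, mediastinum, large
  vessels) are removed; an optional one-voxel face-connected boundary erosion
  then trims the partial-volume rim.
- **Mask propagation**: the reference GTV is translated per phase by the
  tumour displacement, rounded to the nearest voxel per axis.
- **Motion amplitude**: the Euclidean norm of per-axis displacement spans
  (max − min over phases).
- **Minimum ROI size**: 64 voxels (inclusive); smaller ROIs are rejected
  rather than extracted.

## Feature extraction

93 features per image type per ROI: 18 first-order, 24 grey-level
co-occurrence (GLCM), 16 run length (GLRLM), 16 size zone (GLSZM), 5
neighbourhood grey-tone difference (NGTDM) and 14 dependence (GLDM) features,
following the standardised (IBSI-aligned) definitions. Two image types —
the original image and a Laplacian-of-Gaussian filtered image with physical
sigma 1.5 mm (sigma divided by per-axis voxel spacing before filtering) —
and two ROIs give 372 features per phase.

Numerical conventions:

- Fixed bin width 25 HU anchored at the ROI minimum
  (`level = floor((x − min)/25) + 1`); no resampling or resegmentation.
- GLCM: symmetric co-occurrence accumulated over 13 unique 3D direction
  offsets, features averaged over directions; correlation defined as 1 for a
  constant ROI.
- GLRLM: maximal runs per direction, averaged over the 13 directions.
- GLSZM/GLDM/NGTDM: 26-connectivity.
- First-order variance and kurtosis are population moments (kurtosis is not
  excess-corrected); entropy/uniformity use the binned distribution.

## Phase selection

For each patient-feature the summed cyclic neighbour difference
`dX[p] = |x[p] − x[p−1]| + |x[p] − x[p+1]|` is minimised; the modal winner
across all 372 features is the patient's most stable phase. Ties — in the
per-feature argmin and the per-patient vote — are broken toward the phase
cyclically closest to the 50% label, then toward the lower index, encoding
the prior that stable phases cluster near end-exhale.

## Feature sets and stability assessment

Four set-construction methods collapse the phase axis: mean, median, the
fixed 50% phase, and the personalised phase. Four assessment regimes: none;
stability over all 10 phases; stability over the selected phase and its two
cyclic neighbours; averaging over those three phases. Neighbour-based
assessments require a single selected phase, so mean and median admit only
`none` and `stability10` — 12 valid combinations in total, enforced at the
API boundary.

Stability uses ICC(A,1), the two-way mixed-effects intraclass correlation for
absolute agreement of single measurements (McGraw–Wong):

`ICC = (MS_R − MS_E) / (MS_R + (k−1) MS_E + (k/n)(MS_C − MS_E))`

with an F-based 95% confidence interval (Satterthwaite denominator degrees of
freedom). A feature is stable when the lower bound is ≥ 0.85. Zero-variance
matrices have undefined ICC and are classed unstable.

## Unsupervised filtering

Applied after assessment, before any supervised step: (1) features with
|Spearman rho| > 0.5 against tumour volume are removed (volume is already a
clinical covariate); (2) per-ROI greedy redundancy elimination — while any
pair exceeds |Pearson r| > 0.5, remove the pair member with the largest mean
absolute correlation to the remaining features, recomputing after each
removal, ties to the lexicographically later name; (3) z-scoring to zero mean
and unit sample standard deviation.

## Supervised selection and cross-validation

Three selectors run inside repeated event-matched stratified
cross-validation (default 40 repeats × 5 folds = 200 train/test samples;
events and censored patients are shuffled separately and dealt round-robin so
fold event counts differ by at most one):

1. **Univariable**: Wald p < 0.05 in a univariable Cox model.
2. **Multivariable**: likelihood-ratio p < 0.05 for adding the feature to the
   fixed clinical model.
3. **MRMR**: greedy ranking by relevance minus redundancy, where relevance is
   the sign-aligned rescaled concordance `2(max(c, 1−c) − 0.5)` and
   redundancy the mean |Pearson r| to already-selected features; features are
   added while the score is positive.

Each run's selected features plus the clinical covariates form a Cox model
scored by Harrell's concordance on train and test. Selectors are ranked by
`C_test − |C_test − C_train|` of the median concordances (test performance
penalised by the optimism gap). The signature is the occurrence-ranked
feature list truncated to the median per-run selected-set size (fractional
medians round half up; ties broken by mean selection position, then name).

Inside CV loops, Cox models are fit by a vectorised Newton–Raphson on the
Breslow partial likelihood (cross-checked against lifelines to ~1e-6 on
tie-free data); final models use lifelines `CoxPHFitter`.

## Final models and added value

The clinical baseline regresses hazard on tumour volume, lobe (middle merged
into upper), sex, age, T stage (T3 merged into T2) and ECOG status (0 merged
into 1); sparse categories are merged because near-empty dummy columns make
the partial likelihood quasi-separated. Categorical covariates are
dummy-coded against the first category; volume and age enter linearly.

Each clinical-radiomics (CR) model adds one signature. Added value is the
adequacy index `LR_C / LR_CR` — the ratio of likelihood-ratio chi-square
statistics of the nested models — and the fraction of new information
`1 − LR_C/LR_CR`. The concordance index is summarised as the median and
percentile 95% interval over 500 bootstrap refits, each refit on the
resample and scored on the original data unchanged; zero-event resamples are
redrawn.

## Synthetic generators

`gen_phase_features` draws, per patient, a designed stable phase from a prior
peaked at end-exhale, and gives every feature a trajectory quadratic in
cyclic distance from that phase, so the neighbour difference is strictly
minimal there in the noise-free limit. On top of this it adds white noise
(SD 0.1), single-phase artifact spikes (magnitude 1.0 = 10× the noise SD, in
30% of patients, at least two cyclic steps from the designed phase, hitting
80% of features with random sign), block-correlated structure (blocks of 6,
loading 0.7) and volume coupling (45% of features). `gen_outcomes` draws
survival from an exponential-baseline Cox model on planted features (log
hazard ratios per SD) plus a volume effect, with uniform censoring tuned by
bisection to the target event fraction; clinical covariates loosely follow an
early-stage lung SABR cohort (sex ≈ 52/48, median age 75, median volume
4 cm³, median motion 5.5 mm).

`gen_phantom_4d` builds a 4D CT phantom: lung-density background (−750 HU), a
soft-tissue sphere (20 HU plus sinusoidal texture) translating cosinusoidally
in z with the stated peak-to-peak amplitude (reference phase 50%), an
optional high-density slab (+300 HU), Gaussian image noise, and an optional
duplicated-slice artifact at a chosen phase.

What the generators deliberately do **not** emulate: realistic CT noise
spectra or scanner texture, breathing-curve physiology (hysteresis,
irregular cycles), deformable motion (translation only), anatomical
heterogeneity, or inter-feature dependence structures beyond the linear
block model. Their purpose is ground truth for correctness and calibration
checks, not physical realism.

## Limitations

- The stability threshold (0.85 on the CI lower bound), correlation cutoffs
  (0.5), and significance level (0.05) are fixed study conventions, not tuned
  values.
- The fast Cox solver assumes Breslow tie handling; with heavily tied times
  it can differ slightly from Efron-based fits.
- The fraction of new information is a ratio of chi-square statistics, not a
  proportion of explained variance; it is undefined when the full model has
  zero LR chi-square.
- Empirical quantities reported anywhere in this repository (recovery rates,
  concordance values) are computed on the seeded synthetic cohorts described
  above and depend on those design parameters.
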
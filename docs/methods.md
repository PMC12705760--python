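# Methods

This note documents the models, numerical conventions, and design choices
behind `slrsa`, and what the synthetic verification studies do and do not
establish about real data.

## First-level model

BOLD time courses are modelled as a linear combination of task regressors,
slow drifts, optional nuisance columns, and a constant:

- **HRF.** The canonical double-gamma response: a gamma density with shape
  6 (peak ≈ 5 s) minus 1/6 of a gamma density with shape 16 (undershoot),
  dispersions 1, 32 s support, normalized to unit sum after sampling.
  Event boxcars (sticks for zero durations) are laid out on a grid of 16
  bins per TR, convolved, and sampled at volume midpoints
  `(i + 0.5)·TR`; the oversampled grid is what makes sub-TR onset jitter
  meaningful. These conventions are fixed, not exposed as tuning knobs.
- **High-pass filter.** Discrete-cosine basis with
  `K = floor(2·T·TR / cutoff)` columns, default cutoff 128 s; columns are
  mutually orthogonal by construction.
- **AR(1) prewhitening.** A single pooled lag-1 coefficient is estimated
  from the OLS residuals of a reference model (all words as one
  regressor), clipped to |φ| ≤ 0.99, and applied as a Cochrane–Orcutt
  transform to data and design (first row scaled by √(1−φ²) to keep the
  transform full rank). One global φ rather than per-voxel models keeps
  the estimator simple and testable; the prewhitening property test
  verifies that whitening with the generating φ leaves residuals with
  lag-1 autocorrelation centred on zero.
- **LSS.** Each word trial is estimated in its own GLM with exactly three
  task columns — the trial itself, all other word trials aggregated, and
  all pseudoword trials aggregated — solved by pseudoinverse. Rows of the
  returned beta stack are ordered alphabetically by concept label, the
  same order model RDMs use. LSS is an approximation whenever trial
  responses overlap: the aggregate column cannot absorb heterogeneous
  neighbouring amplitudes exactly. This is a property of the estimator,
  not a bug; the exact-identity study therefore uses a wide-spaced design
  (below), while the moderate-noise recovery study uses the rapid
  jittered design and absorbs LSS bias into its realized effect size.
- **Masking.** Estimation is restricted to an explicit binary mask; no
  implicit intensity masking is performed. Statistic maps are NaN outside
  the mask.

## RDMs and their comparison

Dissimilarity is correlation distance, `1 − Pearson r`, giving cells in
[0, 2]; RDM objects enforce symmetry, an exactly zero diagonal, and that
range at construction. Model and neural RDMs are vectorized identically
(row-major strict upper triangle) before comparison. Spearman rank
correlation uses average ranks for ties; permutation p-values come from
jointly relabeling one RDM's conditions. The experience matrix converts
each participant–concept cell's category counts to proportions *within
the cell* before averaging across participants, and averages only over
participants with a non-missing cell; the alternative reading (averaging
raw frequencies) changes row scales but was rejected because proportions
are what the per-cell normalization of a free-listing task measures.

The language-RDM path drops requested concepts that are absent from the
semantic space's vocabulary and reports the dropped labels, mirroring how
multi-word expressions fall out of single-word embedding vocabularies.

## Searchlights

Spheres are defined in voxel units with an inclusive boundary
(`‖offset‖² ≤ r²`; 123 voxels at radius 3). A mask voxel becomes a center
only if at least `min_fraction` (default 0.5) of the *full geometric
sphere* is in-mask — the denominator is 123 even at volume borders, the
stricter reading; neighborhoods always contain their center.
Searchlights where some concept's pattern is constant have undefined
correlation cells; they are skipped and logged (left NaN), never imputed.

**Tie stabilization.** Before rank transformation the RDM cells are
rounded to 10 decimals. Exactly tied dissimilarities (e.g. two concepts
with identical patterns) otherwise pick up ~1e−15 floating-point noise in
the betas, which breaks the tie structure and caps Spearman ρ visibly
below 1 even on noise-free data. 1e−10 is many orders of magnitude below
the resolution of any measured correlation distance, so the rounding is
inert for real data while making exact ties exact. ρ values are *not*
Fisher-z transformed before group statistics; the correlation
coefficients themselves are t-tested.

## Group inference

Per-voxel one-sample, pooled two-sample, and paired t statistics are
computed in closed form; zero-variance voxels are flagged NaN and logged.
Normality screening applies Shapiro–Wilk per voxel with
Benjamini–Hochberg FDR at α = 0.05 across in-mask voxels.

Cluster-level FWE uses the permutation null of the maximum cluster size:
the observed t-map is thresholded at the one-sided `t_df(1 − 0.001)`
cluster-forming threshold, clusters are formed with 18-connectivity
(faces + edges), and each cluster's corrected p is
`(1 + #{null max ≥ size}) / (1 + n_perm)` with sign flips (one-sample /
paired; valid under a symmetric null) or group relabelings (two-sample).
Permutation rather than random-field theory keeps the procedure exact at
desk scale and assumption-light; the minimum attainable p is
`1/(1 + n_perm)`. Conjunctions use the minimum statistic against the
conjunction null (both conjuncts must exceed the threshold), the
conservative formulation. Peak t values are reported alongside
probability-matched z-scores. Reported peaks are cluster local maxima at
least 8 mm apart, at most 16 per cluster.

## Synthetic data: what it emulates and what it does not

The generator reproduces the study conditions of the emulated experiment:
64 + 64 trials of 2400 ms, intertrial intervals from a gamma distribution
matched to mean 3173 ms and SD 3435 ms (the source reports only the
moments of an optimized sequence; a right-skewed zero-truncated family is
the natural choice and the gamma matches both moments), onsets jittered
by uniform sub-TR fractions, no condition more than 3 in a row; localizer
blocks of 24 s/27.8 s rest (visual, 6 blocks), 26 s/26 s (motor, 8
blocks), and 23.8 s with 5.8 s fixation (emotional, 6 + 6 blocks);
property listings with a zero-truncated Poisson number of properties
(mean 3.5) spread over the 11 modal categories by concept-specific
Dirichlet profiles, with cells flagged missing at a configurable rate;
pseudowords formed by replacing exactly one vowel and one consonant
(German inventory, umlauts as vowels).

**Pattern planting is exact.** `embed_geometry` factorizes the target
similarity matrix `S = 1 − d` (rejecting non-PSD targets as not
correlation-realizable) and mixes the factor with centered orthonormal
voxel bases, so the planted patterns' sample correlation matrix equals
`S` exactly over the full ROI. Noise is stationary AR(1) Gaussian added
per in-mask voxel; `motion=True` adds slow cosine drifts with random
per-voxel weights. Not emulated: spatial noise correlations, physiological
noise, slice-timing, true head motion, susceptibility artefacts, and
inter-subject anatomical variability (all subjects share one grid).
Passing tests therefore establish the *correctness of the computations*,
not robustness to real-scanner artefacts.

## Verification studies (`slrsa.studies`)

Problem sizes were chosen so each study runs in seconds to a couple of
minutes on one CPU; all are seeded.

- **Planted identity.** A 58-condition block RDM planted in a 300-voxel
  ROI (18³ grid), zero noise, trials spaced 36 s so their HRF supports do
  not overlap and no drift columns — under these conditions trial-wise
  least squares is exact, and ρ = 1.000 at all searchlights fully inside
  the ROI. The target uses **two** concept groups: its RDM then has
  exactly two cell levels whose order survives any voxel subsampling, so
  the identity is exact for every seed. With three or more graded groups,
  voxel subsampling inside a 123-voxel sphere perturbs the between-group
  correlation levels by up to ~0.1 and can swap two of them; graded
  4-group targets are exercised in the searchlight test module at fixed
  seeds instead.
- **Solver agreement.** On a rapid 64-trial design the LSS estimator must
  agree with independently solved normal equations to ≤ 1e−8 per
  coefficient (it agrees to ~1e−14); this checks the solver, separately
  from the estimator's statistical bias.
- **FWE calibration.** 200 null datasets of 12 subjects × 2000 in-mask
  voxels, 500 sign-flip permutations each. Null maps are Gaussian random
  fields smoothed to 2 voxels FWHM: searchlight maps are inherently
  smooth (overlapping spheres), and on completely unsmoothed i.i.d. noise
  the maximum cluster size takes so few values that the (valid)
  permutation test becomes conservative through discreteness — the
  measured rate would reflect the statistic's granularity rather than
  the procedure's calibration. The measured family-wise rate is ~0.04 at
  a nominal 0.05.
- **Parameter recovery.** A 16-concept graded RDM planted in a 300-voxel
  ROI of an elongated grid, 12 subjects per replicate, 20 replicates.
  Amplitude 10 and noise SD 1 (AR(1) φ = 0.3) were calibrated once to
  give single-subject ROI ρ ≈ 0.2 and then frozen. A disjoint 300-voxel
  control region, 4 voxels clear of the ROI (beyond the searchlight
  radius), monitors false positives. Expected outcome: a significant
  cluster intersecting the ROI in ≥ 90 % of replicates, a clean control
  region in ≥ 95 %.

## Reliability

ICC form is fixed to ICC(A,1) — two-way random effects, absolute
agreement, single measures — computed from the items × raters
mean-squares decomposition. Absolute agreement (not consistency) is the
relevant criterion for whether two coders assign the same categories, and
single measures because each rater coded once; average-measures variants
are out of scope. The per-category unit of analysis is the concept, rated
by each coder's mean classification frequency across participants;
category ICCs are combined by a mean weighted with the categories' mean
frequencies over both raters.

## Known limitations

- LSS betas are biased for overlapping trials with heterogeneous
  amplitudes (inherent to the estimator); no alternative trial estimators
  (least-squares-all, GLMsingle-style regularization) are provided.
- One global AR(1) coefficient; no local or higher-order noise models.
- Cluster inference offers no random-field-theory p-values, TFCE, or
  covariates.
- The permutation test's sign-flip variant assumes a symmetric null
  distribution per voxel.
- Searchlights are volumetric only; no surface-based or cross-validated
  (crossnobis) distances.
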
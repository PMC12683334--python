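# Methods

This note records the models, parameter choices, and numerical decisions
behind `radrobust`, and what the synthetic experiments do and do not show.

## Synthetic phantoms

A phantom is a body-like background (40 HU) containing one ellipsoidal tumor.
The mask is the exact voxelized ellipsoid indicator (voxel centers inside the
ellipsoid). The tumor interior is `tumor_mean_hu` plus two stochastic
components:

* **texture** — white Gaussian noise smoothed with a Gaussian of
  `texture_scale_mm` (default 4 mm) and rescaled to `texture_amplitude_hu`
  standard deviation. This gives non-degenerate gray-level texture matrices
  without mimicking any particular pathology. Because the smoothing scale is
  not small relative to the tumor, the texture field carries a per-patient DC
  offset of up to ±10–15 HU inside small tumors; the ROI mean therefore
  tracks, but does not equal, `tumor_mean_hu`.
* **acquisition noise** — i.i.d. Gaussian, `noise_sigma_hu` (applied to the
  whole grid).

Default grid 64×96×96 voxels at (3, 1, 1) mm: thick-slice, in-plane-fine CT
geometry, chosen so the anisotropic-resampling path is always exercised.
Cohorts draw per-patient parameters uniformly: semi-axes 8–20 mm
(independently per axis, so elongation/flatness vary), mean 40–80 HU, texture
amplitude 15–35 HU, noise 10–20 HU. Seeding is hierarchical
(master → patient → realization), so extending a cohort never changes earlier
patients' streams.

Ellipsoids are axis-aligned and smooth; real tumors are lobulated, oriented
arbitrarily, and far more variable in shape. Consequently the *between*-
patient variance of orientation- and ratio-type shape descriptors
(Elongation, Sphericity, MajorAxisLength) is smaller here than in clinical
cohorts, which depresses their ICC relative to what the same perturbations
produce on real data (see "Known limitations").

Survival outcomes follow an exponential proportional-hazards model
`h(t) = h0 · exp(βᵀz)` on z-scored covariates with independent exponential
censoring — the simplest mechanism satisfying the Cox model's assumptions,
so coefficient-recovery tests have an exact target.

## Perturbation chain

Order is fixed: **rigid transform → noise injection → contour
randomization**. The chain is order-dependent (noise added before rotation
would be smoothed by interpolation); the implemented order perturbs the
acquisition first and the observer last.

* *Rigid*: in-plane rotation about the mask centroid, then in-plane
  translation. Translation magnitudes are drawn per axis from
  {0, 0.4, 0.8} px; z is never perturbed (thick slices make through-plane
  setup error sub-voxel). Images are interpolated linearly (out-of-grid
  voxels −1000 HU); masks linearly then re-binarized at 0.5, which avoids
  nearest-neighbor stair-casing while keeping masks binary. The identity
  transform short-circuits and is bit-exact.
* *Noise*: "m × the original level" is implemented as adding Gaussian noise
  with std m·σ̂, where σ̂ is estimated from the image itself: the median
  absolute deviation of a discrete-Laplacian residual over body voxels,
  rescaled by 1.4826/√42 (the filter's white-noise gain). The estimator is
  within ±15 % for σ ≥ 5 HU on phantoms and is insensitive to DC shifts.
* *Contour randomization*: a per-voxel U(−1,1) 3-vector field, z-component
  constant per slice; each component is Gaussian-smoothed (σ = 10 voxels),
  then the field is normalized so the RMS *magnitude* equals
  `amplitude_vox` (default 1) and applied by backward warping. Normalizing
  before smoothing (the `literal_order=True` variant) leaves displacements
  orders of magnitude below one voxel, because smoothing averages away an
  uncorrelated field — that variant is retained for reference but produces
  effectively no contour change. The magnitude convention (rather than
  per-component RMS = 1, which would give √3-voxel typical displacements)
  makes "amplitude 1" mean "a typical contour displacement of one voxel".

## Feature extraction

IBSI-style: resample to 1 mm isotropic (linear image / linear+0.5 mask),
resegment the intensity mask to [−150, 180] HU (shape keeps the full
morphological mask), discretize ROI intensities to 30 equal-width bins
between the ROI min and max — recomputed per image type, since filtered
intensities are not HU.

Image types: unfiltered, LoG σ = 1…6 mm (computed at 8-σ kernel support; the
default 4-σ truncation leaks ~3·10⁻⁴ of the DC level into flat regions), and
a single-level undecimated Coiflet-1 wavelet transform in the
energy-preserving (`norm=True`) dialect, 8 subbands named by per-axis L/H
letters in x, y, z order. The undecimated dialect keeps subbands on the input
grid so the ROI mask applies unchanged; the decimated alternative would make
mask/subband alignment ambiguous.

Feature set per image type (93): 18 first-order (Entropy/Uniformity on the
discretized histogram, the rest on raw intensities), 24 GLCM and 16 GLRLM
(13 unique 3D directions at distance 1, single matrix per direction,
feature-averaged), 16 GLSZM and 14 GLDM and 5 NGTDM (26-connectivity). GLDM
dependence size counts the center voxel plus its equal-gray-level 26-neighbors
(α = 0). Shape (14): mesh volume/surface from marching cubes over the
0.8-voxel-Gaussian-smoothed mask (meshing the raw binary indicator inflates a
sphere's surface ~9 % through stair-casing; with smoothing, sphere area and
volume land within ~3 % of analytic), voxel volume, surface/volume ratio,
sphericity, max 3D and per-plane 2D diameters (convex-hull pairwise
distances), and PCA axis lengths (4√λ) with elongation and flatness.

Degenerate ROIs (single gray level) return documented fallbacks — entropies
0, correlation-type features 1, NGTDM contrast 0 — rather than NaN; a feature
that still produces non-finite values enters the databank with class
"degenerate" and a warning instead of being dropped.

Extraction crops each volume to the mask bounding box plus a filter-support
margin (≥ 4σ of the largest LoG scale). Features depend only on the ROI and
its neighborhood, so this is value-preserving; the same reasoning lets the
measurement driver skip image interpolation and noise injection when only
mask-derived (shape) features are requested — neither changes the mask, and a
test asserts mask equivalence of the two paths.

## ICC and the databank

One-way random-effects, absolute-agreement, single-measurement ICC from the
ANOVA decomposition of the n×k measurement matrix (column 0 unperturbed).
The default denominator is the standard `MS_n + (k−1)·MS_W`; a
`paper_literal` variant with `(k+1)·MS_W` is kept selectable. A constant
matrix yields NaN (no repeatability information). Databank records report the
mean ICC and percentile 95 % CI over patient-subsampling rounds (default 10
rounds; subsample size configurable), plus the 0.5/0.75/0.9 class, with
boundary values assigned as: 0.5 → moderate, 0.75 → good, 0.9 → good.
Sample-size curves re-estimate the ICC over rounds at sizes 10…100 step 10,
then 100-step increments; the "most size-sensitive" features are ranked by
the variance of the per-size mean ICC with lexicographic tie-breaks.

## Survival modelling cascade

Per ICC threshold (strict `mean_icc > t`; shape features are excluded from
the modelling pool, which uses first-/high-order features only):
univariate Cox on z-scored features, Wald p < 0.05, no multiplicity
correction (deliberately — the screening is a filter, not an inference);
then bootstrap-stabilized LASSO-Cox: patients resampled with replacement,
penalty chosen per bootstrap by 3-fold cross-validated concordance over the
coxnet path, non-zero-coefficient features tallied, top-5 by frequency
(lexicographic ties). If at most 5 features survive screening the LASSO
stage is skipped. The final multivariate Cox model z-scores with *training*
statistics reused verbatim on all evaluation cohorts; zero-variance features
are fixed at coefficient 0; collinear designs are refit with a small ridge
penalty. Concordance is Harrell's C (ties 0.5); cohort-level bootstrap
(evaluation-only resampling, default 100 replicates) gives percentile CIs,
and G is the mean |C_train − C_EV| over EV cohorts, with its CI from paired
bootstrap replicates. G is *not* invariant to monotone rescaling of C; only
non-negativity, the zero-iff-equal property, and EV-permutation invariance
are asserted.

## The noisy-EV generalizability experiment

Question: when external-validation images are noisier than training images,
do ICC-preselected models transfer better (smaller G)? Design: each patient's
"biology" is the noise-free textured tumor; the hazard depends on its two
measurable properties, mean density (β = 0.7) and texture strength
(β = 1.2). Observed images add per-patient noise — 10–20 HU for
training/internal-test, 35–55 HU for the two EV cohorts (about 3× the
training range, matching the upper noise multipliers of the perturbation grid
the databank is built from). Robust features (ROI mean/median — averages over
thousands of voxels) track the biology at any noise level; variance- and
texture-type features are corrupted in the EV cohorts exactly as the
databank's low ICC predicts. The databank (25 phantoms × 15 realizations,
first-order + GLCM on the unfiltered image) is built once and shared across
experiment repetitions, as a published databank would be. Cohort sizes
(train 100 / test 50 / EV 2×100) are chosen so cohort-level concordance noise
(≈ 0.03) is small against the expected G contrast; the hazard weighting
toward the texture channel is what gives the unrestricted model something
fragile to learn — with a hazard carried only by noise-robust features, extra
EV noise would be irrelevant and the comparison uninformative.

## Problem sizes used in the checks

The automated checks run the same code at sizes chosen for single-CPU runs:
shape repeatability at 30 phantoms × 15 realizations in the suite and
100 × 60 (10 rounds × 50 patients) in `scripts/acceptance.py`; noise-
degradation monotonicity at 20 phantoms × 12 realizations per multiplier set;
selection recovery at n = 500 with 2 signal + 50 noise features over 10
seeds; the noisy-EV experiment over 10 seeds with the sizes above.

## Known limitations

* Shape-feature repeatability is bounded by the phantom geometry: with
  axis-aligned ellipsoids and 8–20 mm semi-axes, the between-patient variance
  of Elongation/Sphericity/axis-length descriptors is modest, and amplitude-1
  contour randomization moves their ICC into the high-good range
  (≈ 0.85–0.90) rather than the >0.95 seen on clinical tumors, whose shape
  variance is far larger. Volume-, area-, and in-plane-diameter features do
  reach the excellent class on phantoms.
* The phantom emulates noise, spacing, and texture — not anatomy, partial
  volume at tissue interfaces, beam hardening, or scanner-specific noise
  spectra. Passing tests show the *pipeline* behaves correctly and the
  method's comparative claims hold under controlled conditions; they do not
  certify feature robustness values for clinical data.
* Texture-matrix definitions follow the common single-matrix-per-direction,
  feature-averaged 3D convention; other aggregation dialects will produce
  systematically different (not wrong) values.
* The LASSO penalty path and CV folds are seeded and deterministic, but
  coxnet's path depends on the bootstrap sample; selection frequencies are
  meaningful only relative to the stated 10-bootstrap protocol.
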
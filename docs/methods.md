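# Methods

`radstab` implements the statistical and image-processing machinery of a
CT radiomic-feature stability study: extract a large roster of texture
features from 3D volumes, score their repeatability (test–retest) and
reproducibility (across scanners and acquisition protocols) with the
intraclass correlation coefficient, screen out features that merely track
tumor volume, and report the surviving stable set. Because the original
scans of such studies are rarely shareable, the package ships synthetic
generators — a sphere phantom image model and variance-component feature
tables — with known ground truth, so the entire pipeline is testable end
to end.

## The stability metric

All experiments use the two-way mixed-effects, consistency, single-
measurement intraclass correlation,

    ICC(3,1) = (MS_R − MS_E) / (MS_R + (k − 1) MS_E),

with MS_R the mean square for rows (subjects, or subject×protocol
instances), MS_E the residual mean square of the two-way ANOVA, and k the
number of measurement columns. Its range is [−1/(k−1), 1]. As a
*consistency* coefficient it ignores systematic per-column offsets and is
invariant under one affine map applied to the whole matrix; it is **not**
invariant to rescaling a single column (a column equal to 3x+10 of
another does not score 1 — a point sometimes gotten wrong in informal
accounts, and pinned by a test here). A constant matrix has an undefined
ICC; the implementation returns NaN, logs the event, and summaries treat
it as "poor" — the conservative choice.

Classification bands: good ICC ≥ 0.90, moderate 0.75 < ICC < 0.90, poor
ICC ≤ 0.75. The boundary 0.90 counts as good (sources alternate between
"≥ 0.9" and "> 0.9"; one convention is applied everywhere and both cut
points are configurable). Each ICC carries the row-effect F-test p-value
(F = MS_R/MS_E on (n−1), (n−1)(k−1) degrees of freedom), adjusted across
features by Benjamini–Hochberg FDR (statsmodels). The implementation was
cross-checked against pingouin's ICC(C,1) to 1e-10 on random matrices and
against a loop-written ANOVA oracle on 1000 more.

### Experiment orchestration

* **Repeatability** — columns are the two timepoints; rows are all
  subject×protocol(-×scanner) instances, per scanner and pooled. The
  32-subject two-scan cohort layout is the same computation with real
  subject rows.
* **Intra-scanner reproducibility** — columns are the 6 protocols within
  one scanner; the reported value is the median over the 3 scanners.
* **Inter-scanner reproducibility** — columns are the 3 scanners within
  one protocol; reported value is the median over the 6 protocols.
* **Clinical reproducibility** — columns are the 3 clinical protocols
  over the cohort, plus two k = 2 contrasts: WBCECT2 vs NCCTT2 isolates
  the IV-contrast-medium effect, BLDCT5 vs WBCECT2 the slice-thickness
  effect.
* **Volume collinearity** — Spearman ρ (average-rank ties) of each
  feature against gross tumor volume, per protocol, median of the three;
  classified with the same bands applied to |ρ|.
* **Selection** — step 1 keeps features whose median ICC over the
  repeatability group and over the reproducibility group both exceed 0.9;
  step 2 removes features with |ρ| > 0.9 against volume. The pooling is a
  plain median over the experiment-level reported ICCs within each group;
  since reasonable studies weight experiments differently, the grouping
  is an explicit function argument rather than hard-coded. Output is
  sorted by decreasing overall median ICC and tagged TA (original-image
  features), LOG (any Laplacian-of-Gaussian scale) or WF (any wavelet
  sub-band).

Medians of even-length lists are the mean of the central pair; category
summaries report the median and the n−1 sample standard deviation of the
members' overall median ICCs, rounded to 3 decimals.

## Feature extraction

The extractor produces 1080 features: 12 image channels × 90 features.
Channels: the original image, scale-normalized Laplacian-of-Gaussian at
σ = 1, 2, 3 mm, and the 8 sub-bands (LLL…HHH) of a single-level
undecimated separable 3D Coiflet-1 wavelet decomposition. Classes per
channel: 17 first-order, 22 GLCM, 16 GLRLM, 16 GLSZM, 5 NGTDM and 14
GLDM features, with ids like `log-sigma-2-0-mm-3D_glrlm_RunLengthNonUniformity`.

Pipeline choices (defaults equal the study protocol):

* **Resampling** — cubic B-spline to isotropic 2 mm voxels (SimpleITK);
  masks via nearest-neighbor, re-binarized. Physical extent preserved to
  within one voxel.
* **Segmentation** — threshold at 40% of the global maximum, keep the
  largest 26-connected component. On a noise-free 4:1 sphere phantom the
  cut (1.6× background) sits between background and target, so the mask
  is exactly the supersampled partial-volume set with fraction ≥ 0.2.
* **Discretization** — fixed bin width 25, anchored at the in-mask
  minimum: level(v) = floor((I(v) − min)/25) + 1. Anchoring at the
  minimum makes every discretized texture feature invariant to intensity
  shifts. Each filtered channel is discretized independently — filters
  change the dynamic range, and the fixed width is deliberately *not*
  rescaled per channel.
* **LoG normalization** — responses are γ-normalized (multiplied by σ²).
  Without this the σ = 3 mm channel of a smooth phantom collapses into a
  single gray bin at width 25 and its 90 features degenerate to
  constants; normalization is also the convention of the standard
  toolchains, keeping response amplitudes comparable across scales.
* **Wavelet convention** — periodic (circular) boundary, filters applied
  along array axes; sub-band letter i is the filter (L/H) along axis i.
  Sub-bands stay on the original grid (undecimated).
* **Texture aggregation** — GLCM and GLRLM are built at distance 1 along
  the 13 unique 3D directions; a feature is evaluated per direction and
  the 13 values averaged ("3D average"). GLCM matrices are symmetrized
  and normalized per direction; directions with no valid voxel pair are
  dropped from the average. GLSZM zones, GLDM neighborhoods (α = 0,
  dependence = 1 + number of equal neighbors) and NGTDM neighborhoods use
  26-connectivity. Every matrix builder is tested against an exhaustive
  loop-written counting oracle on random ROIs up to 6×6×6.
* **Degenerate limits** — single-gray-level ROIs take analytic limits
  (JointEnergy 1, entropies/contrasts 0, Correlation 1, normalized
  non-uniformities 1); NGTDM Coarseness is capped at 1e6 when its
  denominator vanishes; a flat ROI's skewness/kurtosis are emitted as the
  sentinel 0.0 with a log entry.

Grids are indexed `[z, y, x]` with spacing/origin in the same order;
world coordinate = origin + index·spacing; masks are strictly {0, 1}.
Volumes and masks are read and written as NRRD via SimpleITK.

## Synthetic data

**Feature tables.** Values follow the two-way mixed-effects model
y_ij = μ + s_i + r_j + e_ij with independent zero-mean normal subject,
rater(column) and residual effects, so the true consistency ICC is
σ_s²/(σ_s²+σ_e²). Every feature gets its own counter-derived random
stream from one explicit seed, making any slot reproducible in
isolation. Study layouts: the 6-protocol × 3-scanner × test–retest
phantom grid (36 slots; protocols crossing tube current 100/200/300 mA
with thin/thick slices, voxel sizes 0.86 mm in-plane/2–5 mm for the two
Philips-like scanners and 0.9653/2.5–5 mm for the GE-like one), the
104-subject × 3-clinical-protocol cohort (BLDCT5, WBCECT2, NCCTT2), and
the 32-subject × 2-scan cohort.

**Tiered fixtures.** The clinical and two-scan cohort fixtures carry
designed ICC tiers {0.95, 0.85, 0.5} using moment-calibrated sampling:
the two-way model is drawn, then the realized row-effect and residual
subspaces are rescaled so the *sample* ICC equals the tier exactly (the
`MASS::mvrnorm(empirical=TRUE)` idiom). Classification-recovery tests are
thereby construction properties rather than Monte-Carlo events; the plain
(uncalibrated) sampler remains available and is what the estimator-bias
tests use. The clinical fixture adds a designated 10% of features built
as a·volume^1.5 with 1% multiplicative noise — the known true positives
of the collinearity screen — and a lognormal per-subject tumor-volume
covariate (median ≈ 90 cm³, clipped to 14–486 cm³, the plausible NSCLC
range).

**Phantom images.** A sphere (default diameter 37 mm, the largest insert
of an image-quality phantom) centered in a uniform background at a 4:1
target-to-background ratio (background level 100). Partial-volume edges
come from 3×-per-axis supersampled sphere membership — deterministic and
resolution-aware. Noise is stationary additive Gaussian with
σ = noise_reference · sqrt(reference_mAmm / (mA · slice thickness)),
a first-order model of CT quantum noise; noise_reference defaults to 10
(10% of background) at the quietest protocol (300 mA × 5 mm). No source
states quantitative noise levels per protocol, so the 1/sqrt(mA·mm) law
is a modeling choice — enough to make protocol effects on features real,
while beam hardening, reconstruction kernels and PET physics are
deliberately out of scope. The field of view defaults to 64 mm per axis,
which keeps the finest grids near 75×75×32 voxels (32³ after 2 mm
resampling) so the full 36-scan pipeline runs in well under a minute on
one CPU; passing tests on these sizes demonstrates the machinery, not
the percentages any particular clinical dataset would produce.

**A confound worth knowing about.** On the single-sphere 36-slot fixture
the repeatability rows are protocol instances, and the per-protocol noise
*level* is itself a deterministic row signature: raising the global noise
makes protocols more distinguishable in feature space and the count of
"good" features rises. The clean design for "noise degrades test–retest
agreement" needs subject variance that is independent of noise, provided
by the sphere-diameter cohort fixture (8 subjects, diameters 24–37 mm,
one protocol, test–retest): there the good-feature count strictly
decreases across a weak-to-strong noise sweep (noise_reference 5/20/80).

## Reference stable set

The package ships a 108-feature reference stable set (3 TA, 46 LOG, 59
WF, ordered by decreasing overall median ICC) used by the reporting and
naming tests. Its category medians computed from the shipped 4-decimal
values are TA 0.933, LOG 0.921, WF 0.913 with sample standard deviations
0.024/0.017/0.014; published summaries of this set quote LOG 0.923 and
WF 0.917, consistent with medians taken on unrounded values, so tests
compare those two numbers at ±0.005 and everything else exactly.

## Known limitations

* The synthetic phantom is homogeneous; it cannot emulate intratumoral
  texture, so absolute feature values and stability percentages on real
  cohorts are out of reach by design.
* Feature definitions follow the public reference rosters, but bit-exact
  parity with any external extractor is a non-goal (interpolators and
  boundary conventions differ legitimately).
* ICC confidence intervals and the absolute-agreement/average-measure
  forms are not provided; shape features, 2D extraction modes and
  resegmentation windows are out of scope.
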
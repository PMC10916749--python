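# Methods

`petrad` implements a two-arm pipeline for discriminating healthy controls
from dementia patients on whole-brain FDG-PET volumes in a common template
space: a radiomics arm (hand-crafted features, small feed-forward network)
and an image arm (3D convolutional network), compared on the probability
scores they assign to a shared held-out test set. Because clinical FDG-PET
cohorts of this kind are not publicly deposited, the pipeline ships a
synthetic cohort generator that reproduces the statistical structure the
analysis relies on; every stage is exercised and validated against that
generator plus analytic and brute-force oracles.

## Synthetic cohort

The generator emulates a cohort of 125 healthy controls (age
64.8 ± 11.33 y) and 85 dementia patients (age 73.9 ± 6.8 y; 38 AD-like,
2 MCI-like, 25 DLB-like, 20 FTD-like) on a 79×95×69 grid with 2 mm
isotropic voxels. One subject volume is built as:

1. a baseline uptake field inside the brain mask: constant 100 plus
   low-frequency noise (white noise smoothed at 24 mm FWHM, scaled to a 5%
   relative SD) to mimic smooth between-subject variation in normalized
   uptake;
2. multiplicative regional hypometabolism for patients: intensities inside
   the subtype's pattern region are multiplied by the hypometabolism
   factor (default 0.75). The reduction is applied *before* smoothing so
   lesion boundaries show partial-volume-like blur;
3. additive voxel noise (relative SD 5%);
4. isotropic Gaussian smoothing at 8 mm FWHM and global-mean scaling of
   the in-mask mean to 1.0, the same operations the preprocessing module
   applies to real normalized volumes.

The brain mask is a centred ellipsoid with semi-axes at 40% of each grid
dimension — a deliberate stand-in for an anatomical template that avoids
any atlas download. Pattern regions are ellipsoids in fractional grid
coordinates with clinically motivated extents: posterior/temporoparietal
for AD-like (~12% of brain volume), the same topography at reduced extent
for MCI-like (~7%, modelling prodromal-AD converters), occipital for
DLB-like (~6%), frontal for FTD-like (~8%). The labels are conventions,
not anatomy. Extents are chosen so that every simulated patient passes
the single-subject t-map confirmation step, mirroring the inclusion
criterion of the clinical cohort the generator emulates. Ages are drawn
from the configured normals and redrawn outside [20, 95].

Randomness is organized as one named substream per subject, derived from
(seed, SHA-256(subject id)), so a cohort is bit-reproducible subject-wise
regardless of generation order.

What the generator does *not* emulate: scanner physics, attenuation and
scatter, anatomical heterogeneity, age-dependent metabolism, overlapping
or diffuse disease patterns, or multi-centre batch effects. Passing tests
on this cohort therefore demonstrate that the pipeline's machinery is
correct and that the design separates groups under its stated effect
sizes; they say nothing about accuracy on clinical data.

### Desk scale

`GeneratorConfig.desk_scale()` halves the grid (40×48×35 at 4 mm voxels);
region specifications are fractional, so geometry is preserved. The
reduced resolution is what the worked examples, the acceptance script and
the end-to-end tests use; it keeps a full 210-subject two-arm run within a
few minutes on one CPU while preserving cohort size, effect size and noise
level.

## Preprocessing

Global-mean scaling divides the whole volume by its in-mask mean over the
target (default 1.0); any positive target is equivalent downstream because
features are computed after min–max discretization or from scale-free
statistics. Smoothing is separable Gaussian with σ = FWHM/(2√(2 ln 2))
per axis in voxel units and reflect boundary handling (a documented
choice; the boundary rule only affects voxels within ~2 FWHM of the array
edge, which lie outside the brain mask here).

## Single-subject t-maps

A patient volume is compared against the control set by per-voxel OLS of
intensity on [intercept, patient indicator, age], df = (n_controls+1) − 3.
The patient-indicator t is negative for hypometabolism. Voxels with zero
residual variance are flagged and forced to t = 0. Thresholding uses
uncorrected two-sided p (default 0.01) with a direction flag, followed by
connected-component labelling (18-connectivity by default, 6/26
available) and a strict extent rule: only clusters with **more than**
`min_extent` voxels (default 100) survive. Type-I calibration under pure
noise and agreement with a flood-fill oracle are asserted in the tests.
The `tmap_qc` pipeline stage automates the reader-review step: it reports
the fraction of patients with at least one supra-extent hypometabolic
cluster overlapping their own pattern region.

## Radiomics

Intensities are discretized with the fixed-bin-number rule over the
in-mask [min, max] into 32 bins (top value clamped into bin 32). The
feature vector has exactly 215 entries in a versioned manifest order:

- **79 first-order features**: 18 voxel-based morphology (volume, surface
  from exposed faces, compactness family, PCA axes, bounding-box density,
  integrated intensity, …), 2 local-intensity peaks (spherical ~1 cm³
  neighborhood), 22 intensity statistics (population moments, percentiles,
  dispersion measures, energy/RMS/sum), 26 intensity-histogram statistics
  on the 32-bin histogram (including mode, entropy, uniformity and the
  four histogram-gradient features), and 11 intensity-volume-histogram
  features (V₁₀…V₉₀, I₁₀…I₉₀, AUC). Morphology features are constant
  across subjects that share the template mask — intentional, mirroring
  the whole-brain VOI design — and are eliminated naturally during
  selection.
- **136 texture features** from six families. GLCM (25 features) and
  GLRLM (16) are directional and appear under two aggregations: *merged*
  (counts pooled over the 13 unique 3D directions into one matrix) and
  *averaged* (features computed per direction, then averaged), giving
  50 + 32; GLSZM (16), GLDZM (16), NGLDM (17) and NGTDM (5) are
  direction-free. 50+32+16+16+17+5 = 136.

Definitions follow the IBSI formulations with base-2 logarithms. Specific
conventions, all documented in code: zones use 26-connectivity; GLDZM
distance is city-block distance to the nearest out-of-mask voxel with
border voxels at distance 1 (array boundary counts as outside); the NGLDM
dependence criterion is |level difference| ≤ α (default α = 0) within
Chebyshev distance δ = 1 (26 neighbors), and the stored dependence count
is j = (number of dependent neighbors) + 1 so that features dividing by j²
are always defined; NGTDM coarseness is capped at 10⁶ when its
denominator vanishes; degenerate features (e.g. busyness with one occupied
gray level, GLCM correlation at zero variance) are NaN, reported rather
than dropped.

Every matrix builder is verified against an exhaustive brute-force
enumeration oracle (pair counting, maximal-run enumeration, flood-fill
zones, BFS distance maps, per-voxel neighbor counts and means) on random
fixtures up to 7×7×7, and the NGLDM features against the worked 2×2×1
example (DN = 2.5, LDLGLE = 0.145833…).

## Feature selection

MRMR uses the greedy mutual-information-quotient rule: first pick by
maximal MI with the label; thereafter maximize relevance / mean MI with
the already-picked set. MI is estimated on 4-bin quantile-discretized
features; ties break by manifest order, so rankings are deterministic.
Selection keeps the top 10% of the 215-entry manifest (= 21 features),
then prunes greedily in rank order, keeping a feature only if its
absolute Pearson correlation with every kept feature is strictly below
0.30. The kept set's correlation matrix is emitted as a certificate and
re-asserted on every run. Features with NaN in any subject are dropped
before ranking and reported. Selection statistics are computed on the
training portion only (the shared test subjects are excluded), to avoid
leakage; a flag allows the whole-cohort variant.

On the strongly separable synthetic cohort most top-ranked features load
on the same group contrast, so pruning typically retains very few
features (often one to three) — more aggressive than the four survivors
seen on clinical data, where feature redundancy is lower.

## Classification

The shared test set is 10 controls + 10 patients drawn stratified from the
cohort; both arms score exactly these subjects. The radiomics arm z-scores
features with training-set mean and sample SD (ddof = 1) — parameters are
never re-fitted on validation or test data — and trains a 16/8 ReLU
multilayer perceptron (scikit-learn, Adam, fixed random state). The image
arm trains the in-package numpy CNN: three blocks of 3×3×3 convolution /
batch normalization / ReLU / 2×2×2 max-pool with 8/16/32 channels, then
dense 64 → 2 with softmax; inputs are trilinearly resampled to 32³ and
standardized by training-set statistics; optimization is Adam (lr 10⁻³,
batch 16, ≤ 20 epochs) with early stopping on validation loss (patience 4,
best-validation weights restored). All layers carry numerical gradient
checks in the test suite. Scores are the winning-class posterior on a
0–100 scale; the two class scores sum to 100 and the prediction is the
class with score ≥ 50.

## Score comparison

Per true group, each model's scores are summarized (mean, sample SD) and
compared by a *paired* two-tailed Student's t-test on per-subject
differences (t = mean(d)/(SD(d)/√n), df = n − 1). The paired form is used
because both models score the same subjects; on the packaged reference
score table (20 held-out subjects scored by both arms) it reproduces the
published-style report: control group 98.05 ± 2.08 vs 85.78 ± 5.95 with
p = 0.0004, dementia group 97.54 ± 2.98 vs 95.57 ± 3.92, not significant.
The implementation is closed-form and is checked against
`scipy.stats.ttest_rel` to 10⁻¹² on random inputs.

## Numerical and design choices

- Percentiles use linear interpolation; moments are population moments;
  summary SDs in score reports are sample SDs (these match the respective
  field conventions for feature definitions vs group summaries).
- Entropies use log₂ with 0·log 0 = 0.
- Seeds: a single global seed derives per-stage and per-subject named
  substreams (SeedSequence with fixed keys); identical configuration ⇒
  bit-identical volumes, tables and run-manifest hashes.
- The pipeline writes NIfTI-1 volumes, CSV tables, YAML configuration and
  a JSON manifest of SHA-256 artifact hashes; voxel indices are 0-based
  everywhere.

## Known limitations

- The ellipsoidal brain mask and pattern regions make morphology features
  degenerate by construction and ignore gyral anatomy.
- The synthetic effect (a uniform multiplicative drop in a compact
  region) is far cleaner than clinical hypometabolism; 100% test accuracy
  on this cohort is expected by design and is a machinery check, not a
  clinical claim.
- MI estimation with 4 quantile bins is coarse for small cohorts; the
  MRMR ranking is stable under the default conditions but the bin count
  is exposed for sensitivity analysis.
- The CNN is sized for desk-scale inputs; full-resolution 79×95×69
  training is supported but slow on one CPU.
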
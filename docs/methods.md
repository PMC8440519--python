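# Methods

This note documents the statistical procedures `concord` implements, the
choices made where the design was genuinely open, and what the synthetic
cohorts do and do not establish.

## Study design the pipeline assumes

A multi-site case-control comparison with three groups — healthy controls
(HC), schizophrenia patients (SZ) and autism patients (ASD) — where the two
patient groups are recruited by *different* datasets: SZ-recruiting datasets
contain HC+SZ, ASD-recruiting datasets contain HC+ASD. Measures arrive as
subject × feature matrices (network-voxel Z-scores, FNC edges, ROI-FC
edges, gray-matter voxels) with per-subject age, gender, site, dataset and
motion annotations.

## Quality screening

**fMRI.** The individual brain mask is the set of voxels of the first
volume whose intensity exceeds 0.9 × the whole-volume mean; the group mask
keeps voxels present in strictly more than 90% of individual masks. Each
subject's mask is Pearson-correlated with the group mask over the top ten
slices, the bottom ten slices, and the whole grid; inclusion requires
r > 0.75 / 0.55 / 0.8 respectively, plus maximum head motion under 3 mm
translation and 3° rotation and strictly more than 120 time points. After
screening, the group mask is recomputed once from the passing subjects —
one pass, not iterated to convergence, since a single recomputation already
removes the influence of excluded subjects and further iteration rarely
changes membership.

Open choices made here: slab correlations are computed on the binary
{0,1} mask values (the screen compares masks, not intensities); "top" and
"bottom" slices are taken along the third array axis (highest indices =
top) of the full grid, configurable via `slice_axis`; per-scan motion is
summarized as the maximum absolute translation/rotation. A slab in which
either mask is constant has no defined correlation and is reported as a
failure with reason "degenerate slab" rather than silently passed.

**sMRI.** The group mask keeps voxels of the group-mean image above 0.2,
and the correlations are computed on the *continuous* image values within
that mask (thresholds 0.6 / 0.6 / 0.8), because structural quality is about
intensity agreement, not support agreement.

## Harmonization

Three steps, in order:

1. **Within-dataset regression.** Per dataset, OLS of every feature on
   [intercept, age, gender, site dummies, age×site, gender×site]. Age is
   z-scored within dataset before interactions (collinearity); gender is
   coded {0,1}; aliased design columns are dropped greedily in declaration
   order, so a singleton site simply contributes no dummies. Residuals are
   returned with the dataset mean added back so that between-dataset
   offsets remain estimable.
2. **Dataset ("data") effects.** The per-dataset offset of a feature is the
   mean of the step-1 values over that dataset's HC subjects minus the grand
   HC mean. The grand mean is the unweighted mean of the per-dataset HC
   means, so offsets sum to zero across datasets. HC-only estimation is
   deliberate: patient-group composition differs across datasets, and an
   offset estimated from all subjects would absorb diagnosis effects.
   The estimator is a mean offset (not a slope or variance scaling) — the
   simplest choice that leaves patient-vs-control contrasts unbiased.
3. **Offset removal.** Every subject of a dataset, patients included, has
   the dataset's HC-derived offset subtracted.

The full procedure is idempotent to < 1e−8 and, on confound-balanced
cohorts, changes planted group contrasts only within sampling noise.

## Connectivity construction

Network time courses are post-processed in a fixed order before
correlation: per-network z-scoring, OLS removal of the six motion
regressors, linear detrending, de-spiking, and 0.01–0.15 Hz band-pass
filtering with a 5th-order zero-phase Butterworth filter (TR known, band
below Nyquist enforced). De-spiking replaces samples more than 4 MADs away
from a running median (window 7); the MAD is the series' own robust scale,
so smooth oscillations pass untouched while isolated excursions are pulled
to the local median. Pearson correlations are Fisher-z transformed
(`atanh`); |r| = 1 entries are clipped at atanh(0.999999) and flagged,
never dropped.

ROI connectivity averages voxel series within each atlas region
(unweighted), excludes regions whose representative series have variance
< 1e−6 and |mean| < 1e−6 in more than 90% of subjects (the thresholds are
package defaults; a flat representative series means the region lies
outside usable coverage), and mirrors the FNC handling — including the
Fisher transform — for the retained regions.

## Contrast engine

Described in the README. Additional conventions:

- Pairwise tests are pooled-variance (Student) *t*-tests — the classical
  two-sample default — with Welch available as an obvious extension point;
  zero pooled variance reports T = 0, p = 1 with a flag.
- Correction multiplicity is the number of features tested within one
  measure family (all FNC edges, all voxels of one analysis, ...).
- Categorization uses the *signs* of the uncorrected pairwise T-values
  among ANOVA-passing features; corrected pairwise significance flags are
  carried separately for map-style reporting. Strict inequalities
  throughout: an exact zero T yields no category, and T(SZ−ASD) = 0 is
  "not weaker".
- Gray-matter pairwise maps default to FDR at 0.05, with the α exposed
  because conventions for voxel-based morphometry vary (0.01 is common).
- Percentages are rounded half-up to one decimal, matching how such
  summary tables are printed.

## Resampling validation

**Permutation test.** All subjects of the two groups are rearranged into
two dummy groups of the original sizes; the empirical p of a feature is the
frequency, over permutations, with which the permuted two-sample p falls
*strictly below* the observed one. No +1 smoothing is applied to numerator
or denominator — the estimator is the plain frequency, so an empirical p of
exactly 0 is possible at finite permutation counts (1000 by default). An
exhaustive mode enumerates every distinct split for small groups and is the
exactness oracle for the sampled mode. Shuffling ignores dataset membership
by default; stratified shuffling is a reasonable alternative but changes
the null being tested, so it is left to the caller.

**Fisher's method.** Per-dataset two-sided p-values for one contrast are
combined as X² = −2 Σ ln p with 2k degrees of freedom; zeros are clipped to
the smallest positive float with a warning. The mean per-dataset T is
reported for features passing Bonferroni correction. For SZ-vs-ASD
contrasts every (SZ-dataset, ASD-dataset) pairing contributes one
comparison.

## Clinical association

Pearson and Spearman correlations between each measure and each symptom
score (PANSS positive/negative for SZ; ADOS total and SRS for ASD),
patients only, pairwise-complete over missing entries; a finding requires
p < 0.01 in *both* correlation types — a deliberately conservative dual
criterion. The chlorpromazine-equivalent (CPZ) analysis fits one linear
regression per measure with CPZ as the sole predictor — nuisance
covariates are already removed upstream, so no further predictors are
included — with Bonferroni at 0.05/m; ASD medication status is tested by
two-sample *t*-tests under the same correction.

## Classification

Feature selection *is* the categorization: the contrast engine runs on the
training datasets only (their HC subjects participate in categorization but
never in classifier training), and the classifier receives the union of
disorder-unique edges and ASD-weaker common edges. A linear SVM is trained
on the SZ/ASD patients of the training datasets, features z-scored by
train-set statistics. The regularization parameter C is tuned over
log₁₀ C ∈ [−3, 3] by Bayesian optimization — Gaussian-process surrogate
(Matérn ν = 2.5), expected-improvement acquisition, 5 random
initializations plus 15 guided evaluations, each scored by stratified
5-fold cross-validation on the training patients. ASD is the positive
class, so sensitivity is ASD recall and specificity SZ recall; metrics are
reported per split to one decimal and averaged to integer percent across
the 12 splits that four SZ-recruiting and two ASD-recruiting datasets
admit (choose 2 train SZ × choose 1 train ASD).

## Synthetic cohorts

The generator plants known structure so every stage can be scored against
ground truth:

- Features: value = N(0, 1) noise + dataset offset + site offset + age
  slope × z-age + gender shift + group shift. Offsets and slopes are drawn
  once per dataset/site/feature from N(0, sd²) with spec-level sds; noise
  sd defaults to 1 so planted magnitudes read as Cohen's d.
- Group shifts per planted effect of magnitude m: SZ moves by ±m according
  to the category's direction; ASD moves by λ·m in the same direction for
  common categories and the opposite direction for unique categories. The
  scale λ ∈ (0, 1] encodes the globally weaker ASD effect; with λ < 1
  every planted common effect is truly ASD-weaker.
- Time series: i.i.d.-in-time draws from per-group latent covariances whose
  planted edges move by `edge_scale` × shift on the Fisher-z scale around a
  base correlation (defaults 0.3 and 0.35) — so the time-series path and
  the direct-matrix path plant the same effects. Indefinite covariances
  from overlapping edges are repaired by eigenvalue clipping.
- Ages uniform on [16, 60]; two sites per dataset; motion summaries with a
  configurable outlier fraction above 3 mm; QC volumes share an ellipsoidal
  support with sub-voxel jitter, while "bad" volumes are translated by half
  the grid or truncated along the slice axis.
- Symptom scores are linear in chosen features plus Gaussian noise,
  patients only.

What the generator does *not* emulate: hemodynamics, temporal and spatial
autocorrelation of real fMRI, scanner-specific artifacts, non-Gaussian
tails, or site-by-diagnosis interactions. Passing tests therefore establish
the statistical machinery — calibration, recovery, leakage-freedom,
arithmetic — not robustness to those real-data features.

## Problem sizes used in validation

The standard validation cohort has 4 SZ-recruiting + 2 ASD-recruiting
datasets, 150 subjects per group per dataset (1800 subjects), 200 FNC-edge
features, 30 planted effects at d = 0.8 with λ = 0.5, site sd 0.4, age
slope sd 0.2, gender shift sd 0.1. Null calibration uses 2000 features at
n = 100/group; permutation uniformity uses 200 features, 30 + 30 subjects,
1000 permutations. These sizes give the recovery and calibration checks
comfortable statistical resolution while keeping the whole validation run
in the seconds-to-minutes range.

## Known limitations

- The ANOVA gate and pairwise tests assume homoscedastic Gaussian
  features; heavy-tailed measures would need the Welch/rank alternatives.
- The permutation scheme is unstratified and not covariate-aware
  (no Freedman–Lane); it validates the *t*-test's null, not a
  confound-adjusted one.
- ComBat-style empirical-Bayes harmonization is intentionally out of
  scope; the three-step regression matches the plain-regression design
  the pipeline targets.
- Dynamic (windowed) connectivity and spatial-network estimation itself
  (the ICA stage producing Z-maps and time courses) are inputs, not parts
  of this package.
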
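# Methods

This note records the mathematical conventions, parameter choices and known
limitations of the `accowave` pipeline in enough detail to re-derive every
number the package produces.

## 1. Zernike conventions

- Modes: radial orders n = 2–6, all azimuthal frequencies m, giving 25 modes.
  Piston, tip and tilt (n ≤ 1) are excluded throughout.
- Indexing: OSA/ANSI single index j = (n(n+2) + m) / 2. Within the package,
  modes are stored in ascending j, i.e. (2,−2), (2,0), (2,2), (3,−3), …
- Normalization: unit-variance (Noll) factors N(n,m) = sqrt(2(n+1)/(1+δ_{m0})),
  so the RMS wavefront error is the Euclidean norm of the coefficient vector.
- Units: coefficients in µm; pupil diameters in mm; accommodative demand in
  diopters (D).
- Laterality: all analyses are in the right-eye convention. A left-eye
  measurement is mirrored (θ → π − θ), which flips the sign of c(n,m) exactly
  when (m < 0 and m even) or (m > 0 and m odd); magnitudes are unchanged.

## 2. Pupil rescaling

Coefficients measured over a natural pupil of diameter D are re-expressed over
a smaller concentric pupil of diameter D′ (ratio ρ = D′/D ≤ 1) by exact
analytic re-expansion: within each azimuthal family m, the radial polynomials
are expanded in monomials, the argument is scaled by ρ, and the result is
re-projected onto the radial polynomials by solving the triangular monomial
system. The transform is linear, block-lower-triangular in n (power cascades
from high to low orders, e.g. spherical aberration feeds defocus), and is
built once per (D, D′) pair (`build_rescale_matrix`), with induced piston/tilt
terms dropped since n ≤ 1 is outside the model. Correctness is checked in the
test suite against an independent dense least-squares refit of the wavefront
on the sub-pupil (agreement < 1e-8).

## 3. Cohort preprocessing

- Standard pupils: per demand, the 5th percentile of natural pupil diameters
  (linear-interpolation quantile). Defaults (mm): 0 D 4.66, 1 D 4.76, 2 D 4.40,
  3 D 4.09, 4 D 4.07, 5 D 3.68. A warning is raised when the percentile is
  estimated from fewer than 20 subjects.
- Exclusion: a measurement whose natural pupil is smaller than the standard
  pupil cannot be rescaled (extrapolation) and is flagged; a subject with more
  than two flagged demands is dropped. Both actions are written to a log.
- Imputation: remaining flagged cells are filled with the column mean of the
  assembled matrix (per parameter, over retained subjects).
- Matrix layout: rows = subjects, columns = 150 parameters in demand-major
  order, column d·25 + p labeled `d{d}_c_{n}_{m}`.

## 4. Eigen-wavefront reduction

PCA is performed on the covariance matrix of the 150-parameter matrix
(denominator N − 1, symmetric eigendecomposition). Eigenvectors are sorted by
descending eigenvalue; each is sign-normalized so its largest-magnitude
loading is positive. The retained rank K is the smallest K whose cumulative
explained variance reaches the cutoff (default 0.9997; a 1e-12 tolerance
absorbs floating-point rounding at the threshold). With the default 191-subject
simulated cohort K ≈ 31, a ≈79% reduction; any K ≤ 51 meets the ≥66% reduction
the method is designed around.

Eigenvector *composition* summarizes each eigen-wavefront as the share of its
RMS carried by each Zernike mode, pooled over the six demands; the largest
share is the eigenvector's *fundamental mode*, flagged "dominant" when it
exceeds 40%.

## 5. Two-component Gaussian mixture and EM

The retained scores (N × K) are modeled as a 2-component full-covariance
Gaussian mixture fitted by a hand-written EM:

- Initialization: k-means++-style responsibility seeding, softened
  (0.9·r + 0.05) to avoid hard assignments; 5 random restarts (default),
  best log-likelihood kept.
- Regularization: ridge 1e-6 × mean score variance added to covariance
  diagonals; a component collapsing to fewer than K + 1 effective members
  triggers a restart.
- Convergence: relative log-likelihood change < 1e-8, max 500 iterations.
- Fixed-point property: at any EM fixed point the mixture's pooled mean and
  pooled second moment equal the sample's exactly; generated cohorts therefore
  reproduce the *sample* means of the source cohort up to sampling noise of
  order SD/√n_generated.

Sampling uses a seeded `numpy.random.Generator`: component choice by weight,
then `multivariate_normal` (Cholesky, with SVD fallback for semi-definite
covariances). Sampled scores are mapped back as x = mean + E·s.

## 6. Equivalence validation

For each parameter (150 Zernike parameters; separately, the K retained scores):

- KS normality: Kolmogorov–Smirnov test of the generated sample against a
  normal with the generated sample's own mean/SD. Declared normal when
  p ≥ α/m (Bonferroni within family).
- TOST mean equivalence: two one-sided Welch t-tests against the margin
  δ = 0.2 × SD of the original parameter; TOST p = max of the two one-sided
  p-values; equivalent when p < α at the **unadjusted** level. Rationale: the
  two one-sided tests already make TOST conservative, and Bonferroni-adjusting
  an equivalence test *reduces* power in the direction that favors claiming a
  difference, the safe direction here; with n = 191 vs 1000 and δ = 0.2 SD, a
  Bonferroni-adjusted TOST (α/150) is mathematically impossible to pass
  (δ/SE ≈ 2.5 < t-quantile ≈ 3.5) regardless of the data, so the adjusted rule
  carries no information. Bonferroni is applied to the KS and F families.
- F-test variance equality: two-sided p = 2·min(tail probabilities) of the
  variance ratio, capped at 1; equal when p ≥ α/m.

Zero-variance parameters are reported with a warning and fail by convention.

## 7. Built-in reference population

`generate_population` simulates a plausible clinical cohort for development
and testing: per-mode marginal means/SDs at each demand for the seven
clinically dominant modes (defocus, the two astigmatisms, the two comas,
trefoil, spherical aberration and c(6,0)) taken from published accommodative
statistics, with unlisted high-order modes given small SDs
(0.01·0.7^(n−4) µm); within-mode correlation across demands r = 0.9, zero
cross-mode correlation (repaired to the nearest positive-semidefinite matrix
by eigenvalue clipping when needed); natural pupils normal around the standard
pupil + 1.6449·0.45 mm (so ≈5% of cells fall below the standard pupil),
SD 0.45 mm, floor 2.0 mm; laterality assigned 50/50 with LE rows mirrored.

This emulates the *marginal and within-mode longitudinal* structure of an
accommodating adult cohort. It does **not** emulate cross-mode correlations
(e.g. defocus–spherical-aberration coupling during accommodation), age
structure, or measurement noise; conclusions about such couplings should not
be drawn from the simulated cohort.

## 8. Default problem sizes

| quantity | default |
|---|---|
| source cohort | 191 subjects |
| parameters | 150 (25 modes × 6 demands) |
| PCA cutoff | 0.9997 → K ≈ 31 (simulated cohort) |
| mixture components | 2 |
| EM restarts / tol / max iter | 5 / 1e-8 / 500 |
| generated subjects | 1000 |
| α / TOST margin | 0.05 / 0.2 SD |

A full default pipeline run takes a few seconds on one CPU core.

## 9. Known limitations

- **High-order variance compression.** The 99.97% cutoff discards entire
  eigen-directions aligned with tiny high-order modes, so generated SDs for
  radial orders ≥ 4 can be 45–75% of the source SDs and their F-tests fail
  even though the means are equivalent. This is intrinsic to the truncation,
  not an estimation error; raising the cutoff (or K) trades compression for
  variance fidelity.
- TOST equivalence is relative to the chosen margin (0.2 SD); parameters with
  near-zero SD have near-zero margins and can fail on numerically trivial
  differences.
- The concentric rescaling assumes the pupil shrinks about the same center;
  pupil decentration during accommodation is not modeled.
- Column-mean imputation slightly shrinks variances when many cells are
  excluded; the exclusion log should be inspected for cohorts with small
  pupils.
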
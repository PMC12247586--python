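# Methods

## Model and assumptions

The pipeline assumes that a white-matter region's functional
connectivity to the rest of the brain changes *smoothly* across the
region — a connectopy — and that this spatial change is the object of
interest, not the connectivity values themselves.  Gradients are
estimated nonparametrically as Laplacian-eigenmap coordinates of an
η²-similarity graph over voxels.  The method is therefore sensitive to
whatever dominates fingerprint variation; it does not assume any
particular relation between connectivity and anatomy, but when
fingerprint change per millimetre is roughly isotropic the gradients
track the region's own spatial axes (see *Phantom* below — this is the
regime the method's validation logic presumes, and what the geometric
checks in `geometry` are designed to detect).

Key modeling commitments:

- **η² similarity** between Fisher-z fingerprint rows, computed exactly
  (the vectorized form is algebraically identical to the defining sums
  of squares; tests verify against a literal loop).  η² of a pair of
  profiles is always in [0, 1]: `SS_within − SS_total = −C_ab −
  (SS_a + SS_b)/2 ≤ 0` by Cauchy–Schwarz.
- **Minimal-ε connected sparsification.** Similarities map to chord
  distances `d = √(2(1−S))` (the Euclidean distance between unit-norm
  points with inner product S).  Edges with `d ≤ ε` are kept with
  weight `S`; ε is the largest edge of a minimum spanning tree of the
  distance graph — exactly the smallest threshold that leaves one
  connected component, found without a scan.  A rule that instead
  *zeroed* weights at distances below ε would delete the strongest
  edges and can never produce a connected sparse graph at a minimal
  threshold; we implement the standard ε-neighborhood convention.
- **Unnormalized Laplacian** `L = D − W` with weighted node strengths.
  On every connected graph the smallest eigenvalue is 0 with a constant
  eigenvector; both facts are asserted at run time (tolerance 1e−8)
  before the mode is discarded.
- **Variance explained** has no canonical definition for Laplacian
  eigenmaps.  We report each retained gradient's `1/λ` share of the sum
  of `1/λ` over all nonzero eigenvalues: small eigenvalues are the
  smoothest, most dominant modes, and `1/λ` is each mode's variance
  share under the graph diffusion interpretation.  An alternative
  (`variance_mode="embedding"`) normalizes over the retained modes
  only.  These fractions are internally consistent but not comparable
  across graph constructions, and printed percentages from any
  particular dataset are not a validation surface.

## Pipeline stages and parameters

| Stage | Parameter | Default | Why |
|---|---|---|---|
| detrend | — | always on | removes scanner drift (per-voxel OLS line) |
| nuisance | confounds | 24-param motion + CSF | standard expansion; computed from 6 columns if needed |
| task removal | HRF peak/undershoot/ratio | 6 s / 16 s / 6 | canonical double-gamma; configurable |
| smoothing | FWHM | 4 mm (white matter), 0 (parcels) | within-mask, kernel renormalized over in-mask neighbors; the dominant SNR rescue for white-matter BOLD |
| denoising | on/off | on | Marchenko–Pastur bulk-edge shrinkage of covariance eigenvalues, per subject over all voxels |
| z-score | — | per run, then concatenate | makes runs commensurate |
| basis | components | T−1 | full PCA basis of gray-matter data; rank-deficient tail zero-padded |
| eigenmaps | k | 3 | principal/second/third gradients |
| solver | method | dense < 2000 nodes, else shift-invert Lanczos (tol 1e−10) | dual routes cross-checked in tests |
| segments | n | 5 | equal spacing between extreme projections; boundary voxels to the lower segment |
| k-means | k, restarts | 3 and 7, 50 restarts | 1-D clustering of the principal gradient; labels ordered by centroid |
| permutation | n_perm | 1,000 | label-shuffle null for matched mean Dice; p = (1+#{null ≥ obs})/(n_perm+1) |
| FWE | method | Bonferroni | conservative and assumption-free at these family sizes |

Temporal filtering is deliberately absent from the chain.  The order is
detrend → nuisance → task removal → smoothing → denoising → z-score →
concatenate; regression-based stages commute in their effect on later
correlations, and whether task removal precedes or follows denoising is
exposed through the stage functions rather than fixed by a wrapper.

The Marchenko–Pastur filter estimates the noise level σ² iteratively as
the mean of eigenvalues below the current bulk edge σ²(1+√γ)², γ = V/T
(the MP distribution has mean σ², and planted above-bulk components
must not inflate the estimate), then shrinks each covariance eigenvalue
to max(λ − edge, 0).  Pure-noise input is attenuated to a few percent
of its variance; noiseless low-rank input passes through essentially
unchanged (per-voxel r ≥ 0.99 in tests).

Statistical choices: adjacent-segment contrasts use two-sample Wilcoxon
rank-sum on voxel values with Bonferroni over the 4 adjacent pairs
(voxels-as-units is the conservative reading; a subject-level mode can
be built from per-subject gradients, which are exposed but estimated
per scan).  Steiger's test for two dependent correlations sharing one
variable uses the Fisher-z statistic with the pooled-correlation
covariance (r̄ = (r1+r2)/2); the test suite verifies agreement with an
independently coded published rearrangement to 1e−6 and a simulated
type-I error of 5% ± 2% at n = 200.  Voxelwise behavior correlations
are deliberately uncorrected — the analysis reads the correlation
landscape as a whole, and the cross-condition test operates on |r| with
voxels as paired units.

## The phantom

`wmgrad.phantom` generates scenes with complete ground truth:

- **Geometry.** An arch: an elliptical cross-section swept along the
  posterior-anterior (y) axis with height `A·sin(πt)`, `A = 0.4 ×`
  length — tall and thin, like a mid-sagittal corpus callosum.  The
  sine is symmetric in t, so arch height is linearly uncorrelated with
  position along the long axis, and the SVD of voxel coordinates
  returns PA/DV/LR axes in that order.  Voxels are 2 mm isotropic on an
  RAS-like grid; parcels with centroid x < 0 are "left".
- **Mixing.** Each planted axis *a* contributes a pair of latent
  networks whose weights trace a quarter-circle arc of radius `s_a`
  as the voxel's axis position goes 0→1:
  `(s_a cos(π/2·u_a), s_a sin(π/2·u_a))`; a seventh constant background
  network keeps every voxel a blend.  Because each pair contributes
  `s_a²` to the squared norm at every position, the raw vector has
  constant norm, and since correlations see only the *direction* of the
  mixture, the fingerprint manifold is an exact flat product of arcs
  with per-axis lengths `(π/2)s_a` — the connectivity-change speed per
  unit axis position is set purely by the strengths.  Simplex weights
  (non-negative, summing to 1) are recovered by L1 normalization, which
  does not change the direction.  We chose this construction over
  kernel-bump mixtures after finding that bump schemes produce saturated
  plateaus and Fisher-z blow-ups near pure-network voxels, warping the
  manifold enough to scramble the eigenmode order even without noise.
- **Default strengths (1.0, 0.55, 0.33)** are proportional to the
  arch's spatial extents, making fingerprint change per millimetre
  isotropic: the similarity graph is then an isometric copy of the
  region, the principal gradient runs along the arch, and the second
  eigenmode — `cos(2πt) = 1 − 2sin²(πt)`, an exact monotone function of
  arch height — tracks the dorsal-ventral axis.  This is the mechanism
  by which an arched structure's second connectivity gradient aligns
  with its height axis, and it is why the phantom's second gradient is
  recoverable at all: a transverse axis much weaker than ~half the
  primary one is overtaken by the primary axis's second harmonic.
- **Noise.** Stationary AR(1) Gaussian (default coefficient 0.3,
  sd 0.5), independent across voxels — the simplest model of the
  autocorrelated noise the cleaning chain targets.  Default scene:
  ~1,500 white-matter voxels, 40 parcels × 10 voxels, T = 400.
- **Couplings.** FA couples to the dorsal-ventral axis and MWF to the
  posterior-anterior axis (defaults ρ = 0.3 and 0.5), each built as
  `ρ·standardized(u) + √(1−ρ²)·noise` mapped onto plausible intensity
  scales (FA 0.55 ± 0.12 clipped to [0, 1]; MWF 0.15 ± 0.04) — an
  affine map, so planted correlations are preserved.  Behavior: each
  subject's wm→cortex coupling is `base + effect·trait + noise`, and
  subdomain scores are noisy copies of the trait, so the first
  principal component of scores recovers it.

What the phantom does **not** emulate: hemodynamics and task-evoked
structure (task regressors are exercised on constructed series, not
"evoked" phantoms), head motion and scanner artifacts, spatially
correlated physiological noise, inter-subject anatomical variability,
and any realistic cortical topography.  Passing tests therefore show
that the estimator chain recovers the statistical structure it targets
at realistic SNR — not that real white-matter BOLD contains that
structure.  With 40 parcels over 7 networks the two hemispheres differ
slightly in network composition (6/6/6/6/6/5/5), which produces a
small genuine laterality; analyses that need an exactly null laterality
(e.g. the cohort driver) use 42 parcels.

## Numerical choices

- Fisher transform: correlations clipped to ±(1 − 1e−7) before atanh.
- "Same grid" affine tolerance: 1e−6 max elementwise difference.
- Probabilistic masks binarize at > 0.5.
- Canonical voxel order: lexicographic on (i, j, k); every per-voxel
  vector in the package is keyed to it, so shuffled input ordering
  cannot misalign gradients against structural maps.
- Constant-column detection uses exact peak-to-peak zero, not a
  floating std threshold.
- k-means ties and label order: labels are re-indexed by ascending
  cluster centroid; the test oracle is exhaustive optimal 1-D
  partitioning.
- Degenerate (repeated) Laplacian eigenvalues set a `degenerate` flag:
  the individual gradients are then identifiable only up to rotation.
- Segment boundaries: `searchsorted(..., side="left")`, so a voxel
  exactly on a hyperplane joins the lower segment.
- Quintile ROIs: average ranks within ties, bin = ceil(rank·5/V) —
  deterministic and invariant under monotone transforms.

## Problem sizes

Unit tests run a ~300-voxel scene at T = 200; end-to-end recovery,
calibration and reliability checks use the default ~1,500-voxel scene
at T = 400 with 200-replicate (Dice) and 2,000-replicate (Steiger)
calibrations, sizes at which the Monte-Carlo tolerances quoted in the
tests are meaningful.  The acceptance script uses the same sizes.

## Known limitations

- Per-scan (single-subject) gradients are stable on the phantom at the
  default SNR, but the group path (averaging η² matrices before graph
  construction) is the supported design; individual-level gradients on
  real data should be treated as experimental.
- The minimal-ε graph is fragile by construction (it is one edge away
  from disconnection); results near the connectivity threshold depend
  on the noise realization through ε.  The sparsifier records ε in its
  output for auditing.
- Variance-explained fractions depend on the full Laplacian spectrum;
  above the dense-solver limit the sparse path normalizes over the
  retained modes only and logs the approximation.
- The behavior module's per-voxel PCA treats parcels as exchangeable
  features; spatially structured FC noise (absent in the phantom) would
  make the latent less interpretable.
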
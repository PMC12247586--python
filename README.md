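# wmgrad — functional-connectivity gradients of white matter

`wmgrad` maps the smooth spatial organization ("gradients" or
connectopies) of functional connectivity inside a white-matter voxel
region — the motivating case is the corpus callosum — from BOLD fMRI,
and validates those gradients against the region's geometry, atlas
partitions, cortical connectivity profiles, behavior, and white-matter
microstructure (FA, myelin water fraction).  It is written for
neuroimaging researchers who want a tested, fully synthetic-data-backed
implementation of connectopic mapping for white matter: every stage of
the pipeline can be exercised on a built-in phantom with known ground
truth, with no data download.

## The method

For a white-matter region with `N_c` voxels and a gray-matter signal
matrix of `T` frames by `N_g` voxels:

1. **Fingerprints.** The gray-matter data is reduced by PCA to a
   `T × (T−1)` component basis; each white-matter voxel's time course is
   Pearson-correlated with every component and Fisher z-transformed,
   giving an `N_c × (T−1)` connectional-fingerprint matrix.
2. **Similarity.** Fingerprint similarity between voxels *v, w* is the
   η² coefficient: with per-position pair means `m_i = (a_i + b_i)/2`
   and their grand mean `M̄`,

       η² = 1 − SS_within / SS_total,
       SS_within = Σ_i (a_i−m_i)² + (b_i−m_i)²,
       SS_total  = Σ_i (a_i−M̄)² + (b_i−M̄)²,

   yielding a symmetric `N_c × N_c` matrix `S` (averaged across
   subjects at the group level).
3. **Graph.** Similarities map to chord distances `d = √(2(1−S))`; the
   ε-neighborhood graph keeps edges with `d ≤ ε`, weighted by `S`, at
   the smallest ε producing one connected component (the largest edge
   of a minimum spanning tree).
4. **Eigenmaps.** The graph Laplacian `L = D − W` (D = diagonal node
   strengths) is eigendecomposed.  The zero-eigenvalue constant mode is
   discarded; the eigenvectors of the next smallest eigenvalues are the
   principal, second, and third gradients.

Downstream modules segment the region along its SVD spatial axes and
test gradient monotonicity, cluster the principal gradient with k-means
and score it against an atlas by optimally-matched mean Dice with a
permutation null, profile gradient-quintile ROIs against a cortical
parcellation (Fisher-z FC, network and hemisphere summaries, condition
contrasts), correlate per-voxel connectivity latents with behavior
composites, couple gradients to FA/MWF with Steiger comparisons of
dependent correlations, and measure cross-scan spatial reliability.

## Worked example

The numbered drivers under `analysis/` run the whole study on the
synthetic phantom (an arch-shaped ~1,500-voxel region whose
connectivity fingerprints drift smoothly along planted
posterior-anterior, dorsal-ventral and left-right axes, plus AR(1)
noise at sd 0.5):

```bash
python analysis/01_simulate_phantom.py
python analysis/02_map_gradients.py
```

`02_map_gradients.py` prints:

```
minimal connected epsilon: 0.0358
 gradient  eigenvalue  variance_explained  spearman_u1  spearman_u2  spearman_u3
        1       0.005               0.290        0.996        0.002        0.007
        2       0.018               0.082        0.129        0.947       -0.035
        3       0.042               0.036        0.022        0.109        0.015
```

The principal gradient recovers the planted posterior-anterior axis
(|ρ| = 0.996) and the second gradient the dorsal-ventral axis
(|ρ| = 0.947); variance-explained fractions are inverse-eigenvalue
shares.  `03_validate_geometry.py` then reports monotone segment
profiles, k-means/atlas overlap (mean Dice 0.83 at k=3 and 0.75 at
k=7, permutation p = 0.001), and a peak-distance correlation of
r = −0.980.  `06_structure_reliability.py` recovers the planted
microstructural couplings — FA correlates with gradient 2 (r = 0.28)
but not gradient 1 (r = 0.01), MWF with gradient 1 (r = 0.51) but not
gradient 2 (r = 0.03), Steiger z = −7.4 / 14.2 — and cross-scan
reliabilities of 0.99 / 0.99 / 0.97 for the three gradients.

In library form:

```python
import wmgrad as w
from wmgrad import preprocess as pp

scene = w.make_scene(n_wm_voxels=1500, n_parcels=40, seed=1)
gm, wm = w.simulate_bold(scene, t_frames=400, noise_sd=0.5, ar1=0.3, seed=2)
gm = pp.preprocess_run(gm, fwhm=0.0, wishart=True)
wm = pp.preprocess_run(wm, fwhm=4.0, wishart=True)
fingerprints = w.fingerprints(wm, w.gm_pca_basis(gm))
graph = w.sparsify_connected(w.similarity_matrix(fingerprints))
gradients = w.laplacian_eigenmaps(graph, k=3, region=scene.wm_region)
```

Real data enters the same way: load NIfTI volumes with
`wmgrad.regions.load_volume`, build `VoxelRegion`/`BoldSeries` objects,
and run the identical chain.

## Layout

- `src/wmgrad/` — the library: `regions` (volumes, masks, ordering),
  `phantom` (synthetic scenes), `preprocess` (signal cleaning),
  `gradients` (the connectopic-mapping core), `geometry` (axis/atlas
  validation), `profiles` (quintile-ROI connectivity), `association`
  (behavior, microstructure, reliability), `pipeline` (orchestration).
- `analysis/` — numbered narrative drivers writing tables to `results/`.
- `tests/` — the pytest suite, including end-to-end recovery and
  calibration checks in `tests/test_acceptance.py`.
- `docs/methods.md` — the methods note.
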
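"""Connectopic mapping core: fingerprints, eta-squared, Laplacian eigenmaps.

The pipeline maps smooth modes of functional-connectivity change across a
white-matter voxel region:

1. the gray-matter data (T x N_g) is reduced to a T x (T-1) PCA basis;
2. each white-matter voxel's signal is Pearson-correlated with every
   basis component and Fisher z-transformed, giving an N_c x (T-1)
   connectivity fingerprint per voxel;
3. fingerprint similarity between voxel pairs is the eta-squared
   coefficient, yielding a symmetric N_c x N_c matrix S (averaged across
   subjects at the group level);
4. S is sparsified at the smallest epsilon-neighborhood (chord distance
   d = sqrt(2(1-S))) that keeps the graph connected, retained edges
   weighted by similarity;
5. the graph Laplacian L = D - W is eigendecomposed; the constant
   zero-eigenvalue mode is discarded and the eigenvectors of the next
   smallest eigenvalues are the gradients (principal = 2nd smallest).

Variance explained is reported as each gradient's inverse-eigenvalue
share over all nonzero eigenvalues (alternative: embedding-variance
share), since small Laplacian eigenvalues correspond to the smoothest,
most dominant modes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree

from wmgrad.regions import BoldSeries, VoxelRegion

logger = logging.getLogger(__name__)

#: correlations are clipped to +/- (1 - FISHER_CLIP) before atanh
FISHER_CLIP = 1e-7

#: dense eigendecomposition below this node count, sparse shift-invert above
DENSE_EIG_LIMIT = 2000

_EIG_TOL = 1e-10


@dataclass
class FingerprintMatrix:
    """Per-voxel connectivity fingerprints in the gray-matter PCA space.

    ``z[v, c]`` is the Fisher-z correlation between white-matter voxel v
    (region order) and basis component c.
    """

    z: np.ndarray
    region: VoxelRegion
    n_components: int

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        if not np.all(np.isfinite(self.z)):
            raise ValueError("fingerprints contain non-finite entries")
        if self.z.shape[0] != self.region.n_voxels:
            raise ValueError("fingerprint rows must match region voxels")


@dataclass
class SimilarityGraph:
    """Eta-squared similarity matrix and its sparsified adjacency."""

    similarity: np.ndarray               # (N, N) symmetric, unit diagonal
    adjacency: sp.csr_matrix | None = None
    epsilon: float | None = None
    connected: bool = False

    @property
    def n_nodes(self) -> int:
        return self.similarity.shape[0]


@dataclass
class GradientSet:
    """Gradients (Laplacian eigenvectors) with eigenvalues and variance shares.

    ``gradients[:, j]`` is the j-th gradient (j=0 is the principal one —
    the eigenvector of the second-smallest Laplacian eigenvalue).
    ``eigenvalues`` are the corresponding nonzero eigenvalues, ascending.
    """

    gradients: np.ndarray                # (N, K), unit-norm columns
    eigenvalues: np.ndarray              # (K,)
    variance_explained: np.ndarray       # (K,) fractions in [0, 1]
    region: VoxelRegion | None = None
    condition: str = ""
    degenerate: bool = False             # repeated eigenvalues: not identifiable

    @property
    def n_gradients(self) -> int:
        return self.gradients.shape[1]


def gm_pca_basis(gm_series: BoldSeries) -> np.ndarray:
    """Principal-component time courses of the gray-matter data.

    Reduces the T x N_g gray-matter matrix to a T x (T-1) component
    matrix, columns ordered by decreasing variance.  If the data rank is
    below T-1 the zero-variance tail is zero-padded (and logged).
    """
    data = gm_series.data
    t_frames, n_gm = data.shape
    if t_frames < 3:
        raise ValueError("need at least 3 frames for a PCA basis")
    if n_gm < 2:
        raise ValueError("need at least 2 gray-matter voxels")
    centered = data - data.mean(axis=0)
    # left singular vectors scaled by singular values = component scores
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    scores = u * s
    n_keep = min(t_frames - 1, scores.shape[1])
    basis = np.zeros((t_frames, t_frames - 1))
    nonzero = s[:n_keep] > s[0] * 1e-12 if s.size else np.zeros(0, bool)
    rank = int(np.sum(nonzero))
    basis[:, :rank] = scores[:, :n_keep][:, nonzero]
    if rank < t_frames - 1:
        logger.info("gm_pca_basis: data rank %d < T-1 = %d; tail zero-padded",
                    rank, t_frames - 1)
    return basis


def fingerprints(wm_series: BoldSeries, basis: np.ndarray) -> FingerprintMatrix:
    """Fisher-z correlations of each white-matter voxel with each component.

    Zero-variance basis columns (rank-deficient tail) contribute z = 0.
    """
    data = wm_series.data
    basis = np.asarray(basis, dtype=float)
    if basis.shape[0] != data.shape[0]:
        raise ValueError("basis and series frame counts differ")
    wm_sd = data.std(axis=0)
    if np.any(wm_sd == 0):
        raise ValueError("zero-variance white-matter voxel; run "
                         "drop_missing_voxels first")
    wm_c = (data - data.mean(axis=0)) / wm_sd
    b_sd = basis.std(axis=0)
    live = b_sd > 0
    b_c = np.zeros_like(basis)
    b_c[:, live] = (basis[:, live] - basis[:, live].mean(axis=0)) / b_sd[live]
    r = (wm_c.T @ b_c) / data.shape[0]
    r = np.clip(r, -1 + FISHER_CLIP, 1 - FISHER_CLIP)
    z = np.arctanh(r)
    z[:, ~live] = 0.0
    return FingerprintMatrix(z=z, region=wm_series.region,
                             n_components=int(np.sum(live)))


def eta_squared(profile_a: np.ndarray, profile_b: np.ndarray) -> float:
    """Eta-squared similarity between two connectivity profiles.

    With per-position pair means ``m_i = (a_i + b_i)/2`` and their grand
    mean ``M``, eta^2 = 1 - SS_within / SS_total where SS_within sums
    squared deviations of a and b from m, and SS_total from M.  Equals 1
    iff the profiles are identical.
    """
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("profiles must be equal-length 1-D with >= 2 entries")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("profiles must be finite")
    m = (a + b) / 2.0
    grand = m.mean()
    ss_within = np.sum((a - m) ** 2 + (b - m) ** 2)
    ss_total = np.sum((a - grand) ** 2 + (b - grand) ** 2)
    if ss_total == 0:
        if np.array_equal(a, b):
            return 1.0
        raise ValueError("eta-squared undefined: zero total sum of squares")
    return float(1.0 - ss_within / ss_total)


def similarity_matrix(fp: FingerprintMatrix) -> SimilarityGraph:
    """Pairwise eta-squared similarity of all fingerprint rows.

    Vectorized via the identities SS_within = ||a - b||^2 / 2 and
    SS_total = SS_a + SS_b + T*(mean_a - mean_b)^2 / 2, which reduce the
    pairwise loop to one Gram-matrix product.
    """
    z = fp.z
    n, t = z.shape
    if n < 2:
        raise ValueError("need at least 2 voxels")
    mu = z.mean(axis=1)
    centered = z - mu[:, None]
    ss = np.sum(centered ** 2, axis=1)
    if np.any(ss == 0):
        # constant rows only pair validly with identical rows; detect early
        for i in np.flatnonzero(ss == 0):
            for j in range(n):
                if j != i and not np.array_equal(z[i], z[j]):
                    raise ValueError("eta-squared undefined for a constant "
                                     f"fingerprint (voxel {i})")
    gram = centered @ centered.T
    d_mu2 = (mu[:, None] - mu[None, :]) ** 2
    ss_sum = ss[:, None] + ss[None, :]
    ss_within = (ss_sum - 2.0 * gram + t * d_mu2) / 2.0
    ss_total = ss_sum + t * d_mu2 / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        s = 1.0 - ss_within / ss_total
    s[ss_total == 0] = 1.0              # identical constant rows
    s = np.clip((s + s.T) / 2.0, None, 1.0)
    np.fill_diagonal(s, 1.0)
    return SimilarityGraph(similarity=s)


def group_average(similarities: list[np.ndarray]) -> np.ndarray:
    """Elementwise mean of per-subject similarity matrices."""
    if not similarities:
        raise ValueError("no similarity matrices")
    mats = [m.similarity if isinstance(m, SimilarityGraph) else np.asarray(m, float)
            for m in similarities]
    shape = mats[0].shape
    for m in mats:
        if m.shape != shape:
            raise ValueError("similarity matrices differ in shape")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("similarity matrix is not symmetric")
    return np.mean(mats, axis=0)


def sparsify_connected(similarity: np.ndarray | SimilarityGraph) -> SimilarityGraph:
    """Minimal-epsilon connected sparsification of a similarity matrix.

    Similarities map to chord distances d = sqrt(2(1 - S)); edges with
    d <= epsilon are kept with weight S, where epsilon is the smallest
    threshold leaving a single connected component — exactly the largest
    edge of a minimum spanning tree of the distance graph.
    """
    s = similarity.similarity if isinstance(similarity, SimilarityGraph) \
        else np.asarray(similarity, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("similarity matrix has non-finite entries")
    if not np.allclose(s, s.T, atol=1e-8):
        raise ValueError("similarity matrix must be symmetric")
    n = s.shape[0]
    d = np.sqrt(np.maximum(2.0 * (1.0 - s), 0.0))
    np.fill_diagonal(d, 0.0)
    # MST needs explicit edges; csgraph treats 0 as "no edge", so shift
    # weights up by a constant that cancels in the argmax
    mst = minimum_spanning_tree(sp.csr_matrix(d + 1.0))
    if mst.nnz != n - 1:
        raise ValueError("distance graph is not connectable")
    epsilon = float(mst.data.max() - 1.0)
    keep = (d <= epsilon + 1e-12)
    np.fill_diagonal(keep, False)
    w = np.where(keep, s, 0.0)
    w = np.maximum(w, 0.0)               # eta^2 weights are non-negative
    adj = sp.csr_matrix(w)
    n_comp, _ = connected_components(adj, directed=False)
    if n_comp != 1:
        raise ValueError("sparsified graph is disconnected at minimal epsilon")
    return SimilarityGraph(similarity=s, adjacency=adj, epsilon=epsilon,
                           connected=True)


def laplacian_eigenmaps(graph: SimilarityGraph, k: int = 3,
                        region: VoxelRegion | None = None,
                        condition: str = "",
                        variance_mode: str = "inverse_eigenvalue",
                        method: str = "auto",
                        ) -> GradientSet:
    """Gradients as eigenvectors of L = D - W for the k smallest nonzero
    eigenvalues.

    The zero-eigenvalue constant mode is verified (|lambda_1| < 1e-8,
    constant eigenvector) and discarded; the next eigenvector is the
    principal gradient.  ``variance_explained`` is each gradient's
    1/lambda share of the total over nonzero eigenvalues
    (``variance_mode="inverse_eigenvalue"``), or its share of total
    embedding variance (``"embedding"``, over the returned k only).

    ``method`` selects the solver: ``"dense"`` (full eigendecomposition),
    ``"sparse"`` (shift-invert Lanczos for the smallest k+1 pairs) or
    ``"auto"`` (dense below 2000 nodes).
    """
    if graph.adjacency is None or not graph.connected:
        raise ValueError("graph must be a connected sparsified graph; "
                         "run sparsify_connected first")
    if k < 1:
        raise ValueError("k must be >= 1")
    n = graph.n_nodes
    if k >= n:
        raise ValueError("k must be smaller than the node count")
    w = graph.adjacency
    degrees = np.asarray(w.sum(axis=1)).ravel()
    lap = sp.diags(degrees) - w

    if method not in ("auto", "dense", "sparse"):
        raise ValueError(f"unknown method {method!r}")
    use_dense = method == "dense" or (method == "auto" and n <= DENSE_EIG_LIMIT)
    if use_dense:
        evals, evecs = np.linalg.eigh(lap.toarray())
        evals_all = evals
    else:
        evals, evecs = sp.linalg.eigsh(lap.tocsc(), k=k + 1, sigma=0,
                                       which="LM", tol=_EIG_TOL)
        order = np.argsort(evals)
        evals, evecs = evals[order], evecs[:, order]
        evals_all = None

    if abs(evals[0]) > 1e-8:
        raise ValueError(f"smallest eigenvalue {evals[0]:.3e} is not zero; "
                         "graph may be disconnected")
    const = evecs[:, 0]
    if np.std(const / np.linalg.norm(const)) > 1e-6:
        raise ValueError("zero-eigenvalue eigenvector is not constant")

    grads = evecs[:, 1:k + 1]
    lam = evals[1:k + 1]
    if lam[0] < 1e-12:
        raise ValueError("second eigenvalue is numerically zero; "
                         "graph is effectively disconnected")
    # repeated eigenvalues leave individual gradients non-identifiable
    degenerate = bool(np.any(np.diff(evals[1:min(k + 2, n)]) < 1e-10 * max(lam[-1], 1)))
    if degenerate:
        logger.warning("laplacian_eigenmaps: repeated eigenvalues — "
                       "gradients are non-identifiable up to rotation")

    if variance_mode == "inverse_eigenvalue":
        if evals_all is not None:
            inv_all = 1.0 / evals_all[1:]
            var = (1.0 / lam) / inv_all.sum()
        else:
            # full spectrum unavailable at sparse scale: report shares over
            # the computed eigenvalues and log the approximation
            logger.info("variance explained computed over the %d returned "
                        "eigenvalues only (sparse path)", k)
            var = (1.0 / lam) / np.sum(1.0 / lam)
    elif variance_mode == "embedding":
        var = (1.0 / lam) / np.sum(1.0 / lam)
    else:
        raise ValueError(f"unknown variance_mode {variance_mode!r}")

    grads = grads / np.linalg.norm(grads, axis=0)
    return GradientSet(gradients=grads, eigenvalues=lam,
                       variance_explained=var, region=region,
                       condition=condition, degenerate=degenerate)


def align_gradient_signs(gradient_set: GradientSet,
                         reference: np.ndarray) -> GradientSet:
    """Flip each gradient whose correlation with its reference is negative.

    ``reference`` is either one vector applied to all gradients or an
    (N, K) matrix of per-gradient references.  Gradient signs are
    arbitrary; flipping leaves every |correlation| statistic unchanged.
    """
    ref = np.asarray(reference, dtype=float)
    g = gradient_set.gradients
    if ref.ndim == 1:
        ref = np.repeat(ref[:, None], g.shape[1], axis=1)
    if ref.shape != g.shape:
        raise ValueError("reference shape does not match gradients")
    if np.any(ref.std(axis=0) == 0):
        raise ValueError("zero-variance reference")
    gc = g - g.mean(axis=0)
    rc = ref - ref.mean(axis=0)
    signs = np.where(np.sum(gc * rc, axis=0) < 0, -1.0, 1.0)
    return GradientSet(gradients=g * signs,
                       eigenvalues=gradient_set.eigenvalues,
                       variance_explained=gradient_set.variance_explained,
                       region=gradient_set.region,
                       condition=gradient_set.condition,
                       degenerate=gradient_set.degenerate)
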
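"""Geometric validation of gradients against the region's own shape.

The region's principal spatial axes come from an SVD of its (centered)
world-mm voxel coordinates.  Along each axis the region is cut into n
equally spaced segments and the gradient profiled segment by segment
(adjacent-segment rank tests, Bonferroni-corrected).  Gradients are also
partitioned by 1-D k-means and scored against an atlas with an optimally
matched mean Dice coefficient plus a label-permutation null, and related
to Euclidean distance from the gradient's peak voxel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

#: preferred world direction per axis rank: posterior->anterior (+y),
#: ventral->dorsal (+z), left->right (+x); axis signs are flipped to have
#: non-negative projection on these.
_PREFERRED_DIRECTIONS = np.array([[0.0, 1.0, 0.0],
                                  [0.0, 0.0, 1.0],
                                  [1.0, 0.0, 0.0]])


@dataclass
class AxisFrame:
    """Principal spatial axes of a voxel cloud.

    ``axes[a]`` is a unit mm-space direction, ordered by decreasing
    spatial extent; ``projections[v, a]`` is voxel v's mm coordinate
    along axis a (centered on the centroid).
    """

    centroid: np.ndarray            # (3,) mm
    axes: np.ndarray                # (3, 3) orthonormal rows
    projections: np.ndarray         # (V, 3) mm
    singular_values: np.ndarray     # (3,) descending
    degenerate: bool = False


@dataclass
class SegmentProfile:
    """Per-segment gradient means along one axis with adjacent-pair tests."""

    axis: int
    n_segments: int
    labels: np.ndarray              # (V,) in 1..n
    segment_means: np.ndarray       # (n,)
    segment_counts: np.ndarray      # (n,)
    statistics: np.ndarray          # (n-1,) adjacent-pair test statistics
    p_values: np.ndarray            # (n-1,) FWE (Bonferroni) corrected
    monotone: bool = False


def principal_axes(coords: np.ndarray) -> AxisFrame:
    """SVD principal axes of voxel mm coordinates.

    Right-singular vectors of the centered coordinate matrix, ordered by
    singular value; each axis is sign-flipped to point along the
    posterior-anterior / ventral-dorsal / left-right world direction.
    Fewer than 4 non-coplanar points set ``degenerate``.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be V x 3")
    if coords.shape[0] < 2:
        raise ValueError("need at least 2 voxels")
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=True)
    s = np.concatenate([s, np.zeros(3 - len(s))])
    degenerate = coords.shape[0] < 4 or s[2] <= 1e-10 * max(s[0], 1.0)
    axes = vt[:3]
    for a in range(3):
        d = float(axes[a] @ _PREFERRED_DIRECTIONS[a])
        if d == 0.0:
            # tie-break: make the largest-magnitude component positive
            d = axes[a][np.argmax(np.abs(axes[a]))]
        if d < 0:
            axes[a] = -axes[a]
    projections = centered @ axes.T
    return AxisFrame(centroid=centroid, axes=axes, projections=projections,
                     singular_values=s[:3], degenerate=degenerate)


def segment_along_axis(frame: AxisFrame, axis: int, n: int = 5) -> np.ndarray:
    """Split voxels into n segments equally spaced along one axis.

    Boundary hyperplanes are equally spaced between the two extreme
    projections; a voxel exactly on a boundary joins the lower segment.
    Returns labels 1..n in voxel order.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if axis not in (1, 2, 3):
        raise ValueError("axis must be 1, 2 or 3")
    p = frame.projections[:, axis - 1]
    lo, hi = p.min(), p.max()
    if hi <= lo:
        raise ValueError("zero extent along the requested axis")
    edges = np.linspace(lo, hi, n + 1)[1:-1]
    labels = np.searchsorted(edges, p, side="left") + 1
    counts = np.bincount(labels, minlength=n + 1)[1:]
    if np.any(counts == 0):
        logger.warning("segment_along_axis: %d empty segment(s)",
                       int(np.sum(counts == 0)))
    return labels.astype(np.int64)


def segment_profile(gradient: np.ndarray, labels: np.ndarray,
                    correction: str = "bonferroni",
                    alpha: float = 0.05) -> SegmentProfile:
    """Segment means plus adjacent-pair Wilcoxon rank-sum tests.

    p-values are Bonferroni-multiplied by the number of adjacent pairs
    and capped at 1; ``monotone`` records whether the segment means are
    strictly monotone.
    """
    if correction != "bonferroni":
        raise ValueError("only bonferroni correction is implemented")
    gradient = np.asarray(gradient, dtype=float)
    labels = np.asarray(labels)
    n = int(labels.max())
    means = np.full(n, np.nan)
    counts = np.zeros(n, dtype=int)
    groups = []
    for seg in range(1, n + 1):
        vals = gradient[labels == seg]
        groups.append(vals)
        counts[seg - 1] = len(vals)
        means[seg - 1] = vals.mean() if len(vals) else np.nan
    n_pairs = n - 1
    statistic = np.full(n_pairs, np.nan)
    p_corr = np.full(n_pairs, np.nan)
    for i in range(n_pairs):
        a, b = groups[i], groups[i + 1]
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"segment {i + 1} or {i + 2} has < 2 voxels")
        if np.array_equal(np.sort(a), np.sort(b)):
            statistic[i], p_corr[i] = 0.0, 1.0
            continue
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        statistic[i] = res.statistic
        p_corr[i] = min(res.pvalue * n_pairs, 1.0)
    diffs = np.diff(means)
    monotone = bool(np.all(diffs > 0) or np.all(diffs < 0))
    return SegmentProfile(axis=0, n_segments=n, labels=labels,
                          segment_means=means, segment_counts=counts,
                          statistics=statistic, p_values=p_corr,
                          monotone=monotone)


def kmeans_partition(gradient: np.ndarray, k: int, seed: int = 0,
                     restarts: int = 50) -> np.ndarray:
    """1-D k-means on gradient values, best of ``restarts`` initializations.

    Labels are 1..k, relabeled in increasing order of cluster centroid so
    the labeling is deterministic.
    """
    gradient = np.asarray(gradient, dtype=float)
    n_distinct = len(np.unique(gradient))
    if k < 1 or k > n_distinct:
        raise ValueError(f"k={k} invalid for {n_distinct} distinct values")
    if k == 1:
        return np.ones(len(gradient), dtype=np.int64)
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    raw = km.fit_predict(gradient[:, None])
    order = np.argsort(km.cluster_centers_.ravel())
    relabel = np.empty(k, dtype=np.int64)
    relabel[order] = np.arange(1, k + 1)
    return relabel[raw]


def _dice_matrix(labels_a: np.ndarray, values_a: np.ndarray,
                 labels_b: np.ndarray, values_b: np.ndarray) -> np.ndarray:
    """Pairwise Dice coefficients between two labelings' classes."""
    d = np.zeros((len(values_a), len(values_b)))
    for i, la in enumerate(values_a):
        in_a = labels_a == la
        na = in_a.sum()
        for j, lb in enumerate(values_b):
            in_b = labels_b == lb
            inter = np.sum(in_a & in_b)
            d[i, j] = 2.0 * inter / (na + in_b.sum())
    return d


def dice_vs_atlas(labels: np.ndarray, atlas_labels: np.ndarray,
                  ) -> tuple[float, dict[int, int], np.ndarray]:
    """Mean Dice between a clustering and an atlas, optimally matched.

    Clusters and atlas classes are matched one-to-one to maximize total
    Dice (linear assignment); returns ``(mean_dice, matching,
    per_pair_dice)``.  If class counts differ the smaller count is
    matched and a warning logged.
    """
    labels = np.asarray(labels)
    atlas_labels = np.asarray(atlas_labels)
    if labels.shape != atlas_labels.shape:
        raise ValueError("clustering and atlas cover different voxel sets")
    vals_c = np.unique(labels)
    vals_a = np.unique(atlas_labels)
    if len(vals_c) != len(vals_a):
        logger.warning("dice_vs_atlas: %d clusters vs %d atlas classes; "
                       "matching the smaller count", len(vals_c), len(vals_a))
    d = _dice_matrix(labels, vals_c, atlas_labels, vals_a)
    rows, cols = linear_sum_assignment(-d)
    pair_dice = d[rows, cols]
    matching = {int(vals_c[r]): int(vals_a[c]) for r, c in zip(rows, cols)}
    return float(pair_dice.mean()), matching, pair_dice


def permutation_test_dice(labels: np.ndarray, atlas_labels: np.ndarray,
                          n_perm: int = 1000, seed: int = 0,
                          ) -> tuple[float, float, np.ndarray]:
    """Permutation p-value for the matched mean Dice.

    Cluster labels are shuffled across voxels ``n_perm`` times and the
    matched mean Dice recomputed; p = (1 + #{null >= observed}) /
    (n_perm + 1).  Returns ``(p, observed, null_distribution)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    observed, _, _ = dice_vs_atlas(labels, atlas_labels)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    labels = np.asarray(labels)
    for b in range(n_perm):
        null[b], _, _ = dice_vs_atlas(rng.permutation(labels), atlas_labels)
    p = (1.0 + np.sum(null >= observed)) / (n_perm + 1.0)
    return float(p), float(observed), null


def distance_from_peak(gradient: np.ndarray, coords: np.ndarray,
                       ) -> tuple[np.ndarray, float, float]:
    """Euclidean distance from the gradient's peak voxel, and its
    correlation with the gradient.

    The peak is the (unique) maximum; ties are broken by voxel order and
    logged.  Returns ``(distances, r, p)`` with a two-sided parametric p.
    """
    gradient = np.asarray(gradient, dtype=float)
    coords = np.asarray(coords, dtype=float)
    if gradient.std() == 0:
        raise ValueError("constant gradient has no peak")
    peak = int(np.argmax(gradient))
    if np.sum(gradient == gradient[peak]) > 1:
        logger.info("distance_from_peak: tied maximum, using first voxel "
                    "in region order")
    dist = np.linalg.norm(coords - coords[peak], axis=1)
    r, p = stats.pearsonr(gradient, dist)
    return dist, float(r), float(p)
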
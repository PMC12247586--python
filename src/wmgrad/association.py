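"""Behavior composites, FC-behavior maps, microstructure coupling,
reliability.

Behavior subdomains with several raw scores are condensed to their first
principal component; each white-matter voxel's subject-by-parcel
connectivity is likewise condensed to one latent score per subject, and
the two are correlated voxelwise (deliberately uncorrected — the analysis
asks about the overall correlation landscape, not single voxels).
Gradient-microstructure coupling is a voxelwise Pearson correlation after
sign alignment, with dependent correlations compared by Steiger's test;
cross-scan reliability is the sign-aligned spatial correlation of
matching gradients.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class VoxelBehaviorMap:
    """Per-voxel, per-behavior Pearson correlations across subjects."""

    r: np.ndarray                 # (V, B)
    behaviors: list[str]
    condition: str = "REST1"
    n_subjects: int = 0

    def __post_init__(self):
        self.r = np.atleast_2d(np.asarray(self.r, dtype=float))
        with np.errstate(invalid="ignore"):
            if np.nanmax(np.abs(self.r)) > 1 + 1e-12:
                raise ValueError("|r| > 1 in behavior map")


def composite_scores(raw: np.ndarray | pd.DataFrame) -> np.ndarray:
    """First-principal-component composite of a subdomain's raw scores.

    Columns are z-standardized (constant columns dropped with a warning)
    and the first-PC scores returned, sign-aligned so the mean loading is
    positive.  A single column returns its z-scores.
    """
    x = raw.to_numpy(dtype=float) if isinstance(raw, pd.DataFrame) \
        else np.asarray(raw, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    sd = x.std(axis=0)
    if np.any(sd == 0):
        warnings.warn("composite_scores: dropping constant column(s)",
                      stacklevel=2)
        x = x[:, sd > 0]
        sd = sd[sd > 0]
    if x.shape[1] == 0:
        raise ValueError("no variable columns")
    z = (x - x.mean(axis=0)) / sd
    if z.shape[1] == 1:
        return z[:, 0]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    loading = vt[0]
    sign = 1.0 if loading.mean() >= 0 else -1.0
    return sign * u[:, 0] * s[0]


def voxel_fc_latent(subject_fc: np.ndarray) -> np.ndarray:
    """One FC latent score per subject per voxel.

    ``subject_fc`` is (S, V, P): per subject, each voxel's Fisher-z
    connectivity to the P parcels.  Per voxel, the subjects-by-parcels
    matrix is reduced to its first principal component across subjects;
    scores are sign-aligned so the loading vector's mean is positive.
    Returns (S, V).
    """
    fc = np.asarray(subject_fc, dtype=float)
    if fc.ndim != 3:
        raise ValueError("subject_fc must be (subjects, voxels, parcels)")
    s, v, p = fc.shape
    if s < 3:
        raise ValueError("need at least 3 subjects")
    latents = np.empty((s, v))
    for vox in range(v):
        m = fc[:, vox, :]
        centered = m - m.mean(axis=0)
        if np.allclose(centered, 0):
            raise ValueError(f"zero-variance connectivity at voxel {vox}")
        u, sv, vt = np.linalg.svd(centered, full_matrices=False)
        sign = 1.0 if vt[0].mean() >= 0 else -1.0
        latents[:, vox] = sign * u[:, 0] * sv[0]
    return latents


def _columnwise_pearson(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of vector y with every column of x."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt(np.sum(xc ** 2, axis=0) * np.sum(yc ** 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (xc.T @ yc) / denom


def behavior_correlation_map(latents: np.ndarray,
                             behavior: pd.DataFrame,
                             subjects: list[str] | None = None,
                             condition: str = "REST1") -> VoxelBehaviorMap:
    """Voxelwise Pearson correlation of FC latents with behavior scores.

    ``latents`` is (S, V); ``behavior`` has a ``subject`` column plus one
    column per behavioral composite.  No multiple-comparison correction
    is applied — the map is read as a landscape, not tested voxelwise.
    Missing behavior entries use pairwise-complete subjects.
    """
    score_cols = [c for c in behavior.columns if c != "subject"]
    if subjects is not None:
        if list(behavior["subject"]) != list(subjects):
            raise ValueError("behavior subjects do not match latent subjects")
    n_subj = latents.shape[0]
    if len(behavior) != n_subj:
        raise ValueError("behavior rows do not match latent subjects")
    if n_subj < 4:
        raise ValueError("need at least 4 subjects")
    r = np.empty((latents.shape[1], len(score_cols)))
    for j, col in enumerate(score_cols):
        y = behavior[col].to_numpy(dtype=float)
        ok = np.isfinite(y)
        if ok.sum() < 4:
            raise ValueError(f"behavior {col!r} has < 4 complete subjects")
        r[:, j] = _columnwise_pearson(latents[ok], y[ok])
    return VoxelBehaviorMap(r=r, behaviors=score_cols, condition=condition,
                            n_subjects=n_subj)


def condition_behavior_contrast(maps: list[VoxelBehaviorMap],
                                alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise t-tests on |r| between conditions, voxels as paired units.

    For every condition pair, a paired two-sided t-test over voxels on
    the absolute correlations (averaged over behaviors when several),
    Bonferroni-corrected over the number of pairs.
    """
    if len(maps) < 2:
        raise ValueError("need at least 2 conditions")
    v = maps[0].r.shape[0]
    for m in maps:
        if m.r.shape[0] != v:
            raise ValueError("condition maps cover different voxel sets")
    n_pairs = len(maps) * (len(maps) - 1) // 2
    rows = []
    for i in range(len(maps)):
        for j in range(i + 1, len(maps)):
            a = np.abs(maps[i].r).mean(axis=1)
            b = np.abs(maps[j].r).mean(axis=1)
            if np.array_equal(a, b):
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_rel(b, a)
            rows.append({"condition_a": maps[i].condition,
                         "condition_b": maps[j].condition,
                         "t": float(t),
                         "p_fwe": min(float(p) * n_pairs, 1.0),
                         "significant": float(p) * n_pairs < alpha})
    return pd.DataFrame(rows)


def structure_coupling(gradient: np.ndarray, structural_map: np.ndarray,
                       ) -> tuple[float, float, int]:
    """Voxelwise Pearson correlation between a gradient and a structural map.

    Voxels with non-finite structural values are dropped (and logged).
    Returns ``(r, p, n)``.  Apply after sign alignment so the reported r
    is non-negative when flipping is enabled.
    """
    g = np.asarray(gradient, dtype=float)
    m = np.asarray(structural_map, dtype=float)
    if g.shape != m.shape:
        raise ValueError("gradient and structural map cover different voxels")
    ok = np.isfinite(m) & np.isfinite(g)
    dropped = int(np.sum(~ok))
    if dropped:
        logger.info("structure_coupling: dropped %d non-finite voxels", dropped)
    g, m = g[ok], m[ok]
    if len(g) < 4:
        raise ValueError("need at least 4 finite voxel pairs")
    if g.std() == 0 or m.std() == 0:
        raise ValueError("constant input")
    r, p = stats.pearsonr(g, m)
    return float(r), float(p), int(len(g))


def steiger_compare(r1: float, r2: float, r12: float, n: int,
                    ) -> tuple[float, float]:
    """Steiger's Z for two dependent correlations sharing one variable.

    Compares r(x, g1) against r(x, g2) given the correlation r12 between
    g1 and g2, using the Fisher-z statistic with the pooled-correlation
    covariance (Steiger 1980): with rbar = (r1 + r2)/2,

        cov = [r12 (1 - 2 rbar^2) - rbar^2 (1 - 2 rbar^2 - r12^2) / 2]
              / (1 - rbar^2)^2
        Z   = (z1 - z2) sqrt(n - 3) / sqrt(2 - 2 cov)

    Returns ``(z, p)`` with a two-sided normal p.  Exchangeable: swapping
    r1 and r2 negates Z.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    for r in (r1, r2, r12):
        if abs(r) > 1:
            raise ValueError("correlations must lie in [-1, 1]")
    if abs(r1) == 1 or abs(r2) == 1:
        raise ValueError("|r| = 1: Fisher transform undefined")
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    rbar = (r1 + r2) / 2.0
    cov = (r12 * (1.0 - 2.0 * rbar ** 2)
           - 0.5 * rbar ** 2 * (1.0 - 2.0 * rbar ** 2 - r12 ** 2)) \
        / (1.0 - rbar ** 2) ** 2
    z = (z1 - z2) * np.sqrt(n - 3) / np.sqrt(2.0 - 2.0 * cov)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def spatial_reliability(grad_a: np.ndarray, grad_b: np.ndarray,
                        ) -> tuple[float, int]:
    """Sign-aligned spatial correlation between two gradient maps.

    Returns ``(|r|, sign)`` where sign is the alignment applied to
    ``grad_b`` (gradient signs are arbitrary, so reliability is the
    magnitude of the spatial correlation).
    """
    a = np.asarray(grad_a, dtype=float)
    b = np.asarray(grad_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("gradients cover different voxel sets")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant gradient")
    r, _ = stats.pearsonr(a, b)
    sign = 1 if r >= 0 else -1
    return float(abs(r)), sign
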
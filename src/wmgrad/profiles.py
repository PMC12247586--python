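"""Gradient-quintile ROIs and their cortical connectivity profiles.

A gradient map is binned into five 20-percentile ROIs; each ROI's mean
time course is correlated with every parcel of a cortical parcellation,
Fisher z-transformed, and summarized by intrinsic network and hemisphere.
Cross-condition and left/right contrasts are paired tests over subjects
with Bonferroni family-wise correction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from wmgrad.gradients import FISHER_CLIP
from wmgrad.regions import BoldSeries

from dataclasses import dataclass, field


@dataclass
class FcProfile:
    """5 x P Fisher-z connectivity of gradient-quintile ROIs to parcels."""

    z: np.ndarray                       # (5, P)
    parcel_network: np.ndarray          # (P,) network name per parcel
    parcel_hemisphere: np.ndarray       # (P,) "L"/"R" per parcel
    condition: str = "REST1"
    subject: str = "group"
    networks: tuple = field(default=None)

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        if self.z.shape[0] != 5:
            raise ValueError("profile must have 5 ROI rows")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("profile has non-finite entries")
        p = self.z.shape[1]
        self.parcel_network = np.asarray(self.parcel_network)
        self.parcel_hemisphere = np.asarray(self.parcel_hemisphere)
        if len(self.parcel_network) != p or len(self.parcel_hemisphere) != p:
            raise ValueError("parcel maps must cover all parcels")
        if self.networks is None:
            self.networks = tuple(dict.fromkeys(self.parcel_network))

    def to_r(self) -> np.ndarray:
        """Back-transform to correlation units (for reporting)."""
        return np.tanh(self.z)


def quintile_rois(gradient: np.ndarray) -> np.ndarray:
    """Bin a gradient into five 20-percentile ROIs (labels 1..5).

    Ranks are averaged within ties so tied values share a bin; bins are
    ``ceil(rank * 5 / V)``, which is deterministic and stable under
    monotone transforms of the gradient.
    """
    gradient = np.asarray(gradient, dtype=float)
    v = len(gradient)
    if len(np.unique(gradient)) < 5:
        raise ValueError("need at least 5 distinct gradient values")
    ranks = stats.rankdata(gradient, method="average")
    labels = np.ceil(ranks * 5.0 / v).astype(np.int64)
    return np.clip(labels, 1, 5)


def roi_timeseries(series: BoldSeries, labels: np.ndarray) -> np.ndarray:
    """Label-wise mean time courses: (n_labels, T), label order ascending.

    ``labels`` has one entry per series voxel; label 0 is background and
    skipped.
    """
    labels = np.asarray(labels)
    if labels.shape != (series.n_voxels,):
        raise ValueError("labels must cover the series voxels")
    out = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        members = labels == lab
        if not np.any(members):
            raise ValueError(f"label {lab} has no voxels")
        out.append(series.data[:, members].mean(axis=1))
    if not out:
        raise ValueError("no labelled voxels")
    return np.vstack(out)


def fc_matrix(roi_ts: np.ndarray, parcel_ts: np.ndarray,
              parcel_network: np.ndarray, parcel_hemisphere: np.ndarray,
              condition: str = "REST1", subject: str = "group") -> FcProfile:
    """Fisher-z Pearson correlations between ROI and parcel time courses."""
    roi_ts = np.asarray(roi_ts, dtype=float)
    parcel_ts = np.asarray(parcel_ts, dtype=float)
    if roi_ts.shape[1] != parcel_ts.shape[1]:
        raise ValueError("ROI and parcel series frame counts differ")
    if roi_ts.shape[1] < 3:
        raise ValueError("need at least 3 frames")
    for name, ts in (("ROI", roi_ts), ("parcel", parcel_ts)):
        if np.any(ts.std(axis=1) == 0):
            raise ValueError(f"zero-variance {name} time course")
    t = roi_ts.shape[1]
    a = (roi_ts - roi_ts.mean(axis=1, keepdims=True)) / roi_ts.std(axis=1, keepdims=True)
    b = (parcel_ts - parcel_ts.mean(axis=1, keepdims=True)) / parcel_ts.std(axis=1, keepdims=True)
    r = (a @ b.T) / t
    z = np.arctanh(np.clip(r, -1 + FISHER_CLIP, 1 - FISHER_CLIP))
    return FcProfile(z=z, parcel_network=parcel_network,
                     parcel_hemisphere=parcel_hemisphere,
                     condition=condition, subject=subject)


def network_summary(fc: FcProfile) -> tuple[pd.DataFrame, np.ndarray]:
    """Mean z per (ROI, network) plus each ROI's strongest network."""
    networks = list(fc.networks)
    table = np.zeros((5, len(networks)))
    for j, net in enumerate(networks):
        members = fc.parcel_network == net
        if not np.any(members):
            raise ValueError(f"network {net!r} has no parcels")
        table[:, j] = fc.z[:, members].mean(axis=1)
    df = pd.DataFrame(table, columns=networks,
                      index=[f"roi_{i}" for i in range(1, 6)])
    strongest = np.array([networks[j] for j in np.argmax(table, axis=1)])
    return df, strongest


def projection_similarity(fc: FcProfile) -> tuple[np.ndarray, np.ndarray]:
    """5 x 5 Pearson similarity of the ROI connectivity maps.

    Also flags, per ROI, whether the off-diagonal maximum is an adjacent
    ROI — the signature of a smoothly drifting connectopy.
    """
    if fc.z.shape[1] < 3:
        raise ValueError("need at least 3 parcels")
    if np.any(fc.z.std(axis=1) == 0):
        raise ValueError("constant connectivity map row")
    sim = np.corrcoef(fc.z)
    neighbor_max = np.zeros(5, dtype=bool)
    for i in range(5):
        off = np.delete(np.arange(5), i)
        j = off[np.argmax(sim[i, off])]
        neighbor_max[i] = abs(j - i) == 1
    return sim, neighbor_max


def laterality_contrast(fc_subjects: list[FcProfile],
                        ) -> pd.DataFrame:
    """Left vs right mean connectivity per ROI, paired over subjects.

    Per subject and ROI the profile is averaged over left-hemisphere and
    right-hemisphere parcels; a paired two-sided t-test per ROI is
    Bonferroni-corrected over the 5 ROIs.
    """
    if len(fc_subjects) < 2:
        raise ValueError("need at least 2 subjects")
    hemi = fc_subjects[0].parcel_hemisphere
    for side in ("L", "R"):
        if not np.any(hemi == side):
            raise ValueError(f"hemisphere {side!r} has no parcels")
    left = np.array([fc.z[:, fc.parcel_hemisphere == "L"].mean(axis=1)
                     for fc in fc_subjects])          # (S, 5)
    right = np.array([fc.z[:, fc.parcel_hemisphere == "R"].mean(axis=1)
                      for fc in fc_subjects])
    rows = []
    for roi in range(5):
        t, p = stats.ttest_rel(left[:, roi], right[:, roi])
        rows.append({"roi": roi + 1,
                     "mean_left_z": left[:, roi].mean(),
                     "mean_right_z": right[:, roi].mean(),
                     "t": float(t),
                     "p_fwe": min(float(p) * 5.0, 1.0)})
    return pd.DataFrame(rows)


def condition_contrast(fc_a: list[FcProfile], fc_b: list[FcProfile],
                       paired: bool = True, alpha: float = 0.05,
                       ) -> dict:
    """Cellwise condition contrast of Fisher-z connectivity.

    Paired (or independent) t-test per (ROI, parcel) cell between the two
    condition lists, Bonferroni-corrected over all 5*P cells, plus a
    per-ROI mean-difference summary.  Returns a dict with ``t_map``,
    ``p_fwe``, ``significant`` and ``roi_mean_difference``.
    """
    if not fc_a or not fc_b:
        raise ValueError("empty condition list")
    if paired:
        if len(fc_a) != len(fc_b):
            raise ValueError("paired contrast needs matched subjects")
        for x, y in zip(fc_a, fc_b):
            if x.subject != y.subject:
                raise ValueError("paired contrast: subject mismatch "
                                 f"({x.subject} vs {y.subject})")
    za = np.stack([fc.z for fc in fc_a])            # (S, 5, P)
    zb = np.stack([fc.z for fc in fc_b])
    if paired:
        with np.errstate(invalid="ignore", divide="ignore"):
            t_map, p_map = stats.ttest_rel(zb, za, axis=0)
        # identical cells (zero difference, zero spread) are a null result
        exact = np.all(zb == za, axis=0)
        t_map = np.where(exact, 0.0, t_map)
        p_map = np.where(exact, 1.0, p_map)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            t_map, p_map = stats.ttest_ind(zb, za, axis=0)
    n_cells = t_map.size
    p_fwe = np.minimum(p_map * n_cells, 1.0)
    roi_diff = zb.mean(axis=(0, 2)) - za.mean(axis=(0, 2))
    return {"t_map": t_map, "p_fwe": p_fwe,
            "significant": p_fwe < alpha,
            "roi_mean_difference": roi_diff}
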
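"""Post-registration BOLD signal cleaning.

Implements the cleaning chain applied before gradient mapping: linear
detrending, nuisance regression (24-parameter motion expansion + mean CSF),
HRF-convolved task-effect removal, within-mask Gaussian smoothing,
Marchenko-Pastur ("Wishart-style") PCA denoising, per-run z-scoring and run
concatenation.  Temporal filtering is deliberately absent from the chain.

The default order is detrend -> nuisance -> task removal -> smooth ->
denoise -> z-score -> concatenate; stages are independent functions so the
order is configurable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import gamma as gamma_dist

from wmgrad.regions import BoldSeries, VoxelRegion

logger = logging.getLogger(__name__)


@dataclass
class ConfoundTable:
    """Nuisance regressors: T x C matrix plus column names.

    Expected content is the 24-parameter motion expansion plus a mean-CSF
    column; any full-rank regressor set is accepted.
    """

    values: np.ndarray
    columns: list[str]

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != len(self.columns):
            raise ValueError("column names do not match matrix width")
        sd = self.values.std(axis=0)
        for name, s in zip(self.columns, sd):
            if s == 0 and name != "intercept":
                raise ValueError(f"confound column {name!r} is constant")

    @classmethod
    def from_tsv(cls, path) -> "ConfoundTable":
        df = pd.read_csv(path, sep="\t")
        return cls(values=df.to_numpy(float), columns=list(df.columns))


@dataclass
class TaskEvents:
    """Task stimulus events: onset/duration in seconds, condition, amplitude."""

    table: pd.DataFrame     # columns: onset, duration, trial_type, amplitude

    def __post_init__(self):
        required = {"onset", "duration", "trial_type"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"events table missing columns {sorted(missing)}")
        if "amplitude" not in self.table.columns:
            self.table = self.table.assign(amplitude=1.0)
        if (self.table["onset"] < 0).any():
            raise ValueError("event onsets must be >= 0")
        if (self.table["duration"] <= 0).any():
            raise ValueError("event durations must be > 0")

    @classmethod
    def from_tsv(cls, path) -> "TaskEvents":
        return cls(pd.read_csv(path, sep="\t"))


def expand_motion_24(motion6: np.ndarray) -> np.ndarray:
    """24-parameter expansion of 6 rigid-body motion columns.

    The 6 parameters, their one-frame backward differences, and the
    squares of both.
    """
    motion6 = np.asarray(motion6, dtype=float)
    if motion6.ndim != 2 or motion6.shape[1] != 6:
        raise ValueError("expected a T x 6 motion matrix")
    diffs = np.vstack([np.zeros((1, 6)), np.diff(motion6, axis=0)])
    return np.hstack([motion6, diffs, motion6 ** 2, diffs ** 2])


def _residualize(data: np.ndarray, design: np.ndarray,
                 what: str) -> np.ndarray:
    """OLS residuals of every column of data on the design (plus intercept)."""
    t_frames = data.shape[0]
    x = np.column_stack([np.ones(t_frames), design])
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise ValueError(f"{what}: rank-deficient design "
                         f"(rank {rank} < {x.shape[1]} columns collide)")
    beta, *_ = np.linalg.lstsq(x, data, rcond=None)
    return data - x @ beta


def detrend_linear(series: BoldSeries) -> BoldSeries:
    """Remove each voxel's least-squares linear trend (drift correction).

    Column means become zero as a side effect of the fitted intercept.
    """
    if series.n_frames < 3:
        raise ValueError("need at least 3 frames to detrend")
    t = np.arange(series.n_frames, dtype=float)
    resid = _residualize(series.data, t[:, None], "detrend_linear")
    return dc_replace(series, data=resid)


def regress_nuisance(series: BoldSeries, confounds: ConfoundTable) -> BoldSeries:
    """Regress the confound columns out of every voxel's time course."""
    if confounds.values.shape[0] != series.n_frames:
        raise ValueError("confound rows do not match series frames")
    resid = _residualize(series.data, confounds.values, "regress_nuisance")
    return dc_replace(series, data=resid)


def double_gamma_hrf(tr: float, duration: float = 32.0, peak: float = 6.0,
                     undershoot: float = 16.0, ratio: float = 6.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled at ``tr``.

    A gamma density peaking at ``peak`` s minus an undershoot gamma
    peaking at ``undershoot`` s scaled by 1/``ratio``; normalized to peak
    amplitude 1.
    """
    t = np.arange(0, duration + tr, tr)
    # gamma with unit scale peaks at shape-1; shift shapes accordingly
    h = (gamma_dist.pdf(t, peak + 1.0)
         - gamma_dist.pdf(t, undershoot + 1.0) / ratio)
    return h / h.max()


def task_regressors(events: TaskEvents, n_frames: int, tr: float,
                    **hrf_kwargs) -> tuple[np.ndarray, list[str]]:
    """One HRF-convolved boxcar-times-amplitude regressor per condition."""
    run_end = n_frames * tr
    if (events.table["onset"] >= run_end).any():
        raise ValueError("event onset beyond the end of the run")
    hrf = double_gamma_hrf(tr, **hrf_kwargs)
    conditions = list(dict.fromkeys(events.table["trial_type"]))
    cols = []
    for cond in conditions:
        box = np.zeros(n_frames)
        for _, ev in events.table[events.table["trial_type"] == cond].iterrows():
            lo = int(np.floor(ev["onset"] / tr))
            hi = int(np.ceil((ev["onset"] + ev["duration"]) / tr))
            box[lo:min(hi, n_frames)] += ev["amplitude"]
        cols.append(np.convolve(box, hrf)[:n_frames])
    return np.column_stack(cols), conditions


def remove_task_effects(series: BoldSeries, events: TaskEvents | None,
                        **hrf_kwargs) -> BoldSeries:
    """Regress HRF-convolved task regressors out of a task run.

    The residuals are what downstream connectivity uses, so task
    co-activation cannot masquerade as connectivity.  An empty or missing
    events table is a warned no-op.
    """
    if events is None or len(events.table) == 0:
        warnings.warn("remove_task_effects: no events — series returned "
                      "unchanged", stacklevel=2)
        return series
    design, _ = task_regressors(events, series.n_frames, series.tr,
                                **hrf_kwargs)
    resid = _residualize(series.data, design, "remove_task_effects")
    return dc_replace(series, data=resid)


def smooth_within_mask(volume_series: np.ndarray, mask: VoxelRegion,
                       fwhm: float) -> np.ndarray:
    """Gaussian smoothing restricted to the mask.

    Kernel weights are renormalized over in-mask neighbors (smoothing the
    masked data and dividing by the smoothed mask), so out-of-mask voxels
    never leak into in-mask values and constants are preserved exactly.
    Out-of-mask output voxels are zero.  ``fwhm`` is in mm; 0 is identity.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be >= 0")
    vol = np.asarray(volume_series, dtype=float)
    squeeze = vol.ndim == 3
    if squeeze:
        vol = vol[..., None]
    if vol.shape[:3] != mask.shape:
        raise ValueError("volume grid does not match mask grid")
    m = mask.to_mask()
    if fwhm == 0:
        out = np.where(m[..., None], vol, 0.0)
        return out[..., 0] if squeeze else out
    voxdim = np.sqrt(np.sum(mask.affine[:3, :3] ** 2, axis=0))
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxdim
    norm = ndimage.gaussian_filter(m.astype(float), sigma)
    out = np.zeros_like(vol)
    for t in range(vol.shape[3]):
        sm = ndimage.gaussian_filter(np.where(m, vol[..., t], 0.0), sigma)
        with np.errstate(invalid="ignore", divide="ignore"):
            frame = sm / norm
        out[..., t] = np.where(m, frame, 0.0)
    return out[..., 0] if squeeze else out


def _mp_bulk_edge(eigenvalues: np.ndarray, gamma: float) -> float:
    """Upper Marchenko-Pastur bulk edge fitted to the noise spectrum.

    sigma^2 is estimated iteratively as the mean of eigenvalues below the
    current edge (the MP distribution has mean sigma^2), so planted
    above-bulk components do not inflate the noise estimate.
    """
    lam = np.sort(eigenvalues)
    edge_factor = (1.0 + np.sqrt(gamma)) ** 2
    sigma2 = lam.mean()
    for _ in range(200):
        edge = sigma2 * edge_factor
        bulk = lam[lam <= edge]
        if bulk.size == 0:
            sigma2_new = lam.min() / edge_factor
        else:
            sigma2_new = bulk.mean()
        if abs(sigma2_new - sigma2) <= 1e-12 * max(sigma2, 1e-300):
            sigma2 = sigma2_new
            break
        sigma2 = sigma2_new
    return sigma2 * edge_factor


def wishart_denoise(series: BoldSeries) -> BoldSeries:
    """PCA reconstruction with Marchenko-Pastur eigenvalue shrinkage.

    The voxel covariance spectrum is compared with the MP bulk fitted to
    its noise part; each component's variance is soft-shrunk to
    max(lambda - bulk_edge, 0), so pure-noise components vanish while
    strong planted components survive essentially intact.
    """
    data = series.data
    t_frames, n_vox = data.shape
    if t_frames < 10 or n_vox < 10:
        raise ValueError("need at least 10 frames and 10 voxels")
    mean = data.mean(axis=0)
    centered = data - mean
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    lam = s ** 2 / t_frames
    if lam[0] <= 0:
        raise ValueError("degenerate covariance: no signal variance")
    edge = _mp_bulk_edge(lam, gamma=n_vox / t_frames)
    lam_shrunk = np.maximum(lam - edge, 0.0)
    s_new = np.sqrt(lam_shrunk * t_frames)
    kept = int(np.sum(s_new > 0))
    logger.info("wishart_denoise: kept %d of %d components above the "
                "Marchenko-Pastur edge %.4g", kept, len(lam), edge)
    denoised = (u * s_new) @ vt + mean
    return dc_replace(series, data=denoised)


def zscore_runs(run: BoldSeries) -> BoldSeries:
    """Z-score each voxel's time course to zero mean, unit sd."""
    sd = run.data.std(axis=0, ddof=0)
    if np.any(np.ptp(run.data, axis=0) == 0):
        raise ValueError("zero-variance voxel: run drop_missing_voxels first")
    return dc_replace(run, data=(run.data - run.data.mean(axis=0)) / sd)


def zscore_concatenate(runs: list[BoldSeries]) -> BoldSeries:
    """Per-run z-scoring followed by temporal concatenation into a session."""
    if not runs:
        raise ValueError("no runs to concatenate")
    first = runs[0]
    for run in runs[1:]:
        if not np.array_equal(run.region.voxels, first.region.voxels):
            raise ValueError("runs cover different regions")
        if abs(run.tr - first.tr) > 1e-9:
            raise ValueError("runs have different sampling intervals")
    zruns = [zscore_runs(run) for run in runs]
    data = np.vstack([zr.data for zr in zruns])
    return BoldSeries(region=first.region, data=data, tr=first.tr,
                      condition=first.condition)


def preprocess_run(series: BoldSeries,
                   confounds: ConfoundTable | None = None,
                   events: TaskEvents | None = None,
                   fwhm: float = 0.0,
                   wishart: bool = True,
                   volume_shape: bool = False,
                   **hrf_kwargs) -> BoldSeries:
    """The full per-run chain in the documented order.

    detrend -> nuisance -> task removal (if events) -> smooth (if fwhm>0)
    -> Marchenko-Pastur denoising (if enabled) -> z-score.
    """
    out = detrend_linear(series)
    if confounds is not None:
        out = regress_nuisance(out, confounds)
    if events is not None and len(events.table):
        out = remove_task_effects(out, events, **hrf_kwargs)
    if fwhm > 0:
        vol = np.zeros(out.region.shape + (out.n_frames,))
        vol[tuple(out.region.voxels.T)] = out.data.T
        sm = smooth_within_mask(vol, out.region, fwhm)
        out = dc_replace(out, data=sm[tuple(out.region.voxels.T)].T)
    if wishart:
        out = wishart_denoise(out)
    return zscore_runs(out)
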
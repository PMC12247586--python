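"""Volumes, voxel regions and the ordering/coordinate conventions.

Every per-voxel vector downstream (gradients, structural samples,
distances) is keyed to a :class:`VoxelRegion`, whose voxel list is held in
a single canonical order — lexicographic on the 0-based ``(i, j, k)``
index triple.  Fixing the order here is what lets gradients, FA samples
and distance maps be compared elementwise without silent misalignment.

Geometry is done in world millimetres (the affine applied to indices) so
anisotropic voxel grids are handled correctly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

#: maximum absolute elementwise affine difference still counted as "same grid"
AFFINE_TOL = 1e-6

#: threshold for binarizing probabilistic masks
MASK_THRESHOLD = 0.5


@dataclass(frozen=True)
class VoxelRegion:
    """A binary mask as an ordered list of voxel indices on a common grid.

    Parameters
    ----------
    shape
        3-tuple of grid dimensions.
    affine
        4x4 voxel-to-mm transform.
    voxels
        ``(V, 3)`` int array of 0-based indices, stored sorted
        lexicographically and duplicate-free.
    name
        Free-text label.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray
    voxels: np.ndarray
    name: str = "region"

    def __post_init__(self):
        vox = np.asarray(self.voxels, dtype=np.intp).reshape(-1, 3)
        order = np.lexsort((vox[:, 2], vox[:, 1], vox[:, 0]))
        vox = vox[order]
        dup = np.all(np.diff(vox, axis=0) == 0, axis=1)
        if np.any(dup):
            vox = vox[np.concatenate([[True], ~dup])]
        if vox.size and (np.any(vox < 0) or np.any(vox >= np.asarray(self.shape))):
            raise ValueError(f"region {self.name!r}: voxel index outside grid {self.shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4) or not np.all(np.isfinite(affine)):
            raise ValueError("affine must be a finite 4x4 matrix")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "affine", affine)
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)

    def __len__(self) -> int:
        return len(self.voxels)

    def to_mask(self) -> np.ndarray:
        """Dense boolean mask on the grid."""
        mask = np.zeros(self.shape, dtype=bool)
        mask[tuple(self.voxels.T)] = True
        return mask

    def extract(self, volume: np.ndarray) -> np.ndarray:
        """Sample a 3-D (``-> (V,)``) or 4-D (``-> (T, V)``) volume at the
        region's voxels, rows/columns in region order."""
        volume = np.asarray(volume)
        if volume.shape[:3] != self.shape:
            raise ValueError(f"volume grid {volume.shape[:3]} != region grid {self.shape}")
        idx = tuple(self.voxels.T)
        if volume.ndim == 3:
            return volume[idx]
        if volume.ndim == 4:
            return volume[idx].T  # (V, T) -> (T, V)
        raise ValueError("expected a 3-D or 4-D volume")

    def embed(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter per-voxel values back into a dense 3-D volume."""
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_voxels,):
            raise ValueError("values must be one per region voxel")
        out = np.full(self.shape, fill, dtype=float)
        out[tuple(self.voxels.T)] = values
        return out

    def subset(self, keep: np.ndarray, name: str | None = None) -> "VoxelRegion":
        """Region restricted to a boolean keep-vector in region order."""
        keep = np.asarray(keep, dtype=bool)
        if keep.shape != (self.n_voxels,):
            raise ValueError("keep mask must match voxel count")
        return replace(self, voxels=self.voxels[keep], name=name or self.name)

    @classmethod
    def from_mask(cls, mask: np.ndarray, affine: np.ndarray,
                  name: str = "region") -> "VoxelRegion":
        """Build from a dense mask; probabilistic maps binarize at > 0.5."""
        mask = np.asarray(mask)
        if mask.ndim != 3:
            raise ValueError("mask must be 3-D")
        binary = mask > MASK_THRESHOLD if mask.dtype.kind == "f" else mask.astype(bool)
        voxels = np.argwhere(binary)
        return cls(shape=mask.shape, affine=np.asarray(affine, float),
                   voxels=voxels, name=name)


@dataclass(frozen=True)
class LabelVolume:
    """Integer-labelled parcellation on a grid (0 = background)."""

    shape: tuple[int, int, int]
    affine: np.ndarray
    labels: np.ndarray
    legend: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.shape != tuple(self.shape):
            raise ValueError("labels grid does not match shape")
        if labels.min() < 0:
            raise ValueError("labels must be non-negative")
        present = set(np.unique(labels)) - {0}
        if self.legend:
            missing = present - set(self.legend)
            if missing:
                raise ValueError(f"legend missing labels {sorted(missing)}")
        else:
            object.__setattr__(self, "legend", {int(v): str(int(v)) for v in present})
        object.__setattr__(self, "labels", labels.astype(np.int64))
        object.__setattr__(self, "affine", np.asarray(self.affine, float))
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))

    def labels_at(self, region: VoxelRegion) -> np.ndarray:
        """Per-voxel labels in region order."""
        return region.extract(self.labels)


@dataclass
class BoldSeries:
    """A ``T x V`` signal matrix bound to a region and sampling interval.

    ``data[t, v]`` is the signal of the region's v-th voxel (region order)
    at frame t; ``tr`` is the sampling interval in seconds.
    """

    region: VoxelRegion
    data: np.ndarray
    tr: float
    condition: str = "REST1"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be T x V")
        if self.data.shape[1] != self.region.n_voxels:
            raise ValueError(
                f"data has {self.data.shape[1]} columns but region has "
                f"{self.region.n_voxels} voxels")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]


def _check_same_grid(a_shape, a_affine, b_shape, b_affine, what: str = "inputs"):
    if tuple(a_shape) != tuple(b_shape):
        raise ValueError(f"{what} on different grids: {a_shape} vs {b_shape}")
    if np.max(np.abs(np.asarray(a_affine) - np.asarray(b_affine))) > AFFINE_TOL:
        raise ValueError(f"{what} have mismatched affines (tol {AFFINE_TOL})")


def load_volume(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a 3-D or 4-D NIfTI volume.

    Returns ``(data, affine)`` with the time axis last for 4-D images.
    """
    try:
        img = nib.load(str(path))
    except FileNotFoundError:
        raise FileNotFoundError(f"no such volume: {path}")
    except Exception as exc:  # nibabel raises assorted format errors
        raise ValueError(f"could not read NIfTI volume {path}: {exc}") from exc
    try:
        data = np.asarray(img.get_fdata())
    except Exception as exc:
        raise ValueError(f"could not read NIfTI volume {path}: {exc}") from exc
    if data.ndim not in (3, 4):
        raise ValueError(f"{path}: expected a 3-D or 4-D image, got {data.ndim}-D")
    affine = np.asarray(img.affine, dtype=float)
    if not np.all(np.isfinite(affine)):
        raise ValueError(f"{path}: non-finite affine")
    return data, affine


def save_volume(path, data: np.ndarray, affine: np.ndarray) -> None:
    """Write a volume as NIfTI."""
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), np.asarray(affine)),
             str(path))


def merge_masks(parts: list[VoxelRegion], name: str = "merged") -> VoxelRegion:
    """Union of subregion masks on a shared grid (e.g. genu + body + splenium).

    All parts must share shape and affine; the union is returned in
    canonical voxel order.
    """
    if not parts:
        raise ValueError("no masks to merge")
    first = parts[0]
    for p in parts[1:]:
        _check_same_grid(first.shape, first.affine, p.shape, p.affine, "masks")
    voxels = np.vstack([p.voxels for p in parts])
    if len(voxels) == 0:
        raise ValueError("union of masks is empty")
    merged = VoxelRegion(shape=first.shape, affine=first.affine,
                         voxels=voxels, name=name)
    if merged.n_voxels == 0:
        raise ValueError("union of masks is empty")
    return merged


def drop_missing_voxels(region: VoxelRegion,
                        series_list: list[BoldSeries]) -> VoxelRegion:
    """Remove voxels with absent signal (all-zero or any non-finite frame)
    in any series.

    Returns the cleaned region; the count removed is logged.  Raises if
    nothing survives.
    """
    keep = np.ones(region.n_voxels, dtype=bool)
    for series in series_list:
        if series.region.n_voxels != region.n_voxels or \
                not np.array_equal(series.region.voxels, region.voxels):
            raise ValueError("series does not cover the region")
        bad = ~np.all(np.isfinite(series.data), axis=0)
        bad |= np.all(series.data == 0, axis=0)
        keep &= ~bad
    n_removed = int(np.sum(~keep))
    if n_removed:
        logger.info("drop_missing_voxels: removed %d of %d voxels",
                    n_removed, region.n_voxels)
    if not np.any(keep):
        raise ValueError("all voxels removed: no usable signal in the region")
    return region.subset(keep)


def voxel_coordinates(region: VoxelRegion, space: str = "mm") -> np.ndarray:
    """``(V, 3)`` coordinates of the region's voxels, in region order.

    ``space="index"`` returns 0-based grid indices; ``space="mm"`` applies
    the affine to give world coordinates.
    """
    if region.n_voxels == 0:
        raise ValueError("empty region has no coordinates")
    idx = region.voxels.astype(float)
    if space == "index":
        return idx
    if space == "mm":
        return idx @ region.affine[:3, :3].T + region.affine[:3, 3]
    raise ValueError(f"unknown coordinate space {space!r} (use 'index' or 'mm')")
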
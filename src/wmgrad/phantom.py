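"""Synthetic phantoms with planted connectopic ground truth.

The phantom emulates the statistical structure the gradient pipeline
assumes, with every latent quantity recorded so recovery can be scored:

* an arch-shaped white-matter voxel region whose longest extent runs
  posterior-anterior, mimicking a mid-sagittal corpus callosum;
* gray-matter parcels whose voxel signals are network latent time courses
  plus AR(1) noise, each parcel tagged with one of seven canonical
  networks and a hemisphere;
* white-matter voxel signals that are smooth mixtures of the network
  latents, with mixing weights drifting along planted orthonormal spatial
  axes — so connectivity fingerprints vary smoothly along known
  directions and the Laplacian-eigenmap gradients have a right answer;
* structural maps (FA, myelin water fraction) and behavior scores with
  known couplings to the planted axes.

Everything is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from wmgrad.regions import BoldSeries, LabelVolume, VoxelRegion

NETWORKS = ("VN", "SMN", "DAN", "VAN", "LN", "FPN", "DMN")

#: relative magnitude of the constant background-network component
_BACKGROUND = 0.3

_VOXEL_MM = 2.0


@dataclass
class PhantomScene:
    """A generated scene plus all of its ground truth.

    ``axis_positions[v, a]`` is voxel v's position in [0, 1] along planted
    axis a; ``planted_axes[a]`` is the corresponding unit mm-space
    direction; ``mixing[v, q]`` the voxel's non-negative weight on network
    latent q (rows sum to 1).
    """

    wm_region: VoxelRegion
    gm_region: VoxelRegion
    gm_parcels: LabelVolume
    parcel_info: pd.DataFrame          # parcel_id, name, network, hemisphere
    planted_axes: np.ndarray           # (3, 3) orthonormal rows, mm space
    axis_positions: np.ndarray         # (V_wm, 3) in [0, 1]
    axis_strengths: tuple[float, float, float]
    mixing: np.ndarray                 # (V_wm, Q) simplex rows
    couplings: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def n_networks(self) -> int:
        return self.mixing.shape[1]

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_info)

    def parcel_voxel_labels(self) -> np.ndarray:
        """Parcel label of each gm voxel, in gm-region order."""
        return self.gm_parcels.labels_at(self.gm_region)


def _arch_geometry(n_wm_voxels: int):
    """Pick arch dimensions whose voxel count lands within 10% of target.

    The arch has an elliptical cross-section (half-width ``rx`` left-right,
    half-thickness ``rz``) swept along the posterior-anterior axis with its
    height following ``A*sin(pi*t)`` — symmetric in t, so arch height is
    linearly uncorrelated with position along the long axis.  The arch is
    tall and thin (amplitude 0.4 x length, thin cross-section), mimicking
    a mid-sagittal corpus callosum whose dorsal-ventral span comes mostly
    from the bend of the arch itself.
    """
    length = max(int(round(10.5 * (n_wm_voxels / 50.0) ** (1.0 / 3.0))), 8)
    amp = 0.40 * length
    best = None
    for rz in np.linspace(1.4, 3.2, 10):
        rx = n_wm_voxels / (length * np.pi * rz)
        count = _count_arch(length, rx, rz, amp)
        err = abs(count - n_wm_voxels)
        if best is None or err < best[0]:
            best = (err, rx, rz, count)
    err, rx, rz, count = best
    if count < 0.9 * n_wm_voxels or count > 1.1 * n_wm_voxels:
        raise ValueError(f"cannot realize a ~{n_wm_voxels}-voxel arch "
                         f"(closest achievable: {count})")
    return length, rx, rz, amp


def _arch_members(length, rx, rz, amp, i_c, j0, z_base):
    """Integer (i, j, k) triples inside the arch."""
    tri = []
    zmax = int(np.ceil(z_base + amp + rz)) + 1
    for j in range(j0, j0 + length):
        t = (j - j0) / max(length - 1, 1)
        z_c = z_base + amp * np.sin(np.pi * t)
        for i in range(int(np.floor(i_c - rx)), int(np.ceil(i_c + rx)) + 1):
            for k in range(0, zmax):
                if ((i - i_c) / rx) ** 2 + ((k - z_c) / rz) ** 2 <= 1.0:
                    tri.append((i, j, k))
    return np.array(tri, dtype=np.intp)


def _count_arch(length, rx, rz, amp):
    return len(_arch_members(length, rx, rz, amp, i_c=0.0, j0=0, z_base=amp + rz + 1))


def make_scene(n_wm_voxels: int = 1500, n_parcels: int = 40, seed: int = 0,
               axis_strengths: tuple[float, float, float] = (1.0, 0.55, 0.33),
               ) -> PhantomScene:
    """Generate a phantom scene.

    Parameters
    ----------
    n_wm_voxels
        Target white-matter voxel count (realized within 10%); >= 50.
    n_parcels
        Number of gray-matter parcels (>= 14, so every network has at
        least two parcels and each hemisphere is populated).
    axis_strengths
        Relative amount of connectivity-fingerprint variation planted
        along each spatial axis.  The default is proportional to the
        arch's spatial extents, so fingerprint change per mm is the same
        in every direction and the connectivity manifold is an isometric
        copy of the region's geometry — the regime the gradient method
        assumes (gradients tracking the structure's own spatial axes),
        with a dominant posterior-anterior axis, a weaker dorsal-ventral
        axis, and a weak left-right axis.
    """
    if n_wm_voxels < 50:
        raise ValueError("n_wm_voxels must be >= 50")
    if n_parcels < 14:
        raise ValueError("n_parcels must be >= 14 (2 per network)")
    rng = np.random.default_rng(seed)

    length, rx, rz, amp = _arch_geometry(n_wm_voxels)

    # grid: gm slabs hug the x extremes, arch sits centered above a gm gap
    gm_margin = 3
    nx = 2 * (int(np.ceil(rx)) + 1) + 1 + 2 * (gm_margin + 2)
    ny = length + 4
    n_side = (n_parcels + 1) // 2
    per_col = max(ny // 6, 1)
    n_cols = int(np.ceil(n_side / per_col))
    nz = max(int(np.ceil(amp + 2 * rz)) + n_cols + 6, 12)
    z_base = n_cols + 3 + rz
    i_c = (nx - 1) / 2.0
    j0 = 2

    affine = np.diag([_VOXEL_MM, _VOXEL_MM, _VOXEL_MM, 1.0])
    affine[:3, 3] = -_VOXEL_MM * (np.array([nx, ny, nz]) - 1) / 2.0

    wm_vox = _arch_members(length, rx, rz, amp, i_c, j0, z_base)
    wm_region = VoxelRegion(shape=(nx, ny, nz), affine=affine,
                            voxels=wm_vox, name="wm_arch")

    # gray-matter parcels: 2x5x1 voxel blocks in left/right slabs
    labels = np.zeros((nx, ny, nz), dtype=np.int64)
    records = []
    for p in range(n_parcels):
        side = p % 2                     # 0 = left (low i / negative x)
        m = p // 2
        col, row = divmod(m, per_col)
        i_lo = 0 if side == 0 else nx - 2
        j_lo = 2 + row * 6
        k = col
        if j_lo + 5 > ny:
            raise ValueError("n_parcels too large for this scene geometry")
        labels[i_lo:i_lo + 2, j_lo:j_lo + 5, k] = p + 1
        network = NETWORKS[p % len(NETWORKS)]
        records.append({"parcel_id": p + 1,
                        "name": f"{network}_{'L' if side == 0 else 'R'}_{m}",
                        "network": network,
                        "hemisphere": "L" if side == 0 else "R"})
    parcel_info = pd.DataFrame(records)
    legend = {r["parcel_id"]: r["name"] for r in records}
    gm_parcels = LabelVolume(shape=(nx, ny, nz), affine=affine,
                             labels=labels, legend=legend)
    gm_region = VoxelRegion.from_mask(labels > 0, affine, name="gm_parcels")

    # planted axes: PA (+y), DV (+z), LR (+x) in world mm
    planted_axes = np.array([[0.0, 1.0, 0.0],
                             [0.0, 0.0, 1.0],
                             [1.0, 0.0, 0.0]])
    mm = wm_region.voxels.astype(float) @ affine[:3, :3].T + affine[:3, 3]
    proj = mm @ planted_axes.T
    lo, hi = proj.min(axis=0), proj.max(axis=0)
    axis_positions = (proj - lo) / np.where(hi > lo, hi - lo, 1.0)

    # smooth simplex mixing weights over the 7 network latents
    mixing = _mixing_weights(axis_positions, axis_strengths)

    couplings = {"fa_axis": 2, "mwf_axis": 1,
                 "behavior_base": 1.0, "fc_profile_scale": 0.6}
    return PhantomScene(wm_region=wm_region, gm_region=gm_region,
                        gm_parcels=gm_parcels, parcel_info=parcel_info,
                        planted_axes=planted_axes,
                        axis_positions=axis_positions,
                        axis_strengths=tuple(float(s) for s in axis_strengths),
                        mixing=mixing, couplings=couplings, seed=int(seed))


def _mixing_weights(u: np.ndarray, strengths) -> np.ndarray:
    """Arc-product mixing: smooth simplex weights with isometric geometry.

    Each planted axis a contributes a pair of networks whose weights
    trace a quarter-circle arc of radius ``strengths[a]`` as the voxel's
    position u_a goes 0 -> 1: ``(s_a cos(pi/2 u_a), s_a sin(pi/2 u_a))``.
    A seventh, constant background network keeps every voxel a genuine
    blend.  Because each pair contributes s_a^2 to the squared L2 norm
    regardless of position, the norm of the raw vector is constant, so
    after normalization the voxel's connectivity *direction* moves at
    constant speed (pi/2)*s_a per unit u_a — the fingerprint manifold is
    a flat product of arcs, with planted per-axis lengths set purely by
    the strengths.  Weights are non-negative and L1-normalized to a
    simplex.
    """
    s = np.asarray(strengths, dtype=float)
    if np.all(s == 0):
        raise ValueError("at least one axis strength must be positive")
    cols = []
    for a in range(3):
        phi = (np.pi / 2.0) * u[:, a]
        cols.append(s[a] * np.cos(phi))
        cols.append(s[a] * np.sin(phi))
    cols.append(np.full(len(u), _BACKGROUND * s.max()))
    m = np.stack(cols, axis=1)
    return m / m.sum(axis=1, keepdims=True)


def _ar1_noise(rng, shape, sd: float, ar1: float) -> np.ndarray:
    """Stationary AR(1) Gaussian noise with marginal sd ``sd``."""
    if sd == 0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    if ar1 == 0:
        return sd * white
    t_frames = shape[0]
    out = np.empty(shape)
    out[0] = white[0]
    innov = np.sqrt(1.0 - ar1 ** 2)
    for t in range(1, t_frames):
        out[t] = ar1 * out[t - 1] + innov * white[t]
    return sd * out


def simulate_bold(scene: PhantomScene, t_frames: int = 400,
                  noise_sd: float = 0.5, ar1: float = 0.3,
                  seed: int = 0, condition: str = "REST1",
                  tr: float = 0.72) -> tuple[BoldSeries, BoldSeries]:
    """Simulate gray- and white-matter BOLD for a scene.

    Gray-matter parcel voxels carry their network's latent time course
    plus AR(1) noise; each white-matter voxel carries its planted mixture
    of the latents plus AR(1) noise.  ``noise_sd=0`` gives noiseless
    mixtures.  Returns ``(gm_series, wm_series)``.
    """
    if t_frames < 2 * scene.n_parcels:
        raise ValueError("t_frames must be >= 2 * n_parcels for a "
                         "well-posed gray-matter PCA basis")
    if not (0.0 <= ar1 < 1.0):
        raise ValueError("ar1 must lie in [0, 1)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)

    q = scene.n_networks
    latents = rng.standard_normal((t_frames, q))

    parcel_network_idx = np.array(
        [NETWORKS.index(n) for n in scene.parcel_info["network"]])
    gm_labels = scene.parcel_voxel_labels()
    gm_net = parcel_network_idx[gm_labels - 1]           # per gm voxel
    gm_signal = latents[:, gm_net]
    gm_data = gm_signal + _ar1_noise(rng, gm_signal.shape, noise_sd, ar1)

    wm_signal = latents @ scene.mixing.T
    wm_data = wm_signal + _ar1_noise(rng, wm_signal.shape, noise_sd, ar1)

    gm = BoldSeries(region=scene.gm_region, data=gm_data, tr=tr,
                    condition=condition)
    wm = BoldSeries(region=scene.wm_region, data=wm_data, tr=tr,
                    condition=condition)
    return gm, wm


def simulate_structural_maps(scene: PhantomScene, rho_fa: float = 0.3,
                             rho_mwf: float = 0.5, seed: int = 0,
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Simulate FA and myelin-water-fraction volumes coupled to the axes.

    Each map's latent is ``rho * standardized(u-axis) + sqrt(1-rho^2) *
    noise`` so its expected correlation with the planted axis is ``rho``.
    FA couples to the dorsal-ventral axis (axis 2) and MWF to the
    posterior-anterior axis (axis 1), mirroring the microstructural
    couplings the pipeline is meant to detect.  FA is mapped onto a
    plausible 0-1 intensity scale (0.55 +/- 0.12) and clipped to [0, 1];
    MWF onto 0.15 +/- 0.04.  Returns dense 3-D volumes (zero outside the
    white-matter region).
    """
    if abs(rho_fa) > 1 or abs(rho_mwf) > 1:
        raise ValueError("|rho| must be <= 1")
    rng = np.random.default_rng(seed)
    v = scene.wm_region.n_voxels

    def latent(rho, axis_idx):
        u = scene.axis_positions[:, axis_idx]
        zu = (u - u.mean()) / u.std()
        return rho * zu + np.sqrt(1.0 - rho ** 2) * rng.standard_normal(v)

    fa_vals = np.clip(0.55 + 0.12 * latent(rho_fa, scene.couplings["fa_axis"] - 1),
                      0.0, 1.0)
    mwf_vals = 0.15 + 0.04 * latent(rho_mwf, scene.couplings["mwf_axis"] - 1)
    return scene.wm_region.embed(fa_vals), scene.wm_region.embed(mwf_vals)


def simulate_behavior(scene: PhantomScene, n_subjects: int = 100,
                      effect: float = 1.0, seed: int = 0,
                      n_subdomains: int = 3, score_noise_sd: float = 0.5,
                      coupling_noise_sd: float = 0.3,
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate behavior scores and per-subject FC-coupling parameters.

    Each subject has a latent trait; the subject's white-matter-to-cortex
    coupling strength is ``base + effect * trait + noise`` and the
    subdomain scores are noisy copies of the trait (so their first
    principal component recovers it).  Returns ``(behavior, params)``
    tables keyed by subject.
    """
    if n_subjects < 10:
        raise ValueError("n_subjects must be >= 10")
    rng = np.random.default_rng(seed)
    trait = rng.standard_normal(n_subjects)
    coupling = (scene.couplings["behavior_base"] + effect * trait
                + coupling_noise_sd * rng.standard_normal(n_subjects))
    subjects = [f"sub-{s + 1:03d}" for s in range(n_subjects)]
    behavior = pd.DataFrame({"subject": subjects})
    for d in range(n_subdomains):
        behavior[f"score_{d + 1}"] = trait + score_noise_sd * rng.standard_normal(n_subjects)
    params = pd.DataFrame({"subject": subjects, "trait": trait,
                           "coupling": coupling})
    return behavior, params


def simulate_subject_fc(scene: PhantomScene, params: pd.DataFrame,
                        noise_sd: float = 0.2, seed: int = 0) -> np.ndarray:
    """Per-subject voxel-by-parcel Fisher-z connectivity matrices.

    The group profile couples each white-matter voxel to a parcel through
    the voxel's mixing weight on the parcel's network; each subject scales
    it by their coupling strength and adds independent noise.  Returns an
    ``(S, V, P)`` array.
    """
    rng = np.random.default_rng(seed)
    parcel_net = np.array([NETWORKS.index(n) for n in scene.parcel_info["network"]])
    base = scene.couplings["fc_profile_scale"] * scene.mixing[:, parcel_net]
    coupling = params["coupling"].to_numpy()
    fc = coupling[:, None, None] * base[None, :, :]
    fc = fc + noise_sd * rng.standard_normal(fc.shape)
    return fc


def make_toy_atlas(scene: PhantomScene, k: int = 3, axis: int = 1) -> LabelVolume:
    """Ground-truth partition: k equal-quantile bands of a planted axis.

    Serves as the anatomical atlas analogue (for k=3: genu/body/splenium
    style bands along the long axis) for Dice validation.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if axis not in (1, 2, 3):
        raise ValueError("axis must be 1, 2 or 3")
    v = scene.wm_region.n_voxels
    if k > v:
        raise ValueError("k exceeds voxel count")
    u = scene.axis_positions[:, axis - 1]
    order = np.argsort(u, kind="stable")
    bands = np.empty(v, dtype=np.int64)
    # equal-count bands (quantile split), ties resolved by stable voxel order
    edges = (np.arange(1, k + 1) * v) // k
    start = 0
    for label, stop in enumerate(edges, start=1):
        bands[order[start:stop]] = label
        start = stop
    labels = np.zeros(scene.wm_region.shape, dtype=np.int64)
    labels[tuple(scene.wm_region.voxels.T)] = bands
    legend = {i: f"band_{i}" for i in range(1, k + 1)}
    return LabelVolume(shape=scene.wm_region.shape,
                       affine=scene.wm_region.affine,
                       labels=labels, legend=legend)
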
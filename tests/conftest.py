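"""Shared fixtures: a small phantom scene and its BOLD simulations.

Session-scoped so the moderately expensive generation runs once; tests
must not mutate fixture objects in place.
"""

import numpy as np
import pytest

import wmgrad as w


@pytest.fixture(scope="session")
def small_scene():
    """~300-voxel arch with 20 parcels — fast enough for unit tests."""
    return w.make_scene(n_wm_voxels=300, n_parcels=20, seed=7)


@pytest.fixture(scope="session")
def small_bold(small_scene):
    """Noiseless BOLD for the small scene (T=200)."""
    return w.simulate_bold(small_scene, t_frames=200, noise_sd=0.0,
                           ar1=0.0, seed=7)


@pytest.fixture(scope="session")
def small_gradients(small_scene, small_bold):
    """Gradients of the noiseless small scene."""
    gm, wm = small_bold
    basis = w.gm_pca_basis(gm)
    sim = w.similarity_matrix(w.fingerprints(wm, basis))
    graph = w.sparsify_connected(sim)
    return w.laplacian_eigenmaps(graph, k=3, region=small_scene.wm_region)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
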
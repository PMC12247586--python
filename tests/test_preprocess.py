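"""Signal-cleaning chain: regression steps, smoothing, spectral denoising."""

import numpy as np
import pytest

from wmgrad.preprocess import (
    ConfoundTable,
    TaskEvents,
    detrend_linear,
    double_gamma_hrf,
    expand_motion_24,
    preprocess_run,
    regress_nuisance,
    remove_task_effects,
    smooth_within_mask,
    task_regressors,
    wishart_denoise,
    zscore_concatenate,
    zscore_runs,
)
from wmgrad.regions import BoldSeries, VoxelRegion

import pandas as pd


def make_series(data, tr=1.0):
    data = np.asarray(data, dtype=float)
    vox = [[i, 0, 0] for i in range(data.shape[1])]
    region = VoxelRegion(shape=(max(data.shape[1], 1), 1, 1),
                         affine=np.eye(4), voxels=np.array(vox))
    return BoldSeries(region=region, data=data, tr=tr)


class TestDetrend:
    def test_pure_line_removed_exactly(self):
        t = np.arange(50.0)
        series = make_series(np.column_stack([3 + 0.5 * t, -2 * t]))
        out = detrend_linear(series)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-10)

    def test_residual_orthogonal_to_time(self, rng):
        series = make_series(rng.normal(size=(100, 5)))
        out = detrend_linear(series)
        t = np.arange(100.0)
        tc = t - t.mean()
        for v in range(5):
            r = out.data[:, v] @ tc / (np.linalg.norm(out.data[:, v])
                                       * np.linalg.norm(tc))
            assert abs(r) < 1e-10
        np.testing.assert_allclose(out.data.mean(axis=0), 0.0, atol=1e-12)

    def test_sine_amplitude_preserved(self):
        # projection-residual oracle: subtract the sine's own OLS line
        t = np.arange(200.0)
        sine = np.sin(2 * np.pi * t / 20)
        x = np.column_stack([np.ones_like(t), t])
        beta = np.linalg.lstsq(x, sine, rcond=None)[0]
        oracle = sine - x @ beta
        out = detrend_linear(make_series(sine[:, None]))
        np.testing.assert_allclose(out.data[:, 0], oracle, atol=1e-10)
        # rms amplitude of a unit sine is 1/sqrt(2)
        assert out.data[:, 0].std() * np.sqrt(2) == pytest.approx(1.0, rel=0.01)


class TestNuisanceRegression:
    def test_series_equal_to_confound_zeroed(self, rng):
        c = rng.normal(size=(80, 3))
        conf = ConfoundTable(values=c, columns=["a", "b", "csf"])
        out = regress_nuisance(make_series(c[:, [1]]), conf)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-10)

    def test_orthogonal_series_unchanged(self, rng):
        c = rng.normal(size=(200, 2))
        y = rng.normal(size=(200, 1))
        # orthogonalize y against confounds and intercept first
        x = np.column_stack([np.ones(200), c])
        y = y - x @ np.linalg.lstsq(x, y, rcond=None)[0]
        out = regress_nuisance(make_series(y),
                               ConfoundTable(values=c, columns=["a", "b"]))
        np.testing.assert_allclose(out.data, y, atol=1e-10)

    def test_planted_effect_removed_leaves_noise_variance(self, rng):
        c1 = rng.normal(size=400)
        e = rng.normal(size=400)
        y = 2.0 * c1 + e
        out = regress_nuisance(make_series(y[:, None]),
                               ConfoundTable(values=c1[:, None], columns=["c1"]))
        assert out.data[:, 0].var() == pytest.approx(e.var(), rel=0.05)

    def test_rank_deficient_design_names_problem(self, rng):
        c = rng.normal(size=(50, 1))
        conf = ConfoundTable(values=np.hstack([c, 2 * c]), columns=["a", "b"])
        with pytest.raises(ValueError, match="rank"):
            regress_nuisance(make_series(rng.normal(size=(50, 2))), conf)

    def test_motion_expansion_shape_and_content(self, rng):
        m6 = rng.normal(size=(30, 6))
        m24 = expand_motion_24(m6)
        assert m24.shape == (30, 24)
        np.testing.assert_array_equal(m24[:, :6], m6)
        np.testing.assert_array_equal(m24[1:, 6:12], np.diff(m6, axis=0))
        np.testing.assert_array_equal(m24[:, 12:18], m6 ** 2)


class TestTaskRemoval:
    def _events(self, rows):
        return TaskEvents(pd.DataFrame(rows))

    def test_convolved_regressor_itself_zeroed(self):
        ev = self._events([{"onset": 5.0, "duration": 10.0,
                            "trial_type": "go", "amplitude": 1.0}])
        design, names = task_regressors(ev, n_frames=100, tr=1.0)
        assert names == ["go"]
        out = remove_task_effects(make_series(design), ev)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-10)

    def test_no_events_is_warned_noop(self, rng):
        series = make_series(rng.normal(size=(50, 2)))
        with pytest.warns(UserWarning, match="no events"):
            out = remove_task_effects(series, None)
        np.testing.assert_array_equal(out.data, series.data)

    def test_two_overlapping_conditions_leave_noise_variance(self, rng):
        ev = self._events([
            {"onset": 10.0, "duration": 20.0, "trial_type": "a", "amplitude": 1.0},
            {"onset": 20.0, "duration": 20.0, "trial_type": "b", "amplitude": 2.0},
            {"onset": 120.0, "duration": 20.0, "trial_type": "a", "amplitude": 1.0},
            {"onset": 160.0, "duration": 15.0, "trial_type": "b", "amplitude": 1.0},
        ])
        design, _ = task_regressors(ev, n_frames=300, tr=1.0)
        noise = rng.normal(size=300)
        y = design.sum(axis=1) + noise
        out = remove_task_effects(make_series(y[:, None]), ev)
        assert out.data[:, 0].var() == pytest.approx(noise.var(), rel=0.10)

    def test_hrf_peaks_where_parameterized(self):
        h = double_gamma_hrf(tr=0.1, peak=6.0)
        assert np.argmax(h) * 0.1 == pytest.approx(6.0, abs=0.2)
        assert h.min() < 0  # undershoot present


class TestSmoothing:
    def _mask(self, shape=(13, 13, 13)):
        m = np.zeros(shape, dtype=bool)
        m[1:-1, 1:-1, 1:-1] = True
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
        return VoxelRegion.from_mask(m, affine)

    def test_zero_fwhm_is_identity_inside_mask(self, rng):
        mask = self._mask()
        vol = rng.normal(size=(13, 13, 13))
        out = smooth_within_mask(vol, mask, fwhm=0.0)
        m = mask.to_mask()
        np.testing.assert_array_equal(out[m], vol[m])
        assert np.all(out[~m] == 0)

    def test_constant_preserved_by_renormalization(self):
        mask = self._mask()
        vol = np.full((13, 13, 13), 3.7)
        out = smooth_within_mask(vol, mask, fwhm=4.0)
        np.testing.assert_allclose(out[mask.to_mask()], 3.7, atol=1e-10)

    def test_impulse_mass_conserved_over_mask(self):
        # impulse far from the mask edge: renormalization redistributes
        # nothing, so the smoothed mass over the mask is exactly the input
        mask = self._mask(shape=(21, 21, 21))
        vol = np.zeros((21, 21, 21))
        vol[10, 10, 10] = 1.0
        out = smooth_within_mask(vol, mask, fwhm=4.0)
        assert out[mask.to_mask()].sum() == pytest.approx(1.0, abs=1e-6)

    def test_out_of_mask_values_never_leak_in(self, rng):
        mask = self._mask()
        vol = rng.normal(size=(13, 13, 13))
        spiked = vol.copy()
        spiked[~mask.to_mask()] = 1e6
        a = smooth_within_mask(vol, mask, fwhm=6.0)
        b = smooth_within_mask(spiked, mask, fwhm=6.0)
        np.testing.assert_allclose(a, b, atol=1e-8)

    def test_negative_fwhm_rejected(self, rng):
        with pytest.raises(ValueError):
            smooth_within_mask(np.zeros((13, 13, 13)), self._mask(), fwhm=-1)


class TestWishartDenoise:
    def test_pure_noise_strongly_attenuated(self, rng):
        series = make_series(rng.normal(size=(200, 100)))
        out = wishart_denoise(series)
        assert out.data.var() < 0.2 * series.data.var()

    def test_noiseless_low_rank_preserved(self, rng):
        latents = rng.normal(size=(150, 3))
        mixing = rng.normal(size=(3, 40))
        series = make_series(latents @ mixing)
        out = wishart_denoise(series)
        for v in range(40):
            r = np.corrcoef(out.data[:, v], series.data[:, v])[0, 1]
            assert r >= 0.99

    def test_denoising_improves_latent_recovery(self, rng):
        # shared latent at SNR 10 (variance ratio), 20 replicates
        wins = 0
        for rep in range(20):
            rng_rep = np.random.default_rng(100 + rep)
            latent = rng_rep.normal(size=120)
            load = rng_rep.normal(size=60)
            data = np.sqrt(10) * latent[:, None] * load[None, :] \
                + rng_rep.normal(size=(120, 60))
            out = wishart_denoise(make_series(data))
            r_raw = np.mean([abs(np.corrcoef(data[:, v], latent)[0, 1])
                             for v in range(60)])
            r_den = np.mean([abs(np.corrcoef(out.data[:, v], latent)[0, 1])
                             for v in range(60)])
            wins += r_den > r_raw
        assert wins >= 18

    def test_too_small_input_rejected(self, rng):
        with pytest.raises(ValueError):
            wishart_denoise(make_series(rng.normal(size=(5, 20))))


class TestZscoreConcatenate:
    def test_single_run_is_zscore(self, rng):
        series = make_series(rng.normal(loc=5, scale=3, size=(100, 4)))
        out = zscore_concatenate([series])
        np.testing.assert_allclose(out.data.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.data.std(axis=0), 1.0, atol=1e-12)

    def test_two_runs_stack_in_time(self, rng):
        series = make_series(rng.normal(size=(60, 3)))
        out = zscore_concatenate([series, series])
        assert out.n_frames == 120
        np.testing.assert_allclose(out.data[:60], out.data[60:])

    def test_runs_contribute_equal_variance_regardless_of_scale(self, rng):
        latent = rng.normal(size=80)
        a = make_series(latent[:, None] * 1.0)
        b = make_series(latent[:, None] * 10.0)
        out = zscore_concatenate([a, b])
        assert out.data[:80, 0].var() == pytest.approx(out.data[80:, 0].var())

    def test_zscoring_is_idempotent(self, rng):
        series = make_series(rng.normal(size=(50, 3)))
        once = zscore_runs(series)
        twice = zscore_runs(once)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-12)

    def test_zero_variance_voxel_rejected(self, rng):
        data = rng.normal(size=(50, 2))
        data[:, 1] = 4.2
        with pytest.raises(ValueError, match="variance"):
            zscore_concatenate([make_series(data)])


class TestChain:
    def test_full_chain_output_is_zscored_and_orthogonal(self, rng):
        t = np.arange(120.0)
        drift = 0.05 * t[:, None]
        conf = ConfoundTable(values=rng.normal(size=(120, 3)),
                             columns=["m1", "m2", "csf"])
        data = rng.normal(size=(120, 30)) + drift
        out = preprocess_run(make_series(data), confounds=conf, wishart=False)
        np.testing.assert_allclose(out.data.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.data.std(axis=0), 1.0, atol=1e-10)
        # residual orthogonality to each confound column survives z-scoring
        for j in range(3):
            c = conf.values[:, j] - conf.values[:, j].mean()
            inner = np.abs(out.data.T @ c)
            norms = np.linalg.norm(out.data, axis=0) * np.linalg.norm(c)
            assert np.all(inner < 1e-8 * norms)
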
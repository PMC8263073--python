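"""Preprocessing contracts: epoch selection, filtering, regression, ROI means."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gaersnet import (
    MotionParams,
    RoiTimeSeries,
    extract_roi_timeseries,
    generate_atlas,
    lowpass_fourier,
    regress_global_signal,
    select_stable_epoch,
    smooth_image,
    temporal_snr,
)


def _motion(trans, rots=None):
    t = np.asarray(trans, dtype=float)
    r = np.zeros_like(t) if rots is None else np.asarray(rots, dtype=float)
    return MotionParams(translations=t, rotations=r)


def _ts(values, tr=1.0):
    values = np.asarray(values, dtype=float)
    labels = tuple(f"r{i}" for i in range(values.shape[1]))
    return RoiTimeSeries(values=values, tr=tr, labels=labels)


def brute_force_epoch(motion, epoch_length, max_t=0.2, max_r=0.3):
    """Independent oracle: scan every window, check every axis."""
    T = motion.n_volumes
    for s in range(T - epoch_length + 1):
        ok = True
        for ax in range(3):
            wt = motion.translations[s: s + epoch_length, ax]
            wr = motion.rotations[s: s + epoch_length, ax]
            if wt.max() - wt.min() >= max_t or wr.max() - wr.min() >= max_r:
                ok = False
                break
        if ok:
            return (s, s + epoch_length)
    return None


class TestStableEpoch:
    def test_stable_run_returns_first_window(self):
        m = _motion(np.zeros((1800, 3)))
        assert select_stable_epoch(m, 900) == (0, 900)

    def test_early_spike_shifts_window_past_it(self):
        t = np.zeros((1800, 3))
        t[10, 0] = 1.0
        m = _motion(t)
        assert select_stable_epoch(m, 900) == (11, 911)
        assert select_stable_epoch(m, 900) == brute_force_epoch(m, 900)

    def test_continuous_drift_disqualifies_everything(self):
        t = np.linspace(0, 5, 1000)[:, None] * np.ones((1, 3))
        assert select_stable_epoch(_motion(t), 900) is None

    def test_matches_exhaustive_scan_on_random_motion(self, rng):
        for _ in range(20):
            t = rng.normal(0, 0.08, size=(200, 3)).cumsum(axis=0) * 0.1
            r = rng.normal(0, 0.1, size=(200, 3)).cumsum(axis=0) * 0.1
            m = _motion(t, r)
            assert select_stable_epoch(m, 50) == brute_force_epoch(m, 50)


class TestLowpassFourier:
    def test_constant_series_unchanged(self):
        ts = _ts(np.full((100, 2), 7.0))
        out = lowpass_fourier(ts, 0.1)
        assert np.allclose(out.values, 7.0)

    def test_stopband_sinusoid_removed(self):
        t = np.arange(200)
        ts = _ts(np.sin(2 * np.pi * 0.2 * t)[:, None])
        out = lowpass_fourier(ts, 0.1)
        assert np.abs(out.values).max() < 1e-10

    def test_passband_component_survives_mixture(self):
        t = np.arange(400, dtype=float)
        slow = np.sin(2 * np.pi * 0.05 * t)
        fast = np.sin(2 * np.pi * 0.3 * t)
        out = lowpass_fourier(_ts((slow + fast)[:, None]), 0.1)
        r = np.corrcoef(out.values[:, 0], slow)[0, 1]
        assert r > 0.99

    def test_cutoff_at_or_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass_fourier(_ts(np.zeros((10, 1)) + np.arange(10)[:, None]), 0.5)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_idempotent_and_linear(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(64, 3))
        y = rng.normal(size=(64, 3))
        fx = lowpass_fourier(_ts(x), 0.1).values
        assert np.allclose(lowpass_fourier(_ts(fx), 0.1).values, fx, atol=1e-10)
        fxy = lowpass_fourier(_ts(x + 2.0 * y), 0.1).values
        fy = lowpass_fourier(_ts(y), 0.1).values
        assert np.allclose(fxy, fx + 2.0 * fy, atol=1e-10)
        assert fx.mean(axis=0) == pytest.approx(x.mean(axis=0), abs=1e-10)


class TestGlobalSignalRegression:
    def test_identical_regions_leave_zero_residuals(self):
        base = np.sin(np.linspace(0, 20, 100))
        ts = _ts(np.tile(base[:, None], (1, 4)))
        out = regress_global_signal(ts)
        assert np.abs(out.values).max() < 1e-10

    def test_antiphase_pair_is_orthogonal_to_constant_global(self):
        base = np.sin(np.linspace(0, 20, 100))
        ts = _ts(np.column_stack([base, -base]))
        with pytest.warns(UserWarning, match="constant"):
            out = regress_global_signal(ts)
        # global signal is exactly zero; series are only centered
        assert np.allclose(out.values, ts.values - ts.values.mean(axis=0), atol=1e-12)

    def test_residuals_uncorrelated_with_global_mean(self, rng):
        ts = _ts(rng.normal(size=(120, 5)))
        g = ts.values.mean(axis=1)
        out = regress_global_signal(ts)
        for j in range(5):
            r = np.corrcoef(out.values[:, j], g)[0, 1]
            assert abs(r) < 1e-10

    def test_invariant_to_positive_rescaling_of_input(self, rng):
        x = rng.normal(size=(80, 4))
        a = regress_global_signal(_ts(x)).values
        b = regress_global_signal(_ts(3.5 * x)).values
        assert np.allclose(b, 3.5 * a, atol=1e-10)


class TestSmoothImage:
    def test_impulse_response_is_normalized_stencil(self):
        img = np.zeros((9, 9, 1, 1))
        img[4, 4, 0, 0] = 1.0
        out = smooth_image(img, pixel_size_mm=(0.3, 0.3))
        assert out.sum() == pytest.approx(1.0, abs=1e-12)
        assert out[4, 4, 0, 0] == out.max()
        assert np.abs(out[:3]).sum() == 0  # truncated 3x3 support

    def test_constant_image_unchanged_in_interior(self):
        img = np.full((8, 8, 2, 2), 5.0)
        out = smooth_image(img, pixel_size_mm=(0.3, 0.3))
        assert np.allclose(out[1:-1, 1:-1], 5.0)

    def test_superposition_of_two_impulses(self):
        a = np.zeros((11, 11, 1, 1)); a[3, 3, 0, 0] = 1.0
        b = np.zeros((11, 11, 1, 1)); b[7, 6, 0, 0] = 1.0
        both = smooth_image(a + b, pixel_size_mm=(0.3, 0.3))
        separate = smooth_image(a, pixel_size_mm=(0.3, 0.3)) + smooth_image(
            b, pixel_size_mm=(0.3, 0.3)
        )
        assert np.allclose(both, separate, atol=1e-12)

    def test_missing_pixel_size_rejected(self):
        with pytest.raises(ValueError, match="pixel"):
            smooth_image(np.zeros((4, 4, 1, 1)))


class TestRoiExtraction:
    @pytest.fixture()
    def small_setup(self, rng):
        atlas = generate_atlas(2, {"thalamus": 2})
        label_map = np.zeros((4, 4, 2), dtype=int)
        label_map[0, 0, 0] = 1
        label_map[1:3, 1:3, 0] = 2
        label_map[0, 0, 1] = 3
        label_map[3, 3, 1] = 4
        data = rng.normal(size=(4, 4, 2, 10))
        return atlas, label_map, data

    def test_uniform_image_gives_constant_series(self):
        atlas = generate_atlas(1, {"limbic": 1})
        lbl = np.zeros((2, 2, 1), dtype=int)
        lbl[0, 0, 0], lbl[1, 1, 0] = 1, 2
        data = np.full((2, 2, 1, 5), 3.25)
        ts = extract_roi_timeseries(data, lbl, atlas)
        assert np.allclose(ts.values, 3.25)

    def test_matches_brute_force_label_means(self, small_setup):
        atlas, lbl, data = small_setup
        ts = extract_roi_timeseries(data, lbl, atlas)
        for ri in range(4):
            vox = np.argwhere(lbl == ri + 1)
            for t in range(10):
                expected = np.mean([data[x, y, z, t] for x, y, z in vox])
                assert ts.values[t, ri] == pytest.approx(expected, abs=1e-12)

    def test_commutes_with_temporal_subsetting(self, small_setup):
        atlas, lbl, data = small_setup
        full = extract_roi_timeseries(data, lbl, atlas)
        sub = extract_roi_timeseries(data[..., 2:7], lbl, atlas)
        assert np.allclose(full.values[2:7], sub.values)

    def test_empty_region_rejected(self, small_setup):
        atlas, lbl, data = small_setup
        lbl = lbl.copy()
        lbl[lbl == 4] = 0
        with pytest.raises(ValueError, match="thal2_R"):
            extract_roi_timeseries(data, lbl, atlas)


class TestTemporalSnr:
    def test_known_mean_over_noise_sd(self, rng):
        data = 100.0 + rng.normal(0, 1, size=(5, 5, 1, 2000))
        mask = np.ones((5, 5, 1), dtype=bool)
        assert temporal_snr(data, mask) == pytest.approx(100.0, rel=0.05)

    def test_zero_mean_noise_gives_near_zero(self, rng):
        data = rng.normal(0, 1, size=(4, 4, 1, 2000))
        mask = np.ones((4, 4, 1), dtype=bool)
        assert abs(temporal_snr(data, mask)) < 0.1

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            temporal_snr(np.zeros((2, 2, 1, 5)), np.zeros((2, 2, 1), dtype=bool))

    def test_zero_sd_voxels_excluded_and_counted(self, rng):
        data = rng.normal(10, 1, size=(2, 2, 1, 500))
        data[0, 0, 0, :] = 42.0  # constant voxel
        mask = np.ones((2, 2, 1), dtype=bool)
        res = temporal_snr(data, mask)
        assert res.n_zero_sd == 1
        assert res.n_voxels == 3
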
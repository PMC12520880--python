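"""The 22 voxel-level features: window statistics, co-occurrence texture
and enhancement kinetics, against brute-force oracles."""

import itertools

import numpy as np
import pytest

from habitatmri.image import DynamicSeries, VolumeImage
from habitatmri.synthetic import PhantomSpec, HabitatParams, generate_phantom
from habitatmri.voxel_features import (
    ENHANCEMENT_FEATURES,
    FEATURE_NAMES,
    STAT_FEATURES,
    TEXTURE_FEATURES,
    VoxelFeatureConfig,
    assemble_voxel_features,
    compute_enhancement_params,
    compute_local_statistics,
    compute_local_texture,
)


def _vol(arr):
    return VolumeImage(np.asarray(arr, dtype=float))


def _series(stacks, times):
    phases = tuple(_vol(s) for s in stacks)
    return DynamicSeries(phases=phases, times_s=tuple(times))


def brute_window_stats(values, mask, center, radius=1):
    """Direct enumeration of the in-mask window around *center*."""
    vals = []
    for off in itertools.product(range(-radius, radius + 1), repeat=3):
        pt = tuple(np.array(center) + off)
        if all(0 <= pt[i] < values.shape[i] for i in range(3)) and mask[pt]:
            vals.append(values[pt])
    v = np.array(vals)
    return {
        "stat_mean": v.mean(), "stat_median": np.median(v),
        "stat_sd": v.std(), "stat_min": v.min(), "stat_max": v.max(),
    }


class TestFeatureContract:
    def test_exactly_22_named_columns(self, small_voxel_table):
        assert small_voxel_table.matrix.shape[1] == 22
        assert len(FEATURE_NAMES) == 22
        assert len(STAT_FEATURES) == 8
        assert len(TEXTURE_FEATURES) == 10
        assert len(ENHANCEMENT_FEATURES) == 4

    def test_row_per_tumor_voxel(self, small_preprocessed, small_voxel_table):
        n_mask = int(small_preprocessed.tumor_mask.values.sum())
        assert small_voxel_table.matrix.shape[0] == n_mask

    def test_all_values_finite(self, small_voxel_table):
        assert np.isfinite(small_voxel_table.matrix).all()

    def test_empty_mask_rejected(self):
        vol = _vol(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError, match="empty"):
            compute_local_statistics(vol, np.zeros((4, 4, 4), dtype=bool))


class TestLocalStatistics:
    def test_constant_image(self):
        vol = _vol(np.full((5, 5, 5), 7.0))
        mask = np.ones((5, 5, 5), dtype=bool)
        _, feats = compute_local_statistics(vol, mask)
        assert np.allclose(feats[:, 0], 7.0)   # mean
        assert np.allclose(feats[:, 2], 0.0)   # sd
        assert np.allclose(feats[:, 5], 0.0)   # skewness convention
        assert np.allclose(feats[:, 6], 0.0)   # kurtosis convention
        assert np.allclose(feats[:, 7], 0.0)   # entropy

    @pytest.mark.parametrize("seed", range(10))
    def test_interior_window_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=(5, 5, 5))
        mask = rng.random((5, 5, 5)) < 0.8
        mask[2, 2, 2] = True
        coords, feats = compute_local_statistics(_vol(values), mask)
        idx = {tuple(c): i for i, c in enumerate(coords)}
        row = feats[idx[(2, 2, 2)]]
        expect = brute_window_stats(values, mask, (2, 2, 2))
        for j, name in enumerate(STAT_FEATURES[:5]):
            assert row[j] == pytest.approx(expect[name], abs=1e-12), name

    def test_mask_clipping_at_boundary(self):
        values = np.arange(27.0).reshape(3, 3, 3)
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[0, 0, 0] = mask[0, 0, 1] = True
        coords, feats = compute_local_statistics(_vol(values), mask)
        # window of (0,0,0) contains only the two in-mask voxels 0 and 1
        idx = {tuple(c): i for i, c in enumerate(coords)}
        row = feats[idx[(0, 0, 0)]]
        assert row[0] == pytest.approx(0.5)
        assert row[3] == 0.0 and row[4] == 1.0


class TestLocalTexture:
    def test_constant_window_conventions(self):
        vol = _vol(np.full((4, 4, 4), 3.0))
        mask = np.ones((4, 4, 4), dtype=bool)
        _, feats = compute_local_texture(vol, mask)
        names = dict(zip(TEXTURE_FEATURES, feats.T))
        assert np.allclose(names["glcm_joint_energy"], 1.0)
        assert np.allclose(names["glcm_contrast"], 0.0)
        assert np.allclose(names["glcm_joint_entropy"], 0.0)
        assert np.allclose(names["glcm_correlation"], 1.0)

    def test_checkerboard_contrast_matches_enumerated_glcm(self):
        """Two-level checkerboard: contrast from the explicitly enumerated
        co-occurrence matrix of the centre window."""
        g = np.indices((5, 5, 5)).sum(axis=0) % 2  # 3-D checkerboard
        values = g.astype(float)
        mask = np.ones((5, 5, 5), dtype=bool)
        cfg = VoxelFeatureConfig(n_bins=2)
        coords, feats = compute_local_texture(_vol(values), mask, cfg)
        idx = {tuple(c): i for i, c in enumerate(coords)}
        contrast = feats[idx[(2, 2, 2)], TEXTURE_FEATURES.index("glcm_contrast")]
        # enumerate all ordered neighbour pairs in the 3x3x3 centre window
        counts = np.zeros((2, 2))
        for a in itertools.product(range(1, 4), repeat=3):
            for d in itertools.product((-1, 0, 1), repeat=3):
                if d == (0, 0, 0):
                    continue
                b = tuple(np.array(a) + d)
                if all(1 <= b[i] <= 3 for i in range(3)):
                    counts[g[a], g[b]] += 1
        p = counts / counts.sum()
        expect = sum(p[i, j] * (i - j) ** 2 for i in (0, 1) for j in (0, 1))
        assert contrast == pytest.approx(expect, abs=1e-12)

    def test_monotone_scaling_invariance_window_mode(self, rng):
        values = rng.normal(size=(6, 6, 6))
        mask = rng.random((6, 6, 6)) < 0.9
        mask[3, 3, 3] = True
        cfg = VoxelFeatureConfig(quantization="window")
        _, a = compute_local_texture(_vol(values), mask, cfg)
        _, b = compute_local_texture(_vol(3.5 * values + 11.0), mask, cfg)
        assert np.allclose(a, b, atol=1e-9)


class TestEnhancementParams:
    def test_flat_curve(self):
        stacks = [np.full((3, 3, 3), 50.0)] * 4
        series = _series(stacks, [0, 60, 120, 180])
        mask = np.ones((3, 3, 3), dtype=bool)
        _, feats = compute_enhancement_params(series, mask)
        pe, ttp, washin, washout = feats.T
        assert np.allclose(pe, 0.0)
        assert np.allclose(washin, 0.0)
        assert np.allclose(washout, 0.0)

    def test_worked_curve(self):
        """S0=100, post phases (150, 200, 180) at 60/120/180 s."""
        shape = (2, 2, 2)
        stacks = [np.full(shape, v) for v in (100.0, 150.0, 200.0, 180.0)]
        series = _series(stacks, [0, 60, 120, 180])
        mask = np.ones(shape, dtype=bool)
        _, feats = compute_enhancement_params(series, mask)
        pe, ttp, washin, washout = feats[0]
        assert pe == pytest.approx(1.0)
        assert ttp == 2
        assert washin == pytest.approx(100 / 120)
        assert washout == pytest.approx((180 - 200) / 60)

    def test_peak_last_washout_zero(self):
        shape = (2, 2, 2)
        stacks = [np.full(shape, v) for v in (100.0, 120.0, 150.0)]
        series = _series(stacks, [0, 60, 120])
        _, feats = compute_enhancement_params(series, np.ones(shape, bool))
        assert np.allclose(feats[:, 3], 0.0)

    def test_too_few_phases_rejected(self):
        shape = (2, 2, 2)
        series = _series([np.ones(shape), np.ones(shape) * 2], [0, 60])
        with pytest.raises(ValueError, match="phases"):
            compute_enhancement_params(series, np.ones(shape, bool))


class TestInvariances:
    def test_translation_invariance(self):
        spec = PhantomSpec(
            grid_shape=(14, 13, 12), tumor_semiaxes_mm=(15.0, 13.0, 11.0),
            noise_sd=2.0, bias_amplitude=0.0, seed=5)
        pat = generate_phantom(spec)
        table = assemble_voxel_features(pat)
        # shift the whole grid by (1, 2, 1) voxels
        shift = (1, 2, 1)
        def shifted(vol, fill=0.0):
            out = np.full_like(vol.values, fill)
            out[shift[0]:, shift[1]:, shift[2]:] = \
                vol.values[:-shift[0], :-shift[1], :-shift[2]]
            return vol.with_values(out)
        import dataclasses
        pat2 = dataclasses.replace(
            pat,
            series=DynamicSeries(
                phases=tuple(shifted(p, fill=1e-6) for p in pat.series.phases),
                times_s=pat.series.times_s),
            tumor_mask=shifted(pat.tumor_mask).astype(np.uint8),
            truth_labels=shifted(pat.truth_labels).astype(np.int16),
        )
        table2 = assemble_voxel_features(pat2)
        assert np.allclose(np.sort(table.matrix, axis=0),
                           np.sort(table2.matrix, axis=0), atol=1e-9)

    def test_window_radius_config(self, small_patient):
        t1 = assemble_voxel_features(small_patient, VoxelFeatureConfig(radius=1))
        t2 = assemble_voxel_features(small_patient, VoxelFeatureConfig(radius=2))
        assert t1.matrix.shape == t2.matrix.shape
        assert not np.allclose(t1.matrix[:, 2], t2.matrix[:, 2])  # sd differs

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            VoxelFeatureConfig(radius=0)
        with pytest.raises(ValueError):
            VoxelFeatureConfig(n_bins=1)
        with pytest.raises(ValueError):
            VoxelFeatureConfig(quantization="weird")
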
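import math
import statistics
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petnoise import (
    NoiseParams,
    PatientMeta,
    SuvVolume,
    block_sd,
    global_noise_index,
    histogram_mode,
    make_phantom,
    noise_histogram,
    slice_noise_map,
    slicewise_gni,
    tissue_mask,
)
from petnoise.errors import (
    DegenerateBlockError,
    NoNoiseSamplesError,
    NoTissueFoundWarning,
    SliceTooSmallError,
)
from petnoise.noise import NoiseHistogram, volume_noise_maps
from petnoise.phantom import PhantomSpec
from tests.conftest import make_homogeneous_volume


def brute_force_block_sd(block, mask):
    """Independent oracle: pure-Python two-pass sample SD over in-mask pixels."""
    vals = [float(v) for v, m in zip(np.asarray(block).ravel(), np.asarray(mask).ravel()) if m]
    return statistics.stdev(vals)


class TestTissueMask:
    def test_all_zero_volume_warns_no_tissue(self):
        vol = SuvVolume(voxels=np.zeros((3, 16, 16)), spacing=(3, 3, 3))
        with pytest.warns(NoTissueFoundWarning):
            m = tissue_mask(vol, threshold=0.15)
        assert m.is_empty

    def test_noiseless_phantom_mask_is_exact(self):
        vol = SuvVolume(voxels=np.zeros((3, 16, 16)), spacing=(3, 3, 3))
        vol.voxels[:, 4:12, 4:12] = 1.0
        m = tissue_mask(vol, threshold=0.15, largest_component=False, fill_holes=False)
        np.testing.assert_array_equal(m.mask, vol.voxels > 0.15)

    def test_noisy_phantom_mask_covers_body(self, small_spec):
        vol, truth = make_phantom(small_spec, 30, "Q.Clear 450")  # sigma ~0.3
        m = tissue_mask(vol, threshold=0.15, largest_component=True, fill_holes=True)
        body = truth.labels > 0
        coverage = (m.mask & body).sum() / body.sum()
        assert coverage >= 0.99

    def test_otsu_threshold_is_deterministic(self, small_spec):
        vol, _ = make_phantom(small_spec, 120, "Q.Clear 450")
        m1 = tissue_mask(vol, threshold="otsu")
        m2 = tissue_mask(vol, threshold="otsu")
        assert m1.threshold_used == m2.threshold_used > 0
        np.testing.assert_array_equal(m1.mask, m2.mask)


class TestBlockSd:
    def test_identical_values(self):
        assert block_sd([3.7] * 64) == pytest.approx(0.0, abs=1e-12)

    def test_bimodal_block_frozen_oracle(self):
        # Oracle: statistics.stdev of 32 zeros and 32 twos = 1.0079052613579393
        vals = [0.0] * 32 + [2.0] * 32
        assert block_sd(vals) == pytest.approx(1.0079052613579393, rel=1e-14)

    def test_gaussian_recovery(self, rng):
        draws = rng.normal(1.0, 0.3, size=10_000)
        mc_se = 0.3 / math.sqrt(2 * (10_000 - 1))
        assert abs(block_sd(draws) - 0.3) < 3 * mc_se

    def test_degenerate(self):
        with pytest.raises(DegenerateBlockError):
            block_sd([1.0])

    @given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=100))
    @settings(max_examples=50, deadline=None)
    def test_matches_statistics_stdev(self, vals):
        assert block_sd(vals) == pytest.approx(statistics.stdev(vals), rel=1e-9, abs=1e-12)


class TestSliceNoiseMap:
    def test_constant_slice_full_mask(self):
        nm = slice_noise_map(np.full((16, 16), 2.0), np.ones((16, 16), bool), block_size=8)
        assert nm.values.shape == (2, 2)
        assert nm.valid.all()
        np.testing.assert_array_equal(nm.values, 0.0)

    def test_trailing_rows_dropped(self, rng):
        nm = slice_noise_map(rng.random((17, 16)), np.ones((17, 16), bool), block_size=8)
        assert nm.values.shape == (2, 2)

    def test_half_coverage_invalid(self):
        mask = np.zeros((8, 8), bool)
        mask.ravel()[:31] = True  # 31/64 < 0.5
        nm = slice_noise_map(np.random.default_rng(0).random((8, 8)), mask,
                             block_size=8, min_valid_fraction=0.5)
        assert nm.values.shape == (1, 1)
        assert not nm.valid[0, 0]

    def test_exact_half_coverage_valid(self):
        mask = np.zeros((8, 8), bool)
        mask.ravel()[:32] = True  # exactly 0.5
        nm = slice_noise_map(np.random.default_rng(0).random((8, 8)), mask, block_size=8)
        assert nm.valid[0, 0]

    def test_too_small_slice(self):
        with pytest.raises(SliceTooSmallError):
            slice_noise_map(np.ones((4, 4)), np.ones((4, 4), bool), block_size=8)

    def test_oracle_equivalence_partial_masks(self, rng):
        """Every valid macro pixel equals brute-force SD over in-mask pixels."""
        sl = rng.random((24, 32)) * 3.0
        mask = rng.random((24, 32)) > 0.3
        nm = slice_noise_map(sl, mask, block_size=8, min_valid_fraction=0.5)
        for by in range(3):
            for bx in range(4):
                block = sl[by * 8:(by + 1) * 8, bx * 8:(bx + 1) * 8]
                bm = mask[by * 8:(by + 1) * 8, bx * 8:(bx + 1) * 8]
                n = bm.sum()
                if n / 64 >= 0.5:
                    assert nm.valid[by, bx]
                    assert nm.values[by, bx] == pytest.approx(
                        brute_force_block_sd(block, bm), rel=1e-12)
                else:
                    assert not nm.valid[by, bx]


def _maps_from_values(values):
    values = np.asarray(values, float)
    from petnoise.noise import NoiseMap
    return [NoiseMap(values=values.reshape(1, -1),
                     valid=np.ones((1, values.size), bool),
                     block_size=8, slice_index=0)]


class TestNoiseHistogram:
    def _maps_from_values(self, values):
        return _maps_from_values(values)

    def test_small_example(self):
        hist = noise_histogram(self._maps_from_values([0.005, 0.005, 0.012]), bin_width=0.01)
        np.testing.assert_array_equal(hist.counts, [2, 1])
        assert hist.n_total == 3
        np.testing.assert_allclose(hist.bin_edges, [0.0, 0.01, 0.02])

    def test_empty_valid_set(self):
        from petnoise.noise import NoiseMap
        nm = NoiseMap(values=np.full((1, 2), np.nan), valid=np.zeros((1, 2), bool),
                      block_size=8, slice_index=0)
        with pytest.raises(NoNoiseSamplesError):
            noise_histogram([nm])

    def test_right_skewed_mean_above_mode(self, rng):
        draws = rng.gamma(2.0, 0.1, size=100_000)
        hist = noise_histogram(self._maps_from_values(draws), bin_width=0.01)
        mode = histogram_mode(hist)
        assert draws.mean() > mode

    def test_counts_conserved(self, rng):
        draws = rng.random(5000)
        hist = noise_histogram(self._maps_from_values(draws), bin_width=0.01)
        assert hist.counts.sum() == hist.n_total == 5000

    def test_left_closed_right_open(self):
        hist = noise_histogram(self._maps_from_values([0.01]), bin_width=0.01)
        np.testing.assert_array_equal(hist.counts, [0, 1])


class TestHistogramMode:
    def test_simple(self):
        hist = NoiseHistogram(bin_width=0.1, bin_edges=np.arange(4) * 0.1,
                              counts=np.array([1, 5, 2]), n_total=8)
        assert histogram_mode(hist) == pytest.approx(0.15)

    def test_tie_breaks_low(self):
        hist = NoiseHistogram(bin_width=0.1, bin_edges=np.arange(3) * 0.1,
                              counts=np.array([3, 3]), n_total=6)
        assert histogram_mode(hist) == pytest.approx(0.05)

    def test_truncated_gaussian_mode(self, rng):
        draws = np.clip(rng.normal(0.30, 0.01, size=1_000_000), 0, None)
        # independent oracle: direct argmax over binned samples
        idx = np.floor(draws / 0.01).astype(int)
        expected = (np.argmax(np.bincount(idx)) + 0.5) * 0.01
        mode = histogram_mode(noise_histogram(_maps_from_values(draws), bin_width=0.01))
        assert mode == pytest.approx(expected)
        assert mode in (0.295, 0.305)


class TestGlobalNoiseIndex:
    def test_noiseless_phantom_lowest_bin(self, small_spec):
        spec = PhantomSpec(grid_size=small_spec.grid_size, sigma_ref=0.0, seed=1)
        vol, _ = make_phantom(spec, 120, "Q.Clear 450")
        result = global_noise_index(vol)
        assert result.gni == pytest.approx(0.005)

    def test_sigma_recovery_homogeneous(self):
        vol = make_homogeneous_volume((40, 96, 96), mean=1.0, sigma=0.30, seed=3)
        result = global_noise_index(vol)
        assert abs(result.gni - 0.30) <= 0.02

    def test_gni_is_histogram_mode_invariant(self, small_spec):
        vol, _ = make_phantom(small_spec, 60, "Q.Clear 450")
        r = global_noise_index(vol)
        k = np.argmax(r.histogram.counts)
        assert r.gni == pytest.approx((k + 0.5) * r.histogram.bin_width)
        assert r.gni >= 0
        assert r.histogram.counts.sum() == r.n_macro_pixels

    def test_determinism(self, small_spec):
        vol, _ = make_phantom(small_spec, 60, "Q.Clear 450")
        r1 = global_noise_index(vol)
        r2 = global_noise_index(vol)
        assert r1.gni == r2.gni
        np.testing.assert_array_equal(r1.histogram.counts, r2.histogram.counts)

    def test_shift_invariance(self, small_spec):
        """Adding a constant above the threshold margin changes nothing."""
        vol, _ = make_phantom(small_spec, 60, "Q.Clear 450")
        r1 = global_noise_index(vol)
        mask = tissue_mask(vol).mask
        shifted = SuvVolume(voxels=vol.voxels + 5.0 * mask,
                            spacing=vol.spacing, meta=vol.meta)
        r2 = global_noise_index(shifted)
        assert r2.gni == r1.gni
        np.testing.assert_array_equal(r2.histogram.counts, r1.histogram.counts)

    def test_scale_equivariance(self, small_spec):
        vol, _ = make_phantom(small_spec, 60, "Q.Clear 450")
        a = 2.5
        params = NoiseParams()
        r1 = global_noise_index(vol, params)
        scaled = SuvVolume(voxels=vol.voxels * a, spacing=vol.spacing, meta=vol.meta)
        r2 = global_noise_index(scaled, NoiseParams(threshold=0.15 * a))
        assert abs(r2.gni - a * r1.gni) <= a * params.bin_width + params.bin_width

    def test_conservation_across_slices(self, small_spec):
        vol, _ = make_phantom(small_spec, 60, "Q.Clear 450")
        mask = tissue_mask(vol)
        maps = volume_noise_maps(vol, mask)
        per_slice = sum(int(nm.valid.sum()) for nm in maps)
        r = global_noise_index(vol)
        assert r.n_macro_pixels == per_slice == r.histogram.counts.sum()


class TestSlicewiseGni:
    def test_homogeneous_slices(self):
        vol = make_homogeneous_volume((12, 96, 96), mean=1.0, sigma=0.2, seed=4)
        series = slicewise_gni(vol)
        assert series.gni.size == 12
        assert np.all(np.isfinite(series.gni))
        assert np.all(np.abs(series.gni - 0.2) <= 0.03)

    def test_empty_slice_undefined(self):
        vox = np.zeros((4, 32, 32))
        vox[1:, 4:28, 4:28] = 1.0
        vol = SuvVolume(voxels=vox, spacing=(3, 3, 3), meta=PatientMeta())
        series = slicewise_gni(vol)
        assert np.isnan(series.gni[0])
        assert np.all(np.isfinite(series.gni[1:]))

    def test_step_between_two_noise_levels(self):
        lo = make_homogeneous_volume((10, 96, 96), sigma=0.1, seed=5).voxels
        hi = make_homogeneous_volume((10, 96, 96), sigma=0.3, seed=6).voxels
        vol = SuvVolume(voxels=np.concatenate([lo, hi]), spacing=(3, 3, 3))
        series = slicewise_gni(vol)
        # oracle: per-half whole-volume GNI
        g_lo = global_noise_index(SuvVolume(voxels=lo, spacing=(3, 3, 3))).gni
        g_hi = global_noise_index(SuvVolume(voxels=hi, spacing=(3, 3, 3))).gni
        assert np.all(np.abs(series.gni[:10] - g_lo) <= 0.03)
        assert np.all(np.abs(series.gni[10:] - g_hi) <= 0.03)
        assert series.gni[10:].mean() > series.gni[:10].mean() + 0.1

    def test_slab_thickness(self, small_spec):
        vol, _ = make_phantom(small_spec, 60, "Q.Clear 450")
        series = slicewise_gni(vol, slab_thickness=6)
        assert series.gni.size == math.ceil(vol.n_slices / 6)
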
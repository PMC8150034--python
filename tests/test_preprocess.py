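import numpy as np
import pytest

from osteofabric.preprocess import (
    FilterChainConfig,
    dog_filter,
    edge_preserving_smooth,
    gaussian_kernel_centre_weight,
    median_filter,
    otsu_threshold,
    polynomial_bias_correct,
    threshold_bone,
)
from osteofabric.volume_io import VoxelVolume


def vol_of(data, spacing=20.0):
    return VoxelVolume(np.asarray(data, dtype=np.float32), spacing)


class TestMedianFilter:
    def test_constant_unchanged(self, constant_volume):
        out = median_filter(constant_volume, 3)
        np.testing.assert_array_equal(out.data, constant_volume.data)

    def test_impulse_removed(self):
        data = np.zeros((5, 5, 5), dtype=np.float32)
        data[2, 2, 2] = 100.0
        out = median_filter(vol_of(data), 3)
        assert out.data.max() == 0.0

    def test_matches_brute_force_on_ramp(self, rng):
        data = np.tile(np.arange(8, dtype=np.float32), (6, 6, 1))
        data += rng.normal(0, 0.5, size=data.shape).astype(np.float32)
        out = median_filter(vol_of(data), 3).data
        # brute force with reflective padding
        padded = np.pad(data, 1, mode="reflect")
        for idx in [(2, 3, 4), (1, 1, 1), (4, 2, 6)]:
            i, j, k = idx
            block = padded[i : i + 3, j : j + 3, k : k + 3]
            assert out[idx] == np.median(block)

    def test_even_kernel_rejected(self, constant_volume):
        with pytest.raises(ValueError):
            median_filter(constant_volume, 4)


class TestEdgePreservingSmooth:
    def test_constant_is_fixed_point(self, constant_volume):
        out = edge_preserving_smooth(constant_volume, 5)
        np.testing.assert_allclose(out.data, constant_volume.data)

    def test_step_edge_position_preserved(self):
        data = np.full((8, 8, 12), 50.0, dtype=np.float32)
        data[:, :, 6:] = 200.0
        out = edge_preserving_smooth(vol_of(data), 5)
        # classify voxels by nearest mode: edge must not move
        assert np.array_equal(out.data > 125.0, data > 125.0)

    def test_noise_variance_reduced(self, rng):
        data = (100.0 + rng.normal(0, 10.0, size=(12, 12, 12))).astype(np.float32)
        out = edge_preserving_smooth(vol_of(data), 5)
        assert out.data.var() < data.var()

    def test_even_window_rejected(self, constant_volume):
        with pytest.raises(ValueError):
            edge_preserving_smooth(constant_volume, 4)


class TestPolynomialBiasCorrect:
    def test_exact_cubic_field_flattened(self):
        x, y, z = np.meshgrid(*[np.linspace(-1, 1, 10)] * 3, indexing="ij")
        field = 5.0 + 2 * x - y**2 + 0.5 * x * y * z + z**3
        out = polynomial_bias_correct(vol_of(field), 3)
        np.testing.assert_allclose(out.data, field.mean(), atol=1e-4)

    def test_constant_unchanged(self, constant_volume):
        out = polynomial_bias_correct(constant_volume, 3)
        np.testing.assert_allclose(out.data, constant_volume.data, atol=1e-5)

    def test_step_contrast_preserved_under_ramp(self):
        z = np.linspace(-1, 1, 24)
        data = np.tile(30.0 * z, (10, 10, 1)).astype(np.float32)
        obj = np.zeros_like(data)
        obj[3:7, 3:7, 8:16] = 100.0
        out = polynomial_bias_correct(vol_of(data + obj), 3)
        inside = out.data[3:7, 3:7, 8:16].mean()
        outside = out.data[3:7, 3:7, :6].mean()
        assert abs((inside - outside) - 100.0) / 100.0 < 0.05


class TestDoGFilter:
    def test_constant_gives_zero(self, constant_volume):
        out = dog_filter(constant_volume, 0.75, 3.0)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-5)

    def test_impulse_centre_response_closed_form(self):
        data = np.zeros((31, 31, 31), dtype=np.float32)
        data[15, 15, 15] = 1.0
        out = dog_filter(vol_of(data), 0.75, 3.0)
        expected = gaussian_kernel_centre_weight(0.75) - gaussian_kernel_centre_weight(3.0)
        assert abs(out.data[15, 15, 15] - expected) / expected < 0.02

    def test_band_pass_prefers_thin_rod_over_thick_slab(self):
        rod = np.zeros((24, 24, 24), dtype=np.float32)
        rod[12, 12, :] = 1.0
        slab = np.zeros((44, 44, 24), dtype=np.float32)
        slab[12:32, 12:32, :] = 1.0
        r = dog_filter(vol_of(rod), 0.75, 3.0).data[12, 12, 12]
        s = dog_filter(vol_of(slab), 0.75, 3.0).data[22, 22, 12]
        assert abs(r) > abs(s)

    def test_sigma_order_enforced(self, constant_volume):
        with pytest.raises(ValueError):
            dog_filter(constant_volume, 3.0, 0.75)


class TestThreshold:
    def test_otsu_equals_exhaustive_oracle(self, rng):
        data = np.concatenate(
            [rng.normal(50, 8, 7000), rng.normal(200, 8, 3000)]
        ).astype(np.float32)
        rng.shuffle(data)
        data = data.reshape(10, 10, 100)
        t = otsu_threshold(data)
        # exhaustive inter-class-variance maximisation over the same 256 bins
        lo, hi = data.min(), data.max()
        counts, edges = np.histogram(data, bins=256, range=(lo, hi))
        centres = 0.5 * (edges[:-1] + edges[1:])
        best, best_t = -1.0, None
        n = counts.sum()
        for i in range(1, 256):
            w0 = counts[:i].sum() / n
            w1 = 1 - w0
            if w0 == 0 or w1 == 0:
                continue
            mu0 = (counts[:i] * centres[:i]).sum() / counts[:i].sum()
            mu1 = (counts[i:] * centres[i:]).sum() / counts[i:].sum()
            v = w0 * w1 * (mu0 - mu1) ** 2
            if v > best:
                best, best_t = v, centres[i - 1]
        assert abs(t - best_t) <= (hi - lo) / 256 + 1e-6

    def test_bimodal_recovers_bright_fraction(self, rng):
        n = 40 * 40 * 40
        frac = 0.3
        data = np.where(
            rng.uniform(size=n) < frac, rng.normal(200, 5, n), rng.normal(50, 5, n)
        ).astype(np.float32).reshape(40, 40, 40)
        mask = threshold_bone(vol_of(data), "otsu")
        t = otsu_threshold(data)
        assert 50 < t < 200
        assert abs(mask.mean() - frac) < 0.02

    def test_fixed_threshold_boundaries(self, rng):
        data = rng.uniform(10, 90, size=(6, 6, 6)).astype(np.float32)
        vol = vol_of(data)
        assert threshold_bone(vol, "fixed", fixed=data.min()).all()
        assert not threshold_bone(vol, "fixed", fixed=data.max() + 1).any()

    def test_fixed_requires_value(self, constant_volume):
        with pytest.raises(ValueError):
            threshold_bone(constant_volume, "fixed")


class TestInvariantsAndConfig:
    def test_filters_preserve_shape_and_spacing(self, rng):
        vol = VoxelVolume(rng.normal(100, 10, size=(9, 10, 11)).astype(np.float32), 21.9)
        for out in (
            median_filter(vol, 3),
            edge_preserving_smooth(vol, 5, max_iter=2),
            polynomial_bias_correct(vol, 2),
            dog_filter(vol, 0.75, 3.0),
        ):
            assert out.shape == vol.shape
            np.testing.assert_array_equal(out.spacing, vol.spacing)

    def test_median_idempotent_on_piecewise_constant(self):
        data = np.full((10, 10, 16), 50.0, dtype=np.float32)
        data[:, :, 8:] = 200.0
        once = median_filter(vol_of(data), 3)
        twice = median_filter(once, 3)
        np.testing.assert_array_equal(once.data, twice.data)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            FilterChainConfig(median_kernel=2)
        with pytest.raises(ValueError):
            FilterChainConfig(dog_sigma1=3.0, dog_sigma2=1.0)
        with pytest.raises(ValueError):
            FilterChainConfig(threshold_method="magic")
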
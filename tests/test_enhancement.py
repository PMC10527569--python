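import numpy as np
import pytest
import scipy.ndimage as ndi

from dermfusion import (
    HazeParams,
    MorphParams,
    bottom_hat,
    dark_channel,
    enhance_image,
    estimate_atmospheric_light,
    estimate_transmission,
    recover_radiance,
    top_hat,
)


def _const_image(value, shape=(8, 8)):
    return np.full(shape + (3,), value, dtype=float)


class TestDarkChannel:
    @pytest.mark.parametrize("value, expected", [(1.0, 1.0), (0.0, 0.0)])
    def test_constant_images(self, value, expected):
        out = dark_channel(_const_image(value), patch_size=3)
        assert np.allclose(out, expected)

    def test_zeroed_channel_gives_zero_map(self, rng):
        img = rng.random((5, 5, 3))
        img[..., 1] = 0.0
        for patch in (1, 3, 5):
            assert np.allclose(dark_channel(img, patch), 0.0)

    def test_matches_bruteforce_neighborhood_min(self, rng):
        img = rng.random((7, 7, 3))
        patch = 3
        out = dark_channel(img, patch)
        per_pixel = img.min(axis=2)
        padded = np.pad(per_pixel, patch // 2, mode="edge")
        for i in range(7):
            for j in range(7):
                assert out[i, j] == pytest.approx(
                    padded[i : i + patch, j : j + patch].min(), abs=1e-15
                )

    @pytest.mark.parametrize("patch", [0, -1, 2, 4])
    def test_invalid_patch_rejected(self, patch):
        with pytest.raises(ValueError):
            dark_channel(_const_image(0.5), patch)

    def test_monotone_in_pixel_intensity(self, rng):
        img = rng.random((6, 6, 3)) * 0.8
        base = dark_channel(img, 3)
        brighter = img.copy()
        brighter[2, 3] = np.minimum(brighter[2, 3] + 0.2, 1.0)
        assert np.all(dark_channel(brighter, 3) >= base - 1e-15)


class TestAtmosphericLight:
    def test_uniform_gray(self):
        img = _const_image(0.5)
        a = estimate_atmospheric_light(img, dark_channel(img, 3))
        assert np.allclose(a, 0.5)

    def test_selects_brightest_dark_channel_pixel(self):
        img = np.zeros((10, 10, 3))
        img[4, 4] = 1.0  # only pixel bright in all channels
        dark = dark_channel(img, 1)
        a = estimate_atmospheric_light(img, dark, light_fraction=1 / 100)
        assert np.allclose(a, 1.0)

    def test_black_image_floored(self):
        img = _const_image(0.0)
        a = estimate_atmospheric_light(img, dark_channel(img, 3), floor=1e-3)
        assert np.allclose(a, 1e-3)

    def test_empty_selection_falls_back_to_max(self, rng):
        img = rng.random((6, 6, 3))
        a = estimate_atmospheric_light(img, dark_channel(img, 3), light_fraction=0.0)
        assert np.allclose(a, img.reshape(-1, 3).max(axis=0))


class TestTransmission:
    def test_image_equal_to_light_hits_floor(self):
        img = _const_image(0.5)
        t = estimate_transmission(img, np.array([0.5, 0.5, 0.5]),
                                  HazeParams(omega=0.95, t0=0.1))
        assert np.allclose(t, 0.1)

    def test_zero_channel_gives_full_transmission(self, rng):
        img = rng.random((6, 6, 3))
        img[..., 2] = 0.0
        t = estimate_transmission(img, np.array([0.8, 0.8, 0.8]))
        assert np.allclose(t, 1.0)

    def test_vanishing_omega_limit(self, rng):
        img = rng.random((6, 6, 3))
        t = estimate_transmission(img, np.ones(3), HazeParams(omega=1e-12))
        assert np.allclose(t, 1.0, atol=1e-10)

    def test_range_always_within_floor_and_one(self, rng):
        for _ in range(10):
            img = rng.random((8, 8, 3))
            a = rng.uniform(0.3, 1.0, 3)
            t = estimate_transmission(img, a, HazeParams(t0=0.1))
            assert t.min() >= 0.1 and t.max() <= 1.0

    def test_nonpositive_light_rejected(self):
        with pytest.raises(ValueError):
            estimate_transmission(_const_image(0.5), np.array([0.5, 0.0, 0.5]))


class TestRecoverRadiance:
    def test_fixed_point_when_image_equals_light(self):
        img = _const_image(0.7)
        t = np.full((8, 8), 0.4)
        out = recover_radiance(img, np.full(3, 0.7), t)
        assert np.allclose(out, 0.7)

    def test_scalar_case(self):
        img = _const_image(0.8, (2, 2))
        out = recover_radiance(img, np.full(3, 0.9), np.full((2, 2), 0.5), t0=0.1)
        assert np.allclose(out, 0.7)

    def test_divisor_clamped_at_floor(self):
        img = _const_image(0.8, (2, 2))
        t_low = np.full((2, 2), 0.01)
        out = recover_radiance(img, np.full(3, 0.9), t_low, t0=0.1, clip=False)
        assert np.allclose(out, (0.8 - 0.9) / 0.1 + 0.9)

    def test_exact_inverse_of_haze_model(self, rng):
        j = rng.random((10, 10, 3))
        a = rng.uniform(0.5, 1.0, 3)
        t = rng.uniform(0.2, 1.0, (10, 10))
        hazy = j * t[..., None] + a[None, None, :] * (1 - t[..., None])
        rec = recover_radiance(np.clip(hazy, 0, 1), a, t, t0=0.1, clip=False)
        assert np.allclose(rec, j, atol=1e-6)


class TestMorphology:
    def test_constant_image_maps_to_zero(self):
        img = _const_image(0.6)
        morph = MorphParams(se_radius=2)
        assert np.allclose(top_hat(img, morph), 0.0)
        assert np.allclose(bottom_hat(img, morph), 0.0)

    def test_bright_spike_caught_by_top_hat(self):
        img = np.zeros((7, 7, 3))
        img[3, 3] = 0.9
        morph = MorphParams(se_radius=1)
        th = top_hat(img, morph)
        assert np.allclose(th, img)  # opening removes the spike entirely
        assert np.allclose(bottom_hat(img, morph), 0.0)

    def test_dark_dip_caught_by_bottom_hat(self):
        img = np.ones((7, 7, 3))
        img[3, 3] = 0.2
        morph = MorphParams(se_radius=1)
        bh = bottom_hat(img, morph)
        assert bh[3, 3, 0] == pytest.approx(0.8)
        assert np.allclose(np.delete(bh.reshape(-1, 3), 3 * 7 + 3, axis=0), 0.0)
        assert np.allclose(top_hat(img, morph), 0.0)

    def test_outputs_nonnegative(self, rng):
        img = rng.random((12, 12, 3))
        morph = MorphParams(se_radius=2)
        assert top_hat(img, morph).min() >= -1e-15
        assert bottom_hat(img, morph).min() >= -1e-15

    def test_opening_idempotent(self, rng):
        chan = rng.random((12, 12))
        fp = MorphParams(se_radius=2).footprint()
        once = ndi.grey_opening(chan, footprint=fp, mode="nearest")
        twice = ndi.grey_opening(once, footprint=fp, mode="nearest")
        assert np.allclose(once, twice)


class TestEnhanceImage:
    def test_constant_image_is_fixed_point(self):
        img = _const_image(0.5, (16, 16))
        assert np.allclose(enhance_image(img), 0.5)

    def test_deterministic_bit_identical(self, small_imageset):
        img = small_imageset.hazy[0]
        out1 = enhance_image(img)
        out2 = enhance_image(img)
        assert np.array_equal(out1, out2)

    def test_reduces_dark_channel_and_raises_contrast(self, small_imageset):
        img = small_imageset.hazy[0]
        out = enhance_image(img)
        assert out.shape == img.shape
        assert dark_channel(out).mean() < dark_channel(img).mean()
        assert out.mean(axis=2).std() > img.mean(axis=2).std()
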
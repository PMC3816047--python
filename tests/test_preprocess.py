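import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from camvessel import CalibratedImage, DiffusionParams, anisotropic_diffusion, despeckle, load_image
from conftest import make_image
from oracles import diffusion_step_oracle, median3_oracle

small_images = hnp.arrays(
    dtype=np.float64,
    shape=hnp.array_shapes(min_dims=2, max_dims=2, min_side=2, max_side=12),
    elements=st.floats(0.0, 1.0, allow_nan=False),
)


class TestCalibratedImage:
    def test_rejects_out_of_range_intensities(self):
        with pytest.raises(ValueError):
            CalibratedImage(np.array([[0.0, 1.5]]), 1.0)

    def test_rejects_nonpositive_pixel_size(self):
        with pytest.raises(ValueError):
            CalibratedImage(np.zeros((2, 2)), 0.0)

    def test_rejects_empty_or_nonfinite(self):
        with pytest.raises(ValueError):
            CalibratedImage(np.zeros((0, 3)), 1.0)
        with pytest.raises(ValueError):
            CalibratedImage(np.array([[np.nan, 0.0]]), 1.0)


class TestLoadImage:
    def test_uint8_rescaled_by_dtype_max(self, tmp_path):
        import imageio.v3 as iio

        path = tmp_path / "white.png"
        iio.imwrite(path, np.full((2, 2), 255, dtype=np.uint8))
        img = load_image(path, pixel_size_um=2.0)
        assert np.allclose(img.pixels, 1.0)
        assert img.pixel_size_um == 2.0

        iio.imwrite(path, np.zeros((2, 2), dtype=np.uint8))
        assert np.allclose(load_image(path, 1.0).pixels, 0.0)

    def test_rgb_converted_via_rec709_luminance(self, tmp_path):
        import imageio.v3 as iio

        path = tmp_path / "red.png"
        rgb = np.zeros((2, 2, 3), dtype=np.uint8)
        rgb[..., 0] = 255
        iio.imwrite(path, rgb)
        img = load_image(path, 1.0)
        assert np.allclose(img.pixels, 0.2126)

    def test_invalid_calibration_and_missing_file(self, tmp_path):
        with pytest.raises(ValueError):
            load_image(tmp_path / "x.png", pixel_size_um=-1.0)
        with pytest.raises(IOError):
            load_image(tmp_path / "missing.png", pixel_size_um=1.0)


class TestAnisotropicDiffusion:
    def test_constant_image_is_fixed_point(self):
        img = make_image(np.full((5, 7), 0.4))
        out = anisotropic_diffusion(img, DiffusionParams(n_iterations=20))
        assert np.array_equal(out.pixels, img.pixels)

    def test_zero_iterations_is_identity(self, rng):
        img = make_image(rng.random((6, 6)))
        out = anisotropic_diffusion(img, DiffusionParams(n_iterations=0))
        assert np.array_equal(out.pixels, img.pixels)

    def test_single_step_matches_hand_computed_row(self):
        # centre of [0, 1, 0] loses flux 2*step*exp(-1) to its neighbours
        img = make_image(np.array([[0.0, 1.0, 0.0]]))
        out = anisotropic_diffusion(img, DiffusionParams(1, kappa=1.0, step=0.25))
        assert out.pixels[0, 1] == pytest.approx(1 - 0.5 * np.exp(-1), abs=1e-12)
        assert np.allclose(out.pixels, diffusion_step_oracle(img.pixels, 1.0, 0.25))

    def test_multi_step_matches_iterated_oracle(self, rng):
        pixels = rng.random((7, 5))
        out = anisotropic_diffusion(make_image(pixels), DiffusionParams(3, 0.2, 0.2))
        expected = pixels
        for _ in range(3):
            expected = diffusion_step_oracle(expected, 0.2, 0.2)
        assert np.allclose(out.pixels, expected, atol=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(pixels=small_images)
    def test_maximum_principle_and_mean_conservation(self, pixels):
        img = make_image(pixels)
        out = anisotropic_diffusion(img, DiffusionParams(5, 0.1, 0.25))
        assert out.pixels.min() >= pixels.min() - 1e-12
        assert out.pixels.max() <= pixels.max() + 1e-12
        assert out.pixels.mean() == pytest.approx(pixels.mean(), abs=5 * 1e-9)

    def test_calibration_preserved(self):
        img = make_image(np.eye(4) * 0.5, pixel_size_um=3.5)
        assert anisotropic_diffusion(img).pixel_size_um == 3.5

    def test_step_stability_bound_enforced(self):
        with pytest.raises(ValueError):
            DiffusionParams(step=0.3)
        with pytest.raises(ValueError):
            DiffusionParams(kappa=0.0)


class TestDespeckle:
    def test_constant_image_unchanged(self):
        img = make_image(np.full((4, 4), 0.7))
        assert np.array_equal(despeckle(img).pixels, img.pixels)

    def test_isolated_speckle_removed(self):
        pixels = np.zeros((5, 5))
        pixels[2, 2] = 1.0
        out = despeckle(make_image(pixels))
        assert out.pixels[2, 2] == 0.0

    def test_centre_of_1_to_9_block_becomes_median(self):
        block = (np.arange(1, 10, dtype=float) / 9).reshape(3, 3)
        out = despeckle(make_image(block))
        assert out.pixels[1, 1] == pytest.approx(5 / 9)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(pixels=small_images)
    def test_matches_oracle_and_window_membership(self, pixels):
        out = despeckle(make_image(pixels)).pixels
        assert np.allclose(out, median3_oracle(pixels))
        # median of an odd window is a member of the padded window's values
        padded = np.pad(pixels, 1, mode="symmetric")
        for i in range(pixels.shape[0]):
            for j in range(pixels.shape[1]):
                window = padded[i : i + 3, j : j + 3]
                assert np.any(np.isclose(window, out[i, j]))
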
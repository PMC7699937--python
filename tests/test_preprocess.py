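"""Preprocessing chain: diffusion, mean-shift quantization, channel ratio."""

import numpy as np
import pytest

from drtb import (
    MeanshiftParams,
    PMParams,
    hadamard_divide,
    meanshift_quantize,
    perona_malik,
    preprocess_pipeline,
    saturation_channel,
)


def _reference_pm(img, params):
    """Independent per-pixel explicit diffusion scheme (slow loops)."""
    out = img.astype(float).copy()
    n, m = out.shape
    for _ in range(params.iterations):
        new = out.copy()
        for i in range(n):
            for j in range(m):
                acc = 0.0
                for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                    ii = min(max(i + di, 0), n - 1)
                    jj = min(max(j + dj, 0), m - 1)
                    d = out[ii, jj] - out[i, j]
                    g = np.exp(-((abs(d) / params.kappa) ** 2))
                    acc += g * d
                new[i, j] = out[i, j] + params.step * acc
        out = new
    return np.clip(out, 0, 1)


class TestPeronaMalik:
    def test_constant_image_is_fixed_point(self):
        img = np.full((12, 9), 0.5)
        out = perona_malik(img, PMParams(iterations=5))
        np.testing.assert_allclose(out, img, atol=1e-12)

    def test_iteration_composes_as_semigroup(self, rng):
        img = rng.uniform(0.2, 0.8, size=(20, 20))
        once = perona_malik(img, PMParams(iterations=6))
        half = perona_malik(img, PMParams(iterations=3))
        twice = perona_malik(half, PMParams(iterations=3))
        np.testing.assert_allclose(once, twice, atol=1e-12)

    def test_matches_reference_scheme(self, rng):
        img = rng.uniform(0, 1, size=(10, 11))
        params = PMParams(iterations=3, kappa=0.15, step=0.2)
        np.testing.assert_allclose(perona_malik(img, params),
                                   _reference_pm(img, params), atol=1e-10)

    def test_denoises_flat_regions_and_keeps_edge(self, rng):
        img = np.zeros((40, 60))
        img[:, 30:] = 0.8
        noisy = np.clip(img + rng.normal(0, 0.05, img.shape), 0, 1)
        out = perona_malik(noisy, PMParams(iterations=10, kappa=0.3))
        # noise variance drops in the flat half away from the edge
        assert out[:, 5:25].var() < noisy[:, 5:25].var()
        grad_col = np.abs(np.diff(out, axis=1)).mean(axis=0).argmax()
        assert grad_col == 29

    def test_mean_is_conserved_each_iteration(self, rng):
        img = rng.uniform(0.1, 0.9, size=(30, 30))
        out = img
        for _ in range(5):
            nxt = perona_malik(out, PMParams(iterations=1))
            assert abs(nxt.mean() - out.mean()) < 1e-6
            out = nxt

    def test_vanishing_step_is_identity(self, rng):
        img = rng.uniform(0, 1, size=(15, 15))
        out = perona_malik(img, PMParams(iterations=1, step=1e-12))
        np.testing.assert_allclose(out, img, atol=1e-9)

    def test_rejects_invalid_inputs(self):
        with pytest.raises(ValueError):
            perona_malik(np.array([[np.nan, 0.5]]))
        with pytest.raises(ValueError):
            PMParams(step=0.3)
        with pytest.raises(ValueError):
            PMParams(iterations=0)
        with pytest.raises(ValueError):
            PMParams(conductance="linear")


def _brute_force_modes(sample, bandwidth, starts):
    """1-D flat-kernel mode seeking by direct iteration on raw samples."""
    modes = []
    for x in starts:
        for _ in range(500):
            win = sample[np.abs(sample - x) <= bandwidth]
            new = win.mean()
            if abs(new - x) < 1e-9:
                break
            x = new
        modes.append(x)
    return np.array(modes)


class TestMeanshiftQuantize:
    def test_constant_image_unchanged(self):
        img = np.full((8, 8), 0.37)
        out = meanshift_quantize(img)
        np.testing.assert_array_equal(out, img)

    def test_two_population_image_yields_two_modes(self, rng):
        lo = rng.uniform(0.18, 0.22, size=500)
        hi = rng.uniform(0.78, 0.82, size=500)
        sample = np.concatenate([lo, hi])
        img = sample.reshape(25, 40)
        out = meanshift_quantize(img, MeanshiftParams(bandwidth=0.1))
        vals = np.unique(out)
        assert vals.size == 2
        expected = np.unique(np.round(
            _brute_force_modes(sample, 0.1, np.array([0.2, 0.8])), 6))
        np.testing.assert_allclose(np.sort(vals), np.sort(expected), atol=1e-3)

    def test_huge_bandwidth_collapses_ramp(self):
        img = np.linspace(0, 1, 64).reshape(8, 8)
        out = meanshift_quantize(img, MeanshiftParams(bandwidth=2.0))
        assert np.unique(out).size == 1

    def test_idempotent(self, rng):
        img = rng.uniform(0, 1, size=(40, 40))
        once = meanshift_quantize(img)
        twice = meanshift_quantize(once)
        np.testing.assert_allclose(once, twice, atol=1e-9)

    def test_output_within_input_range_and_fewer_values(self, rng):
        img = rng.uniform(0.3, 0.6, size=(30, 30))
        out = meanshift_quantize(img, MeanshiftParams(bandwidth=0.05))
        assert out.min() >= img.min() - 1e-12
        assert out.max() <= img.max() + 1e-12
        assert np.unique(out).size <= np.unique(img).size

    def test_rejects_bad_bandwidth(self):
        with pytest.raises(ValueError):
            MeanshiftParams(bandwidth=0.0)


class TestHadamardDivide:
    def test_equal_images_give_constant(self):
        img = np.array([[0.2, 0.7], [0.4, 0.9]])
        out = hadamard_divide(img, img, eps=0.0)
        np.testing.assert_allclose(out, 0.0)

    def test_zero_denominator_stays_finite(self, rng):
        num = rng.uniform(0, 1, size=(6, 6))
        out = hadamard_divide(num, np.zeros((6, 6)), eps=1e-6)
        assert np.all(np.isfinite(out))
        assert out.min() >= 0 and out.max() <= 1

    def test_hand_computed_rescaling(self):
        num = np.array([[0.2, 0.4], [0.6, 0.8]])
        den = np.full((2, 2), 0.4)
        out = hadamard_divide(num, den, eps=0.0)
        np.testing.assert_allclose(
            out, [[0.0, 1 / 3], [2 / 3, 1.0]], atol=1e-12)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            hadamard_divide(np.zeros((2, 2)), np.zeros((3, 2)))


class TestPipeline:
    def test_grey_input_gives_zero_saturation_and_zero_f(self):
        rgb = np.repeat(np.linspace(0.1, 0.9, 64).reshape(8, 8, 1), 3, axis=2)
        assert saturation_channel(rgb).max() == 0
        f = preprocess_pipeline(rgb)
        np.testing.assert_allclose(f, 0.0)

    def test_output_shape_matches_input(self, rng):
        rgb = rng.uniform(0, 1, size=(17, 23, 3))
        assert preprocess_pipeline(rgb).shape == (17, 23)

    def test_blobs_separate_from_background(self, clean_fixture):
        import drtb
        img, pts = clean_fixture
        f = preprocess_pipeline(img)
        mask = np.zeros(f.shape, dtype=bool)
        yy, xx = np.mgrid[0:f.shape[0], 0:f.shape[1]]
        for x, y in pts:
            mask |= (yy - y) ** 2 + (xx - x) ** 2 < 3.0 ** 2
        assert np.median(f[mask]) - np.median(f[~mask]) >= 0.2

    def test_deterministic(self, clean_fixture):
        img, _ = clean_fixture
        f1 = preprocess_pipeline(img)
        f2 = preprocess_pipeline(img)
        np.testing.assert_array_equal(f1, f2)
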
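"""MIX generator: template exactness, noise statistics, determinism."""

import numpy as np
import pytest

from mventropy import MixParams, ParameterError, generate_mix1d, generate_mix2d


def sine_template_2d(h, w):
    i = np.arange(h)[:, None]
    j = np.arange(w)[None, :]
    return np.sin(2 * np.pi * i / 12) + np.sin(2 * np.pi * j / 12)


class TestMix1D:
    def test_pure_sine_at_p_zero(self):
        sig = generate_mix1d(MixParams(p=0.0, shape=24, q=3, seed=0))
        expected = np.sin(2 * np.pi * np.arange(24) / 12)
        assert sig.shape == (24, 3)
        for k in range(3):
            np.testing.assert_allclose(sig[:, k], expected, atol=1e-12)
        assert sig[3, 0] == pytest.approx(1.0)

    def test_pure_noise_moments(self):
        n = 100_000
        sig = generate_mix1d(MixParams(p=1.0, shape=n, q=1, seed=7))[:, 0]
        sigma = np.sqrt(3.0)  # Uniform[-3,3] standard deviation
        assert abs(sig.mean()) < 3 * sigma / np.sqrt(n)
        assert sig.var() == pytest.approx(3.0, abs=0.05)
        assert sig.min() >= -3.0 and sig.max() <= 3.0

    def test_noise_fraction_matches_p(self):
        n = 100_000
        sig = generate_mix1d(MixParams(p=0.5, shape=n, q=1, seed=3))[:, 0]
        template = np.sin(2 * np.pi * np.arange(n) / 12)
        frac = np.mean(sig != template)  # exact-equality collisions have measure zero
        assert frac == pytest.approx(0.5, abs=0.01)


class TestMix2D:
    def test_template_values_and_periodicity(self):
        img = generate_mix2d(MixParams(p=0.0, shape=(24, 24), q=3, seed=0))
        px = img.pixels
        assert px[0, 0, 0] == pytest.approx(0.0, abs=1e-12)
        assert px[3, 3, 1] == pytest.approx(2.0)
        np.testing.assert_allclose(px, np.roll(px, 12, axis=0), atol=1e-12)
        np.testing.assert_allclose(px, np.roll(px, 12, axis=1), atol=1e-12)

    def test_pure_noise_is_uniform(self):
        from scipy import stats

        px = generate_mix2d(MixParams(p=1.0, shape=(100, 100), q=1, seed=5)).pixels
        flat = px.ravel()
        template = sine_template_2d(100, 100)
        assert not np.any(flat.reshape(100, 100) == template)
        ks = stats.kstest(flat, stats.uniform(loc=-3, scale=6).cdf)
        assert ks.pvalue > 0.01

    @pytest.mark.parametrize("p", [0.1, 0.3, 0.7])
    def test_noise_fraction_concentration(self, p):
        h = w = 100
        px = generate_mix2d(MixParams(p=p, shape=(h, w), q=3, seed=11)).pixels
        template = sine_template_2d(h, w)[:, :, None]
        n = px.size
        frac = np.mean(px != template)
        assert abs(frac - p) < 4 * np.sqrt(p * (1 - p) / n)

    def test_shared_mask_ties_channels(self):
        params = MixParams(p=0.4, shape=(50, 50), q=3, seed=2, shared_mask=True)
        px = generate_mix2d(params).pixels
        template = sine_template_2d(50, 50)
        noisy = px != template[:, :, None]
        # same pixels corrupted in every channel, but with channel-specific values
        assert np.array_equal(noisy[:, :, 0], noisy[:, :, 1])
        assert np.array_equal(noisy[:, :, 0], noisy[:, :, 2])
        mask = noisy[:, :, 0]
        assert not np.array_equal(px[mask, 0], px[mask, 1])


class TestContracts:
    @pytest.mark.parametrize("p", [-0.1, 1.5])
    def test_invalid_probability_rejected(self, p):
        with pytest.raises(ParameterError):
            MixParams(p=p, shape=10)

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ParameterError):
            MixParams(p=0.5, shape=(0, 10))
        with pytest.raises(ParameterError):
            MixParams(p=0.5, shape=10, q=0)

    def test_shape_mode_mismatch(self):
        with pytest.raises(ParameterError):
            generate_mix1d(MixParams(p=0.5, shape=(5, 5)))
        with pytest.raises(ParameterError):
            generate_mix2d(MixParams(p=0.5, shape=16))

    @pytest.mark.parametrize("q", [1, 3])
    def test_determinism(self, q):
        params = MixParams(p=0.6, shape=(20, 30), q=q, seed=99)
        a = generate_mix2d(params).pixels
        b = generate_mix2d(params).pixels
        assert np.array_equal(a, b)
        c = generate_mix2d(MixParams(p=0.6, shape=(20, 30), q=q, seed=100)).pixels
        assert not np.array_equal(a, c)

    def test_channels_are_independent_processes(self):
        px = generate_mix2d(MixParams(p=0.5, shape=(40, 40), q=3, seed=1)).pixels
        assert not np.array_equal(px[:, :, 0], px[:, :, 1])
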
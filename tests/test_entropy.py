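"""Entropy kernel: embedding construction, distances, estimator behavior."""

import numpy as np
import pytest

from mventropy import (
    EmbeddingConfig,
    ImageSizeError,
    ParameterError,
    ShapeError,
    build_composite_delay_vectors,
    chebyshev_distance,
    mfuzen_rgb,
    msampen_mfuzen_rgb,
    msampen_rgb,
)
from mventropy.reference import mfuzen_naive, msampen_naive


class TestDelayVectors:
    def test_single_pixel_patches(self):
        img = np.arange(9, dtype=float).reshape(3, 3)
        vectors = build_composite_delay_vectors(img, EmbeddingConfig(M=(1,), r=1.0))
        # anchors row-major: (0,0),(0,1),(1,0),(1,1)
        np.testing.assert_array_equal(vectors, [[0], [1], [3], [4]])

    def test_row_major_patch_readout(self):
        img = np.arange(1, 10, dtype=float).reshape(3, 3)
        vectors = build_composite_delay_vectors(img, EmbeddingConfig(M=(2,), r=1.0))
        np.testing.assert_array_equal(vectors[0], [1, 2, 4, 5])

    def test_composite_length_sums_squared_sizes(self, rng):
        img = rng.random((4, 4, 3))
        vectors = build_composite_delay_vectors(img, EmbeddingConfig(M=(2, 2, 2), r=1.0))
        assert vectors.shape == (4, 12)

    def test_channel_concatenation_order(self, rng):
        img = rng.random((4, 4, 2))
        vectors = build_composite_delay_vectors(img, EmbeddingConfig(M=(1, 2), r=1.0))
        v00 = vectors[0]
        assert v00[0] == img[0, 0, 0]
        np.testing.assert_array_equal(
            v00[1:], [img[0, 0, 1], img[0, 1, 1], img[1, 0, 1], img[1, 1, 1]]
        )

    def test_too_small_image_rejected(self, rng):
        with pytest.raises(ImageSizeError):
            build_composite_delay_vectors(rng.random((2, 2)), EmbeddingConfig(M=(2,), r=1.0))
        # a single anchor is enough to build vectors, but not to estimate
        with pytest.raises(ImageSizeError):
            msampen_rgb(rng.random((3, 3)), EmbeddingConfig(M=(2,), r=1.0))


class TestChebyshev:
    def test_examples(self, rng):
        assert chebyshev_distance([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert chebyshev_distance([0, 1, 2, 3], [1, 1, 2, 0]) == 3.0
        u, v = rng.random(6), rng.random(6)
        assert chebyshev_distance(u, v) == chebyshev_distance(v, u)

    def test_length_mismatch(self):
        with pytest.raises(ShapeError):
            chebyshev_distance([1.0], [1.0, 2.0])


class TestConfigValidation:
    def test_bad_parameters(self):
        with pytest.raises(ParameterError):
            EmbeddingConfig(M=(0,), r=0.1)
        with pytest.raises(ParameterError):
            EmbeddingConfig(M=(1,), r=0.0)
        with pytest.raises(ParameterError):
            EmbeddingConfig(M=(1,), r=0.1, s=-1.0)

    def test_channel_count_mismatch(self, noise_image):
        with pytest.raises(ParameterError):
            msampen_rgb(noise_image, EmbeddingConfig(M=(2, 2), r=0.1))

    def test_fuzzy_needs_power(self, noise_image):
        with pytest.raises(ParameterError):
            mfuzen_rgb(noise_image, EmbeddingConfig(M=(1, 1, 1), r=0.1))

    def test_unknown_normalization_mode(self, noise_image):
        with pytest.raises(ParameterError):
            msampen_rgb(noise_image, EmbeddingConfig(M=(1, 1, 1), r=0.1), normalization="x")


class TestEstimators:
    def test_constant_array_gives_zero(self):
        img = np.full((8, 8, 3), 3.7)
        cfg = EmbeddingConfig(M=(2, 2, 2), r=0.15, s=2.0)
        assert msampen_rgb(img, cfg).value == pytest.approx(0.0, abs=1e-12)
        assert mfuzen_rgb(img, cfg).value == pytest.approx(0.0, abs=1e-12)

    def test_zero_matches_flagged_not_raised(self, rng):
        img = rng.random((12, 12, 3))
        res = msampen_rgb(img, EmbeddingConfig(M=(2, 2, 2), r=1e-9))
        assert not res.defined
        assert np.isnan(res.value)
        assert res.b_m1 == 0.0

    def test_huge_tolerance_drives_fuzzy_to_zero(self, rng):
        img = rng.random((10, 10, 3))
        vals = []
        for r in (1.0, 1e3, 1e6):
            vals.append(mfuzen_rgb(img, EmbeddingConfig(M=(1, 1, 1), r=r, s=2.0)).value)
        assert vals[0] > vals[1] > vals[2]
        assert vals[2] < 1e-6

    @pytest.mark.parametrize("q,M", [(1, (2,)), (3, (1, 1, 1)), (2, (1, 2))])
    def test_matches_naive_oracle(self, rng, q, M):
        img = rng.random((7, 7, q))
        cfg = EmbeddingConfig(M=M, r=0.3, s=2.0)
        assert msampen_rgb(img, cfg).value == pytest.approx(
            msampen_naive(img, M, 0.3), abs=1e-10
        )
        assert mfuzen_rgb(img, cfg).value == pytest.approx(
            mfuzen_naive(img, M, 0.3, 2.0), abs=1e-10
        )

    def test_dual_scan_equals_separate_calls(self, rng):
        img = rng.random((9, 9, 3))
        cfg = EmbeddingConfig(M=(2, 2, 2), r=0.1, s=2.0)
        s_res, f_res = msampen_mfuzen_rgb(img, cfg, r_sample=0.4)
        assert f_res.value == pytest.approx(mfuzen_rgb(img, cfg).value, abs=1e-12)
        direct = msampen_rgb(img, EmbeddingConfig(M=(2, 2, 2), r=0.4))
        assert s_res.value == pytest.approx(direct.value, abs=1e-12)

    def test_normalization_modes_differ_by_constant_offset(self, rng):
        cfg = EmbeddingConfig(M=(2, 2, 2), r=0.5)
        offsets = []
        for _ in range(2):
            img = rng.random((9, 9, 3))
            cons = msampen_rgb(img, cfg).value
            lit = msampen_rgb(img, cfg, normalization="literal").value
            offsets.append(lit - cons)
        assert offsets[0] == pytest.approx(offsets[1], abs=1e-10)

    def test_tolerance_monotonicity(self, rng):
        img = (rng.random((12, 12, 3)) - 0.5) * 2
        r_grid = [0.1, 0.2, 0.5, 1.0, 2.0]
        samp = [msampen_rgb(img, EmbeddingConfig(M=(1, 1, 1), r=r)) for r in r_grid]
        fuz = [
            mfuzen_rgb(img, EmbeddingConfig(M=(1, 1, 1), r=r, s=2.0)).value
            for r in r_grid
        ]
        defined = [res.value for res in samp if res.defined]
        assert all(a >= b - 1e-12 for a, b in zip(defined, defined[1:]))
        assert all(a >= b - 1e-12 for a, b in zip(fuz, fuz[1:]))

    def test_result_reports_match_statistics(self, rng):
        img = rng.random((8, 8, 3))
        res = msampen_rgb(img, EmbeddingConfig(M=(1, 1, 1), r=0.5))
        assert res.n_vectors == 49
        assert 0.0 <= res.b_m1 <= res.b_m <= 1.0
        assert res.method == "msampen"
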
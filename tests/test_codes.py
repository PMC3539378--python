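import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mammotex import NeighborhoodConfig, compute_code_maps, decompose
from mammotex.codes import (
    center_mean,
    cglld_code,
    lbp_code,
    mglld_code,
    mglld_threshold,
    riu2_code,
    sglld_code,
    uniformity,
)

from reference import naive_center_mean, naive_glld_rasters, naive_riu2


class TestScalarCoders:
    def test_lbp_extremes(self):
        assert lbp_code(5, np.full(8, 9.0)) == 255
        assert lbp_code(5, np.full(8, 1.0)) == 0
        # ties count as 1 (inclusive >=)
        assert lbp_code(5, np.full(8, 5.0)) == 255

    def test_lbp_matches_per_bit_enumeration(self, rng):
        for _ in range(20):
            center = float(rng.integers(0, 256))
            neigh = rng.integers(0, 256, 8).astype(float)
            expected = sum((1 << p) for p in range(8) if neigh[p] >= center)
            assert lbp_code(center, neigh) == expected

    @pytest.mark.parametrize(
        "bits,u",
        [
            ([0] * 8, 0),
            ([1] * 8, 0),
            ([0, 0, 0, 0, 1, 1, 1, 1], 2),
            ([0, 1, 0, 1, 0, 1, 0, 1], 8),
            ([1, 1, 0, 0, 1, 0, 0, 1], 4),
        ],
    )
    def test_uniformity_transition_count(self, bits, u):
        assert uniformity(np.array(bits)) == u
        assert uniformity(np.array(bits)) % 2 == 0

    def test_riu2_uniform_patterns_keep_popcount(self):
        assert riu2_code(np.ones(8, dtype=int)) == 8
        assert riu2_code(np.zeros(8, dtype=int)) == 0
        assert riu2_code(np.array([0, 0, 1, 1, 1, 0, 0, 0])) == 3

    def test_riu2_exhaustive_p8_codomain(self):
        """All 256 8-bit patterns map to exactly the P+2 = 10 codes."""
        seen = {}
        for bits in itertools.product([0, 1], repeat=8):
            code = riu2_code(np.array(bits))
            seen.setdefault(code, 0)
            seen[code] += 1
            assert code == naive_riu2(list(bits))
        assert set(seen) == set(range(10))
        # only non-uniform patterns land on the miscellaneous label
        assert seen[9] == 256 - sum(v for k, v in seen.items() if k < 9)

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.integers(0, 1), min_size=4, max_size=24))
    def test_riu2_invariant_under_circular_rotation(self, bits):
        """Rotating the bit pattern never changes its riu2 code."""
        b = np.array(bits)
        base = riu2_code(b)
        for shift in range(1, len(bits)):
            assert riu2_code(np.roll(b, shift)) == base
        assert uniformity(b) % 2 == 0

    def test_sglld_sign_packing(self, rng):
        assert sglld_code(np.ones(8)) == 255
        assert sglld_code(-np.ones(8)) == 0
        signs = rng.choice([-1, 1], size=8)
        expected = sum((1 << p) for p in range(8) if signs[p] == 1)
        assert sglld_code(signs) == expected

    def test_mglld_inclusive_threshold(self, rng):
        assert mglld_code(np.full(8, 2.0), 1.0) == 255
        assert mglld_code(np.zeros(8), 0.0) == 255  # x >= c inclusive
        m = rng.random(8)
        c = 0.5
        expected = sum((1 << p) for p in range(8) if m[p] >= c)
        assert mglld_code(m, c) == expected

    def test_cglld_inclusive(self):
        assert cglld_code(10.0, 10.0) == 1
        assert cglld_code(9.999, 10.0) == 0
        assert cglld_code(11.0, 10.0) == 1


class TestCenterMean:
    def test_constant_image_unchanged(self):
        img = np.full((8, 8), 42.0)
        np.testing.assert_array_equal(center_mean(img), img)

    def test_three_by_three_patch(self):
        img = np.arange(1, 10, dtype=np.float64).reshape(3, 3)
        assert center_mean(img)[1, 1] == 5.0  # mean of 1..9

    def test_interior_matches_nine_term_loop(self, random_int_image):
        cm = center_mean(random_int_image)
        for r in range(1, 15):
            for c in range(1, 15):
                assert cm[r, c] == pytest.approx(
                    naive_center_mean(random_int_image, r, c), abs=1e-12
                )

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            center_mean(np.zeros((2, 5)))


class TestDecompose:
    def test_constant_image_all_zero_diffs_positive_signs(self):
        ld = decompose(np.full((12, 12), 9.0), NeighborhoodConfig(8, 1))
        np.testing.assert_array_equal(ld.diffs, 0.0)
        np.testing.assert_array_equal(ld.signs, 1)
        np.testing.assert_array_equal(ld.moduli, 0.0)

    def test_modulus_times_sign_reconstructs_diff(self, random_float_image):
        ld = decompose(random_float_image, NeighborhoodConfig(8, 1))
        np.testing.assert_array_equal(ld.moduli * ld.signs, ld.diffs)
        assert (ld.moduli >= 0).all()
        # sign is +1 exactly when the difference is non-negative
        np.testing.assert_array_equal(ld.signs == 1, ld.diffs >= 0)

    def test_mglld_threshold_is_flat_average(self, random_float_image):
        ld = decompose(random_float_image, NeighborhoodConfig(8, 1))
        assert mglld_threshold(ld.moduli) == pytest.approx(
            float(np.mean(ld.moduli)), rel=1e-12
        )
        assert mglld_threshold(np.full((4, 3, 3), 2.5)) == 2.5

    def test_empty_moduli_rejected(self):
        with pytest.raises(ValueError):
            mglld_threshold(np.empty((8, 0, 0)))


class TestOracleEquivalence:
    """Vectorized code rasters must equal the scalar per-pixel reference."""

    @pytest.mark.parametrize("p,r", [(8, 1), (16, 2)])
    @pytest.mark.parametrize("mapping", ["riu2", "raw"])
    def test_rasters_match_naive_loops(self, rng, p, r, mapping):
        for _ in range(4):
            img = rng.random((16, 16)) * 255.0
            maps = compute_code_maps(
                img, NeighborhoodConfig(p, r), mapping=mapping, include_lbp=True
            )
            ref = naive_glld_rasters(img, p, r, mapping=mapping)
            assert maps.modulus_threshold == pytest.approx(
                ref["modulus_threshold"], rel=1e-10
            )
            np.testing.assert_array_equal(maps.sglld, ref["sglld"])
            np.testing.assert_array_equal(maps.mglld, ref["mglld"])
            np.testing.assert_array_equal(maps.cglld, ref["cglld"])
            np.testing.assert_array_equal(maps.lbp, ref["lbp"])

    def test_riu2_codes_in_range(self, random_float_image):
        for p, r in [(8, 1), (16, 2), (24, 3)]:
            maps = compute_code_maps(random_float_image, NeighborhoodConfig(p, r))
            assert maps.sglld.min() >= 0 and maps.sglld.max() <= p + 1
            assert maps.mglld.min() >= 0 and maps.mglld.max() <= p + 1
            assert set(np.unique(maps.cglld)) <= {0, 1}

    def test_unknown_mapping_rejected(self, random_float_image):
        with pytest.raises(ValueError):
            compute_code_maps(random_float_image, NeighborhoodConfig(8, 1), mapping="u2")
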
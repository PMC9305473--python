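"""ACRI-LBP: sampling, codes, rotation orbits and the compensated map."""

import numpy as np
import pytest

from mdam_drnet.texture_path import (
    acri_lbp_map,
    bilinear,
    lbp_code,
    lbp_code_map,
    min_rotation,
    min_rotation_table,
    region_compensation,
    region_stats,
    rgb_to_gray,
    ring_coordinates,
    rotation_sequence,
)


class TestRgbToGray:
    def test_gray_input_unchanged(self):
        img = np.full((4, 4, 3), 77, dtype=np.uint8)
        assert (rgb_to_gray(img) == 77).all()

    def test_white_is_255(self):
        assert rgb_to_gray(np.full((1, 1, 3), 255, dtype=np.uint8))[0, 0] == 255

    def test_pure_red_luma(self):
        img = np.zeros((1, 1, 3), dtype=np.uint8)
        img[0, 0, 0] = 255
        assert rgb_to_gray(img)[0, 0] == 76  # round(0.299 * 255)

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(ValueError):
            rgb_to_gray(np.zeros((4, 4), dtype=np.uint8))


class TestRegionStats:
    def test_constant_tile_compensates_to_itself(self):
        s = region_stats(np.full((16, 16), 40))
        assert s.compensation == pytest.approx(40.0)

    def test_small_tile_direct_evaluation(self):
        s = region_stats(np.array([[10, 20], [30, 40]]))
        assert (s.mean, s.min, s.max) == (25.0, 10.0, 40.0)
        assert s.compensation == pytest.approx(6.25)

    def test_all_zero_tile_guarded(self):
        assert region_stats(np.zeros((4, 4))).compensation == 0.0

    def test_empty_tile_rejected(self):
        with pytest.raises(ValueError):
            region_stats(np.empty((0, 0)))

    def test_compensation_never_exceeds_mean(self, rng):
        for _ in range(20):
            tile = rng.integers(0, 256, (5, 5))
            s = region_stats(tile)
            assert s.min <= s.mean <= s.max
            assert s.compensation <= s.mean + 1e-12


class TestRingCoordinates:
    def test_four_point_unit_ring(self):
        ring = ring_coordinates(10, 10, 1, 4)
        expected = [(11, 10), (10, 9), (9, 10), (10, 11)]
        assert np.allclose(ring.points, expected)

    def test_first_point_lies_east(self):
        ring = ring_coordinates(10, 10, 3, 8)
        assert np.allclose(ring.points[0], (13, 10))

    @pytest.mark.parametrize("radius,n_points", [(1, 4), (2.5, 8), (3, 16)])
    def test_all_points_on_circle(self, radius, n_points):
        ring = ring_coordinates(5.0, 7.0, radius, n_points)
        d = np.hypot(ring.points[:, 0] - 5.0, ring.points[:, 1] - 7.0)
        assert np.allclose(d, radius, atol=1e-9)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            ring_coordinates(0, 0, 0, 8)
        with pytest.raises(ValueError):
            ring_coordinates(0, 0, 1, 3)


class TestBilinear:
    def test_exact_at_grid_points(self, rng):
        img = rng.integers(0, 256, (5, 5)).astype(float)
        for y in range(5):
            for x in range(5):
                assert bilinear(img, x, y) == pytest.approx(img[y, x])

    def test_midpoint_of_step_block(self):
        img = np.array([[0.0, 0.0], [100.0, 100.0]])
        assert bilinear(img, 0.5, 0.5) == pytest.approx(50.0)

    def test_matrix_form_matches_expanded_weights(self, rng):
        """Matrix product form equals the expanded four-weight sum oracle."""
        img = rng.integers(0, 256, (8, 8)).astype(float)
        for _ in range(50):
            x = rng.uniform(0, 6.999)
            y = rng.uniform(0, 6.999)
            x1, y1 = int(x), int(y)
            fx, fy = x - x1, y - y1
            expected = (
                img[y1, x1] * (1 - fx) * (1 - fy)
                + img[y1, x1 + 1] * fx * (1 - fy)
                + img[y1 + 1, x1] * (1 - fx) * fy
                + img[y1 + 1, x1 + 1] * fx * fy
            )
            assert bilinear(img, x, y) == pytest.approx(expected, abs=1e-9)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            bilinear(np.zeros((4, 4)), 4.5, 1.0)


class TestLbpCode:
    def test_all_below_center_is_zero(self):
        assert lbp_code(100, np.full(8, 50)) == 0

    def test_ties_count_as_one(self):
        assert lbp_code(100, np.full(8, 100)) == 255

    def test_mixed_neighbors_bit_by_bit(self):
        assert lbp_code(100, np.array([101, 99, 100, 50, 200, 100, 1, 255])) == 181

    def test_monotone_transform_invariance(self, rng):
        """Any strictly increasing intensity transform leaves the code fixed."""
        for _ in range(30):
            c = float(rng.integers(0, 256))
            nb = rng.integers(0, 256, 8).astype(float)
            transformed = np.sqrt(nb) * 3 + 0.01 * nb**2
            ct = np.sqrt(c) * 3 + 0.01 * c**2
            assert lbp_code(c, nb) == lbp_code(ct, transformed)


class TestRotationOrbit:
    def test_worked_example_sequence(self):
        assert set(rotation_sequence(225, 8)) == {240, 120, 60, 30, 15, 135, 195}

    def test_worked_example_minimum(self):
        assert min_rotation(225, 8) == 15

    @pytest.mark.parametrize("code,expected", [(0, 0), (255, 255)])
    def test_fixed_codes(self, code, expected):
        assert min_rotation(code, 8) == expected
        assert all(v == expected for v in rotation_sequence(code, 8))

    def test_orbit_invariance_all_codes_all_shifts(self):
        """min over the orbit is constant on the orbit: all 256 x 8 cases."""

        def rotate_via_string(code, k):  # independent oracle
            bits = format(code, "08b")
            return int(bits[-k:] + bits[:-k], 2) if k else code

        for code in range(256):
            ref = min_rotation(code, 8)
            for k in range(8):
                assert min_rotation(rotate_via_string(code, k), 8) == ref

    def test_distinct_minima_count_equals_binary_necklaces(self):
        """|{min_rotation(c)}| equals the Burnside count of 8-bit necklaces."""
        from math import gcd

        necklaces = sum(2 ** gcd(k, 8) for k in range(8)) // 8
        assert len({min_rotation(c, 8) for c in range(256)}) == necklaces


def oracle_acri_map(gray, radius, n_points, region):
    """Straight-line per-pixel reference: explicit loops, no vectorization.

    Applies the same documented tie tolerance as the map (a bit is set when
    sample >= center - TIE_TOLERANCE) by shifting the center before coding.
    """
    from mdam_drnet.texture_path import TIE_TOLERANCE

    gray = gray.astype(float)
    h, w = gray.shape
    margin = int(np.ceil(radius))
    codes = np.zeros((h, w), dtype=np.int64)
    for y in range(margin, h - margin):
        for x in range(margin, w - margin):
            ring = ring_coordinates(x, y, radius, n_points)
            nb = [bilinear(gray, round(px, 9), round(py, 9)) for px, py in ring.points]
            code = lbp_code(gray[y, x] - TIE_TOLERANCE, np.array(nb))
            codes[y, x] = min_rotation(code, n_points)
    comp = region_compensation(gray, region)
    out = codes.astype(float)
    out[margin : h - margin, margin : w - margin] += comp[margin : h - margin, margin : w - margin]
    return codes, out


class TestAcriLbpMap:
    def test_constant_image_saturates(self):
        tm = acri_lbp_map(np.full((40, 40), 90, dtype=np.uint8))
        inner = tm.codes[3:-3, 3:-3]
        assert (inner == 255).all()
        assert (tm.compensated[3:-3, 3:-3] == 255).all()

    @pytest.mark.parametrize("radius", [1, 3])
    def test_matches_straight_line_oracle(self, rng, radius):
        gray = rng.integers(0, 256, (8, 8)).astype(np.uint8)
        tm = acri_lbp_map(gray, radius=radius, n_points=8, region=4)
        codes, comp = oracle_acri_map(gray, radius, 8, 4)
        assert np.array_equal(tm.codes, codes)
        assert np.allclose(tm.compensated_raw, comp)

    def test_rot90_equivariance_of_code_raster(self, rng):
        """Min-orbit codes commute with 90-degree image rotation (interior)."""
        gray = rng.integers(0, 256, (24, 24)).astype(np.uint8)
        m = 4
        codes = acri_lbp_map(gray, radius=3).codes
        codes_rot = acri_lbp_map(np.rot90(gray).copy(), radius=3).codes
        expected = np.rot90(codes)
        assert np.array_equal(codes_rot[m:-m, m:-m], expected[m:-m, m:-m])

    def test_affine_illumination_invariance_of_codes(self, rng):
        """Scaling/offsetting intensity (no clipping) leaves codes unchanged;
        the compensated raster is brightness dependent by design."""
        gray = rng.integers(10, 200, (20, 20)).astype(float)
        bright = gray * 1.3 + 7.5
        a = acri_lbp_map(gray, radius=3)
        b = acri_lbp_map(bright, radius=3)
        assert np.array_equal(a.codes, b.codes)
        assert not np.allclose(a.compensated_raw, b.compensated_raw)

    def test_radius_changes_the_map(self, rng):
        gray = rng.integers(0, 256, (40, 40)).astype(np.uint8)
        maps = [acri_lbp_map(gray, radius=r).codes for r in (1, 2, 3, 4, 5)]
        for i in range(len(maps)):
            for j in range(i + 1, len(maps)):
                assert not np.array_equal(maps[i], maps[j])

    def test_compensated_at_least_codes(self, rng):
        gray = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        tm = acri_lbp_map(gray)
        assert (tm.compensated_raw >= tm.codes - 1e-12).all()

    def test_no_compensation_mode_is_plain_ri_lbp(self, rng):
        gray = rng.integers(0, 256, (20, 20)).astype(np.uint8)
        tm = acri_lbp_map(gray, compensate=False)
        assert np.array_equal(tm.compensated_raw, tm.codes)

    def test_radius_too_large_rejected(self):
        with pytest.raises(ValueError):
            acri_lbp_map(np.zeros((8, 8), dtype=np.uint8), radius=4)

    def test_code_map_border_is_zero(self, rng):
        gray = rng.integers(1, 256, (16, 16)).astype(np.uint8)
        codes = lbp_code_map(gray, radius=3)
        assert codes[:3].sum() == 0 and codes[-3:].sum() == 0
        assert codes[:, :3].sum() == 0 and codes[:, -3:].sum() == 0
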
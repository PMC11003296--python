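"""Moment-based descriptors against brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from phoskit import shapes
from phoskit.errors import EmptyDrawingError

from conftest import random_mask


# ---------------------------------------------------------------------------
# independent oracles


def moment_oracle(mask, i, j):
    """Direct double summation over the raster (x = column, y = row)."""
    total = 0.0
    for y in range(mask.shape[0]):
        for x in range(mask.shape[1]):
            if mask[y, x]:
                total += x**i * y**j
    return total


def flood_fill_oracle(mask):
    """8-connected labeling by explicit breadth-first flood fill."""
    labels = np.zeros(mask.shape, dtype=int)
    current = 0
    for y in range(mask.shape[0]):
        for x in range(mask.shape[1]):
            if mask[y, x] and labels[y, x] == 0:
                current += 1
                stack = [(y, x)]
                labels[y, x] = current
                while stack:
                    cy, cx = stack.pop()
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            ny, nx = cy + dy, cx + dx
                            if (
                                0 <= ny < mask.shape[0]
                                and 0 <= nx < mask.shape[1]
                                and mask[ny, nx]
                                and labels[ny, nx] == 0
                            ):
                                labels[ny, nx] = current
                                stack.append((ny, nx))
    return labels, current


def rasterized_ellipse(a, b, angle_deg=0.0, pad=6):
    """Filled ellipse with semi-axes a >= b, rotated by angle_deg."""
    n = int(2 * a) + 2 * pad + 1
    c = n // 2
    yy, xx = np.mgrid[0:n, 0:n] - c
    t = math.radians(angle_deg)
    u = xx * math.cos(t) + yy * math.sin(t)
    v = -xx * math.sin(t) + yy * math.cos(t)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


class TestConnectedRegions:
    def test_two_disjoint_squares(self):
        arr = np.zeros((20, 20), dtype=bool)
        arr[2:6, 2:6] = True
        arr[10:16, 10:16] = True
        regions = shapes.connected_regions(arr)
        assert len(regions) == 2
        assert regions[0].sum() == 36  # larger region first
        assert regions[1].sum() == 16

    def test_corner_touching_squares_are_one_region(self):
        arr = np.zeros((10, 10), dtype=bool)
        arr[0:3, 0:3] = True
        arr[3:6, 3:6] = True  # touches only at the (2,2)/(3,3) corner
        assert len(shapes.connected_regions(arr)) == 1

    def test_matches_flood_fill_oracle(self, rng):
        for _ in range(20):
            arr = random_mask(rng, (32, 32), density=0.35)
            regions = shapes.connected_regions(arr)
            labels, n = flood_fill_oracle(arr)
            assert len(regions) == n
            # each returned region coincides with exactly one oracle label
            for region in regions:
                ids = np.unique(labels[region])
                assert len(ids) == 1
                assert (labels == ids[0]).sum() == region.sum()

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyDrawingError):
            shapes.connected_regions(np.zeros((5, 5), dtype=bool))


class TestRawMoments:
    def test_single_pixel_moments(self):
        arr = np.zeros((8, 8), dtype=bool)
        arr[5, 3] = True  # x = 3, y = 5
        assert shapes.raw_moment(arr, 0, 0) == 1
        assert shapes.raw_moment(arr, 1, 0) == 3
        assert shapes.raw_moment(arr, 0, 1) == 5

    def test_area_equals_pixel_count(self, rng):
        arr = random_mask(rng, (16, 16))
        assert shapes.raw_moment(arr, 0, 0) == arr.sum()

    def test_matches_direct_summation_oracle(self, rng):
        for _ in range(10):
            arr = random_mask(rng, (16, 16), density=0.5)
            for i in range(4):
                for j in range(4):
                    got = shapes.raw_moment(arr, i, j)
                    want = moment_oracle(arr, i, j)
                    assert got == pytest.approx(want, rel=1e-12)


class TestMomentProperties:
    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        arr=hnp.arrays(bool, hnp.array_shapes(min_dims=2, max_dims=2, min_side=2, max_side=12)),
        i=st.integers(0, 3),
        j=st.integers(0, 3),
    )
    def test_moments_equal_double_loop(self, arr, i, j):
        assert shapes.raw_moment(arr, i, j) == pytest.approx(
            moment_oracle(arr, i, j), rel=1e-12, abs=1e-12
        )

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        arr=hnp.arrays(bool, (10, 10)),
        dy=st.integers(0, 6),
        dx=st.integers(0, 6),
    )
    def test_m00_translation_invariant(self, arr, dy, dx):
        if not arr.any():
            return
        moved = np.zeros((20, 20), dtype=bool)
        moved[dy : dy + 10, dx : dx + 10] = arr
        assert shapes.raw_moment(moved, 0, 0) == shapes.raw_moment(arr, 0, 0)


class TestCentroid:
    def test_symmetric_square(self):
        arr = np.zeros((5, 5), dtype=bool)
        arr[0:3, 0:3] = True
        assert shapes.centroid(arr) == pytest.approx((1.0, 1.0))

    def test_l_tromino(self):
        arr = np.zeros((4, 4), dtype=bool)
        arr[0, 0] = arr[1, 0] = arr[0, 1] = True
        assert shapes.centroid(arr) == pytest.approx((1 / 3, 1 / 3))


class TestAxisLengths:
    def test_single_pixel_degenerate(self):
        arr = np.zeros((5, 5), dtype=bool)
        arr[2, 2] = True
        assert shapes.axis_lengths(arr) == (0.0, 0.0)
        assert shapes.describe_region(arr).degenerate

    def test_horizontal_bar_closed_form(self):
        # 1x9 bar: x-variance = (9^2 - 1)/12 = 20/3, y-variance = 0
        arr = np.zeros((3, 11), dtype=bool)
        arr[1, 1:10] = True
        major, minor = shapes.axis_lengths(arr)
        assert major == pytest.approx(4 * math.sqrt(20 / 3), rel=1e-12)
        assert minor == 0.0

    def test_rasterized_ellipse_axes(self):
        for angle in (0.0, 30.0):
            arr = rasterized_ellipse(40, 15, angle)
            major, minor = shapes.axis_lengths(arr)
            assert major == pytest.approx(80, rel=0.03)
            assert minor == pytest.approx(30, rel=0.03)

    def test_matches_covariance_eigenvalue_oracle(self, rng):
        for _ in range(10):
            arr = random_mask(rng, (16, 16))
            ys, xs = np.nonzero(arr)
            cov = np.cov(np.vstack([xs, ys]), ddof=0)
            lam = np.sort(np.linalg.eigvalsh(np.atleast_2d(cov)))[::-1]
            major, minor = shapes.axis_lengths(arr)
            assert major == pytest.approx(4 * math.sqrt(max(lam[0], 0)), rel=1e-9)


class TestPerimeter:
    def test_single_pixel_is_zero(self):
        arr = np.zeros((3, 3), dtype=bool)
        arr[1, 1] = True
        assert shapes.perimeter(arr) == 0.0

    def test_filled_square_border_polyline(self):
        arr = np.zeros((6, 6), dtype=bool)
        arr[1:5, 1:5] = True
        assert shapes.perimeter(arr) == pytest.approx(12.0)

    def test_disk_circumference_within_5_percent(self):
        yy, xx = np.mgrid[0:80, 0:80]
        disk = (xx - 40) ** 2 + (yy - 40) ** 2 <= 30**2
        assert shapes.perimeter(disk) == pytest.approx(2 * math.pi * 30, rel=0.05)

    def test_translation_and_right_angle_rotation_invariance(self, rng):
        arr = np.zeros((40, 40), dtype=bool)
        arr[5:20, 5:12] = True
        arr[10:14, 12:25] = True
        p0 = shapes.perimeter(arr)
        assert shapes.perimeter(np.roll(arr, (7, 9), axis=(0, 1))) == pytest.approx(p0)
        assert shapes.perimeter(np.rot90(arr)) == pytest.approx(p0)


class TestDescribeDrawing:
    def test_disjoint_union_concatenates(self, rng):
        blob = rasterized_ellipse(8, 4)
        n = blob.shape[0]
        arr = np.zeros((n, 3 * n), dtype=bool)
        arr[:, :n] = blob
        arr[:, 2 * n :] = blob
        desc = shapes.describe_drawing(arr)
        solo = shapes.describe_drawing(blob).phosphenes[0]
        assert desc.n_phosphenes == 2
        for shape in desc.phosphenes:
            assert shape.area == solo.area
            assert shape.perimeter == pytest.approx(solo.perimeter)
            assert shape.major_axis_length == pytest.approx(solo.major_axis_length)
            assert shape.minor_axis_length == pytest.approx(solo.minor_axis_length)

    def test_translation_invariance_of_descriptors(self, rng):
        arr = random_mask(rng, (20, 20), density=0.6)
        arr = shapes.connected_regions(arr)[0]  # a single connected blob
        moved = np.zeros((40, 40), dtype=bool)
        moved[13 : 13 + 20, 7 : 7 + 20] = arr
        a = shapes.describe_drawing(arr).phosphenes[0]
        b = shapes.describe_drawing(moved).phosphenes[0]
        assert (a.area, a.perimeter) == (b.area, b.perimeter)
        assert a.major_axis_length == pytest.approx(b.major_axis_length, abs=1e-9)

    def test_region_wise_equality_with_crop_oracle(self, rng):
        for _ in range(10):
            arr = random_mask(rng, (32, 32), density=0.3)
            desc = shapes.describe_drawing(arr)
            for region, shape in zip(shapes.connected_regions(arr), desc.phosphenes):
                ys, xs = np.nonzero(region)
                crop = region[ys.min() : ys.max() + 1, xs.min() : xs.max() + 1]
                solo = shapes.describe_drawing(crop).phosphenes[0]
                assert shape.area == solo.area
                assert shape.perimeter == pytest.approx(solo.perimeter)
                assert shape.major_axis_length == pytest.approx(
                    solo.major_axis_length, abs=1e-9
                )

    def test_ellipse_area_consistency(self):
        # pi * (major/2) * (minor/2) approximates area for convex regions
        arr = rasterized_ellipse(30, 12)
        s = shapes.describe_drawing(arr).phosphenes[0]
        est = math.pi * (s.major_axis_length / 2) * (s.minor_axis_length / 2)
        assert est == pytest.approx(s.area, rel=0.25)
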
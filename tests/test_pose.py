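"""Moments, orientation, heading disambiguation and standardization."""

import math

import numpy as np
import pytest

from shellmetrics import (
    compute_moments,
    estimate_pose,
    make_random_binary_grid,
    orientation_from_moments,
    resolve_heading,
    standardize,
)
from shellmetrics.errors import DegenerateInputError
from tests.conftest import mask_f1


def brute_force_moments(mask):
    """Independent double-loop evaluation of the raw moment sums."""
    h, w = mask.shape
    M00 = M10 = M01 = M20 = M02 = M11 = 0
    for row in range(h):
        for col in range(w):
            v = 1 if mask[row, col] == 255 else 0
            x, y = col, row
            M00 += v
            M10 += x * v
            M01 += y * v
            M20 += x * x * v
            M02 += y * y * v
            M11 += x * y * v
    return M00, M10, M01, M20, M02, M11


def bar_mask(angle_deg, length=101, size=161):
    """Rasterized 1-px-thick bar through the center at a y-up angle."""
    m = np.zeros((size, size), np.uint8)
    c = size // 2
    for t in np.linspace(-length / 2, length / 2, 4 * length):
        x = t * math.cos(math.radians(angle_deg))
        y_up = t * math.sin(math.radians(angle_deg))
        m[int(round(c - y_up)), int(round(c + x))] = 255
    return m


def angdiff(a, b, period=360.0):
    d = abs(a - b) % period
    return min(d, period - d)


class TestMoments:
    def test_single_pixel(self):
        m = np.zeros((8, 8), np.uint8)
        m[5, 3] = 255
        ms = compute_moments(m)
        assert (ms.m00, ms.m10, ms.m01) == (1, 3, 5)
        assert (ms.xc, ms.yc) == (3, 5)

    def test_2x2_block_symmetry(self):
        m = np.zeros((4, 4), np.uint8)
        m[0:2, 0:2] = 255
        ms = compute_moments(m)
        assert ms.m00 == 4 and ms.xc == 0.5 and ms.yc == 0.5

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_match_with_brute_force(self, seed):
        m = make_random_binary_grid(12, 10, 0.4, seed=seed)
        if not (m == 255).any():
            return
        ms = compute_moments(m)
        assert (ms.m00, ms.m10, ms.m01, ms.m20, ms.m02, ms.m11) == brute_force_moments(m)

    def test_m00_is_foreground_count_and_psd(self):
        m = make_random_binary_grid(15, 15, 0.5, seed=8)
        ms = compute_moments(m)
        assert ms.m00 == (m == 255).sum()
        assert ms.a >= 0 and ms.c >= 0 and ms.a * ms.c - ms.b**2 >= -1e-9

    def test_empty_mask_raises(self):
        with pytest.raises(DegenerateInputError):
            compute_moments(np.zeros((4, 4), np.uint8))

    def test_translation_equivariance(self):
        m = np.zeros((30, 30), np.uint8)
        m[4:9, 3:11] = 255
        shifted = np.roll(np.roll(m, 7, axis=0), 5, axis=1)
        a, b = compute_moments(m), compute_moments(shifted)
        assert (b.yc - a.yc, b.xc - a.xc) == (7, 5)
        assert orientation_from_moments(a) == pytest.approx(orientation_from_moments(b), abs=1e-9)


class TestOrientation:
    def test_horizontal_line_is_zero(self):
        m = np.zeros((9, 21), np.uint8)
        m[4, 2:19] = 255
        assert orientation_from_moments(compute_moments(m)) == 0.0

    def test_vertical_line_is_ninety(self):
        m = np.zeros((21, 9), np.uint8)
        m[2:19, 4] = 255
        assert orientation_from_moments(compute_moments(m)) == 90.0

    @pytest.mark.parametrize("angle", [10, 30, 50, 70, 110, 130, 150, 170])
    def test_bar_angles_recovered(self, angle):
        theta = orientation_from_moments(compute_moments(bar_mask(angle)))
        assert angdiff(theta, angle, period=180.0) <= 1.0

    def test_isotropic_shape_returns_zero(self):
        m = np.zeros((9, 9), np.uint8)
        m[3:6, 3:6] = 255  # square: a == c, b == 0
        assert orientation_from_moments(compute_moments(m)) == 0.0

    def test_rotation_equivariance_on_phantoms(self, phantom_at):
        _, base = phantom_at(0.0)
        theta0 = orientation_from_moments(compute_moments(base.mask))
        for phi in range(0, 180, 20):
            _, truth = phantom_at(float(phi))
            theta = orientation_from_moments(compute_moments(truth.mask))
            assert angdiff(theta, theta0 + phi, period=180.0) <= 1.0


class TestHeading:
    def test_phantom_heading_recovered(self, phantom_at):
        _, truth = phantom_at(139.11)
        heading, low = resolve_heading(truth.mask)
        assert not low
        assert angdiff(heading, 139.11) <= 2.0

    def test_symmetric_ellipse_low_confidence(self):
        m = np.zeros((81, 121), np.uint8)
        rows, cols = np.mgrid[0:81, 0:121]
        m[((cols - 60) / 50.0) ** 2 + ((rows - 40) / 25.0) ** 2 <= 1] = 255
        heading, low = resolve_heading(m)
        assert low
        theta = orientation_from_moments(compute_moments(m))
        assert heading == pytest.approx(theta)

    def test_mirrored_phantom_flips_heading(self, phantom_at):
        _, truth = phantom_at(30.0)
        mirrored = truth.mask[:, ::-1].copy()
        h1, _ = resolve_heading(truth.mask)
        h2, _ = resolve_heading(mirrored)
        # horizontal mirror maps heading 30 -> 150, i.e. not a 180 flip of 30;
        # compare against the mirrored ground truth instead
        assert angdiff(h1, 30.0) <= 2.0
        assert angdiff(h2, 150.0) <= 2.0

    def test_opposite_headings_differ_by_180(self, phantom_at):
        _, t1 = phantom_at(30.0)
        _, t2 = phantom_at(210.0)
        h1, _ = resolve_heading(t1.mask)
        h2, _ = resolve_heading(t2.mask)
        assert angdiff(abs(h1 - h2), 180.0) <= 2.0


class TestStandardize:
    def test_rotated_phantom_becomes_horizontal_head_left(self, phantom_at):
        img, truth = phantom_at(30.0)
        pose = estimate_pose(truth.mask)
        _, smask, rec = standardize(img, truth.mask, pose)
        theta = orientation_from_moments(compute_moments(smask))
        assert min(theta, 180.0 - theta) <= 0.5
        _, head_col = rec.apply(truth.head_center_rc)
        assert head_col < compute_moments(smask).xc

    def test_identity_rotation_preserves_mask(self, phantom_at):
        img, truth = phantom_at(0.0)
        pose = estimate_pose(truth.mask)
        _, smask, _ = standardize(img, truth.mask, pose)
        h, w = truth.mask.shape
        inter = ((smask[:h, :w] == 255) & (truth.mask == 255)).sum()
        union = ((smask[:h, :w] == 255) | (truth.mask == 255)).sum()
        assert inter / union >= 0.99

    @pytest.mark.parametrize("heading", [90.0, 200.0, 270.0])
    def test_arbitrary_headings_standardized(self, phantom_at, heading):
        img, truth = phantom_at(heading)
        pose = estimate_pose(truth.mask)
        _, smask, _ = standardize(img, truth.mask, pose)
        theta = orientation_from_moments(compute_moments(smask))
        assert min(theta, 180.0 - theta) <= 0.5

    def test_foreground_count_conserved(self, phantom_at):
        img, truth = phantom_at(55.0)
        pose = estimate_pose(truth.mask)
        _, smask, _ = standardize(img, truth.mask, pose)
        n0 = (truth.mask == 255).sum()
        n1 = (smask == 255).sum()
        assert abs(n1 - n0) / n0 <= 0.02

    def test_empty_mask_raises(self):
        from shellmetrics import Pose

        img = np.zeros((4, 4, 3), np.uint8)
        with pytest.raises(DegenerateInputError):
            standardize(img, np.zeros((4, 4), np.uint8), Pose(1, 1, 0, 0))
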
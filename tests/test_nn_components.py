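"""Attention and loss primitives against closed-form and hand oracles."""

import math

import numpy as np
import pytest

from shellmetrics import (
    Box,
    SEWeights,
    focal_loss,
    giou,
    iou,
    se_enhance,
    simam_energy,
    simam_enhance,
)
from shellmetrics.errors import InputError, ParameterError


def energy_minimum_oracle(t, others, lam):
    """Numerically minimize the per-neuron separability energy.

    e(w, b) = mean_i (-1 - (w x_i + b))^2 + (1 - (w t + b))^2 + lam w^2,
    solved via its normal equations -- an independent path from the closed
    form used by the implementation.
    """
    x = np.asarray(others, dtype=float)
    m = len(x)
    # gradient = 0 (quadratic, convex):
    #  w * (mean(x^2) + t^2 + lam) + b * (mean(x) + t) = t - mean(x)
    #  w * (mean(x) + t)           + b * 2             = 1 - 1
    A = np.array(
        [
            [np.mean(x**2) + t * t + lam, np.mean(x) + t],
            [np.mean(x) + t, 2.0],
        ]
    )
    rhs = np.array([t - np.mean(x), 0.0])
    w, b = np.linalg.solve(A, rhs)
    return np.mean((-1 - (w * x + b)) ** 2) + (1 - (w * t + b)) ** 2 + lam * w * w


class TestSimAM:
    def test_constant_channel_uniform_weights(self):
        x = np.full((2, 3, 3), 5.0)
        out = simam_enhance(x, lam=1e-4)
        # all positions identical -> identical attention -> uniform output
        assert np.allclose(out, out[:, :1, :1])

    def test_two_neuron_closed_form_equals_energy_minimum(self):
        lam = 1e-4
        t1, t2 = 1.0, 3.0
        e = simam_energy(np.array([[[t1, t2]]]), lam)
        assert e[0, 0, 0] == pytest.approx(energy_minimum_oracle(t1, [t2], lam), rel=1e-10)
        assert e[0, 0, 1] == pytest.approx(energy_minimum_oracle(t2, [t1], lam), rel=1e-10)

    @pytest.mark.parametrize("seed", range(3))
    def test_random_maps_match_oracle(self, seed):
        lam = 1e-4
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, (2, 4, 4))
        E = simam_energy(x, lam)
        for c in range(2):
            vals = x[c].ravel()
            for idx, t in enumerate(vals):
                expected = energy_minimum_oracle(t, np.delete(vals, idx), lam)
                assert E[c].ravel()[idx] == pytest.approx(expected, rel=1e-9)

    def test_scaling_preserves_attention_ordering(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, (1, 4, 4))
        w1 = simam_enhance(x) / x
        w2 = simam_enhance(2 * x) / (2 * x)
        assert np.array_equal(np.argsort(w1.ravel()), np.argsort(w2.ravel()))

    def test_shape_preserved_and_weights_in_unit_interval(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 2, (3, 5, 7))
        out = simam_enhance(x)
        assert out.shape == x.shape
        w = 1.0 / (1.0 + np.exp(-1.0 / simam_energy(x)))
        assert ((w > 0) & (w < 1)).all()

    def test_invalid_inputs(self):
        with pytest.raises(ParameterError):
            simam_enhance(np.ones((1, 2, 2)), lam=0.0)
        with pytest.raises(InputError):
            simam_enhance(np.ones((1, 1, 1)))


class TestSE:
    def test_zero_weights_halve_the_map(self):
        x = np.arange(16.0).reshape(1, 4, 4)
        w = SEWeights(reduce=np.zeros((1, 1)), expand=np.zeros((1, 1)))
        np.testing.assert_allclose(se_enhance(x, w), 0.5 * x)

    def test_saturated_gates_pass_input_through(self):
        x = np.ones((2, 3, 3))
        w = SEWeights(reduce=np.full((2, 1), 100.0), expand=np.full((1, 2), 100.0))
        np.testing.assert_allclose(se_enhance(x, w), x, rtol=1e-6)

    def test_matches_hand_matrix_chain(self):
        rng = np.random.default_rng(42)
        x = rng.normal(0, 1, (4, 2, 2))
        w = SEWeights.random(channels=4, r=2, seed=42)
        z = x.reshape(4, -1).mean(axis=1)
        hidden = np.maximum(z @ w.reduce, 0.0)
        gates = 1.0 / (1.0 + np.exp(-(hidden @ w.expand)))
        expected = gates[:, None, None] * x
        np.testing.assert_allclose(se_enhance(x, w), expected, rtol=1e-12)
        assert ((gates > 0) & (gates < 1)).all()

    def test_channel_mismatch_rejected(self):
        w = SEWeights.random(channels=4, r=2)
        with pytest.raises(InputError):
            se_enhance(np.ones((3, 2, 2)), w)
        with pytest.raises(ParameterError):
            SEWeights(reduce=np.zeros((4, 2)), expand=np.zeros((2, 3)))


class TestFocalLoss:
    def test_perfect_prediction_vanishes(self):
        assert focal_loss(np.array([1.0 - 1e-9]), np.array([1])) == pytest.approx(0.0, abs=1e-6)

    def test_gamma_zero_reduces_to_half_cross_entropy(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.05, 0.95, 20)
        y = rng.integers(0, 2, 20)
        ce = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert focal_loss(p, y, alpha=0.5, gamma=0.0) == pytest.approx(0.5 * ce, rel=1e-9)

    def test_hand_value(self):
        # alpha (1-p)^gamma (-log p) = 0.25 * 0.01 * (-ln 0.9)
        expected = 0.25 * 0.1**2 * (-math.log(0.9))
        assert focal_loss(np.array([0.9]), np.array([1])) == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(2.634e-4, rel=1e-3)

    def test_nonnegative_and_monotone_for_positives(self):
        ps = np.linspace(0.05, 0.95, 19)
        losses = [focal_loss(np.array([p]), np.array([1])) for p in ps]
        assert all(l >= 0 for l in losses)
        assert all(a >= b for a, b in zip(losses, losses[1:]))

    def test_invalid_parameters(self):
        with pytest.raises(ParameterError):
            focal_loss(np.array([0.5]), np.array([1]), alpha=1.5)
        with pytest.raises(ParameterError):
            focal_loss(np.array([0.5]), np.array([1]), gamma=-1.0)
        with pytest.raises(InputError):
            focal_loss(np.array([0.5]), np.array([2]))


class TestGIoU:
    def test_identical_boxes(self):
        b = Box(0, 0, 2, 3)
        assert iou(b, b) == 1.0 and giou(b, b) == 1.0

    def test_disjoint_unit_boxes(self):
        a, b = Box(0, 0, 1, 1), Box(2, 2, 3, 3)
        assert iou(a, b) == 0.0
        assert giou(a, b) == pytest.approx(-7.0 / 9.0)

    def test_abutting_boxes(self):
        a, b = Box(0, 0, 1, 1), Box(1, 0, 2, 1)
        assert giou(a, b) == 0.0 == iou(a, b)

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetry_translation_scale_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(-5, 5, 8)
        a = Box(min(x[0], x[1]), min(x[2], x[3]), max(x[0], x[1]), max(x[2], x[3]))
        b = Box(min(x[4], x[5]), min(x[6], x[7]), max(x[4], x[5]), max(x[6], x[7]))
        g = giou(a, b)
        assert g == pytest.approx(giou(b, a), rel=1e-12)
        dx, dy, k = 3.7, -1.2, 2.5
        shifted = lambda bx: Box(bx.x1 + dx, bx.y1 + dy, bx.x2 + dx, bx.y2 + dy)
        scaled = lambda bx: Box(k * bx.x1, k * bx.y1, k * bx.x2, k * bx.y2)
        assert giou(shifted(a), shifted(b)) == pytest.approx(g, rel=1e-9, abs=1e-12)
        assert giou(scaled(a), scaled(b)) == pytest.approx(g, rel=1e-9, abs=1e-12)
        assert g <= iou(a, b) + 1e-12
        assert -1.0 < g <= 1.0

    def test_zero_area_boxes(self):
        a = Box(0, 0, 0, 0)
        b = Box(1, 1, 2, 2)
        assert iou(a, b) == 0.0
        assert giou(a, b) <= 0.0

    def test_degenerate_corners_rejected(self):
        with pytest.raises(ParameterError):
            Box(2, 0, 1, 1)
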
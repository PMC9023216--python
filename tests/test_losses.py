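import itertools

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from otoseg.losses import (
    LossConfig,
    boundary_loss,
    boundary_loss_grad,
    ce_loss,
    ce_loss_grad,
    dice_loss,
    dice_loss_grad,
    ensemble_loss,
    ensemble_loss_grad,
    signed_distance,
)


def brute_force_phi(mask: np.ndarray) -> np.ndarray:
    """All-pairs oracle: signed distance to the nearest opposite-class voxel."""
    coords = np.argwhere(np.ones_like(mask, dtype=bool)).astype(float)
    flat = mask.ravel().astype(bool)
    if flat.all() or not flat.any():
        return np.zeros(mask.shape)
    d = cdist(coords, coords)
    phi = np.empty(flat.size)
    for i in range(flat.size):
        opposite = flat != flat[i]
        phi[i] = d[i, opposite].min() * (-1 if flat[i] else 1)
    return phi.reshape(mask.shape)


class TestDiceLoss:
    def test_identical_binary_masks_score_zero(self, rng):
        g = (rng.random((3, 4, 5)) > 0.7).astype(float)
        assert dice_loss(g, g, w=1e-5) == pytest.approx(0.0, abs=1e-5)

    def test_half_overlap_example(self):
        p = np.array([1.0, 1.0, 0.0, 0.0])
        g = np.array([1.0, 0.0, 1.0, 0.0])
        assert dice_loss(p, g, w=1e-12) == pytest.approx(0.5, abs=1e-9)

    def test_smoothing_saves_empty_case(self):
        z = np.zeros((2, 2, 2))
        assert dice_loss(z, z, w=1e-5) == 0.0

    def test_range_and_errors(self, rng):
        p = rng.random((4, 4, 4))
        g = (rng.random((4, 4, 4)) > 0.9).astype(float)
        assert 0.0 <= dice_loss(p, g) < 1.0
        with pytest.raises(ValueError):
            dice_loss(p, g[:2])
        with pytest.raises(ValueError):
            dice_loss(p, g, w=0.0)


class TestCrossEntropy:
    def test_confident_correct_is_near_zero(self):
        assert ce_loss(np.array([1.0, 0.0]), np.array([1.0, 0.0])) < 1e-5

    def test_half_probability_single_voxel(self):
        assert ce_loss(np.array([0.5]), np.array([1.0])) == pytest.approx(np.log(2), rel=1e-9)

    def test_mean_of_two_equal_terms(self):
        p = np.array([0.5, 0.5])
        g = np.array([1.0, 0.0])
        assert ce_loss(p, g) == pytest.approx(np.log(2), rel=1e-9)

    def test_finite_at_saturated_probabilities(self):
        p = np.array([0.0, 1.0])
        g = np.array([1.0, 0.0])
        assert np.isfinite(ce_loss(p, g))

    def test_single_term_mode(self):
        p = np.array([0.5, 0.5])
        g = np.array([1.0, 0.0])
        # only the foreground voxel contributes
        assert ce_loss(p, g, single_term=True) == pytest.approx(np.log(2) / 2, rel=1e-9)


class TestSignedDistance:
    def test_three_voxel_line(self):
        phi = signed_distance(np.array([[[0, 1, 0]]]))
        np.testing.assert_allclose(phi, [[[1, -1, 1]]])

    def test_four_voxel_line(self):
        phi = signed_distance(np.array([[[0, 0, 1, 1]]]))
        np.testing.assert_allclose(phi, [[[2, 1, -1, -2]]])

    def test_sign_pattern_matches_mask(self, rng):
        g = (rng.random((4, 5, 6)) > 0.5).astype(np.uint8)
        phi = signed_distance(g)
        np.testing.assert_array_equal(np.sign(phi), 1 - 2 * g.astype(float))

    def test_degenerate_masks_give_zero_map(self):
        assert (signed_distance(np.zeros((2, 3, 4), dtype=np.uint8)) == 0).all()
        assert (signed_distance(np.ones((2, 3, 4), dtype=np.uint8)) == 0).all()

    def test_spacing_scales_distances(self):
        g = np.array([[[0, 1, 0]]], dtype=np.uint8)
        np.testing.assert_allclose(
            signed_distance(g, spacing=(1, 1, 0.5)), [[[0.5, -0.5, 0.5]]]
        )

    @pytest.mark.parametrize("shape", [(1, 3, 3), (2, 2, 3)])
    def test_exhaustive_brute_force_oracle(self, shape):
        """Every mask of a small block agrees exactly with the all-pairs
        nearest-opposite-class search."""
        n = int(np.prod(shape))
        for bits in range(2**n):
            mask = np.array([(bits >> k) & 1 for k in range(n)], dtype=np.uint8).reshape(shape)
            np.testing.assert_allclose(signed_distance(mask), brute_force_phi(mask))

    def test_sampled_larger_blocks_match_oracle(self, rng):
        for _ in range(300):
            mask = (rng.random((2, 3, 3)) > rng.random()).astype(np.uint8)
            np.testing.assert_allclose(signed_distance(mask), brute_force_phi(mask))

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            signed_distance(np.array([[[0, 2, 0]]]))


class TestBoundaryLoss:
    PHI = np.array([[[1.0, -1.0, 1.0]]])

    def test_perfect_prediction_is_negative(self):
        assert boundary_loss(np.array([[[0.0, 1.0, 0.0]]]), self.PHI) == pytest.approx(-1 / 3)

    def test_all_ones_prediction(self):
        assert boundary_loss(np.ones((1, 1, 3)), self.PHI) == pytest.approx(1 / 3)

    def test_empty_prediction_is_zero(self):
        assert boundary_loss(np.zeros((1, 1, 3)), self.PHI) == 0.0

    def test_minimised_by_most_negative_phi_voxels(self):
        """Among binary predictions with a fixed foreground budget, the loss
        is minimal when the budget sits on the smallest-phi voxels."""
        g = np.zeros((1, 3, 3), dtype=np.uint8)
        g[0, 1, 1] = 1
        g[0, 1, 2] = 1
        phi = signed_distance(g)
        flat = phi.ravel()
        n = flat.size
        for k in range(1, n):
            best = min(
                sum(flat[list(comb)]) for comb in itertools.combinations(range(n), k)
            )
            assert best == pytest.approx(np.sort(flat)[:k].sum())
            # and as a loss: mean of the chosen phis
            p = np.zeros(n)
            p[np.argsort(flat)[:k]] = 1.0
            assert boundary_loss(p.reshape(phi.shape), phi) == pytest.approx(best / n)


class TestGradients:
    """Closed-form gradients match central finite differences."""

    @pytest.mark.parametrize(
        "loss,grad,extra",
        [
            (dice_loss, dice_loss_grad, {"w": 1e-3}),
            (ce_loss, ce_loss_grad, {}),
        ],
    )
    def test_voxel_losses(self, rng, loss, grad, extra):
        p = rng.uniform(0.05, 0.95, size=(3, 3, 3))
        g = (rng.random((3, 3, 3)) > 0.6).astype(float)
        ana = grad(p, g, **extra)
        eps = 1e-6
        for idx in [(0, 0, 0), (1, 2, 1), (2, 2, 2)]:
            pp, pm = p.copy(), p.copy()
            pp[idx] += eps
            pm[idx] -= eps
            num = (loss(pp, g, **extra) - loss(pm, g, **extra)) / (2 * eps)
            assert num == pytest.approx(ana[idx], rel=1e-4, abs=1e-10)

    def test_boundary_gradient(self, rng):
        g = (rng.random((3, 3, 3)) > 0.7).astype(np.uint8)
        phi = signed_distance(g)
        p = rng.uniform(0.1, 0.9, size=(3, 3, 3))
        ana = boundary_loss_grad(p, phi)
        eps = 1e-6
        idx = (1, 1, 1)
        pp, pm = p.copy(), p.copy()
        pp[idx] += eps
        pm[idx] -= eps
        num = (boundary_loss(pp, phi) - boundary_loss(pm, phi)) / (2 * eps)
        assert num == pytest.approx(ana[idx], rel=1e-6)

    def test_ensemble_gradient(self, rng):
        cfg = LossConfig(mode="dice+boundary", aux_weight=0.7)
        g = (rng.random((3, 3, 3)) > 0.7).astype(float)
        p = rng.uniform(0.1, 0.9, size=(3, 3, 3))
        ana = ensemble_loss_grad(p, g, cfg)
        eps = 1e-6
        idx = (0, 2, 1)
        pp, pm = p.copy(), p.copy()
        pp[idx] += eps
        pm[idx] -= eps
        num = (ensemble_loss(pp, g, cfg)[0] - ensemble_loss(pm, g, cfg)[0]) / (2 * eps)
        assert num == pytest.approx(ana[idx], rel=1e-4)


class TestEnsembles:
    def test_zero_weight_reduces_to_dice(self, rng):
        p = rng.random((3, 3, 3))
        g = (rng.random((3, 3, 3)) > 0.8).astype(float)
        d = dice_loss(p, g, 1e-5)
        for mode in ("dice", "dice+ce", "dice+boundary"):
            cfg = LossConfig(mode=mode, aux_weight=0.0)
            assert ensemble_loss(p, g, cfg)[0] == pytest.approx(d)

    def test_dice_ce_vanishes_on_perfect_binary(self, rng):
        g = (rng.random((3, 3, 3)) > 0.7).astype(float)
        total, _ = ensemble_loss(g, g, LossConfig(mode="dice+ce"))
        assert total == pytest.approx(0.0, abs=1e-4)

    def test_dice_boundary_worked_example(self):
        g = np.array([[[0.0, 1.0, 0.0]]])
        cfg = LossConfig(mode="dice+boundary", smooth_w=1e-12)
        total, comps = ensemble_loss(g, g, cfg)
        assert comps["dice"] == pytest.approx(0.0, abs=1e-9)
        assert total == pytest.approx(-1 / 3, abs=1e-9)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            LossConfig(mode="tversky")

    def test_ramp_schedule(self):
        cfg = LossConfig(mode="dice+boundary", aux_weight=2.0, aux_ramp=True, aux_ramp_rate=0.1)
        assert cfg.effective_aux_weight(0, 10) == pytest.approx(0.2)
        assert cfg.effective_aux_weight(4, 10) == pytest.approx(1.0)
        assert cfg.effective_aux_weight(50, 100) == pytest.approx(2.0)  # capped
        flat = LossConfig(mode="dice")
        assert flat.effective_aux_weight(3, 10) == flat.aux_weight
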
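"""Loss closed forms, CSS gate semantics and adversarial loss directions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chorangio.losses import (
    GateThresholds,
    LossWeights,
    adapt_loss,
    confidence_gate,
    domain_gate,
    edd_loss,
    make_pseudo_labels,
    selection_mask,
    soft_dice_loss,
    source_loss,
    target_loss,
    total_loss,
)
from chorangio.models import ProbabilityMaps
from chorangio.nn import Tensor


def _onehot(labels, c):
    out = np.zeros((c,) + labels.shape, np.float32)
    for k in range(c):
        out[k][labels == k] = 1
    return out


class TestSoftDice:
    def test_perfect_overlap_is_zero(self):
        labels = np.array([[0, 1], [2, 1]], np.uint8)
        probs = _onehot(labels, 3)
        assert soft_dice_loss(probs, labels).item() == pytest.approx(0.0, abs=1e-6)

    def test_disjoint_one_hot_approaches_one(self):
        pred = np.zeros((30, 30), np.uint8)
        pred[:15] = 1
        gt = np.zeros((30, 30), np.uint8)
        gt[15:] = 1
        loss = soft_dice_loss(_onehot(pred, 2), gt, smooth=1e-7)
        assert loss.item() == pytest.approx(1.0, abs=1e-3)

    def test_half_overlap_strip_matches_set_formula(self):
        # 4-pixel strips, 2 of 4 pixels agree: dice = 2*2/(4+4) = 0.5
        pred = np.zeros((1, 8), np.uint8)
        pred[0, :4] = 1
        gt = np.zeros((1, 8), np.uint8)
        gt[0, 2:6] = 1
        loss = soft_dice_loss(_onehot(pred, 2), gt, smooth=1e-9)
        assert loss.item() == pytest.approx(0.5, abs=1e-5)

    def test_random_probs_match_brute_force_formula(self, rng):
        probs = rng.random((3, 5, 5)).astype(np.float32)
        probs /= probs.sum(axis=0)
        labels = rng.integers(0, 3, (5, 5)).astype(np.uint8)
        y = _onehot(labels, 3)
        eps = 1.0
        expected = 1 - np.mean([
            (2 * (probs[c] * y[c]).sum() + eps) / (probs[c].sum() + y[c].sum() + eps)
            for c in (1, 2)
        ])
        assert soft_dice_loss(probs, labels).item() == pytest.approx(expected, abs=1e-5)

    def test_empty_mask_returns_zero(self):
        labels = np.zeros((4, 4), np.uint8)
        loss = soft_dice_loss(_onehot(labels, 2), labels, mask=np.zeros((4, 4), np.uint8))
        assert loss.item() == 0.0

    def test_gradient_flows_to_probability_tensor(self):
        probs = Tensor(np.full((1, 2, 4, 4), 0.5, np.float32), requires_grad=True)
        labels = np.ones((4, 4), np.uint8)
        soft_dice_loss(probs, labels).backward()
        assert probs.grad is not None and np.abs(probs.grad).sum() > 0


class TestSourceLoss:
    def _maps(self, rng, n=2):
        lp = rng.random((n, 3, 8, 8)).astype(np.float32)
        lp /= lp.sum(axis=1, keepdims=True)
        vp = rng.random((n, 2, 8, 8)).astype(np.float32)
        vp /= vp.sum(axis=1, keepdims=True)
        return ProbabilityMaps(layer_probs=Tensor(lp), vessel_probs=Tensor(vp))

    def test_perfect_predictions_give_zero(self):
        vessel = np.zeros((2, 8, 8), np.uint8)
        layers = np.ones((2, 8, 8), np.uint8)
        pm = ProbabilityMaps(
            layer_probs=Tensor(np.stack([_onehot(l, 3) for l in layers])),
            vessel_probs=Tensor(np.stack([_onehot(v, 2) for v in vessel])),
        )
        assert source_loss(pm, vessel, layers).item() == pytest.approx(0.0, abs=1e-6)

    def test_decomposes_into_per_head_sums(self, rng):
        pm = self._maps(rng)
        vessel = rng.integers(0, 2, (2, 8, 8)).astype(np.uint8)
        layers = rng.integers(0, 3, (2, 8, 8)).astype(np.uint8)
        total = source_loss(pm, vessel, layers).item()
        sep = (soft_dice_loss(pm.vessel_probs, vessel).item()
               + soft_dice_loss(pm.layer_probs, layers).item())
        assert total == pytest.approx(sep, abs=1e-6)

    def test_missing_ground_truth_is_an_error(self, rng):
        with pytest.raises(ValueError):
            source_loss(self._maps(rng), None, np.zeros((2, 8, 8), np.uint8))


class TestPseudoLabels:
    def test_simple_argmax(self):
        probs = np.array([[[0.1]], [[0.7]], [[0.2]]], np.float32)
        labels, maxprob = make_pseudo_labels(probs)
        assert labels[0, 0] == 1 and maxprob[0, 0] == pytest.approx(0.7)

    def test_uniform_ties_break_to_background(self):
        probs = np.full((3, 2, 2), 1 / 3, np.float32)
        labels, maxprob = make_pseudo_labels(probs)
        assert (labels == 0).all() and maxprob[0, 0] == pytest.approx(1 / 3)

    def test_matches_per_pixel_scan_oracle(self, rng):
        probs = rng.random((4, 6, 6)).astype(np.float32)
        labels, maxprob = make_pseudo_labels(probs)
        for i in range(6):
            for j in range(6):
                col = probs[:, i, j]
                assert labels[i, j] == int(np.argmax(col))
                assert maxprob[i, j] == pytest.approx(col.max())


class TestGates:
    def test_confidence_gate_is_strict(self):
        mp = np.array([[0.9, 0.85], [0.1, 0.86]])
        np.testing.assert_array_equal(confidence_gate(mp, 0.85),
                                      [[1, 0], [0, 1]])

    def test_domain_gate_bounds_are_strict(self):
        s = np.array([[0.5, 0.05], [0.95, 0.1]])
        np.testing.assert_array_equal(domain_gate(s, 0.1, 0.9),
                                      [[1, 0], [0, 0]])

    def test_vessel_preset_bounds(self):
        g = GateThresholds.vessel_preset()
        assert (g.alpha, g.beta1, g.beta2) == (0.85, 0.15, 0.85)
        s = np.array([0.15, 0.5, 0.85])
        np.testing.assert_array_equal(domain_gate(s, g.beta1, g.beta2), [0, 1, 0])

    def test_random_maps_match_elementwise_oracle(self, rng):
        mp = rng.random((10, 10))
        s = rng.random((10, 10))
        np.testing.assert_array_equal(confidence_gate(mp, 0.85), (mp > 0.85))
        np.testing.assert_array_equal(domain_gate(s, 0.1, 0.9),
                                      (s > 0.1) & (s < 0.9))

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            domain_gate(np.ones((2, 2)) * 0.5, 0.9, 0.1)
        with pytest.raises(ValueError):
            GateThresholds(0.85, 0.9, 0.1)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(alpha_lo=st.floats(0.05, 0.45), step=st.floats(0.05, 0.4))
    def test_gates_are_monotone_in_their_thresholds(self, alpha_lo, step):
        rng = np.random.default_rng(0)
        mp = rng.random((12, 12))
        low = confidence_gate(mp, alpha_lo)
        high = confidence_gate(mp, alpha_lo + step)
        assert not np.any(high & ~low)  # raising alpha never adds pixels
        s = rng.random((12, 12))
        narrow = domain_gate(s, 0.3, 0.6)
        wide = domain_gate(s, 0.3 - min(step, 0.25), 0.6 + min(step, 0.35))
        assert not np.any(narrow & ~wide)  # widening never removes pixels

    def test_selection_mask_is_conjunction(self, rng):
        mp = rng.random((8, 8))
        s = rng.random((8, 8))
        sel = selection_mask(mp, s, GateThresholds.layer_preset())
        np.testing.assert_array_equal(sel.m, sel.mc & sel.md)
        assert 0.0 <= sel.fraction <= 1.0


class TestTargetLoss:
    def _probs(self, rng):
        p = rng.random((1, 3, 6, 6)).astype(np.float32)
        return Tensor(p / p.sum(axis=1, keepdims=True))

    def test_all_zero_mask_is_flagged_zero(self, rng):
        loss, stats = target_loss(self._probs(rng),
                                  np.zeros((1, 6, 6), np.uint8),
                                  np.zeros((1, 6, 6), np.uint8))
        assert loss.item() == 0.0 and stats["empty_selection"]

    def test_full_mask_equals_unmasked_dice(self, rng):
        probs = self._probs(rng)
        pseudo = rng.integers(0, 3, (1, 6, 6)).astype(np.uint8)
        masked, stats = target_loss(probs, pseudo, np.ones((1, 6, 6), np.uint8))
        assert not stats["empty_selection"]
        assert masked.item() == pytest.approx(soft_dice_loss(probs, pseudo).item(),
                                              abs=1e-6)

    def test_checkerboard_mask_matches_selected_pixel_oracle(self, rng):
        probs = self._probs(rng)
        pseudo = rng.integers(0, 3, (1, 6, 6)).astype(np.uint8)
        mask = np.indices((6, 6)).sum(axis=0) % 2
        loss, _ = target_loss(probs, pseudo, mask[None].astype(np.uint8))
        p = probs.data[0]
        eps = 1.0
        dices = []
        for c in (1, 2):
            pc = p[c][mask == 1]
            yc = (pseudo[0][mask == 1] == c).astype(float)
            dices.append((2 * (pc * yc).sum() + eps) / (pc.sum() + yc.sum() + eps))
        assert loss.item() == pytest.approx(1 - np.mean(dices), abs=1e-5)


class TestAdversarial:
    def test_midpoint_scores_give_two_log_two(self):
        s = Tensor(np.array([[0.5]], np.float32))
        assert edd_loss(s, s).item() == pytest.approx(2 * np.log(2), abs=1e-5)

    def test_perfect_discrimination_drives_le_to_zero(self):
        s_t = Tensor(np.array([[1.0 - 1e-7]], np.float32))
        s_s = Tensor(np.array([[1e-7]], np.float32))
        assert edd_loss(s_t, s_s).item() == pytest.approx(0.0, abs=1e-4)

    def test_le_gradient_signs(self):
        s_t = Tensor(np.array([[0.4]], np.float32), requires_grad=True)
        s_s = Tensor(np.array([[0.6]], np.float32), requires_grad=True)
        edd_loss(s_t, s_s).backward()
        assert s_t.grad[0, 0] < 0  # pushing target scores up lowers Le
        assert s_s.grad[0, 0] > 0  # pushing source scores up raises Le

    def test_adapt_loss_midpoint_and_monotonicity(self):
        assert adapt_loss(Tensor(np.array([[0.5]], np.float32))).item() == \
            pytest.approx(np.log(2), abs=1e-6)
        values = [adapt_loss(Tensor(np.array([[s]], np.float32))).item()
                  for s in (0.2, 0.5, 0.8, 0.99)]
        assert all(a > b for a, b in zip(values, values[1:]))


class TestTotalLoss:
    def test_unit_components_with_published_weights(self):
        assert total_loss(1.0, 1.0, 1.0) == pytest.approx(3.0)

    def test_zero_weights_reduce_to_source_loss(self):
        w = LossWeights(0.0, 0.0)
        assert total_loss(0.7, 123.0, 456.0, w) == pytest.approx(0.7)

    def test_linearity_in_each_component(self):
        base = total_loss(1.0, 1.0, 1.0)
        assert total_loss(2.0, 1.0, 1.0) - base == pytest.approx(1.0)
        assert total_loss(1.0, 3.0, 1.0) - base == pytest.approx(3.0)
        assert total_loss(1.0, 1.0, 5.0) - base == pytest.approx(2.0)

    def test_non_finite_component_is_named(self):
        with pytest.raises(FloatingPointError, match="Lt"):
            total_loss(1.0, np.nan, 1.0)
        with pytest.raises(ValueError):
            LossWeights(-1.0, 0.5)
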
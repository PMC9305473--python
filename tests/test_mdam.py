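"""Multi-directional attention: profiles, aggregation, weight strategies."""

import numpy as np
import pytest

from mdam_drnet.autograd import Tensor
from mdam_drnet.mdam import (
    MDAM,
    AttentionParams,
    attention_aggregate,
    direction_weights,
    directional_profiles,
    max_strategy,
    mdam_forward,
    multiply_strategy,
    secondary_weights,
)


class TestDirectionalProfiles:
    def test_constant_tensor_gives_constant_profiles(self):
        prof = directional_profiles(np.full((5, 6, 6), 3.25))
        assert prof.h.shape == (4, 5)
        assert np.allclose(prof.h, 3.25)

    def test_transpose_symmetric_tensor_h_equals_v(self, rng):
        f = rng.normal(size=(3, 7, 7))
        f = f + f.transpose(0, 2, 1)
        prof = directional_profiles(f)
        assert np.allclose(prof.h[0], prof.h[1])

    def test_2x2_diagonal_bands_hand_enumeration(self):
        """Band partition of [[1,2],[3,4]]: main-diagonal bands {3},{1,4},{2}
        and anti-diagonal bands {1},{2,3},{4}; band means averaged equally."""
        f = np.array([[[1.0, 2.0], [3.0, 4.0]]])
        w = direction_weights(2, 2)
        ld = (3 + (1 + 4) / 2 + 2) / 3
        rd = (1 + (2 + 3) / 2 + 4) / 3
        assert (f[0].ravel() * w["left_diagonal"].ravel()).sum() == pytest.approx(ld)
        assert (f[0].ravel() * w["right_diagonal"].ravel()).sum() == pytest.approx(rd)
        prof = directional_profiles(f)
        assert prof.h[2, 0] == pytest.approx(ld)
        assert prof.h[3, 0] == pytest.approx(rd)

    def test_direction_weights_sum_to_one(self):
        for w in direction_weights(5, 9).values():
            assert w.sum() == pytest.approx(1.0)

    def test_too_small_tensor_rejected(self):
        with pytest.raises(ValueError):
            directional_profiles(np.zeros((2, 1, 5)))


class TestAttentionAggregate:
    def test_uniform_coefficients_average_nodes(self, rng):
        prof = directional_profiles(rng.normal(size=(4, 6, 6)))
        params = AttentionParams.init(4, seed=0)
        params = AttentionParams(W=params.W, a=params.a, e=np.zeros((4, 4)))
        out = attention_aggregate(prof, params)
        assert np.allclose(out.coefficients, 0.25)
        assert np.allclose(out.C, prof.h.mean(axis=0))

    def test_saturated_diagonal_recovers_own_node(self, rng):
        prof = directional_profiles(rng.normal(size=(4, 6, 6)))
        params = AttentionParams.init(4, seed=0)
        params = AttentionParams(W=params.W, a=params.a, e=np.eye(4) * 1e4)
        out = attention_aggregate(prof, params)
        assert np.allclose(out.C, prof.h, atol=1e-8)

    def test_softmax_rows_sum_to_one(self, rng):
        prof = directional_profiles(rng.normal(size=(5, 8, 8)))
        out = attention_aggregate(prof, AttentionParams.init(5, seed=3))
        assert np.allclose(out.coefficients.sum(axis=1), 1.0)
        assert (out.coefficients > 0).all()

    def test_matches_scalar_loop_oracle(self, rng):
        """Term-by-term scalar evaluation of the softmax aggregation."""
        prof = directional_profiles(rng.normal(size=(3, 6, 6)))
        params = AttentionParams.init(3, seed=9)
        out = attention_aggregate(prof, params)
        h = prof.h
        wh = h @ params.W
        fp = params.W.shape[1]
        e = np.empty((4, 4))
        for i in range(4):
            for j in range(4):
                s = float(np.concatenate([wh[i], wh[j]]) @ params.a)
                e[i, j] = s if s > 0 else params.leaky_slope * s
        for i in range(4):
            denom = sum(np.exp(e[i, k]) for k in range(4))
            ci = sum(np.exp(e[i, j]) / denom * h[j] for j in range(4))
            assert np.allclose(out.C[i], ci, atol=1e-9)

    def test_nonfinite_coefficients_rejected(self, rng):
        prof = directional_profiles(rng.normal(size=(2, 4, 4)))
        params = AttentionParams.init(2, seed=0)
        bad = AttentionParams(W=params.W, a=params.a, e=np.full((4, 4), np.nan))
        with pytest.raises(FloatingPointError):
            attention_aggregate(prof, bad)

    def test_alpha_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            AttentionParams.init(4, alpha=1.0)


class TestWeightStrategies:
    def test_multiply_worked_values(self):
        assert multiply_strategy(np.array(0.9), np.array(0.7)) == pytest.approx(-0.07)
        c = np.array(0.4)
        assert multiply_strategy(c, c) == pytest.approx(0.16 - 0.4)
        x = np.array(0.6)
        assert multiply_strategy(np.array(1.0), x) == pytest.approx(0.0)

    def test_max_worked_values(self):
        assert max_strategy(np.array(0.9), np.array(0.7), 0.3) == pytest.approx(1.11)
        c = np.array(0.5)
        assert max_strategy(c, c, 0.2) == pytest.approx(0.5 * 1.2)

    def test_max_alpha_small_limit(self, rng):
        a, b = rng.uniform(size=10), rng.uniform(size=10)
        out = max_strategy(a, b, 1e-12)
        assert np.allclose(out, np.maximum(a, b), atol=1e-10)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            multiply_strategy(np.zeros(3), np.zeros(4))
        with pytest.raises(ValueError):
            max_strategy(np.zeros(3), np.zeros(4), 0.3)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            max_strategy(np.zeros(2), np.zeros(2), 1.5)

    def test_strategies_match_scalar_oracle_bulk(self, rng):
        """Elementwise identities on random triples vs scalar arithmetic."""
        a = rng.uniform(-2, 2, 10_000)
        b = rng.uniform(-2, 2, 10_000)
        alpha = 0.3
        mult = multiply_strategy(a, b)
        mx = max_strategy(a, b, alpha)
        for i in rng.integers(0, 10_000, 200):
            assert mult[i] == pytest.approx(a[i] * b[i] - min(a[i], b[i]), abs=1e-12)
            assert mx[i] == pytest.approx(max(a[i], b[i]) + alpha * min(a[i], b[i]), abs=1e-12)


class TestMDAMForward:
    def test_concat_has_eight_slabs_and_gate_in_unit_interval(self, rng):
        out = mdam_forward(rng.normal(size=(6, 10, 12)), seed=2)
        assert out.concat.shape[0] == 8
        assert out.reweighted.shape == (6, 10, 12)
        assert ((out.gate > 0) & (out.gate < 1)).all()

    def test_constant_input_scales_by_one_plus_gate(self):
        f = np.full((4, 6, 6), 1.5)
        out = mdam_forward(f, seed=5)
        g = float(out.gate.flat[0])
        assert 0 < g < 1
        assert np.allclose(out.gate, g)
        assert np.allclose(out.reweighted, (1 + g) * f)

    def test_secondary_weights_follow_strategies(self, rng):
        prof = directional_profiles(rng.normal(size=(5, 6, 6)))
        pw = attention_aggregate(prof, AttentionParams.init(5, seed=1))
        sec = secondary_weights(pw, alpha=0.3)
        ch, cv, cld, crd = pw.C
        assert np.allclose(sec.C21, ch * cv - np.minimum(ch, cv))
        assert np.allclose(sec.C22, np.maximum(ch, cv) + 0.3 * np.minimum(ch, cv))
        assert np.allclose(sec.C23, cld * crd - np.minimum(cld, crd))
        assert np.allclose(sec.C24, np.maximum(cld, crd) + 0.3 * np.minimum(cld, crd))

    def test_transpose_equivariance_with_symmetric_kernels(self, rng):
        """With transpose-symmetric mining kernels the block commutes with
        spatial transposition (h/v profiles swap, diagonal profiles fixed)."""
        block = MDAM(3, seed=4)
        for conv in (block.mine.layers[0], block.mine.layers[2]):
            wd = conv.weight.data
            conv.weight.data = 0.5 * (wd + wd.transpose(0, 1, 3, 2))
        f = rng.normal(size=(3, 7, 7))
        out = mdam_forward(f, block=block)
        out_t = mdam_forward(f.transpose(0, 2, 1).copy(), block=block)
        assert np.allclose(out_t.reweighted, out.reweighted.transpose(0, 2, 1), atol=1e-10)

    def test_all_parameters_receive_gradients(self, rng):
        block = MDAM(4, seed=0)
        x = Tensor(rng.normal(size=(2, 4, 6, 6)), requires_grad=True)
        out = block(x)
        (out * out).sum().backward()
        for p in block.parameters():
            assert p.grad is not None
            assert np.abs(p.grad).max() > 0
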
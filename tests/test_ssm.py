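"""Selective state-space encoder: discretization closed forms, scan oracle,
causality, residual/gate identities and selectivity scores."""

import numpy as np
import pytest

from dfcmamba.autodiff import Tensor
from dfcmamba.ssm import (
    MambaBlock,
    MambaConfig,
    MambaEncoder,
    SelectivityTrace,
    discretize_zoh,
    selectivity_scores,
)


@pytest.fixture
def cfg():
    return MambaConfig(d_model=4, d_state=3, d_conv=2, expand=2, n_layers=2,
                       dropout_p=0.0)


@pytest.fixture
def block(cfg):
    return MambaBlock(cfg, np.random.default_rng(0))


class TestDiscretization:
    def test_closed_form_exponential(self):
        a_bar, _ = discretize_zoh(-1.0, 1.0, np.log(2.0))
        assert a_bar == pytest.approx(0.5)

    def test_small_delta_limit_carries_state(self):
        a_bar, _ = discretize_zoh(-1.0, 1.0, 1e-9)
        assert a_bar == pytest.approx(1.0, abs=1e-8)

    def test_euler_and_exact_zoh_agree_to_first_order(self):
        for delta in [1e-3, 1e-2]:
            _, b_euler = discretize_zoh(-1.0, 2.0, delta, rule="euler")
            _, b_zoh = discretize_zoh(-1.0, 2.0, delta, rule="zoh")
            assert abs(b_zoh - b_euler) / abs(b_euler) < delta

    def test_nonpositive_delta_rejected(self):
        with pytest.raises(ValueError):
            discretize_zoh(-1.0, 1.0, 0.0)


class TestSelectiveParameters:
    def test_zero_projection_gives_softplus_zero(self, cfg, block):
        block.delta_weight.data[:] = 0.0
        block.delta_bias.data[:] = 0.0
        u = Tensor(np.random.default_rng(1).standard_normal((5, cfg.d_inner)))
        z = Tensor(np.zeros((5, cfg.d_model)))
        delta, _, _ = block.selective_parameters(u, z)
        assert np.allclose(delta.data, np.log(2.0))

    def test_delta_always_positive(self, cfg, block):
        rng = np.random.default_rng(2)
        u = Tensor(rng.standard_normal((7, cfg.d_inner)) * 10)
        z = Tensor(rng.standard_normal((7, cfg.d_model)))
        delta, _, _ = block.selective_parameters(u, z)
        assert np.all(delta.data > 0)

    def test_hand_evaluation_tiny_config(self):
        cfg = MambaConfig(d_model=2, d_state=2, d_conv=2, expand=1, n_layers=1,
                          dropout_p=0.0)
        block = MambaBlock(cfg, np.random.default_rng(3))
        u = np.array([[0.5, -1.0], [2.0, 0.3], [0.0, 0.0]])
        z = np.array([[1.0, 0.0], [0.0, 1.0], [0.5, 0.5]])
        delta, b_sel, c_sel = block.selective_parameters(Tensor(u), Tensor(z))
        expect_delta = np.logaddexp(0, u * block.delta_weight.data + block.delta_bias.data)
        assert np.allclose(delta.data, expect_delta)
        expect_b = (z @ block.w_b.data).reshape(3, cfg.d_inner, cfg.d_state)
        assert np.allclose(b_sel.data, expect_b)


class TestScan:
    def test_telescoping_sum(self, cfg, block):
        # a_bar = 1, b_bar*u = 1, C = 1 with d_state=1 -> y_k = k+1
        k = 6
        block2 = MambaBlock(MambaConfig(d_model=2, d_state=1, d_conv=2, expand=1,
                                        n_layers=1, dropout_p=0.0),
                            np.random.default_rng(0))
        u = Tensor(np.ones((k, 2)))
        delta = Tensor(np.full((k, 2), 1.0))
        b = Tensor(np.ones((k, 2, 1)))
        c = Tensor(np.ones((k, 2, 1)))
        block2.a_log.data[:] = -30.0  # A ~ -1e-13 => a_bar ~ 1
        y = block2.ssm_scan(u, delta, b, c)
        assert np.allclose(y.data, np.arange(1, k + 1)[:, None], atol=1e-6)

    def test_forgetting_limit_is_memoryless(self, block, cfg):
        rng = np.random.default_rng(4)
        k = 5
        block.a_log.data[:] = np.log(1e6)  # A = -1e6 -> a_bar ~ 0
        u = Tensor(rng.standard_normal((k, cfg.d_inner)))
        delta = Tensor(np.full((k, cfg.d_inner), 0.5))
        b = Tensor(rng.standard_normal((k, cfg.d_inner, cfg.d_state)))
        c = Tensor(rng.standard_normal((k, cfg.d_inner, cfg.d_state)))
        y = block.ssm_scan(u, delta, b, c).data
        # y_k should equal <C_k, b_bar_k u_k> with no history
        for kk in range(k):
            h = delta.data[kk][:, None] * b.data[kk] * u.data[kk][:, None]
            assert np.allclose(y[kk], (c.data[kk] * h).sum(-1), atol=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_naive_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        k, d_inner, d_state = rng.integers(2, 9), rng.integers(1, 5), rng.integers(1, 4)
        cfg = MambaConfig(d_model=2, d_state=int(d_state), d_conv=2,
                          expand=1, n_layers=1, dropout_p=0.0)
        cfg_block = MambaBlock(cfg, rng)
        # overwrite d_inner usage by building tensors directly
        u = rng.standard_normal((k, cfg.d_inner))
        delta = np.abs(rng.standard_normal((k, cfg.d_inner))) + 0.1
        b = rng.standard_normal((k, cfg.d_inner, cfg.d_state))
        c = rng.standard_normal((k, cfg.d_inner, cfg.d_state))
        a = -np.exp(cfg_block.a_log.data)
        y = cfg_block.ssm_scan(Tensor(u), Tensor(delta), Tensor(b), Tensor(c)).data
        # naive per-channel recurrence
        expect = np.zeros((k, cfg.d_inner))
        for d in range(cfg.d_inner):
            h = np.zeros(cfg.d_state)
            for kk in range(k):
                for n in range(cfg.d_state):
                    h[n] = np.exp(delta[kk, d] * a[d, n]) * h[n] + delta[kk, d] * b[kk, d, n] * u[kk, d]
                expect[kk, d] = c[kk, d] @ h
        assert np.allclose(y, expect, atol=1e-6)


class TestBlockIdentities:
    def _input(self, cfg, k=5, seed=5):
        return Tensor(np.random.default_rng(seed).standard_normal((k, cfg.d_model)))

    def test_zero_output_projection_is_identity(self, cfg, block):
        block.w_out.weight.data[:] = 0.0
        z = self._input(cfg)
        out, _ = block(z)
        assert np.allclose(out.data, z.data)

    def test_closed_gate_is_identity(self, cfg, block):
        block.w_g.weight.data[:] = 0.0  # G = SiLU(0) = 0
        z = self._input(cfg)
        out, _ = block(z)
        assert np.allclose(out.data, z.data)

    def test_causality_by_perturbation(self, cfg, block):
        z = self._input(cfg, k=6)
        base, _ = block(z)
        z2 = Tensor(z.data.copy())
        z2.data[4] += 10.0  # perturb window 4
        pert, _ = block(z2)
        assert np.allclose(pert.data[:4], base.data[:4], atol=1e-12)
        assert not np.allclose(pert.data[4:], base.data[4:])

    def test_trace_positive_and_recorded(self, cfg, block):
        out, trace = block(self._input(cfg))
        assert trace.delta.shape == (5, cfg.d_inner)
        assert np.all(trace.delta > 0)

    def test_dropout_only_in_train_mode(self, cfg):
        cfg2 = MambaConfig(**{**vars(cfg), "dropout_p": 0.5})
        block = MambaBlock(cfg2, np.random.default_rng(0))
        z = self._input(cfg2)
        a, _ = block(z)
        b, _ = block(z)
        assert np.allclose(a.data, b.data)  # eval mode deterministic
        c, _ = block(z, train_mode=True, rng=np.random.default_rng(0))
        d, _ = block(z, train_mode=True, rng=np.random.default_rng(1))
        assert not np.allclose(c.data, d.data)


class TestEncoder:
    def test_residual_reduction_to_mean_pooling(self, cfg):
        enc = MambaEncoder(cfg, np.random.default_rng(0))
        for blk in enc.blocks:
            blk.w_out.weight.data[:] = 0.0
        z = np.random.default_rng(1).standard_normal((7, cfg.d_model))
        ctx, traces = enc(z)
        assert np.allclose(ctx.data, z.mean(axis=0), atol=1e-7)
        assert len(traces) == cfg.n_layers

    def test_constant_rows_mean_is_row(self, cfg):
        enc = MambaEncoder(cfg, np.random.default_rng(0))
        for blk in enc.blocks:
            blk.w_out.weight.data[:] = 0.0
        row = np.array([1.0, -2.0, 0.5, 3.0])
        z = np.tile(row, (6, 1))
        ctx, _ = enc(z)
        assert np.allclose(ctx.data, row)

    def test_order_sensitivity_on_trend_input(self, cfg):
        enc = MambaEncoder(cfg, np.random.default_rng(2))
        k = 8
        rng = np.random.default_rng(3)
        trend = rng.standard_normal((k, cfg.d_model)) + np.linspace(-2, 2, k)[:, None]
        ctx_fwd, _ = enc(trend)
        ctx_rev, _ = enc(trend[::-1].copy())
        assert not np.allclose(ctx_fwd.data, ctx_rev.data)

    def test_width_check(self, cfg):
        enc = MambaEncoder(cfg, np.random.default_rng(0))
        with pytest.raises(ValueError, match="d_model"):
            enc(np.zeros((5, cfg.d_model + 1)))


class TestSelectivityScores:
    def test_constant_and_linearity(self):
        delta = np.full((4, 6), 2.5)
        s = selectivity_scores(SelectivityTrace(delta=delta, block_index=0))
        assert np.allclose(s, 2.5)
        delta2 = delta.copy()
        delta2[1] *= 2
        s2 = selectivity_scores(SelectivityTrace(delta=delta2, block_index=0))
        assert s2[1] == pytest.approx(2 * s[1])

    def test_mean_matches_hand_computation(self):
        rng = np.random.default_rng(0)
        delta = np.abs(rng.standard_normal((5, 3))) + 0.01
        s = selectivity_scores(SelectivityTrace(delta=delta, block_index=0))
        assert np.allclose(s, delta.mean(axis=1))

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            selectivity_scores(SelectivityTrace(delta=np.empty((0,)), block_index=0))
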
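import numpy as np
import pytest

import ssm6ma.autodiff as ad
from ssm6ma import (Model, ModelConfig, discretize_zoh, fuse_scales,
                    load_model, position_specific_conv, selective_scan)
from ssm6ma.training import _bce_from_logits


def naive_pos_conv(weights, d):
    """Direct nested-loop evaluation of the per-position convolution."""
    L, F, K, M = weights.shape
    pad = K // 2
    dp = np.zeros((L + 2 * pad, M))
    dp[pad:pad + L] = d
    out = np.zeros((L, F))
    for i in range(L):
        for p in range(F):
            out[i, p] = sum(weights[i, p, k, j] * dp[i + k, j]
                            for k in range(K) for j in range(M))
    return out


def naive_scan(g, abar, bbar, c):
    """Step-by-step recurrence: h_t = abar_t h_{t-1} + bbar_t g_t[f]."""
    L, F = g.shape
    S = abar.shape[1]
    z = np.zeros((L, F))
    for f in range(F):
        h = np.zeros(S)
        for t in range(L):
            h = abar[t] * h + bbar[t] * g[t, f]
            z[t, f] = c[t] @ h
    return z


class TestPositionSpecificConv:
    def test_worked_example_position_one(self):
        # L=2, M=1, K=3: position 1 filter [1,1,1] sees pad,1,2 -> 3
        d = np.array([[1.0], [2.0]])
        bank = np.zeros((2, 1, 3, 1))
        bank[0, 0, :, 0] = [1.0, 1.0, 1.0]
        out = position_specific_conv(d, bank)
        assert out[0, 0] == pytest.approx(3.0)

    def test_worked_example_tap_hits_padding(self):
        d = np.array([[1.0], [2.0]])
        bank = np.zeros((2, 1, 3, 1))
        bank[1, 0, :, 0] = [0.0, 0.0, 1.0]  # third tap beyond row 2 -> pad
        out = position_specific_conv(d, bank)
        assert out[1, 0] == pytest.approx(0.0)

    def test_zero_bank_gives_zero(self, rng):
        out = position_specific_conv(rng.standard_normal((5, 3)),
                                     np.zeros((5, 2, 3, 3)))
        assert (out == 0).all()

    def test_matches_nested_loop_oracle(self, rng):
        for _ in range(100):
            L = int(rng.integers(1, 10))
            M = int(rng.integers(1, 5))
            K = int(rng.choice([1, 3, 5, 7]))
            F = int(rng.integers(1, 5))
            w = rng.standard_normal((L, F, K, M))
            d = rng.standard_normal((L, M))
            assert np.allclose(position_specific_conv(d, w),
                               naive_pos_conv(w, d), atol=1e-6)

    def test_tied_filters_match_shared_cross_correlation(self, rng):
        # identical per-position slices == ordinary correlate with zero pad
        from scipy.ndimage import correlate1d
        for _ in range(100):
            L = int(rng.integers(3, 12))
            M = int(rng.integers(1, 4))
            K = int(rng.choice([3, 5]))
            shared = rng.standard_normal((1, 2, K, M))
            tied = np.repeat(shared, L, axis=0)
            d = rng.standard_normal((L, M))
            got = position_specific_conv(d, tied)
            want = np.zeros((L, 2))
            for p in range(2):
                for j in range(M):
                    want[:, p] += correlate1d(d[:, j], shared[0, p, :, j],
                                              mode="constant", cval=0.0)
            assert np.allclose(got, want, atol=1e-6)
            # the (1,...) shared form computes the same thing
            assert np.allclose(position_specific_conv(d, shared), got,
                               atol=1e-6)

    def test_locality(self, rng):
        # output row i depends only on rows i-K//2 .. i+K//2
        L, M, K, F = 9, 2, 3, 2
        w = rng.standard_normal((L, F, K, M))
        d = rng.standard_normal((L, M))
        base = position_specific_conv(d, w)
        d2 = d.copy()
        d2[7] += 1.0
        moved = position_specific_conv(d2, w)
        changed = np.nonzero(np.abs(moved - base).sum(axis=1) > 1e-12)[0]
        assert set(changed) <= {6, 7, 8}


class TestDiscretizeZoh:
    def test_zero_state_matrix(self):
        abar, bbar = discretize_zoh(np.zeros(3), 0.7, np.ones(3))
        assert np.allclose(abar, 1.0)
        assert np.allclose(bbar, 0.7)

    def test_closed_form_half_life(self):
        abar, _ = discretize_zoh(np.array([-1.0]), np.log(2.0),
                                 np.array([1.0]))
        assert abar[0] == pytest.approx(0.5)

    def test_continuity_limit(self):
        abar, bbar = discretize_zoh(np.array([-2.0]), 1e-9, np.array([3.0]))
        assert abar[0] == pytest.approx(1.0, abs=1e-8)
        assert abs(bbar[0]) < 1e-8

    def test_nonpositive_delta_rejected(self):
        with pytest.raises(ValueError):
            discretize_zoh(np.zeros(2), 0.0, np.zeros(2))

    def test_stability_for_negative_a(self, rng):
        a = -np.abs(rng.standard_normal(4))
        delta = np.abs(rng.standard_normal(6)) + 1e-3
        abar, _ = discretize_zoh(a, delta, np.ones(4))
        assert (np.abs(abar) <= 1.0).all()


class TestSelectiveScan:
    def test_memoryless_limit(self):
        # abar=0, bbar=1, c=2 with scalar state: z = 2*g
        g = np.array([[1.0], [3.0]])
        z = selective_scan(g, np.zeros((2, 1)), np.ones((2, 1)),
                           np.full((2, 1), 2.0))
        assert np.allclose(z[:, 0], [2.0, 6.0])

    def test_integrator_limit(self):
        g = np.ones((3, 1))
        z = selective_scan(g, np.ones((3, 1)), np.ones((3, 1)),
                           np.ones((3, 1)))
        assert np.allclose(z[:, 0], [1.0, 2.0, 3.0])

    def test_matches_naive_recurrence_oracle(self, rng):
        for _ in range(100):
            L = int(rng.integers(1, 12))
            S = int(rng.integers(1, 6))
            F = int(rng.integers(1, 5))
            g = rng.standard_normal((L, F))
            abar = rng.standard_normal((L, S))
            bbar = rng.standard_normal((L, S))
            c = rng.standard_normal((L, S))
            assert np.allclose(selective_scan(g, abar, bbar, c),
                               naive_scan(g, abar, bbar, c), atol=1e-5)

    def test_causality_perturbation(self, rng):
        L, S, F = 8, 4, 3
        g = rng.standard_normal((L, F))
        abar, bbar, c = (rng.standard_normal((L, S)) for _ in range(3))
        base = selective_scan(g, abar, bbar, c)
        for t in range(L):
            g2 = g.copy()
            g2[t] += 1.0
            diff = np.abs(selective_scan(g2, abar, bbar, c) - base)
            assert (diff[:t] == 0).all()
            assert diff[t:].sum() > 0


class TestFuseScales:
    def test_symmetry_returns_input(self, rng):
        z = rng.standard_normal((5, 4))
        q = rng.standard_normal(4)
        fused, weights = fuse_scales(z, z, z, q, q, q)
        assert np.allclose(fused, z)
        for w in weights:
            assert np.allclose(w, 1.0 / 3.0)

    def test_worked_example(self):
        # pre-softmax weights (ln2, 0, 0), values (4, 8, 8) -> 6
        z3 = np.array([[4.0]])
        z5 = np.array([[8.0]])
        z7 = np.array([[8.0]])
        q3 = np.array([np.log(2.0) / 4.0])
        q5 = np.array([0.0])
        q7 = np.array([0.0])
        fused, (w3, w5, w7) = fuse_scales(z3, z5, z7, q3, q5, q7)
        assert w3[0, 0] == pytest.approx(0.5)
        assert w5[0, 0] == pytest.approx(0.25)
        assert w7[0, 0] == pytest.approx(0.25)
        assert fused[0, 0] == pytest.approx(6.0)

    def test_weights_sum_to_one_and_convexity(self, rng):
        for _ in range(20):
            zs = [rng.standard_normal((6, 5)) for _ in range(3)]
            qs = [rng.standard_normal(5) for _ in range(3)]
            fused, ws = fuse_scales(*zs, *qs)
            assert np.allclose(sum(ws), 1.0, atol=1e-6)
            assert all(((w > 0) & (w < 1)).all() for w in ws)
            lo = np.minimum.reduce(zs)
            hi = np.maximum.reduce(zs)
            assert (fused >= lo - 1e-9).all() and (fused <= hi + 1e-9).all()


class TestModelForward:
    def test_embedding_lookup_identical_rows(self, tiny_model_config):
        m = Model(tiny_model_config, seed=0)
        out = ad.embedding(m.params["embedding"],
                           np.zeros((1, 5), dtype=int))
        assert np.allclose(out.data[0], out.data[0][0])

    def test_embedding_out_of_range(self, tiny_model_config):
        m = Model(tiny_model_config, seed=0)
        with pytest.raises(IndexError):
            ad.embedding(m.params["embedding"], np.array([[4]]))

    def test_zero_weight_layer_is_identity(self, tiny_model_config):
        m = Model(tiny_model_config, seed=0)
        for name, p in m.params.items():
            if name.startswith("branch"):
                p.data = np.zeros_like(p.data)
        x = ad.Tensor(np.random.default_rng(0).standard_normal((2, 41, 8)))
        out = m._branch(x, 3)
        assert np.allclose(out.data, x.data)

    def test_scores_in_unit_interval(self, tiny_model_config, rng):
        m = Model(tiny_model_config, seed=1)
        scores = m.predict(rng.integers(0, 4, (10, 41)))
        assert ((scores > 0) & (scores < 1)).all()

    def test_zero_head_gives_half(self, tiny_model_config, rng):
        m = Model(tiny_model_config, seed=1)
        for i in (1, 2, 3):
            m.params[f"head.W{i}"].data *= 0.0
            m.params[f"head.b{i}"].data *= 0.0
        scores = m.predict(rng.integers(0, 4, (4, 41)))
        assert np.allclose(scores, 0.5)

    def test_final_bias_monotonicity(self, tiny_model_config, rng):
        m = Model(tiny_model_config, seed=1)
        idx = rng.integers(0, 4, (3, 41))
        lo = m.predict(idx)
        m.params["head.b3"].data += 1.0
        hi = m.predict(idx)
        assert (hi > lo).all()

    def test_batch_equivariance_and_determinism(self, tiny_model_config, rng):
        m = Model(tiny_model_config, seed=2)
        idx = rng.integers(0, 4, (6, 41))
        s1 = m.predict(idx)
        s2 = m.predict(idx)
        assert (s1 == s2).all()  # bit-identical repeated inference
        rev = m.predict(idx[::-1])
        assert np.allclose(rev, s1[::-1])
        dup = m.predict(np.vstack([idx[:1], idx[:1]]))
        assert dup[0] == dup[1]

    def test_identical_sequences_identical_intermediates(
            self, tiny_model_config, rng):
        m = Model(tiny_model_config, seed=2)
        idx = np.repeat(rng.integers(0, 4, (1, 41)), 3, axis=0)
        with ad.no_grad():
            _, inter = m.forward(idx, return_intermediates=True)
        assert np.allclose(inter["Z"][0], inter["Z"][1])
        assert inter["penultimate"].shape == (3, 8)

    def test_shared_mode_conv_param_ratio(self):
        cfg_ps = ModelConfig(dtype="float32")
        cfg_sh = ModelConfig(conv_mode="shared", dtype="float32")
        n_ps = Model(cfg_ps, seed=0).conv_parameter_count()
        n_sh = Model(cfg_sh, seed=0).conv_parameter_count()
        assert n_ps == cfg_ps.L * n_sh

    def test_wrong_width_rejected(self, tiny_model_config, rng):
        m = Model(tiny_model_config, seed=0)
        with pytest.raises(ValueError):
            m.forward(rng.integers(0, 4, (2, 13)))


class TestGradients:
    def _fd_check(self, model, idx, y, n_per_param=4, tol=1e-3):
        logits = model.forward(idx)
        loss = _bce_from_logits(logits, y)
        loss.backward()
        grads = {n: (p.grad.copy() if p.grad is not None
                     else np.zeros_like(p.data))
                 for n, p in model.params.items()}

        def loss_value():
            with ad.no_grad():
                lg = model.forward(idx)
            return float(np.mean(np.logaddexp(0.0, lg.data)
                                 - y * lg.data))

        worst = 0.0
        for name, p in model.params.items():
            flat = p.data.ravel()
            sel = np.random.default_rng(abs(hash(name)) % 2**31).choice(
                flat.size, size=min(n_per_param, flat.size), replace=False)
            for i in sel:
                eps = 1e-6
                orig = flat[i]
                flat[i] = orig + eps
                lp = loss_value()
                flat[i] = orig - eps
                lm = loss_value()
                flat[i] = orig
                fd = (lp - lm) / (2 * eps)
                an = grads[name].ravel()[i]
                rel = abs(fd - an) / max(abs(fd), abs(an), 1e-4)
                worst = max(worst, rel)
        assert worst < tol

    def test_end_to_end_gradient_check(self, grad_check_config, rng):
        model = Model(grad_check_config, seed=3)
        idx = rng.integers(0, 4, (3, 7))
        y = rng.integers(0, 2, 3).astype(float)
        self._fd_check(model, idx, y)

    def test_shared_mode_gradient_check(self, grad_check_config, rng):
        from dataclasses import replace
        model = Model(replace(grad_check_config, conv_mode="shared"), seed=4)
        idx = rng.integers(0, 4, (2, 7))
        y = np.array([1.0, 0.0])
        self._fd_check(model, idx, y)


class TestCheckpoint:
    def test_save_load_bit_identical(self, tiny_model_config, tmp_path, rng):
        m = Model(tiny_model_config, seed=5)
        idx = rng.integers(0, 4, (4, 41))
        before = m.predict(idx)
        m.save(tmp_path / "ckpt")
        m2 = load_model(tmp_path / "ckpt")
        after = m2.predict(idx)
        assert (before == after).all()
        for n, p in m.params.items():
            assert (p.data == m2.params[n].data).all()

    def test_config_roundtrip(self, tiny_model_config, tmp_path):
        m = Model(tiny_model_config, seed=5)
        m.save(tmp_path / "ckpt")
        m2 = load_model(tmp_path / "ckpt")
        assert m2.config == tiny_model_config
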
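"""Unit and oracle tests for the sparse-response RBM."""

import numpy as np
import pytest
from scipy.special import expit

from sparsebelief import srrbm
from sparsebelief._utils import ValidationError
from sparsebelief.srrbm import (
    RBMParams,
    SRTrainConfig,
    cd1_update,
    cd_statistics,
    exact_model_statistics,
    hidden_probs,
    sample_bernoulli,
    sparsity_gradient,
    train_srrbm,
    visible_probs,
)

from conftest import enumerate_joint_statistics


class TestConditionals:
    def test_zero_params_give_half_everywhere(self):
        p = RBMParams(np.zeros((3, 2)), np.zeros(3), np.zeros(2))
        assert np.allclose(hidden_probs(p, np.random.default_rng(0).random((5, 3))), 0.5)
        assert np.allclose(visible_probs(p, np.random.default_rng(0).random((5, 2))), 0.5)

    def test_bias_only_case(self):
        p = RBMParams(np.zeros((3, 2)), np.array([1.0, -1.0, 0.0]), np.array([2.0, -0.5]))
        assert np.allclose(hidden_probs(p, np.zeros((4, 3))), expit(p.b_hid))
        assert np.allclose(visible_probs(p, np.zeros((4, 2))), expit(p.c_vis))

    def test_hand_computed_single_unit(self):
        # W couples (v0=+1, v1=-1) to one hidden unit; v=(1,0) -> sigmoid(1)
        p = RBMParams(np.array([[1.0], [-1.0]]), np.zeros(2), np.zeros(1))
        got = hidden_probs(p, np.array([[1.0, 0.0]]))
        assert got[0, 0] == pytest.approx(0.7310586, abs=1e-6)
        # transposed mirror through the visible conditional
        pm = RBMParams(np.array([[1.0, -1.0]]), np.zeros(1), np.zeros(2))
        got_v = visible_probs(pm, np.array([[1.0, 0.0]]))
        assert got_v[0, 0] == pytest.approx(0.7310586, abs=1e-6)

    def test_shape_mismatch_raises(self, tiny_rbm):
        with pytest.raises(ValidationError):
            hidden_probs(tiny_rbm, np.zeros((2, 5)))
        with pytest.raises(ValidationError):
            visible_probs(tiny_rbm, np.zeros((2, 5)))

    def test_conditionals_match_enumerated_joint(self, tiny_rbm):
        """p(h|v) from the weights equals the conditional of the exact joint."""
        oracle = enumerate_joint_statistics(tiny_rbm)
        # check conditional at v = (1,0,1,0) by direct Boltzmann restriction
        v = np.array([1.0, 0.0, 1.0, 0.0])
        nh = tiny_rbm.n_hidden
        weights = []
        hs = []
        for code in range(2 ** nh):
            h = np.array([(code >> j) & 1 for j in range(nh)], dtype=float)
            e = -(v @ tiny_rbm.W @ h + tiny_rbm.c_vis @ v + tiny_rbm.b_hid @ h)
            weights.append(np.exp(-e))
            hs.append(h)
        weights = np.array(weights) / np.sum(weights)
        cond = np.sum(weights[:, None] * np.array(hs), axis=0)
        assert np.allclose(hidden_probs(tiny_rbm, v[None])[0], cond, atol=1e-10)
        assert oracle["log_Z"] > 0  # sanity: partition function computed


class TestSampling:
    def test_degenerate_probabilities(self):
        rng = np.random.default_rng(0)
        assert not sample_bernoulli(np.zeros((3, 3)), rng).any()
        assert sample_bernoulli(np.ones((3, 3)), rng).all()

    def test_mean_concentrates(self):
        rng = np.random.default_rng(1)
        draws = sample_bernoulli(np.full((100_000, 1), 0.3), rng)
        assert abs(draws.mean() - 0.3) < 0.01

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            sample_bernoulli(np.array([[1.5]]), np.random.default_rng(0))


class TestCDStatistics:
    def test_deterministic_given_rng_state(self, tiny_rbm):
        V = np.random.default_rng(5).random((10, 4))
        a = cd_statistics(tiny_rbm, V, 3, np.random.default_rng(99))
        b = cd_statistics(tiny_rbm, V, 3, np.random.default_rng(99))
        for key in a:
            assert np.array_equal(a[key], b[key])

    def test_single_unit_hand_chain(self):
        # v=1 clamped, all params zero, k=1: h ~ Bern(0.5), v' prob = 0.5
        p = RBMParams(np.zeros((1, 1)), np.zeros(1), np.zeros(1))
        stats = cd_statistics(p, np.array([[1.0]]), 1, np.random.default_rng(0))
        assert stats["pos_vh"][0, 0] == pytest.approx(0.5)
        assert stats["neg_v"][0] == pytest.approx(0.5)

    def test_k_below_one_rejected(self, tiny_rbm):
        with pytest.raises(ValidationError):
            cd_statistics(tiny_rbm, np.zeros((1, 4)), 0, np.random.default_rng(0))

    @pytest.mark.parametrize("k,tol", [(5, 0.05), (50, 0.02)])
    def test_negative_phase_approaches_equilibrium(self, tiny_rbm, k, tol):
        """Gibbs-chain statistics converge to exhaustive-enumeration values."""
        exact = exact_model_statistics(tiny_rbm)
        V0 = np.random.default_rng(3).random((20_000, 4))
        stats = cd_statistics(tiny_rbm, V0, k, np.random.default_rng(17))
        assert np.abs(stats["neg_vh"] - exact["vh"]).max() < tol
        assert np.abs(stats["neg_v"] - exact["v"]).max() < tol
        assert np.abs(stats["neg_h"] - exact["h"]).max() < tol


class TestCDUpdate:
    def test_zero_learning_rate_is_identity(self, tiny_rbm):
        cfg = SRTrainConfig(epsilon=1e-300)  # epsilon must be > 0; effectively zero
        batch = np.random.default_rng(0).random((6, 4))
        out = cd1_update(tiny_rbm, batch, cfg, np.random.default_rng(0))
        assert np.allclose(out.W, tiny_rbm.W, atol=1e-12)

    def test_equal_phases_are_a_fixed_point(self, tiny_rbm):
        stats = {k: np.full((4, 3), 0.2) for k in ("pos_vh", "neg_vh")}
        stats |= {"pos_v": np.full(4, 0.4), "neg_v": np.full(4, 0.4),
                  "pos_h": np.full(3, 0.3), "neg_h": np.full(3, 0.3)}
        out = cd1_update(tiny_rbm, np.zeros((1, 4)), SRTrainConfig(epsilon=0.7),
                         np.random.default_rng(0), stats=stats)
        assert np.array_equal(out.W, tiny_rbm.W)
        assert np.array_equal(out.c_vis, tiny_rbm.c_vis)
        assert np.array_equal(out.b_hid, tiny_rbm.b_hid)

    def test_update_rules_scalar_recomputation(self, tiny_rbm):
        """Each rule recomputed independently from injected statistics."""
        rng = np.random.default_rng(8)
        stats = {
            "pos_vh": rng.random((4, 3)), "neg_vh": rng.random((4, 3)),
            "pos_v": rng.random(4), "neg_v": rng.random(4),
            "pos_h": rng.random(3), "neg_h": rng.random(3),
        }
        eps = 0.37
        out = cd1_update(tiny_rbm, np.zeros((1, 4)), SRTrainConfig(epsilon=eps),
                         np.random.default_rng(0), stats=stats)
        for i in range(4):
            for j in range(3):
                assert out.W[i, j] == pytest.approx(
                    tiny_rbm.W[i, j] + eps * (stats["pos_vh"][i, j] - stats["neg_vh"][i, j])
                )
        for i in range(4):
            assert out.c_vis[i] == pytest.approx(
                tiny_rbm.c_vis[i] + eps * (stats["pos_v"][i] - stats["neg_v"][i])
            )
        for j in range(3):
            assert out.b_hid[j] == pytest.approx(
                tiny_rbm.b_hid[j] + eps * (stats["pos_h"][j] - stats["neg_h"][j])
            )


def _penalty(params, batch):
    """Independent L1 activation penalty Σ_l ||p(h|v_l)||_1."""
    return float(expit(batch @ params.W + params.b_hid).sum())


class TestSparsityGradient:
    def test_saturated_units_have_zero_gradient(self):
        p = RBMParams(np.full((2, 2), 50.0), np.zeros(2), np.array([50.0, -50.0]))
        gW, gb = sparsity_gradient(p, np.ones((3, 2)))
        assert np.abs(gW).max() < 1e-10
        assert np.abs(gb).max() < 1e-10

    def test_zero_params_give_quarter_per_sample(self):
        m = 7
        p = RBMParams(np.zeros((3, 2)), np.zeros(3), np.zeros(2))
        gW, gb = sparsity_gradient(p, np.ones((m, 3)))
        assert np.allclose(gW, -0.25 * m)
        assert np.allclose(gb, -0.25 * m)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        nv, nh, m = 5, 4, 6
        p = RBMParams(rng.normal(0, 0.8, (nv, nh)), rng.normal(size=nv), rng.normal(size=nh))
        batch = rng.random((m, nv))
        gW, gb = sparsity_gradient(p, batch)
        step = 1e-5
        # finite differences on a few W entries
        for (i, j) in [(0, 0), (2, 3), (4, 1)]:
            Wp, Wm = p.W.copy(), p.W.copy()
            Wp[i, j] += step
            Wm[i, j] -= step
            fd = (_penalty(RBMParams(Wp, p.c_vis, p.b_hid), batch)
                  - _penalty(RBMParams(Wm, p.c_vis, p.b_hid), batch)) / (2 * step)
            assert -fd == pytest.approx(gW[i, j], rel=1e-6)
        for j in range(nh):
            bp, bm = p.b_hid.copy(), p.b_hid.copy()
            bp[j] += step
            bm[j] -= step
            fd = (_penalty(RBMParams(p.W, p.c_vis, bp), batch)
                  - _penalty(RBMParams(p.W, p.c_vis, bm), batch)) / (2 * step)
            assert -fd == pytest.approx(gb[j], rel=1e-6)


def _toy_training_data(seed=0, n=64, d=20):
    rng = np.random.default_rng(seed)
    protos = rng.random((2, d))
    X = protos[np.arange(n) % 2] + rng.normal(0, 0.05, (n, d))
    return np.clip(X, 0, 1)


class TestTraining:
    def test_full_training_is_seed_reproducible(self):
        cfg = SRTrainConfig(epochs=5, seed=42)
        X = _toy_training_data()
        a = train_srrbm(X, cfg, n_hidden=8)
        b = train_srrbm(X, cfg, n_hidden=8)
        assert np.array_equal(a.params.W, b.params.W)
        assert a.reconstruction_error == b.reconstruction_error

    def test_lambda_zero_equals_plain_cd(self):
        """λ=0 must reproduce a hand-rolled plain CD-1 loop bit-for-bit."""
        from sparsebelief.srrbm import init_params
        from sparsebelief._utils import substream

        X = _toy_training_data()
        cfg = SRTrainConfig(epochs=3, lam=0.0, seed=7, batch_size=16)
        got = train_srrbm(X, cfg, n_hidden=6)

        rng = substream(7, "srrbm")
        params = init_params(X.shape[1], 6, cfg.weight_init_sd, rng)
        for _ in range(cfg.epochs):
            order = rng.permutation(X.shape[0])
            for start in range(0, X.shape[0], cfg.batch_size):
                batch = X[order[start:start + cfg.batch_size]]
                params = cd1_update(params, batch, cfg, rng)
        assert np.array_equal(got.params.W, params.W)
        assert np.array_equal(got.params.b_hid, params.b_hid)

    def test_sparsity_lowers_hidden_activation(self):
        X = _toy_training_data(seed=3)
        base = train_srrbm(X, SRTrainConfig(epochs=20, lam=0.0, seed=9), n_hidden=10)
        sparse = train_srrbm(X, SRTrainConfig(epochs=20, lam=0.5, seed=9), n_hidden=10)
        assert sparse.mean_hidden_activation[-1] < base.mean_hidden_activation[-1]

    def test_lambda_monotone_activation(self):
        X = _toy_training_data(seed=4)
        acts = [
            train_srrbm(X, SRTrainConfig(epochs=15, lam=lam, seed=2), n_hidden=10)
            .mean_hidden_activation[-1]
            for lam in (0.0, 0.1, 0.5)
        ]
        assert acts[0] >= acts[1] >= acts[2]

    def test_reconstruction_error_decreases_on_prototypes(self):
        rng = np.random.default_rng(0)
        protos = (rng.random((2, 8)) > 0.5).astype(float)
        X = protos[np.arange(60) % 2]
        trace = train_srrbm(X, SRTrainConfig(epochs=200, lam=0.0, epsilon=0.1, seed=1),
                            n_hidden=4)
        assert trace.reconstruction_error[-1] < trace.reconstruction_error[0]

    def test_out_of_range_data_rejected(self):
        with pytest.raises(ValidationError):
            train_srrbm(np.array([[1.5, 0.2]]), SRTrainConfig(epochs=1), n_hidden=2)


class TestExactStatistics:
    def test_uniform_at_zero_params(self):
        p = RBMParams(np.zeros((1, 1)), np.zeros(1), np.zeros(1))
        stats = exact_model_statistics(p)
        assert stats["vh"][0, 0] == pytest.approx(0.25)
        assert stats["v"][0] == pytest.approx(0.5)
        assert stats["h"][0] == pytest.approx(0.5)

    def test_log_partition_at_zero_params(self):
        p = RBMParams(np.zeros((3, 2)), np.zeros(3), np.zeros(2))
        assert exact_model_statistics(p)["log_Z"] == pytest.approx(5 * np.log(2))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_independent_joint_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        p = RBMParams(rng.normal(0, 1, (3, 2)), rng.normal(size=3), rng.normal(size=2))
        ours = exact_model_statistics(p)
        oracle = enumerate_joint_statistics(p)
        for key in ("vh", "v", "h"):
            assert np.allclose(ours[key], oracle[key], atol=1e-12)
        assert ours["log_Z"] == pytest.approx(oracle["log_Z"], abs=1e-10)

    def test_size_limit(self):
        p = RBMParams(np.zeros((15, 15)), np.zeros(15), np.zeros(15))
        with pytest.raises(ValidationError):
            exact_model_statistics(p)
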
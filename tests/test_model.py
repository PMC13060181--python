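"""Core model: gradients, optimizers, the online protocol, and its
reductions and invariants."""

import numpy as np
import pytest

from neuragem import nn
from neuragem.baselines import make_rnn_baseline
from neuragem.model import (
    NeuraGemModel,
    TrainConfig,
    ZPopulation,
    evaluate_frozen,
    infer_z_frozen,
    prediction_error,
    run_training,
)
from neuragem.tasks import ConfigurationError, generate_cst


def _fd_check(mode, z_transform, seed=1):
    rng = np.random.default_rng(seed)
    net = nn.init_params(2, 2, 4, mode, seed=seed, hidden=8)
    X = rng.normal(size=(2, 5, 2))
    Z = rng.normal(size=4) * 0.5
    Tgt = rng.normal(size=(2, 5, 2))
    slices = [slice(0, 2), slice(2, 4)]

    def loss(net, Z):
        Y, _ = nn.forward_window(net, X, Z, mode, z_transform, slices)
        return 0.5 * ((Y - Tgt) ** 2).sum() / X.shape[1]

    Y, cache = nn.forward_window(net, X, Z, mode, z_transform, slices)
    grads, dZ = nn.backward_window(net, cache, (Y - Tgt) / X.shape[1], mode, z_transform, slices)
    eps = 1e-6
    fd = np.zeros(4)
    for i in range(4):
        Zp, Zm = Z.copy(), Z.copy()
        Zp[i] += eps
        Zm[i] -= eps
        fd[i] = (loss(net, Zp) - loss(net, Zm)) / (2 * eps)
    rel_z = np.abs(fd - dZ).max() / (np.abs(fd).max() + 1e-12)
    rel_w = 0.0
    for k in ("Wx", "Wh", "We1", "We2", "Wo1", "Wo2", "b"):
        P = net.params[k]
        idx = tuple(rng.integers(0, s) for s in P.shape)
        orig = P[idx]
        P[idx] = orig + eps
        lp = loss(net, Z)
        P[idx] = orig - eps
        lm = loss(net, Z)
        P[idx] = orig
        fdw = (lp - lm) / (2 * eps)
        rel_w = max(rel_w, abs(fdw - grads[k][idx]) / (abs(fdw) + 1e-12))
    return rel_z, rel_w


class TestGradients:
    @pytest.mark.parametrize("mode", ["multiplicative", "additive", "none"])
    @pytest.mark.parametrize("z_transform", ["softmax", "affine"])
    def test_bptt_matches_finite_differences(self, mode, z_transform):
        for seed in range(3):
            rel_z, rel_w = _fd_check(mode, z_transform, seed=seed + 1)
            assert rel_w < 1e-4
            if mode != "none":
                assert rel_z < 1e-4

    def test_prediction_sensitivity_to_z(self, trained_ng, cst_stream):
        # analytic dL/dZ vs central differences through the full model
        model, _ = trained_ng
        obs = cst_stream.observations
        X = obs[100:105][None]
        Tgt = obs[101:106][None]
        Y, cache = nn.forward_window(
            model.net, X, model.fast.Z, model.mode, model.z_transform, model.fast.slices
        )
        _, dZ = nn.backward_window(
            model.net, cache, (Y - Tgt) / 5, model.mode, model.z_transform, model.fast.slices
        )
        eps = 1e-6
        for i in range(2):
            Zp, Zm = model.fast.Z.copy(), model.fast.Z.copy()
            Zp[i] += eps
            Zm[i] -= eps
            lp = 0.5 * ((nn.forward_window(model.net, X, Zp, model.mode, model.z_transform,
                                           model.fast.slices)[0] - Tgt) ** 2).sum() / 5
            lm = 0.5 * ((nn.forward_window(model.net, X, Zm, model.mode, model.z_transform,
                                           model.fast.slices)[0] - Tgt) ** 2).sum() / 5
            fd = (lp - lm) / (2 * eps)
            assert abs(fd - dZ[i]) < 1e-4 * max(abs(fd), 1e-6) + 1e-9


class TestForward:
    def test_affine_gate_neutral_at_zero(self):
        """With the affine transform, Z=0 gives an all-ones gate: identical to
        the ungated forward pass."""
        net = nn.init_params(1, 1, 2, "multiplicative", seed=0)
        X = np.random.default_rng(0).normal(size=(1, 4, 1))
        Y_gated, _ = nn.forward_window(net, X, np.zeros(2), "multiplicative", "affine")
        Y_plain, _ = nn.forward_window(net, X, np.zeros(2), "none", "affine")
        np.testing.assert_array_equal(Y_gated, Y_plain)

    def test_zeroed_output_map_gives_bias(self):
        model = NeuraGemModel(d_in=1, z_dim=2, seed=0)
        model.net.params["Wo2"][:] = 0.0
        model.net.params["bo2"][:] = 0.37
        out = model.forward_predict(np.array([[0.5], [0.1], [0.9]]))
        assert out[0] == pytest.approx(0.37)

    def test_dimension_mismatch_raises(self):
        model = NeuraGemModel(d_in=1, z_dim=2, seed=0)
        with pytest.raises(ConfigurationError):
            model.forward_predict(np.zeros((3, 2)))
        with pytest.raises(ConfigurationError):
            model.forward_predict(np.zeros((3, 1)), Z=np.zeros(5))


class TestPredictionError:
    def test_examples(self):
        assert prediction_error([0.2], [0.2]) == 0.0
        assert prediction_error([0.2], [0.8]) == pytest.approx(0.18)

    def test_gradient_is_residual(self):
        p, t = np.array([0.3, 0.9]), np.array([0.1, 0.4])
        eps = 1e-7
        for i in range(2):
            pp = p.copy()
            pp[i] += eps
            g = (prediction_error(pp, t) - prediction_error(p, t)) / eps
            assert g == pytest.approx(p[i] - t[i], abs=1e-6)


class TestOptimizers:
    def test_zero_gradient_leaves_w_unchanged(self):
        model = NeuraGemModel(d_in=1, z_dim=2, seed=0)
        before = {k: v.copy() for k, v in model.net.params.items()}
        model.w_opt.step(model.net.params, {k: np.zeros_like(v) for k, v in before.items()})
        for k in before:
            np.testing.assert_array_equal(model.net.params[k], before[k])

    def test_sgd_matches_closed_form(self):
        opt = nn.SGD({"w": (1,)}, lr=0.1)
        p = {"w": np.array([2.0])}
        opt.step(p, {"w": np.array([0.5])})
        assert p["w"][0] == pytest.approx(2.0 - 0.1 * 0.5)

    def test_gate_matrix_immutable_across_updates(self, trained_ng, cst_stream):
        model, _ = trained_ng
        fresh = NeuraGemModel(d_in=1, z_dim=2, config=TrainConfig(h=5, seed=0), seed=0)
        np.testing.assert_array_equal(model.net.gate_matrix, fresh.net.gate_matrix)

    def test_additive_z_projection_is_learnable(self, cst_stream):
        model = NeuraGemModel(d_in=1, z_dim=2, gating_mode="additive",
                              config=TrainConfig(h=5, seed=0), seed=0)
        before = model.net.params["Wx"][nn.HIDDEN:, :].copy()
        for t in range(50):
            model.online_step(cst_stream.observations, t)
        after = model.net.params["Wx"][nn.HIDDEN:, :]
        assert not np.array_equal(before, after)


class TestFastState:
    def test_pure_decay_contracts_z_sgd(self):
        from neuragem.model import FastState

        fs = FastState([ZPopulation(2, 0.5, 0.1)], optimizer="sgd")
        fs.Z = np.array([1.0, -2.0])
        norms = []
        for _ in range(10):
            fs.update(np.zeros(2))
            norms.append(np.linalg.norm(fs.Z))
        assert all(np.diff([np.linalg.norm([1.0, -2.0])] + norms) < 0)

    def test_zero_rates_keep_z_constant(self):
        from neuragem.model import FastState

        fs = FastState([ZPopulation(2, 1e-12, 0.0)], optimizer="sgd")
        fs.Z = np.array([0.5, -0.5])
        fs.update(np.array([1.0, 1.0]))
        np.testing.assert_allclose(fs.Z, [0.5, -0.5], atol=1e-10)

    def test_scalar_quadratic_sgd_matches_recursion(self):
        # loss 0.5*(z-a)^2 under SGD with decay: z' = (1-d)*(z - lr*(z-a))
        from neuragem.model import FastState

        lr, d, a = 0.2, 0.05, 1.5
        fs = FastState([ZPopulation(1, lr, d)], optimizer="sgd")
        z_ref = 0.0
        for _ in range(20):
            fs.update(np.array([fs.Z[0] - a]))
            z_ref = (1 - d) * (z_ref - lr * (z_ref - a))
            assert fs.Z[0] == pytest.approx(z_ref)

    def test_adam_decay_pulls_large_z_toward_zero(self):
        from neuragem.model import FastState

        fs = FastState([ZPopulation(2, 0.5, 1e-2)], optimizer="adam")
        fs.Z = np.array([8.0, -8.0])
        n0 = np.linalg.norm(fs.Z)
        for _ in range(10):
            fs.update(np.zeros(2))
        assert np.linalg.norm(fs.Z) < n0


class TestOnlineProtocol:
    def test_h1_uses_single_observation(self, cst_stream):
        model = NeuraGemModel(d_in=1, z_dim=2, config=TrainConfig(h=1, seed=0), seed=0)
        log = model.online_step(cst_stream.observations, 10, train_w=False, z_enabled=False)
        direct = model.forward_predict(cst_stream.observations[10:11])
        np.testing.assert_allclose(log.prediction, direct)

    def test_pure_inference_depends_only_on_window(self, trained_rnn_short):
        model, _ = trained_rnn_short
        obs_a = np.concatenate([np.full((50, 1), 0.9), np.full((10, 1), 0.3)])
        obs_b = np.concatenate([np.full((50, 1), -0.4), np.full((10, 1), 0.3)])
        la = model.copy().online_step(obs_a, 58, train_w=False, z_enabled=False)
        lb = model.copy().online_step(obs_b, 58, train_w=False, z_enabled=False)
        np.testing.assert_array_equal(la.prediction, lb.prediction)

    def test_training_reduces_error_from_initial_transient(self):
        """Online learning brings the error from the untrained transient down
        to the task plateau."""
        early, late = [], []
        for seed in range(5):
            stream = generate_cst(seed=seed)
            model = NeuraGemModel(d_in=1, z_dim=2, config=TrainConfig(h=5, seed=seed), seed=seed)
            traj = run_training(model, stream)
            early.append(traj.squared_errors[:30].mean())
            late.append(traj.squared_errors[-150:].mean())
        assert np.mean(early) > np.mean(late)

    def test_gradient_balance_shifts_toward_z(self):
        """Adaptation shifts from the slow to the fast substrate: the Z/W
        gradient-norm ratio rises over training."""
        ratios = []
        for seed in range(4):
            stream = generate_cst(seed=seed)
            model = NeuraGemModel(d_in=1, z_dim=2, config=TrainConfig(h=5, seed=seed), seed=seed)
            traj = run_training(model, stream)
            r_early = traj.grad_norm_z[:150].mean() / traj.grad_norm_w[:150].mean()
            r_late = traj.grad_norm_z[-150:].mean() / traj.grad_norm_w[-150:].mean()
            ratios.append((r_early, r_late))
        ratios = np.array(ratios)
        assert np.all(ratios[:, 1] > ratios[:, 0])

    def test_timescale_separation(self, trained_ng, cst_stream):
        """Per-step relative change of Z exceeds that of W during training."""
        stream = generate_cst(seed=11)
        model = NeuraGemModel(d_in=1, z_dim=2, config=TrainConfig(h=5, seed=11), seed=11)
        w_before = np.concatenate([v.ravel() for v in model.net.params.values()])
        z_rel, w_rel = [], []
        z_prev = model.fast.Z.copy()
        for t in range(200):
            model.online_step(stream.observations, t)
            w_now = np.concatenate([v.ravel() for v in model.net.params.values()])
            z_now = model.fast.Z
            w_rel.append(np.abs(w_now - w_before).mean() / (np.abs(w_now).mean() + 1e-12))
            z_rel.append(np.abs(z_now - z_prev).mean() / (np.abs(z_now).mean() + 1e-9))
            w_before, z_prev = w_now, z_now.copy()
        assert np.mean(z_rel) > np.mean(w_rel)

    def test_stream_too_short_raises(self):
        short = generate_cst(seed=0)
        short.block_ids = short.block_ids[:100]
        short.observations = short.observations[:100]
        model = NeuraGemModel(d_in=1, z_dim=2, config=TrainConfig(h=5, n_blocks=40), seed=0)
        with pytest.raises(ConfigurationError):
            run_training(model, short)

    def test_seed_determinism_bit_for_bit(self, cst_stream):
        t1 = run_training(NeuraGemModel(d_in=1, z_dim=2, config=TrainConfig(h=5, seed=0), seed=0),
                          cst_stream)
        t2 = run_training(NeuraGemModel(d_in=1, z_dim=2, config=TrainConfig(h=5, seed=0), seed=0),
                          cst_stream)
        np.testing.assert_array_equal(t1.predictions, t2.predictions)
        np.testing.assert_array_equal(t1.z, t2.z)

    def test_substrate_disabled_equals_rnn_short_bit_for_bit(self, cst_stream):
        ng = NeuraGemModel(d_in=1, z_dim=2,
                           config=TrainConfig(h=5, z_enabled=False, seed=0), seed=0)
        rnn = make_rnn_baseline("short", seed=0)
        t1 = run_training(ng, cst_stream)
        t2 = run_training(rnn, cst_stream)
        np.testing.assert_array_equal(t1.predictions, t2.predictions)


class TestFrozenInference:
    def test_empty_stream_gives_empty_trajectory(self, trained_ng):
        model, _ = trained_ng
        traj = infer_z_frozen(model.copy(), np.zeros((1, 1)))
        assert len(traj.errors) == 0

    def test_constant_stream_activity_converges(self, trained_ng):
        # constant input at a trained mean: the competition settles on that
        # context and the population activity stops moving
        model, _ = trained_ng
        traj = infer_z_frozen(model.copy(), np.full((120, 1), 0.2))
        act = np.stack([nn.z_activity(z, "softmax", model.fast.slices) for z in traj.z])
        steps = np.abs(np.diff(act, axis=0)).sum(axis=1)
        assert steps[-20:].mean() < 0.05

    def test_z_separates_contexts_above_chance(self, trained_ng):
        from sklearn.linear_model import LogisticRegression

        model, _ = trained_ng
        test = generate_cst(seed=1000)
        traj = infer_z_frozen(model.copy(), test.observations)
        labels = test.latent_labels[1:, 0]
        acc = LogisticRegression().fit(traj.z, labels).score(traj.z, labels)
        assert acc > 0.65

    def test_batched_frozen_eval_matches_sequential(self, trained_rnn_short):
        model, _ = trained_rnn_short
        obs = generate_cst(seed=55).observations[:80]
        fast = evaluate_frozen(model, obs)
        slow = model.copy().run(obs, train_w=False, z_enabled=False)
        np.testing.assert_allclose(fast.predictions, slow.predictions, atol=1e-10)


def test_checkpoint_round_trip(tmp_path, trained_ng):
    model, _ = trained_ng
    p = tmp_path / "ckpt.npz"
    model.save(p)
    loaded = NeuraGemModel.load(p)
    window = np.array([[0.3], [0.6], [0.2]])
    np.testing.assert_allclose(model.forward_predict(window), loaded.forward_predict(window))
    assert loaded.w_frozen == model.w_frozen
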
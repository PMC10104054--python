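"""GRU cell, initializers, and the hand-rolled TD training loop."""

import numpy as np
import pytest

from beliefrnn.rnn import (
    TrainConfig,
    ValueRnn,
    _td_loss_and_grads,
    gru_step,
    load_model,
    save_model,
    train_td,
)
from beliefrnn.tasks import StarkweatherConfig, generate_session


def naive_gru_step(params, o, z_prev):
    """Independent scalar-loop GRU implementation (oracle)."""
    H = params["Wh"].shape[0]
    D = params["Wx"].shape[0]

    def gate(W, b, vec, sl):
        out = np.zeros(H)
        for i in range(H):
            acc = b[sl.start + i]
            for j in range(len(vec)):
                acc += W[j, sl.start + i] * vec[j]
            out[i] = acc
        return out

    r_pre = gate(params["Wx"], params["bx"], o, slice(0, H)) + gate(
        params["Wh"], params["bh"], z_prev, slice(0, H)
    )
    u_pre = gate(params["Wx"], params["bx"], o, slice(H, 2 * H)) + gate(
        params["Wh"], params["bh"], z_prev, slice(H, 2 * H)
    )
    r = 1 / (1 + np.exp(-r_pre))
    u = 1 / (1 + np.exp(-u_pre))
    n_pre = gate(params["Wx"], params["bx"], o, slice(2 * H, 3 * H)) + r * gate(
        params["Wh"], params["bh"], z_prev, slice(2 * H, 3 * H)
    )
    n = np.tanh(n_pre)
    return (1 - u) * n + u * z_prev


class TestGruStep:
    def test_zero_parameters_halve_previous_state(self, rng):
        model = ValueRnn.init_default(6, 0)
        zeros = {k: np.zeros_like(v) for k, v in model.params.items()}
        z = rng.normal(size=6)
        out = gru_step(zeros, np.array([1.0, 0.0]), z)
        assert np.allclose(out, 0.5 * z)

    def test_saturated_update_gate_is_perfect_memory(self, rng):
        model = ValueRnn.init_default(6, 1)
        p = {k: v.copy() for k, v in model.params.items()}
        p["bx"][6:12] = 50.0  # update gate saturates at 1
        z = rng.normal(size=6)
        out = gru_step(p, rng.normal(size=2), z)
        assert np.allclose(out, z, atol=1e-12)

    def test_matches_naive_reference_implementation(self, rng):
        model = ValueRnn.init_default(9, 7)
        for _ in range(5):
            o = rng.normal(size=2)
            z = rng.normal(size=9)
            fast = gru_step(model.params, o, z)
            slow = naive_gru_step(model.params, o, z)
            assert np.abs(fast - slow).max() < 1e-6

    def test_shape_mismatch_raises(self, rng):
        model = ValueRnn.init_default(4, 0)
        with pytest.raises(ValueError):
            gru_step(model.params, np.zeros(3), np.zeros(4))


class TestInitializers:
    def test_default_init_bound(self):
        model = ValueRnn.init_default(50, 0)
        a = 1 / np.sqrt(50)
        assert a == pytest.approx(0.1414, abs=1e-3)
        for k, v in model.params.items():
            assert np.abs(v).max() <= a

    def test_same_seed_is_deterministic(self):
        m1 = ValueRnn.init_default(12, 5)
        m2 = ValueRnn.init_default(12, 5)
        assert all(np.array_equal(m1.params[k], m2.params[k]) for k in m1.params)

    def test_untrained_response_is_decaying_transient(self):
        model = ValueRnn.init_default(50, 3)
        z = np.zeros(50)
        for _ in range(200):
            z = model.step([0.0, 0.0], z)
        base = z.copy()
        z = model.step([1.0, 0.0], z)
        d0 = np.linalg.norm(z - base)
        for _ in range(30):
            z = model.step([0.0, 0.0], z)
        assert d0 > 1e-3
        assert np.linalg.norm(z - base) < 0.05 * d0

    def test_esn_recurrence_is_gain_scaled_orthogonal(self):
        model = ValueRnn.init_esn(8, 1.9, 0)
        W = model.params["Wh"].T  # (3H, H): one block per gate
        for g in range(3):
            Q = W[g * 8:(g + 1) * 8]
            assert np.allclose(Q.T @ Q, 1.9**2 * np.eye(8), atol=1e-10)
        assert np.allclose(model.params["bx"], 0)
        assert np.allclose(model.params["bh"], 0)
        assert not model.core_trainable

    def test_esn_transient_duration_grows_with_gain(self):
        def transient_len(gain):
            model = ValueRnn.init_esn(50, gain, 0)
            z = np.zeros(50)
            z = model.step([1.0, 0.0], z)
            for t in range(1, 500):
                z = model.step([0.0, 0.0], z)
                if (z**2).sum() < 1e-6:
                    return t
            return 500

        assert transient_len(0.1) < transient_len(1.5) <= transient_len(1.9)


class TestTraining:
    def test_semi_gradient_matches_finite_differences(self, rng):
        """The full-gradient option is checked against numerical derivatives
        of the loss; the semi-gradient path shares all machinery except the
        bootstrap term."""
        model = ValueRnn.init_default(4, 0)
        X = rng.normal(size=(10, 2, 2))
        R = rng.normal(size=(10, 2))
        mask = np.ones((10, 2))
        mask[-1] = 0
        loss, g = _td_loss_and_grads(model.params, X, R, mask, 0.9, True)
        for k, p in model.params.items():
            flat = p.reshape(-1)
            for idx in range(0, flat.size, max(1, flat.size // 5)):
                orig = flat[idx]
                flat[idx] = orig + 1e-6
                lp, _ = _td_loss_and_grads(model.params, X, R, mask, 0.9, True)
                flat[idx] = orig - 1e-6
                lm, _ = _td_loss_and_grads(model.params, X, R, mask, 0.9, True)
                flat[idx] = orig
                numeric = (lp - lm) / 2e-6
                assert g[k].reshape(-1)[idx] == pytest.approx(numeric, abs=1e-6)

    def test_semi_gradient_drops_bootstrap_term(self, rng):
        model = ValueRnn.init_default(4, 1)
        X = rng.normal(size=(8, 2, 2))
        R = rng.normal(size=(8, 2))
        mask = np.ones((8, 2))
        mask[-1] = 0
        _, g_semi = _td_loss_and_grads(model.params, X, R, mask, 0.9, False)
        _, g_full = _td_loss_and_grads(model.params, X, R, mask, 0.9, True)
        assert any(
            not np.allclose(g_semi[k], g_full[k]) for k in g_semi
        )

    def test_zero_learning_rate_changes_nothing(self):
        session = generate_session(StarkweatherConfig(variant=1), 250, 5)
        model = ValueRnn.init_default(8, 1)
        result = train_td(model, session, TrainConfig(max_epochs=2, lr=0.0, seed=0))
        assert all(
            np.array_equal(result.model.params[k], model.params[k])
            for k in model.params
        )
        assert len(set(np.round(result.losses, 12))) == 1

    def test_loss_decreases_on_small_task(self):
        session = generate_session(StarkweatherConfig(variant=1), 400, 2)
        model = ValueRnn.init_default(10, 3)
        result = train_td(
            model, session,
            TrainConfig(episode_len_trials=5, batch_size=8, max_epochs=25,
                        patience=8, seed=0),
        )
        assert min(result.losses) < 0.8 * result.losses[0]
        assert np.isfinite(result.losses).all()
        assert result.best_epoch == int(np.argmin(result.losses))

    def test_esn_core_is_bitwise_frozen(self):
        session = generate_session(StarkweatherConfig(variant=2), 300, 4)
        model = ValueRnn.init_esn(10, 1.0, 2)
        result = train_td(model, session, TrainConfig(max_epochs=3, seed=0))
        for k in ("Wx", "Wh", "bx", "bh"):
            assert np.array_equal(result.model.params[k], model.params[k])
        assert not np.allclose(result.model.params["w"], model.params["w"])

    def test_forward_is_deterministic(self, session2):
        model = ValueRnn.init_default(12, 9)
        Z1 = model.forward(session2)
        Z2 = model.forward(session2)
        assert np.array_equal(Z1, Z2)

    def test_checkpoint_round_trip(self, tmp_path):
        model = ValueRnn.init_esn(6, 1.3, 8)
        path = tmp_path / "model.json"
        save_model(model, path, losses=[1.0, 0.5])
        loaded = load_model(path)
        assert all(
            np.array_equal(loaded.params[k], model.params[k]) for k in model.params
        )
        assert loaded.core_trainable == model.core_trainable

    def test_corrupt_checkpoint_shapes_rejected(self, tmp_path):
        import json

        model = ValueRnn.init_default(5, 0)
        path = tmp_path / "model.json"
        save_model(model, path)
        payload = json.loads(path.read_text())
        payload["params"]["w"] = [0.0, 1.0]
        path.write_text(json.dumps(payload))
        with pytest.raises(ValueError):
            load_model(path)
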
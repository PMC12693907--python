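import numpy as np
import pytest

from tomaqual.maturity_model import (
    AttentionParams,
    GRUAttentionForecaster,
    GRUCellParams,
    attention,
    gru_cell_step,
    rollout_fractions,
    to_simplex,
)

from oracles import attention_scalar, gru_step_scalar


def random_gru(rng, n_in, n_hidden):
    mk = lambda shape: rng.normal(size=shape)
    return GRUCellParams(
        mk((n_in, n_hidden)), mk((n_hidden, n_hidden)),
        mk((n_in, n_hidden)), mk((n_hidden, n_hidden)),
        mk((n_in, n_hidden)), mk((n_hidden, n_hidden)),
        mk(n_hidden), mk(n_hidden), mk(n_hidden),
    )


class TestGRUCellStep:
    def test_zero_parameters_halve_hidden_state(self):
        params = GRUCellParams(
            np.zeros((1, 2)), np.zeros((2, 2)), np.zeros((1, 2)),
            np.zeros((2, 2)), np.zeros((1, 2)), np.zeros((2, 2)),
            np.zeros(2), np.zeros(2), np.zeros(2),
        )
        h_prev = np.array([0.6, -0.2])
        np.testing.assert_allclose(gru_cell_step(np.array([1.0]), h_prev, params), 0.5 * h_prev)

    def test_saturated_update_gate_is_pure_memory(self):
        params = GRUCellParams(
            np.zeros((1, 2)), np.zeros((2, 2)), np.zeros((1, 2)),
            np.zeros((2, 2)), np.ones((1, 2)), np.zeros((2, 2)),
            np.zeros(2), np.full(2, 60.0), np.zeros(2),
        )
        h_prev = np.array([0.3, -0.9])
        np.testing.assert_allclose(gru_cell_step(np.array([2.0]), h_prev, params), h_prev, atol=1e-12)

    def test_matches_scalar_oracle(self, rng):
        for _ in range(50):
            n_in, n_hidden = int(rng.integers(1, 5)), int(rng.integers(1, 9))
            params = random_gru(rng, n_in, n_hidden)
            x, h = rng.normal(size=n_in), rng.normal(size=n_hidden)
            ref = gru_step_scalar(
                x.tolist(), h.tolist(),
                params.w_xr.tolist(), params.w_hr.tolist(), params.w_xz.tolist(),
                params.w_hz.tolist(), params.w_xh.tolist(), params.w_hh.tolist(),
                params.b_r.tolist(), params.b_z.tolist(), params.b_h.tolist(),
            )
            np.testing.assert_allclose(gru_cell_step(x, h, params), ref, atol=1e-10)

    def test_hidden_state_stays_in_unit_box(self, rng):
        params = random_gru(rng, 3, 5)
        h = rng.uniform(-1, 1, size=5)
        for _ in range(30):
            h = gru_cell_step(rng.normal(size=3) * 2, h, params)
            assert np.abs(h).max() <= 1.0


class TestAttention:
    def test_identical_states_give_uniform_weights(self, rng):
        params = AttentionParams(*[rng.normal(size=(4, 3)) for _ in range(3)])
        H = np.tile(rng.normal(size=4), (5, 1))
        out = attention(H, params)
        np.testing.assert_allclose(out.weights, 0.2, atol=1e-12)
        np.testing.assert_allclose(out.context, (H[0] @ params.W_V), atol=1e-9)

    def test_dominant_score_gives_one_hot(self):
        # keys aligned with the query for one step only
        W = np.eye(2)
        params = AttentionParams(W, W, W)
        H = np.array([[0.0, 0.0], [30.0, 0.0], [0.0, 0.0], [1.0, 0.0]])
        out = attention(H, params)
        assert out.weights[1] > 0.999
        np.testing.assert_allclose(out.context, H[1], atol=1e-3)

    def test_matches_explicit_summation_oracle(self, rng):
        for _ in range(50):
            T, hid, d = int(rng.integers(1, 7)), int(rng.integers(1, 6)), int(rng.integers(1, 5))
            params = AttentionParams(*[rng.normal(size=(hid, d)) for _ in range(3)])
            H = rng.normal(size=(T, hid))
            out = attention(H, params)
            alpha_ref, ctx_ref = attention_scalar(
                H.tolist(), params.W_Q.tolist(), params.W_K.tolist(), params.W_V.tolist()
            )
            np.testing.assert_allclose(out.weights, alpha_ref, atol=1e-10)
            np.testing.assert_allclose(out.context, ctx_ref, atol=1e-10)
            assert out.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_sequence_rejected(self, rng):
        params = AttentionParams(*[rng.normal(size=(4, 3)) for _ in range(3)])
        with pytest.raises(ValueError):
            attention(np.empty((0, 4)), params)


class TestSimplexProjection:
    def test_rows_land_on_simplex(self, rng):
        raw = rng.normal(size=(40, 3)) * 2
        out = to_simplex(raw)
        assert (out >= 0).all() and (out <= 1).all()
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-12)

    def test_all_zero_row_becomes_uniform(self):
        np.testing.assert_allclose(to_simplex(np.array([-1.0, -2.0, -3.0]))[0], 1 / 3)


def toy_dataset(rng, n=60, T=8):
    X = rng.uniform(0, 1, size=(n, T, 6))
    Y = to_simplex(rng.uniform(0, 1, size=(n, 3)))
    return X, Y


class TestForecaster:
    def test_forward_equals_composition_of_functional_ops(self, rng):
        """Dual route: estimator forward vs gru_cell_step + attention + affine."""
        model = GRUAttentionForecaster(hidden_size=5, attention_dim=4, fc_size=3,
                                       time_steps=6, epochs=0, seed=2)
        X, Y = toy_dataset(rng, n=4, T=6)
        model.fit(X, Y)  # builds (0 epochs)
        cell = model.cell_params()
        att = model.attention_params()
        for window in X:
            h = np.zeros(5)
            states = []
            for x in window:
                h = gru_cell_step(x, h, cell)
                states.append(h)
            ctx = attention(np.array(states), att).context
            fc = np.maximum(ctx @ model.fc_.W.data + model.fc_.b.data, 0.0)
            raw = fc @ model.head_.W.data + model.head_.b.data
            np.testing.assert_allclose(model.predict_raw(window)[0], raw, atol=1e-9)

    def test_zero_weight_network_outputs_projected_bias(self, rng):
        model = GRUAttentionForecaster(hidden_size=4, time_steps=5, epochs=0, seed=0)
        X, Y = toy_dataset(rng, n=2, T=5)
        model.fit(X, Y)
        for module in (model.gru_, model.attention_, model.fc_):
            for p in module.parameters():
                p.data = np.zeros_like(p.data)
        model.head_.W.data = np.zeros_like(model.head_.W.data)
        model.head_.b.data = np.array([0.2, 0.1, 0.7])
        np.testing.assert_allclose(model.predict(X[0]), [0.2, 0.1, 0.7], atol=1e-12)

    def test_identical_seeds_identical_histories(self, rng):
        X, Y = toy_dataset(rng)
        kw = dict(hidden_size=6, time_steps=8, epochs=3, seed=9)
        h1 = GRUAttentionForecaster(**kw).fit(X, Y).loss_history_
        h2 = GRUAttentionForecaster(**kw).fit(X, Y).loss_history_
        assert h1 == h2

    def test_predictions_on_simplex(self, rng):
        X, Y = toy_dataset(rng)
        model = GRUAttentionForecaster(hidden_size=6, time_steps=8, epochs=2, seed=0).fit(X, Y)
        pred = model.predict(X[:10])
        assert (pred >= 0).all()
        np.testing.assert_allclose(pred.sum(axis=1), 1.0, atol=1e-9)

    def test_checkpoint_round_trip(self, rng, tmp_path):
        X, Y = toy_dataset(rng)
        model = GRUAttentionForecaster(hidden_size=6, time_steps=8, epochs=1, seed=0).fit(X, Y)
        model.save(tmp_path / "m.json")
        back = GRUAttentionForecaster.load(tmp_path / "m.json")
        np.testing.assert_array_equal(back.predict(X[:3]), model.predict(X[:3]))

    def test_rollout_contract(self, rng):
        X, Y = toy_dataset(rng)
        model = GRUAttentionForecaster(hidden_size=4, time_steps=8, epochs=1, seed=0).fit(X, Y)
        env_future = rng.uniform(0, 1, size=(4, 3))
        out = rollout_fractions(model, env_future, X[0], horizon=4)
        assert out.shape == (4, 3)
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-9)
        with pytest.raises(ValueError):
            rollout_fractions(model, env_future, X[0], horizon=0)
        with pytest.raises(ValueError):
            rollout_fractions(model, env_future[:2], X[0], horizon=4)
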
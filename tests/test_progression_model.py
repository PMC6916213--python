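import math
import random

import numpy as np
import pytest

from copdatlas import progression_model as pm
from copdatlas.errors import ValidationError
from copdatlas.preprocess import DailySample

from _oracles import random_scalar_weights, scalar_lstm_forward, scalar_lstm_step
from conftest import weights_from_dict, zero_lstm_weights

import datetime

DAY = datetime.date(2016, 1, 1)


def make_samples(ids_rows, labels):
    return [
        DailySample("p", DAY, 10, np.asarray(row, dtype=np.int32), int(lab))
        for row, lab in zip(ids_rows, labels)
    ]


class TestLstmStep:
    def test_zero_weights_zero_state(self):
        w = zero_lstm_weights(3, 2)
        state = pm.lstm_step(np.ones(2), pm.initial_state(3), w)
        assert np.allclose(state.c, 0.0)
        assert np.allclose(state.h, 0.0)

    def test_zero_weights_unit_memory(self):
        """With zero weights all gates sit at 0.5, so c halves and h follows."""
        w = zero_lstm_weights(2, 2)
        prev = pm.LSTMState(h=np.zeros(2), c=np.ones(2))
        state = pm.lstm_step(np.ones(2), prev, w)
        assert np.allclose(state.c, 0.5)
        assert np.allclose(state.h, 0.5 * math.tanh(0.5))
        assert np.allclose(state.h, 0.23105857863000487 * np.ones(2), atol=1e-12)

    def test_matches_scalar_oracle(self):
        rng = random.Random(5)
        for _ in range(20):
            L, v = rng.randint(1, 4), rng.randint(1, 4)
            wd = random_scalar_weights(rng, L, v)
            x = [rng.uniform(-1, 1) for _ in range(v)]
            h0 = [rng.uniform(-1, 1) for _ in range(L)]
            c0 = [rng.uniform(-1, 1) for _ in range(L)]
            got = pm.lstm_step(
                np.array(x), pm.LSTMState(np.array(h0), np.array(c0)), weights_from_dict(wd)
            )
            h_exp, c_exp = scalar_lstm_step(x, h0, c0, wd)
            assert np.allclose(got.h, h_exp, atol=1e-10)
            assert np.allclose(got.c, c_exp, atol=1e-10)

    def test_hidden_state_bounded(self):
        rng = random.Random(9)
        wd = random_scalar_weights(rng, 3, 3, scale=3.0)
        state = pm.LSTMState(np.full(3, 0.9), np.full(3, 5.0))
        out = pm.lstm_step(np.full(3, 2.0), state, weights_from_dict(wd))
        assert np.all(np.abs(out.h) <= 1.0)


class TestLstmForward:
    def test_single_step_equivalence(self):
        rng = random.Random(1)
        wd = random_scalar_weights(rng, 2, 3)
        x = np.array([[0.3, -0.2, 0.7]])
        hidden = pm.lstm_forward(x, weights_from_dict(wd))
        step = pm.lstm_step(x[0], pm.initial_state(2), weights_from_dict(wd))
        assert np.allclose(hidden[0], step.h)

    def test_zero_weights_all_zero(self):
        hidden = pm.lstm_forward(np.random.default_rng(0).normal(size=(4, 2)),
                                 zero_lstm_weights(3, 2))
        assert np.allclose(hidden, 0.0)

    def test_matches_scalar_oracle_over_time(self):
        rng = random.Random(2)
        wd = random_scalar_weights(rng, 2, 2)
        xs = [[rng.uniform(-1, 1) for _ in range(2)] for _ in range(3)]
        got = pm.lstm_forward(np.array(xs), weights_from_dict(wd))
        exp = scalar_lstm_forward(xs, wd, 2)
        assert np.allclose(got, exp, atol=1e-10)


class TestEmbedAndDense:
    def test_embed_identity_rows(self):
        E = np.eye(4)
        out = pm.embed(np.array([2, 0, 3]), E)
        assert np.array_equal(out, E[[2, 0, 3]])

    def test_embed_all_pad_and_bounds(self):
        E = np.arange(8.0).reshape(4, 2)
        out = pm.embed(np.zeros(5, dtype=int), E)
        assert np.array_equal(out, np.tile(E[0], (5, 1)))
        assert out.shape == (5, 2)
        with pytest.raises(IndexError):
            pm.embed(np.array([4]), E)

    def test_flatten_dense_zero_weights(self):
        hidden = np.random.default_rng(0).normal(size=(3, 2))
        probs = pm.flatten_dense(hidden, np.zeros((6, 4)), np.zeros(4))
        assert np.allclose(probs, 0.25)
        mort = pm.flatten_dense(hidden, np.zeros((6, 1)), np.zeros(1))
        assert np.allclose(mort, 0.5)

    def test_flatten_dense_hand_computed(self):
        hidden = np.array([[1.0, 2.0], [3.0, 4.0]])  # flatten -> [1,2,3,4]
        W = np.ones((4, 2))
        W[:, 1] = [0.1, 0.2, 0.3, 0.4]
        b = np.array([0.0, 0.5])
        z0 = 1 + 2 + 3 + 4
        z1 = 0.1 + 0.4 + 0.9 + 1.6 + 0.5
        expected = np.exp([z0, z1]) / np.exp([z0, z1]).sum()
        assert np.allclose(pm.flatten_dense(hidden, W, b), expected, atol=1e-12)

    def test_flatten_dense_shape_mismatch(self):
        with pytest.raises(ValidationError):
            pm.flatten_dense(np.ones((2, 2)), np.ones((5, 2)), np.zeros(2))


def tiny_config(**kw):
    defaults = dict(vocab_size=12, embed_dim=3, max_len=5, hidden_units=4,
                    n_classes=3, window_days=30)
    defaults.update(kw)
    return pm.ModelConfig(**defaults)


class TestTraining:
    def test_smoke_one_epoch_logs_one_loss(self):
        rng = np.random.default_rng(0)
        samples = make_samples(rng.integers(0, 12, size=(10, 5)), rng.integers(0, 3, 10))
        model = pm.train(samples, tiny_config(), epochs=1, seed=0)
        assert len(model.loss_history) == 1
        assert np.isfinite(model.loss_history[0])

    def test_determinism_same_seed(self):
        rng = np.random.default_rng(1)
        ids = rng.integers(0, 12, size=(12, 5))
        labs = rng.integers(0, 3, 12)
        m1 = pm.train(make_samples(ids, labs), tiny_config(), epochs=3, seed=4)
        m3 = pm.train(make_samples(ids, labs), tiny_config(), epochs=3, seed=4)
        assert m1.loss_history == m3.loss_history
        for k in m1.params:
            assert np.array_equal(m1.params[k], m3.params[k])

    def test_loss_decreases_on_separable_data(self):
        # class 0 documents use tokens {2,3}, class 1 documents tokens {8,9}
        rng = np.random.default_rng(2)
        ids = np.where(
            (np.arange(40) % 2 == 0)[:, None], rng.integers(2, 4, (40, 5)),
            rng.integers(8, 10, (40, 5)),
        )
        labs = np.arange(40) % 2
        cfg = tiny_config(n_classes=2)
        short = pm.train(make_samples(ids, labs), cfg, epochs=1, seed=0,
                         learning_rate=0.3, batch_size=8)
        long = pm.train(make_samples(ids, labs), cfg, epochs=60, seed=0,
                        learning_rate=0.3, batch_size=8)
        assert long.loss_history[-1] < short.loss_history[-1]
        assert long.loss_history[-1] < 0.1

    def test_empty_and_single_class_rejected(self):
        with pytest.raises(ValidationError):
            pm.train([], tiny_config(), epochs=1, seed=0)
        ids = np.zeros((4, 5), dtype=np.int32)
        with pytest.raises(ValidationError, match="2 classes"):
            pm.train(make_samples(ids, [1, 1, 1, 1]), tiny_config(), epochs=1, seed=0)

    def test_mortality_head_binary_loss(self):
        rng = np.random.default_rng(3)
        ids = rng.integers(0, 12, size=(10, 5))
        labs = rng.integers(0, 2, 10)
        model = pm.train(make_samples(ids, labs), tiny_config(n_classes=1), epochs=2, seed=0)
        probs = model.predict_proba(ids)
        assert probs.shape == (10, 1)
        assert np.all((probs > 0) & (probs < 1))


class TestGradients:
    def test_analytic_matches_finite_differences(self):
        """Central finite differences on every parameter of a tiny model."""
        cfg = tiny_config(vocab_size=6, embed_dim=2, max_len=3, hidden_units=2)
        params = pm.init_params(cfg, seed=0)
        rng = np.random.default_rng(0)
        ids = rng.integers(0, 6, size=(4, 3))
        labels = np.array([0, 1, 2, 1])
        _, grads = pm.loss_and_grads(params, ids, labels)
        eps = 1e-6
        for key, arr in params.items():
            if key in ("W_seg", "b_seg"):
                continue
            flat = arr.ravel()
            for idx in range(0, flat.size, max(1, flat.size // 5)):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp, _ = pm.loss_and_grads(params, ids, labels)
                flat[idx] = orig - eps
                lm, _ = pm.loss_and_grads(params, ids, labels)
                flat[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert abs(num - grads[key].ravel()[idx]) < 1e-5, key


class TestPrediction:
    def test_uniform_output_tie_breaks_to_class_zero(self):
        cfg = tiny_config()
        params = pm.init_params(cfg, seed=0)
        params["W_d"][:] = 0.0
        params["b_d"][:] = 0.0
        model = pm.TrainedModel(config=cfg, params=params)
        cls, probs = pm.predict_window(model, np.zeros(5, dtype=int))
        assert cls == 0
        assert abs(probs.sum() - 1.0) < 1e-9
        assert np.allclose(probs, 1 / 3)

    def test_dimensional_contract(self):
        cfg = tiny_config()
        params = pm.init_params(cfg, seed=1)
        model = pm.TrainedModel(config=cfg, params=params)
        ids = np.zeros((7, 5), dtype=int)
        emb = pm.embed(ids[0], params["E"])
        assert emb.shape == (5, 3)
        hidden = pm.lstm_forward(emb, model.lstm_weights)
        assert hidden.shape == (5, 4)
        flat = model.hidden_flat(ids)
        assert flat.shape == (7, 20)
        probs = model.predict_proba(ids)
        assert probs.shape == (7, 3)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)


class TestCheckpoint:
    def test_round_trip_and_byte_identity(self, tmp_path):
        rng = np.random.default_rng(0)
        samples = make_samples(rng.integers(0, 12, (8, 5)), rng.integers(0, 3, 8))
        model = pm.train(samples, tiny_config(), epochs=2, seed=1)
        p1, p2 = tmp_path / "a.ckpt", tmp_path / "b.ckpt"
        pm.save_model(model, p1)
        loaded = pm.load_model(p1)
        assert loaded.config == model.config
        assert loaded.loss_history == model.loss_history
        for k in model.params:
            assert np.array_equal(loaded.params[k], model.params[k])
        pm.save_model(loaded, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_corrupt_file_rejected(self, tmp_path):
        path = tmp_path / "bad.ckpt"
        path.write_bytes(b"not a checkpoint")
        with pytest.raises(ValidationError):
            pm.load_model(path)


class TestSegmentSignal:
    def test_first_window_always_opens_a_segment(self):
        cfg = tiny_config()
        model = pm.TrainedModel(config=cfg, params=pm.init_params(cfg, seed=0))
        windows = [np.zeros((2, 5), dtype=int)]
        assert pm.segment_signal(model, windows).tolist() == [1]

    def test_low_sigmoid_yields_single_segment(self):
        cfg = tiny_config()
        params = pm.init_params(cfg, seed=0)
        params["W_seg"][:] = 0.0
        params["b_seg"][:] = -10.0  # sigmoid ~ 0 regardless of content
        model = pm.TrainedModel(config=cfg, params=params)
        rng = np.random.default_rng(0)
        windows = [rng.integers(0, 12, (3, 5)) for _ in range(4)]
        assert pm.segment_signal(model, windows).tolist() == [1, 0, 0, 0]

    def test_empty_window_inherits_zero(self):
        cfg = tiny_config()
        params = pm.init_params(cfg, seed=0)
        params["b_seg"][:] = 10.0  # sigmoid ~ 1 for non-empty windows
        model = pm.TrainedModel(config=cfg, params=params)
        rng = np.random.default_rng(0)
        windows = [rng.integers(0, 12, (2, 5)), np.zeros((0, 5), dtype=int),
                   rng.integers(0, 12, (2, 5))]
        signal = pm.segment_signal(model, windows)
        assert signal[0] == 1 and signal[1] == 0 and signal[2] == 1
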
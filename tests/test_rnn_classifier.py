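import math

import numpy as np
import pytest

from kidneyhist import (
    CLASS_NAMES,
    LSTMClassifier,
    LSTMParams,
    TrainConfig,
    cross_entropy_loss,
    encode_sequence,
    forward,
    lstm_cell_step,
    predict,
    train,
)
from kidneyhist.rnn_classifier import decode_sequence, predict_batch


def zero_model(hidden=4, features=16):
    lstm = LSTMParams(np.zeros((4 * hidden, features)),
                      np.zeros((4 * hidden, hidden)), np.zeros(4 * hidden))
    return LSTMClassifier(lstm, np.zeros((4, hidden)), np.zeros(4),
                          TrainConfig(hidden_units=hidden))


def reference_forward(model, seq):
    """Independent step-by-step oracle evaluating every gate formula per unit."""
    H = model.lstm.hidden_units
    sig = lambda v: 1.0 / (1.0 + math.exp(-v))
    h = [0.0] * H
    c = [0.0] * H
    Wxf, Whf, bf = model.lstm.gate("f")
    Wxi, Whi, bi = model.lstm.gate("i")
    Wxc, Whc, bc = model.lstm.gate("g")
    Wxo, Who, bo = model.lstm.gate("o")
    for x in seq:
        hn, cn = [0.0] * H, [0.0] * H
        for u in range(H):
            f = sig(float(Wxf[u] @ x + Whf[u] @ h + bf[u]))
            i = sig(float(Wxi[u] @ x + Whi[u] @ h + bi[u]))
            g = math.tanh(float(Wxc[u] @ x + Whc[u] @ h + bc[u]))
            o = sig(float(Wxo[u] @ x + Who[u] @ h + bo[u]))
            cn[u] = f * c[u] + i * g
            hn[u] = o * math.tanh(cn[u])
        h, c = hn, cn
    logits = model.W_fc @ np.asarray(h) + model.b_fc
    e = np.exp(logits - logits.max())
    return e / e.sum()


class TestEncodeSequence:
    def test_shape_and_layout(self):
        fv = np.zeros(1600)
        fv[16] = 1.0  # window 2, intensity bin 1 (1-based)
        seq = encode_sequence(fv)
        assert seq.shape == (100, 16)
        assert seq[1, 0] == 1.0 and seq.sum() == 1.0

    def test_decode_inverts_encode(self):
        fv = np.random.default_rng(0).random(1600)
        np.testing.assert_array_equal(decode_sequence(encode_sequence(fv)), fv)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            encode_sequence(np.zeros(1601))


class TestLSTMCellStep:
    def test_zero_parameters_give_zero_state(self):
        model = zero_model()
        h, c = lstm_cell_step(model.lstm, np.ones(16), np.zeros(4), np.zeros(4))
        np.testing.assert_array_equal(h, 0.0)
        np.testing.assert_array_equal(c, 0.0)

    def test_scalar_cell_matches_hand_computation(self):
        # single unit, single input feature, hand-picked weights
        Wx = np.array([[0.5], [-0.3], [0.8], [0.2]])   # f, i, g, o
        Wh = np.array([[0.1], [0.4], [-0.2], [0.3]])
        b = np.array([0.05, -0.1, 0.2, 0.0])
        params = LSTMParams(Wx, Wh, b)
        x, hp, cp = 0.7, 0.25, -0.4
        sig = lambda v: 1.0 / (1.0 + math.exp(-v))
        f = sig(0.5 * x + 0.1 * hp + 0.05)
        i = sig(-0.3 * x + 0.4 * hp - 0.1)
        g = math.tanh(0.8 * x - 0.2 * hp + 0.2)
        o = sig(0.2 * x + 0.3 * hp + 0.0)
        c_exp = f * cp + i * g
        h_exp = o * math.tanh(c_exp)
        h, c = lstm_cell_step(params, np.array([x]), np.array([hp]), np.array([cp]))
        assert c[0] == pytest.approx(c_exp, abs=1e-14)
        assert h[0] == pytest.approx(h_exp, abs=1e-14)

    def test_saturated_forget_gate_reduces_to_input_times_candidate(self):
        rng = np.random.default_rng(2)
        H, F = 3, 5
        params = LSTMParams.init(F, H, rng)
        params.b[:H] = 50.0  # forget gate saturated at 1
        x = rng.normal(size=F)
        h, c = lstm_cell_step(params, x, np.zeros(H), np.zeros(H))
        # with c_prev = 0: c_t = i*g regardless of f, and f ~ 1 exactly
        sig = lambda v: 1.0 / (1.0 + np.exp(-v))
        i = sig(params.gate("i")[0] @ x + params.gate("i")[2])
        g = np.tanh(params.gate("g")[0] @ x + params.gate("g")[2])
        np.testing.assert_allclose(c, i * g, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            lstm_cell_step(zero_model().lstm, np.ones(7), np.zeros(4), np.zeros(4))


class TestForward:
    def test_zero_parameters_give_uniform_probabilities(self):
        probs = forward(zero_model(), np.zeros((100, 16)))
        np.testing.assert_allclose(probs, 0.25, atol=1e-12)

    def test_softmax_shift_invariance(self):
        model = zero_model()
        model.b_fc = np.full(4, 13.7)  # constant logits -> uniform
        probs = forward(model, np.zeros((100, 16)))
        np.testing.assert_allclose(probs, 0.25, atol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_per_timestep_oracle_on_random_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        H = int(rng.integers(1, 5))
        T = int(rng.integers(1, 6))
        F = int(rng.integers(1, 6))
        lstm = LSTMParams.init(F, H, rng)
        model = LSTMClassifier(lstm, rng.normal(size=(4, H)), rng.normal(size=4),
                               TrainConfig(hidden_units=H))
        seq = rng.normal(size=(T, F))
        np.testing.assert_allclose(forward(model, seq),
                                   reference_forward(model, seq), atol=1e-10)

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(0)
        lstm = LSTMParams.init(16, 8, rng)
        model = LSTMClassifier(lstm, rng.normal(size=(4, 8)), np.zeros(4),
                               TrainConfig(hidden_units=8))
        probs = forward(model, rng.normal(size=(100, 16)))
        assert probs.sum() == pytest.approx(1.0, abs=1e-9)
        assert (probs >= 0).all()


class TestCrossEntropy:
    def test_perfect_prediction_has_near_zero_loss(self):
        assert cross_entropy_loss(np.array([1, 0, 0, 0]),
                                  np.array([1, 0, 0, 0])) < 1e-10

    def test_uniform_prediction_loss_is_ln4(self):
        assert cross_entropy_loss(np.array([1.0, 0, 0, 0]), np.full(4, 0.25)) == \
            pytest.approx(math.log(4), abs=1e-9)

    def test_non_one_hot_rejected(self):
        with pytest.raises(ValueError):
            cross_entropy_loss(np.array([0.5, 0.5, 0, 0]), np.full(4, 0.25))


def _tiny_separable_dataset(n_per_class=6, seed=0):
    """Linearly separable toy features: one indicator block per class."""
    rng = np.random.default_rng(seed)
    data = []
    for k, cls in enumerate(CLASS_NAMES):
        for _ in range(n_per_class):
            fv = rng.random(1600) * 0.05
            fv[k * 400:(k + 1) * 400] += 0.5
            data.append((fv, cls))
    return data


class TestTrain:
    def test_loss_decreases_on_separable_data(self):
        data = _tiny_separable_dataset()
        model = train(data, TrainConfig(hidden_units=8, epochs=15, batch_size=8,
                                        learning_rate=3e-3, seed=0))
        assert len(model.loss_history) == 15
        assert model.loss_history[-1] < model.loss_history[0]

    def test_identical_seeds_give_identical_histories(self):
        data = _tiny_separable_dataset()
        cfg = TrainConfig(hidden_units=6, epochs=3, seed=7)
        m1 = train(data, cfg)
        m2 = train(data, cfg)
        assert m1.loss_history == m2.loss_history
        np.testing.assert_array_equal(m1.lstm.Wx, m2.lstm.Wx)

    def test_one_epoch_gives_one_history_entry(self):
        model = train(_tiny_separable_dataset(), TrainConfig(hidden_units=4, epochs=1))
        assert len(model.loss_history) == 1

    def test_single_class_dataset_rejected(self):
        data = [(np.zeros(1600), "cyst") for _ in range(4)]
        with pytest.raises(ValueError):
            train(data, TrainConfig(epochs=1))

    def test_unknown_label_rejected(self):
        data = [(np.zeros(1600), "cyst"), (np.zeros(1600), "polyp")]
        with pytest.raises(ValueError):
            train(data, TrainConfig(epochs=1))


class TestPredict:
    def test_argmax_and_tie_break(self):
        model = zero_model()
        label, probs = predict(model, np.zeros(1600))
        np.testing.assert_allclose(probs, 0.25)
        assert label == "cyst"  # exact tie -> first class in fixed order

    def test_prediction_deterministic_and_batch_consistent(self):
        data = _tiny_separable_dataset()
        model = train(data, TrainConfig(hidden_units=8, epochs=10, seed=0))
        fv = data[0][0]
        l1, p1 = predict(model, fv)
        l2, p2 = predict(model, fv)
        assert l1 == l2
        np.testing.assert_array_equal(p1, p2)
        labels, probs = predict_batch(model, np.stack([fv, data[-1][0]]))
        assert labels[0] == l1
        np.testing.assert_allclose(probs[0], p1, atol=1e-12)

    def test_save_load_roundtrip(self, tmp_path):
        model = train(_tiny_separable_dataset(),
                      TrainConfig(hidden_units=5, epochs=2, seed=1))
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = LSTMClassifier.load(path)
        fv = np.random.default_rng(3).random(1600)
        np.testing.assert_allclose(predict(model, fv)[1],
                                   predict(loaded, fv)[1], atol=1e-15)
        assert loaded.config == model.config
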
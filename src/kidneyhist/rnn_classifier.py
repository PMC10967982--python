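"""LSTM sequence classifier over the merged local-histogram features.

Architecture: sequence input -> LSTM (last-output mode) -> dropout
(training only) -> fully connected -> softmax over the 4 classes. The
1x1600 feature vector is presented as a sequence of 100 timesteps, one per
spatial window, each carrying that window's 16 histogram frequencies
(8 intensity + 8 gradient), preserving the descriptor's spatial structure.

The cell uses the standard gate system: sigmoid forget/input/output gates,
tanh candidate, additive cell update

    f_t = sigmoid(W_xf x_t + W_hf h_{t-1} + b_f)
    i_t = sigmoid(W_xi x_t + W_hi h_{t-1} + b_i)
    g_t = tanh   (W_xc x_t + W_hc h_{t-1} + b_c)
    o_t = sigmoid(W_xo x_t + W_ho h_{t-1} + b_o)
    c_t = f_t * c_{t-1} + i_t * g_t
    h_t = o_t * tanh(c_t)

and training minimises categorical cross-entropy with Adam, with gradients
obtained by backpropagation through time. Everything is plain NumPy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .image_prep import CLASS_NAMES
from .local_histogram import FEATURE_LENGTH

__all__ = [
    "N_TIMESTEPS",
    "N_STEP_FEATURES",
    "TrainConfig",
    "LSTMParams",
    "LSTMClassifier",
    "encode_sequence",
    "decode_sequence",
    "lstm_cell_step",
    "forward",
    "cross_entropy_loss",
    "train",
    "predict",
]

N_TIMESTEPS = 100
N_STEP_FEATURES = 16
N_CLASSES = len(CLASS_NAMES)
_EPS = 1e-12

# gate order inside the stacked weight matrices
_GATES = ("f", "i", "g", "o")


@dataclass(frozen=True)
class TrainConfig:
    hidden_units: int = 128
    dropout_rate: float = 0.2
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    lstm_output_mode: str = "last"

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.epochs < 1 or self.batch_size < 1 or self.hidden_units < 1:
            raise ValueError("epochs, batch_size and hidden_units must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.lstm_output_mode != "last":
            raise ValueError("only 'last' output mode is supported")


@dataclass
class LSTMParams:
    """Gate weights stacked in (forget, input, candidate, output) order.

    ``Wx`` is (4H, F), ``Wh`` is (4H, H), ``b`` is (4H,). Per-gate blocks are
    accessible through :meth:`gate`.
    """

    Wx: np.ndarray
    Wh: np.ndarray
    b: np.ndarray

    @property
    def hidden_units(self) -> int:
        return self.Wh.shape[1]

    @property
    def input_features(self) -> int:
        return self.Wx.shape[1]

    def gate(self, name: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (W_x, W_h, b) for gate ``name`` in {'f','i','g','o'}."""
        k = _GATES.index(name)
        H = self.hidden_units
        sl = slice(k * H, (k + 1) * H)
        return self.Wx[sl], self.Wh[sl], self.b[sl]

    @classmethod
    def init(cls, input_features: int, hidden_units: int,
             rng: np.random.Generator,
             timesteps: int = 100) -> "LSTMParams":
        """Glorot-uniform weights with chrono-style gate biases.

        A lesion occupies only a couple of the 100 windows, so its signature
        must survive in the cell state for up to ~100 steps to reach the
        last-mode readout. Initialising the forget biases as
        ``log U(1, T-1)`` (and the input biases as their negation) spreads
        the units' memory timescales up to the sequence length, without
        which brief early events decay before training can learn to latch
        them.
        """
        H, F = hidden_units, input_features
        sx = np.sqrt(6.0 / (F + H))
        sh = np.sqrt(6.0 / (H + H))
        Wx = rng.uniform(-sx, sx, size=(4 * H, F))
        Wh = rng.uniform(-sh, sh, size=(4 * H, H))
        b = np.zeros(4 * H)
        b_f = np.log(rng.uniform(1.0, max(timesteps - 1, 2), size=H))
        b[:H] = b_f
        b[H:2 * H] = -b_f
        return cls(Wx, Wh, b)


def encode_sequence(fv: np.ndarray) -> np.ndarray:
    """Reshape a feature vector to (100 timesteps, features-per-step).

    For the canonical 1x1600 combined descriptor each timestep w carries
    window w's 8 intensity then 8 gradient frequencies (100 x 16). The
    single-channel ablation descriptors (length 800) reshape to 100 x 8 the
    same way. Invertible (see :func:`decode_sequence`).
    """
    fv = np.asarray(fv, dtype=np.float64).ravel()
    if fv.size == 0 or fv.size % N_TIMESTEPS != 0:
        raise ValueError(
            f"feature vector length must be a positive multiple of {N_TIMESTEPS}"
            f" (canonically {FEATURE_LENGTH}), got {fv.size}")
    return fv.reshape(N_TIMESTEPS, fv.size // N_TIMESTEPS)


def decode_sequence(seq: np.ndarray) -> np.ndarray:
    seq = np.asarray(seq)
    if seq.ndim != 2 or seq.shape[0] != N_TIMESTEPS:
        raise ValueError(f"sequence must have {N_TIMESTEPS} timesteps")
    return seq.ravel()


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def lstm_cell_step(
    params: LSTMParams,
    x_t: np.ndarray,
    h_prev: np.ndarray,
    c_prev: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """One step of the gate system; accepts a single row or a batch."""
    x_t, h_prev, c_prev = (np.atleast_2d(np.asarray(a, dtype=np.float64))
                           for a in (x_t, h_prev, c_prev))
    if x_t.shape[1] != params.input_features or h_prev.shape[1] != params.hidden_units:
        raise ValueError("input/state width does not match the cell parameters")
    H = params.hidden_units
    a = x_t @ params.Wx.T + h_prev @ params.Wh.T + params.b
    f = _sigmoid(a[:, 0 * H:1 * H])
    i = _sigmoid(a[:, 1 * H:2 * H])
    g = np.tanh(a[:, 2 * H:3 * H])
    o = _sigmoid(a[:, 3 * H:4 * H])
    c_t = f * c_prev + i * g
    h_t = o * np.tanh(c_t)
    if h_t.shape[0] == 1:
        return h_t[0], c_t[0]
    return h_t, c_t


def cross_entropy_loss(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Categorical cross-entropy -sum(y_true * log(y_pred + eps)) for one sample."""
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y_true.shape != y_pred.shape:
        raise ValueError("shape mismatch between y_true and y_pred")
    if not (np.isin(y_true, (0.0, 1.0)).all() and y_true.sum() == 1.0):
        raise ValueError("y_true must be one-hot")
    return float(-(y_true * np.log(y_pred + _EPS)).sum())


@dataclass
class LSTMClassifier:
    """Trained model: feature scaler + LSTM cell + fully connected softmax head.

    ``feat_mean``/``feat_std`` hold the per-position standardisation fitted
    on the training features (histogram frequencies are small numbers;
    standardising them conditions the optimisation). ``None`` means no
    scaling (hand-constructed models).
    """

    lstm: LSTMParams
    W_fc: np.ndarray      # (4, H)
    b_fc: np.ndarray      # (4,)
    config: TrainConfig
    loss_history: list[float] = field(default_factory=list)
    feat_mean: np.ndarray | None = None   # (n_features,)
    feat_std: np.ndarray | None = None    # (n_features,)

    FORMAT_VERSION = 1

    def scale(self, fvs: np.ndarray) -> np.ndarray:
        """Apply the stored training-set standardisation to feature vectors."""
        if self.feat_mean is None:
            return np.asarray(fvs, dtype=np.float64)
        return (np.asarray(fvs, dtype=np.float64) - self.feat_mean) / self.feat_std

    def save(self, path: str | Path) -> None:
        meta = {"format_version": self.FORMAT_VERSION,
                "config": self.config.__dict__,
                "loss_history": self.loss_history,
                "class_names": list(CLASS_NAMES)}
        scaler = {} if self.feat_mean is None else {
            "feat_mean": self.feat_mean, "feat_std": self.feat_std}
        np.savez(Path(path), Wx=self.lstm.Wx, Wh=self.lstm.Wh, b=self.lstm.b,
                 W_fc=self.W_fc, b_fc=self.b_fc, meta=json.dumps(meta), **scaler)

    @classmethod
    def load(cls, path: str | Path) -> "LSTMClassifier":
        with np.load(Path(path), allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            if meta.get("format_version") != cls.FORMAT_VERSION:
                raise ValueError("unsupported model file format version")
            return cls(LSTMParams(z["Wx"], z["Wh"], z["b"]), z["W_fc"], z["b_fc"],
                       TrainConfig(**meta["config"]), list(meta["loss_history"]),
                       z["feat_mean"] if "feat_mean" in z else None,
                       z["feat_std"] if "feat_std" in z else None)


def _forward_batch(model: LSTMClassifier, X: np.ndarray):
    """Run the LSTM over all timesteps for a batch; returns probs and caches."""
    B, T, _ = X.shape
    H = model.lstm.hidden_units
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    caches = []
    Wx, Wh, b = model.lstm.Wx, model.lstm.Wh, model.lstm.b
    for t in range(T):
        x_t = X[:, t, :]
        a = x_t @ Wx.T + h @ Wh.T + b
        f = _sigmoid(a[:, 0 * H:1 * H])
        i = _sigmoid(a[:, 1 * H:2 * H])
        g = np.tanh(a[:, 2 * H:3 * H])
        o = _sigmoid(a[:, 3 * H:4 * H])
        c_new = f * c + i * g
        caches.append((x_t, h, c, f, i, g, o, c_new))
        c = c_new
        h = o * np.tanh(c_new)
    logits = h @ model.W_fc.T + model.b_fc
    return h, logits, caches


def forward(model: LSTMClassifier, seq: np.ndarray) -> np.ndarray:
    """Class probabilities for one encoded sequence (dropout inactive)."""
    seq = np.asarray(seq, dtype=np.float64)
    if seq.ndim != 2 or seq.shape[1] != model.lstm.input_features:
        raise ValueError("sequence shape does not match the model")
    _, logits, _ = _forward_batch(model, seq[None, :, :])
    return _softmax(logits)[0]


class _Adam:
    def __init__(self, shapes: list[tuple[int, ...]], lr: float) -> None:
        self.lr = lr
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mh = m / (1 - self.b1 ** self.t)
            vh = v / (1 - self.b2 ** self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)


def train(
    dataset: list[tuple[np.ndarray, str]],
    cfg: TrainConfig | None = None,
) -> LSTMClassifier:
    """Train the classifier on (feature-vector, label) pairs.

    Dropout is applied to the LSTM's last output during training only
    (inverted dropout, so inference needs no rescaling). Reproducible from
    ``cfg.seed``; the per-epoch mean training loss is recorded on the model.
    """
    cfg = cfg or TrainConfig()
    if not dataset:
        raise ValueError("empty dataset")
    labels = [lab for _, lab in dataset]
    unknown = set(labels) - set(CLASS_NAMES)
    if unknown:
        raise ValueError(f"unknown class labels: {sorted(unknown)}")
    if len(set(labels)) < 2:
        raise ValueError("training requires at least 2 classes")

    F = np.stack([np.asarray(fv, dtype=np.float64).ravel() for fv, _ in dataset])
    # Standardise each of the k per-timestep channels with statistics pooled
    # over all windows and images. Pooling keeps the encoding of a histogram
    # value identical at every timestep, so the LSTM's shared weights can
    # recognise a lesion signature regardless of which window it falls in.
    n_chan = F.shape[1] // N_TIMESTEPS
    chans = F.reshape(len(F), N_TIMESTEPS, n_chan).reshape(-1, n_chan)
    mu_c = chans.mean(axis=0)
    sd_c = chans.std(axis=0)
    sd_c = np.where(sd_c > 1e-8, sd_c, 1.0)
    feat_mean = np.tile(mu_c, N_TIMESTEPS)
    feat_std = np.tile(sd_c, N_TIMESTEPS)
    X = np.stack([encode_sequence(fv) for fv in (F - feat_mean) / feat_std])
    y = np.array([CLASS_NAMES.index(lab) for lab in labels])
    Y = np.eye(N_CLASSES)[y]
    N = len(dataset)
    H = cfg.hidden_units

    rng = np.random.default_rng(cfg.seed)
    lstm = LSTMParams.init(X.shape[2], H, rng)
    s_fc = np.sqrt(6.0 / (H + N_CLASSES))
    model = LSTMClassifier(lstm, rng.uniform(-s_fc, s_fc, size=(N_CLASSES, H)),
                           np.zeros(N_CLASSES), cfg,
                           feat_mean=feat_mean, feat_std=feat_std)

    params = [lstm.Wx, lstm.Wh, lstm.b, model.W_fc, model.b_fc]
    opt = _Adam([p.shape for p in params], cfg.learning_rate)
    keep = 1.0 - cfg.dropout_rate

    for _ in range(cfg.epochs):
        order = rng.permutation(N)
        epoch_loss = 0.0
        for start in range(0, N, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            Xb, Yb = X[idx], Y[idx]
            B = len(idx)
            h_last, _, caches = _forward_batch(model, Xb)
            mask = (rng.random((B, H)) < keep) / keep if cfg.dropout_rate > 0 else 1.0
            h_drop = h_last * mask
            logits = h_drop @ model.W_fc.T + model.b_fc
            probs = _softmax(logits)
            epoch_loss += float(-(Yb * np.log(probs + _EPS)).sum())

            # ---- backward ----
            dlogits = (probs - Yb) / B
            gW_fc = dlogits.T @ h_drop
            gb_fc = dlogits.sum(axis=0)
            dh = (dlogits @ model.W_fc) * mask
            dc = np.zeros((B, H))
            gWx = np.zeros_like(lstm.Wx)
            gWh = np.zeros_like(lstm.Wh)
            gb = np.zeros_like(lstm.b)
            for t in range(len(caches) - 1, -1, -1):
                x_t, h_prev, c_prev, f, i, g, o, c_t = caches[t]
                tc = np.tanh(c_t)
                do = dh * tc
                dc = dc + dh * o * (1 - tc * tc)
                df = dc * c_prev
                di = dc * g
                dg = dc * i
                dc = dc * f
                da = np.concatenate([df * f * (1 - f), di * i * (1 - i),
                                     dg * (1 - g * g), do * o * (1 - o)], axis=1)
                gWx += da.T @ x_t
                gWh += da.T @ h_prev
                gb += da.sum(axis=0)
                dh = da @ lstm.Wh
            opt.step(params, [gWx, gWh, gb, gW_fc, gb_fc])
        model.loss_history.append(epoch_loss / N)
    return model


def predict(model: LSTMClassifier, fv: np.ndarray) -> tuple[str, np.ndarray]:
    """Predicted label (argmax; ties -> lowest class index) and probabilities."""
    probs = forward(model, encode_sequence(model.scale(np.asarray(fv).ravel())))
    return CLASS_NAMES[int(np.argmax(probs))], probs


def predict_batch(model: LSTMClassifier, fvs: np.ndarray) -> tuple[list[str], np.ndarray]:
    """Vectorised prediction over an (N, 1600) feature matrix."""
    fvs = model.scale(np.asarray(fvs, dtype=np.float64))
    X = fvs.reshape(len(fvs), N_TIMESTEPS, -1)
    if X.shape[2] != model.lstm.input_features:
        raise ValueError("feature width does not match the trained model")
    _, logits, _ = _forward_batch(model, X)
    probs = _softmax(logits)
    labels = [CLASS_NAMES[k] for k in np.argmax(probs, axis=1)]
    return labels, probs
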
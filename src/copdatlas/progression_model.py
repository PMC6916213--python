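"""The four-layer death-window model: embedding, LSTM, flatten, dense.

Each daily sample — the integer-encoded merge of one patient-day's notes,
padded to length ``T`` — flows through

* an embedding layer mapping each of the ``T`` token ids to a learned
  ``v``-dimensional vector,
* a single LSTM layer with ``L`` hidden units whose gates are

  .. math::

     i_t &= \\sigma(W_{hi} h_{t-1} + W_{xi} x_t + b_i) \\\\
     f_t &= \\sigma(W_{hf} h_{t-1} + W_{xf} x_t + b_f) \\\\
     o_t &= \\sigma(W_{ho} h_{t-1} + W_{xo} x_t + b_o) \\\\
     g_t &= \\tanh(W_{hg} h_{t-1} + W_{xg} x_t + b_g) \\\\
     c_t &= f_t \\odot c_{t-1} + i_t \\odot g_t \\\\
     h_t &= o_t \\odot \\tanh(c_t)

* a flatten layer unrolling the ``(T, L)`` hidden matrix to ``T·L``, and
* a dense head: softmax over ``P`` death-window classes, or a single
  sigmoid when ``P = 1`` (mortality score).

Training is plain mini-batch gradient descent on the cross-entropy loss with
analytic backpropagation through time, implemented here in NumPy end to end.
A second, dedicated sigmoid head over the flattened hidden state drives the
irregular time-lapse segmentation (see :func:`segment_signal`).

Dimensional contract per batch of ``n`` samples:
``(n, T)`` ids -> ``(n, T, v)`` -> ``(n, T, L)`` -> ``(n, T·L)`` -> ``(n, P)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit as sigmoid

from .errors import ConfigurationError, ValidationError
from .preprocess import DailySample, sample_matrix

_GATES = ("i", "f", "o", "g")
_PARAM_KEYS = (
    "E",
    "W_xi", "W_hi", "b_i",
    "W_xf", "W_hf", "b_f",
    "W_xo", "W_ho", "b_o",
    "W_xg", "W_hg", "b_g",
    "W_d", "b_d",
    "W_seg", "b_seg",
)


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the four-layer model.

    vocab_size
        V, number of distinct token ids (including padding and OOV).
    embed_dim
        v, dimension of the word-embedding space (default 64).
    max_len
        T, number of token positions per daily sample (default 1000).
    hidden_units
        L, LSTM hidden/cell size.
    n_classes
        P, death-window classes predicted by the softmax head; ``P = 1``
        switches the head to a sigmoid mortality score.
    window_days
        B, length in days of the initial regular time window.
    n_samples, n_windows
        D and N = D/B bookkeeping, filled in at training time.
    """

    vocab_size: int
    embed_dim: int = 64
    max_len: int = 1000
    hidden_units: int = 32
    n_classes: int = 12
    window_days: int = 30
    n_samples: int | None = None
    n_windows: int | None = None

    def __post_init__(self) -> None:
        for name in ("vocab_size", "embed_dim", "max_len", "hidden_units", "n_classes", "window_days"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be a positive integer")


@dataclass
class LSTMWeights:
    """Recurrent (L, L), input (v, L) and bias (L,) parameters of the four gates."""

    W_hi: np.ndarray
    W_hf: np.ndarray
    W_ho: np.ndarray
    W_hg: np.ndarray
    W_xi: np.ndarray
    W_xf: np.ndarray
    W_xo: np.ndarray
    W_xg: np.ndarray
    b_i: np.ndarray
    b_f: np.ndarray
    b_o: np.ndarray
    b_g: np.ndarray

    def __post_init__(self) -> None:
        L = self.W_hi.shape[0]
        v = self.W_xi.shape[0]
        for g in _GATES:
            if getattr(self, f"W_h{g}").shape != (L, L):
                raise ValidationError(f"W_h{g} must have shape ({L}, {L})")
            if getattr(self, f"W_x{g}").shape != (v, L):
                raise ValidationError(f"W_x{g} must have shape ({v}, {L})")
            if getattr(self, f"b_{g}").shape != (L,):
                raise ValidationError(f"b_{g} must have shape ({L},)")
        for name in ("W_hi", "W_hf", "W_ho", "W_hg", "W_xi", "W_xf", "W_xo", "W_xg",
                     "b_i", "b_f", "b_o", "b_g"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValidationError(f"{name} contains non-finite entries")


@dataclass(frozen=True)
class LSTMState:
    """Hidden state h and memory cell c after one step (each length L)."""

    h: np.ndarray
    c: np.ndarray


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def embed(token_ids: np.ndarray, embedding: np.ndarray) -> np.ndarray:
    """Look up each of the T token ids; padding id 0 has its own learned row."""
    ids = np.asarray(token_ids)
    if ids.max(initial=0) >= embedding.shape[0]:
        raise IndexError("token id exceeds vocabulary size")
    return embedding[ids]


def lstm_step(x_t: np.ndarray, prev: LSTMState, w: LSTMWeights) -> LSTMState:
    """One LSTM recurrence: gates, memory update, hidden update."""
    i = sigmoid(prev.h @ w.W_hi + x_t @ w.W_xi + w.b_i)
    f = sigmoid(prev.h @ w.W_hf + x_t @ w.W_xf + w.b_f)
    o = sigmoid(prev.h @ w.W_ho + x_t @ w.W_xo + w.b_o)
    g = np.tanh(prev.h @ w.W_hg + x_t @ w.W_xg + w.b_g)
    c = f * prev.c + i * g
    h = o * np.tanh(c)
    return LSTMState(h=h, c=c)


def initial_state(hidden_units: int) -> LSTMState:
    return LSTMState(h=np.zeros(hidden_units), c=np.zeros(hidden_units))


def lstm_forward(embedded: np.ndarray, w: LSTMWeights) -> np.ndarray:
    """Run the recurrence over a (T, v) sequence from the zero state -> (T, L)."""
    T = embedded.shape[0]
    L = w.W_hi.shape[0]
    state = initial_state(L)
    hidden = np.empty((T, L))
    for t in range(T):
        state = lstm_step(embedded[t], state, w)
        hidden[t] = state.h
    return hidden


def flatten_dense(hidden: np.ndarray, W_d: np.ndarray, b_d: np.ndarray) -> np.ndarray:
    """Row-major flatten to T·L, affine map, softmax (P > 1) or sigmoid (P = 1)."""
    flat = np.ravel(hidden)
    if W_d.shape[0] != flat.shape[0]:
        raise ValidationError(
            f"dense weights expect input {W_d.shape[0]}, got flattened size {flat.shape[0]}"
        )
    z = flat @ W_d + b_d
    return softmax(z) if W_d.shape[1] > 1 else sigmoid(z)


# ---------------------------------------------------------------------------
# batched training path

def init_params(config: ModelConfig, seed: int) -> dict[str, np.ndarray]:
    """Seeded random initialization; forget-gate bias starts at 1 so the cell
    retains memory early in training."""
    rng = np.random.default_rng(seed)
    V, v, T, L, P = (config.vocab_size, config.embed_dim, config.max_len,
                     config.hidden_units, config.n_classes)
    u = lambda *shape: rng.uniform(-0.08, 0.08, size=shape)
    params: dict[str, np.ndarray] = {"E": rng.uniform(-0.05, 0.05, size=(V, v))}
    for g in _GATES:
        params[f"W_x{g}"] = u(v, L)
        params[f"W_h{g}"] = u(L, L)
        params[f"b_{g}"] = np.zeros(L)
    params["b_f"] = np.ones(L)
    params["W_d"] = u(T * L, P)
    params["b_d"] = np.zeros(P)
    params["W_seg"] = u(T * L)
    params["b_seg"] = np.zeros(1)
    return params


def _forward_batch(params: dict[str, np.ndarray], ids: np.ndarray) -> dict[str, np.ndarray]:
    """Forward pass for (n, T) id batches, caching everything BPTT needs."""
    n, T = ids.shape
    L = params["W_hi"].shape[0]
    x = params["E"][ids]  # (n, T, v)
    gates = {g: np.empty((n, T, L)) for g in _GATES}
    c_all = np.empty((n, T, L))
    h_all = np.empty((n, T, L))
    h = np.zeros((n, L))
    c = np.zeros((n, L))
    for t in range(T):
        xt = x[:, t]
        i = sigmoid(h @ params["W_hi"] + xt @ params["W_xi"] + params["b_i"])
        f = sigmoid(h @ params["W_hf"] + xt @ params["W_xf"] + params["b_f"])
        o = sigmoid(h @ params["W_ho"] + xt @ params["W_xo"] + params["b_o"])
        g = np.tanh(h @ params["W_hg"] + xt @ params["W_xg"] + params["b_g"])
        c = f * c + i * g
        h = o * np.tanh(c)
        gates["i"][:, t], gates["f"][:, t], gates["o"][:, t], gates["g"][:, t] = i, f, o, g
        c_all[:, t] = c
        h_all[:, t] = h
    flat = h_all.reshape(n, -1)
    logits = flat @ params["W_d"] + params["b_d"]
    probs = softmax(logits) if params["W_d"].shape[1] > 1 else sigmoid(logits)
    return {"x": x, "ids": ids, **{f"gate_{g}": gates[g] for g in _GATES},
            "c": c_all, "h": h_all, "flat": flat, "probs": probs}


def loss_and_grads(
    params: dict[str, np.ndarray], ids: np.ndarray, labels: np.ndarray
) -> tuple[float, dict[str, np.ndarray]]:
    """Mean cross-entropy on one batch and its analytic gradients.

    Categorical cross-entropy against integer labels for P > 1, binary
    cross-entropy against 0/1 labels for P = 1.
    """
    cache = _forward_batch(params, ids)
    n, T = ids.shape
    P = params["W_d"].shape[1]
    probs = cache["probs"]
    eps = 1e-12
    if P > 1:
        loss = -float(np.mean(np.log(probs[np.arange(n), labels] + eps)))
        dlogits = probs.copy()
        dlogits[np.arange(n), labels] -= 1.0
        dlogits /= n
    else:
        y = labels.reshape(n, 1).astype(float)
        loss = -float(np.mean(y * np.log(probs + eps) + (1 - y) * np.log(1 - probs + eps)))
        dlogits = (probs - y) / n

    grads = {k: np.zeros_like(v) for k, v in params.items()}
    grads["W_d"] = cache["flat"].T @ dlogits
    grads["b_d"] = dlogits.sum(axis=0)
    dH = (dlogits @ params["W_d"].T).reshape(cache["h"].shape)

    i, f, o, g = (cache[f"gate_{k}"] for k in _GATES)
    c = cache["c"]
    h = cache["h"]
    x = cache["x"]
    tanh_c = np.tanh(c)
    L = params["W_hi"].shape[0]
    dh_next = np.zeros((n, L))
    dc_next = np.zeros((n, L))
    dx = np.empty_like(x)
    for t in range(ids.shape[1] - 1, -1, -1):
        dh = dH[:, t] + dh_next
        do = dh * tanh_c[:, t]
        dc = dh * o[:, t] * (1.0 - tanh_c[:, t] ** 2) + dc_next
        di = dc * g[:, t]
        dg = dc * i[:, t]
        c_prev = c[:, t - 1] if t > 0 else np.zeros((n, L))
        h_prev = h[:, t - 1] if t > 0 else np.zeros((n, L))
        df = dc * c_prev
        dc_next = dc * f[:, t]
        da = {
            "i": di * i[:, t] * (1.0 - i[:, t]),
            "f": df * f[:, t] * (1.0 - f[:, t]),
            "o": do * o[:, t] * (1.0 - o[:, t]),
            "g": dg * (1.0 - g[:, t] ** 2),
        }
        dh_next = np.zeros((n, L))
        dx_t = np.zeros((n, x.shape[2]))
        for k in _GATES:
            grads[f"W_x{k}"] += x[:, t].T @ da[k]
            grads[f"W_h{k}"] += h_prev.T @ da[k]
            grads[f"b_{k}"] += da[k].sum(axis=0)
            dh_next += da[k] @ params[f"W_h{k}"].T
            dx_t += da[k] @ params[f"W_x{k}"].T
        dx[:, t] = dx_t
    np.add.at(grads["E"], ids.ravel(), dx.reshape(-1, x.shape[2]))
    return loss, grads


def _clip_global_norm(grads: dict[str, np.ndarray], max_norm: float) -> None:
    total = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
    if total > max_norm:
        scale = max_norm / total
        for g in grads.values():
            g *= scale


@dataclass
class TrainedModel:
    """All learned parameters plus the configuration and per-epoch loss log."""

    config: ModelConfig
    params: dict[str, np.ndarray]
    loss_history: list[float] = field(default_factory=list)
    seed: int = 0
    boundary_threshold: float = 0.5

    @property
    def lstm_weights(self) -> LSTMWeights:
        p = self.params
        return LSTMWeights(
            W_hi=p["W_hi"], W_hf=p["W_hf"], W_ho=p["W_ho"], W_hg=p["W_hg"],
            W_xi=p["W_xi"], W_xf=p["W_xf"], W_xo=p["W_xo"], W_xg=p["W_xg"],
            b_i=p["b_i"], b_f=p["b_f"], b_o=p["b_o"], b_g=p["b_g"],
        )

    def hidden_flat(self, ids: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Flattened (n, T·L) LSTM output for a batch of id sequences."""
        ids = np.atleast_2d(ids)
        out = np.empty((ids.shape[0], self.config.max_len * self.config.hidden_units))
        for lo in range(0, ids.shape[0], batch_size):
            out[lo : lo + batch_size] = _forward_batch(self.params, ids[lo : lo + batch_size])["flat"]
        return out

    def predict_proba(self, ids: np.ndarray, batch_size: int = 256) -> np.ndarray:
        ids = np.atleast_2d(ids)
        out = np.empty((ids.shape[0], self.config.n_classes))
        for lo in range(0, ids.shape[0], batch_size):
            out[lo : lo + batch_size] = _forward_batch(self.params, ids[lo : lo + batch_size])["probs"]
        return out


def train(
    samples: Sequence[DailySample],
    config: ModelConfig,
    epochs: int = 20,
    seed: int = 0,
    learning_rate: float = 0.01,
    batch_size: int = 64,
    clip_norm: float = 5.0,
) -> TrainedModel:
    """Mini-batch gradient descent on the cross-entropy loss.

    Deterministic given ``seed`` (weight init and batch shuffling share one
    generator).  The per-epoch mean loss is recorded in ``loss_history``.
    """
    if not samples:
        raise ValidationError("cannot train on an empty sample list")
    ids, labels = sample_matrix(samples)
    return train_arrays(ids, labels, config, epochs=epochs, seed=seed,
                        learning_rate=learning_rate, batch_size=batch_size,
                        clip_norm=clip_norm)


def train_arrays(
    ids: np.ndarray,
    labels: np.ndarray,
    config: ModelConfig,
    epochs: int = 20,
    seed: int = 0,
    learning_rate: float = 0.01,
    batch_size: int = 64,
    clip_norm: float = 5.0,
) -> TrainedModel:
    n = ids.shape[0]
    if n == 0:
        raise ValidationError("cannot train on an empty sample list")
    if config.n_classes > 1 and len(np.unique(labels)) < 2:
        raise ValidationError("multi-class training requires at least 2 classes present")
    if ids.shape[1] != config.max_len:
        raise ValidationError(f"samples have length {ids.shape[1]}, config.max_len={config.max_len}")
    config = ModelConfig(**{**config.__dict__,
                            "n_samples": n,
                            "n_windows": max(1, n // config.window_days)})
    params = init_params(config, seed)
    rng = np.random.default_rng(seed + 1)
    history: list[float] = []
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, batch_size):
            batch = order[lo : lo + batch_size]
            loss, grads = loss_and_grads(params, ids[batch], labels[batch])
            _clip_global_norm(grads, clip_norm)
            for k in params:
                if k not in ("W_seg", "b_seg"):
                    params[k] -= learning_rate * grads[k]
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return TrainedModel(config=config, params=params, loss_history=history, seed=seed)


def predict_window(model: TrainedModel, token_ids: np.ndarray) -> tuple[int, np.ndarray]:
    """Predicted death-window class and full probability vector for one sample.

    Ties break toward the smaller class id (the window closer to death).
    """
    probs = model.predict_proba(np.asarray(token_ids))[0]
    return int(np.argmax(probs)), probs


# ---------------------------------------------------------------------------
# irregular time-lapse boundary head

def _window_mean_features(
    model: TrainedModel, window_ids: Sequence[np.ndarray]
) -> tuple[list[np.ndarray | None], list[np.ndarray | None]]:
    """Per-window mean flattened hidden state and mean class distribution.

    Empty windows yield ``None`` entries.
    """
    feats: list[np.ndarray | None] = []
    probs: list[np.ndarray | None] = []
    for ids in window_ids:
        if len(ids) == 0:
            feats.append(None)
            probs.append(None)
        else:
            arr = np.asarray(ids)
            feats.append(model.hidden_flat(arr).mean(axis=0))
            probs.append(model.predict_proba(arr).mean(axis=0))
    return feats, probs


def fit_boundary_head(
    model: TrainedModel,
    window_ids: Sequence[np.ndarray],
    shift_threshold: float = 0.3,
    learning_rate: float = 0.5,
    epochs: int = 300,
) -> TrainedModel:
    """Train the dedicated sigmoid boundary head, self-supervised.

    The head scores the *change* between consecutive initial windows: its
    input for window ``j`` is the difference between the mean flattened LSTM
    outputs of windows ``j`` and ``j-1``.  Training targets come from the
    classifier itself: window ``j`` is labelled a boundary when the total
    variation between the mean predicted class distributions of windows
    ``j`` and ``j-1`` reaches ``shift_threshold``.  Gradient descent on the
    binary cross-entropy; deterministic.
    """
    feats, probs = _window_mean_features(model, window_ids)
    X, y = [], []
    prev = 0 if feats and feats[0] is not None else None
    for j in range(1, len(window_ids)):
        if feats[j] is None:
            continue
        if prev is not None:
            tv = 0.5 * float(np.abs(probs[j] - probs[prev]).sum())
            X.append(feats[j] - feats[prev])
            y.append(1.0 if tv >= shift_threshold else 0.0)
        prev = j
    # fall back to predicting "no boundary" when there is nothing to fit
    if X:
        Xm = np.stack(X)
        yv = np.array(y)
        w = model.params["W_seg"]
        b = model.params["b_seg"]
        for _ in range(epochs):
            p = sigmoid(Xm @ w + b[0])
            dz = (p - yv) / len(yv)
            w -= learning_rate * (Xm.T @ dz)
            b -= learning_rate * dz.sum()
    return model


def segment_signal(model: TrainedModel, window_ids: Sequence[np.ndarray]) -> np.ndarray:
    """Binary boundary signal over N consecutive initial windows.

    ``window_ids[j]`` holds the (n_j, T) id sequences of the j-th B-day
    window before death (window 0 adjacent to death).  Window 0 always opens
    a segment; window ``j > 0`` opens one when the sigmoid head applied to
    the change in mean flattened LSTM output since the previous non-empty
    window exceeds the 0.5 threshold.  Empty windows never open a segment.
    """
    feats, _ = _window_mean_features(model, window_ids)
    signal = np.zeros(len(window_ids), dtype=int)
    if len(window_ids) == 0:
        raise ValidationError("need at least one window")
    signal[0] = 1
    w = model.params["W_seg"]
    b = model.params["b_seg"]
    prev = 0 if feats[0] is not None else None
    for j in range(1, len(window_ids)):
        if feats[j] is None:
            continue
        if prev is not None:
            p = sigmoid(float(feats[j] @ w - feats[prev] @ w + b[0]))
            if p >= model.boundary_threshold:
                signal[j] = 1
        prev = j
    return signal


# ---------------------------------------------------------------------------
# checkpoint format: magic line, JSON header, raw little-endian float64 blocks

_MAGIC = b"COPDATLAS-MODEL-1\n"


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Single-file checkpoint: JSON header then the arrays in a fixed order."""
    header = {
        "config": {k: v for k, v in model.config.__dict__.items()},
        "seed": model.seed,
        "boundary_threshold": model.boundary_threshold,
        "loss_history": model.loss_history,
        "arrays": [
            {"name": k, "shape": list(model.params[k].shape)} for k in _PARAM_KEYS
        ],
    }
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(json.dumps(header, sort_keys=True).encode("utf-8"))
        fh.write(b"\n\x00")
        for k in _PARAM_KEYS:
            fh.write(np.ascontiguousarray(model.params[k], dtype="<f8").tobytes())


def load_model(path: str | Path) -> TrainedModel:
    raw = Path(path).read_bytes()
    if not raw.startswith(_MAGIC):
        raise ValidationError("not a model checkpoint")
    body = raw[len(_MAGIC):]
    sep = body.index(b"\n\x00")
    header = json.loads(body[:sep].decode("utf-8"))
    blob = body[sep + 2:]
    params: dict[str, np.ndarray] = {}
    offset = 0
    for spec in header["arrays"]:
        shape = tuple(spec["shape"])
        count = int(np.prod(shape)) if shape else 1
        arr = np.frombuffer(blob, dtype="<f8", count=count, offset=offset).reshape(shape)
        params[spec["name"]] = arr.copy()
        offset += count * 8
    config = ModelConfig(**header["config"])
    expected = {
        "E": (config.vocab_size, config.embed_dim),
        "W_d": (config.max_len * config.hidden_units, config.n_classes),
    }
    for name, shape in expected.items():
        if params[name].shape != shape:
            raise ValidationError(f"checkpoint array {name} has shape "
                                  f"{params[name].shape}, expected {shape}")
    return TrainedModel(
        config=config,
        params=params,
        loss_history=list(header["loss_history"]),
        seed=int(header["seed"]),
        boundary_threshold=float(header["boundary_threshold"]),
    )
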
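"""A compact numpy CNN-LSTM for sequences of 8x8 thermal frames.

Each 40-frame record is treated as a short video.  Three 3x3 convolutional
layers (16, 32, 32 filters; same padding, ReLU, no pooling — the frames are
only 8x8) are applied identically to every frame; the per-frame activations
are flattened and fed through two stacked LSTM layers of 32 units, and the
final hidden state drives a softmax over activity classes.  Training uses
Adam on the cross-entropy loss with mini-batches (default 32); the reference
setting is 1000 epochs, reducible for quick runs.

Forward and backward passes are written directly in numpy (im2col
convolutions, truncated-nothing BPTT through the full 40 steps), so runs are
bit-reproducible on CPU given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FRAME_SHAPE = (8, 8)
SEQ_LEN = 40


@dataclass
class NetConfig:
    conv_filters: tuple[int, ...] = (16, 32, 32)
    kernel: int = 3
    lstm_units: tuple[int, ...] = (32, 32)
    epochs: int = 1000
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.conv_filters) or any(u <= 0 for u in self.lstm_units):
            raise ValueError("layer sizes must be positive")
        if self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("epochs and batch size must be positive")


class _Conv2DSame:
    """3x3 same-padding convolution + ReLU over (N, 8, 8, Cin) via im2col."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        fan_in, fan_out = k * k * cin, k * k * cout
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        self.W = rng.uniform(-limit, limit, size=(k * k * cin, cout))
        self.b = np.zeros(cout)
        self.k, self.cin, self.cout = k, cin, cout

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, h, w, cin = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        cols = np.empty((n, h, w, self.k * self.k * cin))
        for idx, (di, dj) in enumerate(
            (i, j) for i in range(self.k) for j in range(self.k)
        ):
            cols[..., idx * cin : (idx + 1) * cin] = xp[:, di : di + h, dj : dj + w, :]
        return cols

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        cols = self._im2col(x)
        pre = cols.reshape(-1, cols.shape[-1]) @ self.W + self.b
        out = np.maximum(pre, 0.0).reshape(*x.shape[:3], self.cout)
        if train:
            self._cache = (cols, out, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, out, xshape = self._cache
        dpre = (dout * (out > 0)).reshape(-1, self.cout)
        colsf = cols.reshape(-1, cols.shape[-1])
        self.dW = colsf.T @ dpre
        self.db = dpre.sum(axis=0)
        dcols = (dpre @ self.W.T).reshape(cols.shape)
        n, h, w, cin = xshape
        p = self.k // 2
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, cin))
        for idx, (di, dj) in enumerate(
            (i, j) for i in range(self.k) for j in range(self.k)
        ):
            dxp[:, di : di + h, dj : dj + w, :] += dcols[..., idx * cin : (idx + 1) * cin]
        return dxp[:, p : p + h, p : p + w, :]

    def params(self):
        return [("W", self), ("b", self)]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class _LSTM:
    """Standard LSTM; gate order [i, f, g, o], zero initial state."""

    def __init__(self, din: int, units: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (din + units))
        self.Wx = rng.uniform(-limit, limit, size=(din, 4 * units))
        self.Wh = rng.uniform(-limit, limit, size=(units, 4 * units))
        self.b = np.zeros(4 * units)
        self.b[units : 2 * units] = 1.0  # forget-gate bias, standard init
        self.units, self.din = units, din

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, T, _ = x.shape
        u = self.units
        h = np.zeros((n, u))
        c = np.zeros((n, u))
        hs = np.empty((n, T, u))
        caches = []
        for t in range(T):
            z = x[:, t] @ self.Wx + h @ self.Wh + self.b
            i = _sigmoid(z[:, :u])
            f = _sigmoid(z[:, u : 2 * u])
            g = np.tanh(z[:, 2 * u : 3 * u])
            o = _sigmoid(z[:, 3 * u :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            if train:
                caches.append((x[:, t], h, c, i, f, g, o, c_new, tc))
            h, c = h_new, c_new
            hs[:, t] = h
        if train:
            self._caches = caches
        return hs

    def backward(self, dhs: np.ndarray) -> np.ndarray:
        n, T, _ = dhs.shape
        u = self.units
        self.dWx = np.zeros_like(self.Wx)
        self.dWh = np.zeros_like(self.Wh)
        self.db = np.zeros_like(self.b)
        dx = np.empty((n, T, self.din))
        dh_next = np.zeros((n, u))
        dc_next = np.zeros((n, u))
        for t in range(T - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, c_new, tc = self._caches[t]
            dh = dhs[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1 - tc**2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
                axis=1,
            )
            self.dWx += x_t.T @ dz
            self.dWh += h_prev.T @ dz
            self.db += dz.sum(axis=0)
            dx[:, t] = dz @ self.Wx.T
            dh_next = dz @ self.Wh.T
            dc_next = dc * f
        return dx

    def params(self):
        return [("Wx", self), ("Wh", self), ("b", self)]


class _Dense:
    def __init__(self, din: int, dout: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (din + dout))
        self.W = rng.uniform(-limit, limit, size=(din, dout))
        self.b = np.zeros(dout)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.W.T

    def params(self):
        return [("W", self), ("b", self)]


class CNNLSTM:
    """Time-distributed conv stack + stacked LSTMs + softmax head."""

    def __init__(self, config: NetConfig, n_classes: int):
        if n_classes < 2:
            raise ValueError("need at least 2 classes")
        self.config = config
        self.n_classes = n_classes
        rng = np.random.default_rng(config.seed)
        self.convs = []
        cin = 1
        for cout in config.conv_filters:
            self.convs.append(_Conv2DSame(cin, cout, config.kernel, rng))
            cin = cout
        feat_dim = FRAME_SHAPE[0] * FRAME_SHAPE[1] * cin
        self.lstms = []
        din = feat_dim
        for units in config.lstm_units:
            self.lstms.append(_LSTM(din, units, rng))
            din = units
        self.head = _Dense(din, n_classes, rng)
        self.classes: np.ndarray | None = None
        self.norm_mean = 0.0
        self.norm_std = 1.0

    # -- forward / backward -------------------------------------------------
    def _forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, T = x.shape[:2]
        a = ((x - self.norm_mean) / self.norm_std).reshape(n * T, *FRAME_SHAPE, 1)
        for conv in self.convs:
            a = conv.forward(a, train=train)
        a = a.reshape(n, T, -1)
        for lstm in self.lstms:
            a = lstm.forward(a, train=train)
        self._T = T
        logits = self.head.forward(a[:, -1, :], train=train)
        return logits

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        logits = self._forward(np.asarray(x, float), train=False)
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, x: np.ndarray) -> np.ndarray:
        idx = np.argmax(self.predict_proba(x), axis=1)
        if self.classes is not None:
            return self.classes[idx]
        return idx

    def _backward(self, dlogits: np.ndarray) -> None:
        dh_last = self.head.backward(dlogits)
        n = dh_last.shape[0]
        da = np.zeros((n, self._T, self.lstms[-1].units))
        da[:, -1, :] = dh_last
        for lstm in reversed(self.lstms):
            da = lstm.backward(da)
        a = da.reshape(n * self._T, *FRAME_SHAPE, self.convs[-1].cout)
        for conv in reversed(self.convs):
            a = conv.backward(a)

    def _layers(self):
        return [*self.convs, *self.lstms, self.head]


def build_model(config: NetConfig, n_classes: int) -> CNNLSTM:
    """Seeded construction; two builds with equal seeds give equal outputs."""
    return CNNLSTM(config, n_classes)


class _Adam:
    def __init__(self, layers, lr: float):
        self.entries = [entry for layer in layers for entry in layer.params()]
        self.lr = lr
        self.m = [np.zeros_like(getattr(l, n)) for n, l in self.entries]
        self.v = [np.zeros_like(getattr(l, n)) for n, l in self.entries]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for i, (name, layer) in enumerate(self.entries):
            g = getattr(layer, "d" + name)
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g**2
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p = getattr(layer, name)
            setattr(layer, name, p - self.lr * mhat / (np.sqrt(vhat) + eps))


def train_model(
    model: CNNLSTM, frames: np.ndarray, labels: np.ndarray, config: NetConfig | None = None
) -> tuple[CNNLSTM, np.ndarray]:
    """Train on (Z, 40, 8, 8) sequences; returns the model and the loss curve.

    Standardization (scalar mean/std of the training temperatures) is fitted
    here and stored on the model.  Mini-batch order is reshuffled each epoch
    from the config seed, so runs are reproducible.
    """
    config = config or model.config
    frames = np.asarray(frames, float)
    labels = np.asarray(labels)
    if len(frames) == 0:
        raise ValueError("empty training set")
    classes = np.unique(labels)
    if len(classes) != model.n_classes:
        raise ValueError(
            f"labels have {len(classes)} classes but model was built for {model.n_classes}"
        )
    model.classes = classes
    y_idx = np.searchsorted(classes, labels)
    model.norm_mean = float(frames.mean())
    model.norm_std = float(frames.std()) or 1.0

    rng = np.random.default_rng(config.seed + 1)
    opt = _Adam(model._layers(), config.learning_rate)
    n = len(frames)
    losses = np.empty(config.epochs)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            logits = model._forward(frames[idx], train=True)
            logits = logits - logits.max(axis=1, keepdims=True)
            p = np.exp(logits)
            p /= p.sum(axis=1, keepdims=True)
            yi = y_idx[idx]
            batch_loss = -np.mean(np.log(p[np.arange(len(idx)), yi] + 1e-12))
            epoch_loss += batch_loss * len(idx)
            dlogits = p.copy()
            dlogits[np.arange(len(idx)), yi] -= 1.0
            dlogits /= len(idx)
            model._backward(dlogits)
            opt.step()
        losses[epoch] = epoch_loss / n
    return model, losses


def evaluate_model(
    model: CNNLSTM, frames: np.ndarray, labels: np.ndarray
) -> tuple[float, pd.DataFrame]:
    """Accuracy and confusion matrix (rows = true class) on held-out samples."""
    frames = np.asarray(frames, float)
    labels = np.asarray(labels)
    if len(frames) == 0:
        raise ValueError("empty evaluation set")
    pred = model.predict(frames)
    classes = model.classes if model.classes is not None else np.unique(labels)
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    lut = {c: i for i, c in enumerate(classes)}
    for t, p in zip(labels, pred):
        cm[lut[t], lut[p]] += 1
    acc = float(np.trace(cm) / cm.sum())
    return acc, pd.DataFrame(cm, index=classes, columns=classes)
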
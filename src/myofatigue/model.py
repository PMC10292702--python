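"""Fatigue-state classification from labeled SEMG windows.

The reference classifier is a single-layer LSTM (100 units) over the raw
window, downsampled to a fixed number of time steps, with a ReLU dense
stage and a sigmoid output, trained with Adam (batch size 70, learning rate
1e-3) and early stopping on a validation carve-out.  Baselines: an RBF-kernel
SVM and a one-hidden-layer back-propagation network (BPNN) on the
(IEMG, RMS, MPF) feature triple, and a small 1-D CNN on the raw window.

The recurrent and convolutional networks are implemented directly in numpy
(forward, back-propagation through time, Adam) with all randomness drawn
from one explicit seed, so two runs with the same seed produce identical
predictions on one machine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from myofatigue.features import Window, iemg, mpf, rms
from myofatigue.synthetic import LabeledWindowSet

BaselineKind = Literal["svm", "bpnn", "cnn"]


# ---------------------------------------------------------------------------
# configuration, splitting, metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrainingConfig:
    """LSTM training configuration (defaults follow the reference setup:
    100 hidden units, ReLU, Adam, batch 70, learning rate 1e-3, early
    stopping)."""

    hidden_units: int = 100
    activation: str = "relu"
    optimizer: str = "adam"
    batch_size: int = 70
    learning_rate: float = 1e-3
    early_stopping_patience: int = 10
    max_epochs: int = 200
    seed: int = 0
    n_time_steps: int = 200  # raw window is block-RMS downsampled to this length
    val_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.early_stopping_patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.7
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


def split_dataset(dataset: LabeledWindowSet,
                  spec: SplitSpec) -> tuple[LabeledWindowSet, LabeledWindowSet]:
    """Disjoint, exhaustive train/eval split with |train| =
    round(train_fraction · n); stratified by label when flagged;
    deterministic given the seed."""
    n = len(dataset)
    if n == 0:
        raise ValueError("dataset is empty")
    if spec.stratified and n < 2:
        raise ValueError("cannot stratify a single-element dataset")
    n_train = int(round(spec.train_fraction * n))
    idx_train, idx_eval = train_test_split(
        np.arange(n),
        train_size=n_train,
        random_state=spec.seed,
        stratify=dataset.labels if spec.stratified else None,
        shuffle=True,
    )
    mk = lambda idx: LabeledWindowSet(dataset.windows[idx], dataset.labels[idx],
                                      dataset.fs)
    return mk(idx_train), mk(idx_eval)


@dataclass(frozen=True)
class EvalMetrics:
    """Confusion-matrix metrics for the binary fatigue label, in percent."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / (self.tp + self.fp + self.tn + self.fn)

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp)

    @property
    def precision(self) -> float:
        if self.tp + self.fp == 0:
            return float("nan")
        return 100.0 * self.tp / (self.tp + self.fp)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "accuracy_pct": self.accuracy, "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity, "precision_pct": self.precision,
        }

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "EvalMetrics":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


def evaluate(model, eval_set: LabeledWindowSet) -> EvalMetrics:
    """Confusion-matrix evaluation of any trained model handle."""
    if len(eval_set) == 0:
        raise ValueError("evaluation set is empty")
    if len(np.unique(eval_set.labels)) < 2:
        raise ValueError("evaluation set must contain both classes")
    preds = model.predict(eval_set.windows)
    return EvalMetrics.from_predictions(eval_set.labels, preds)


# ---------------------------------------------------------------------------
# shared numerics
# ---------------------------------------------------------------------------


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _bce_with_logits(logits: np.ndarray, y: np.ndarray) -> float:
    # numerically stable binary cross-entropy
    return float(np.mean(np.maximum(logits, 0) - logits * y
                         + np.log1p(np.exp(-np.abs(logits)))))


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _clip_grads(grads: dict[str, np.ndarray], max_norm: float = 5.0) -> None:
    total = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
    if total > max_norm:
        scale = max_norm / total
        for g in grads.values():
            g *= scale


def _downsample(windows: np.ndarray, n_steps: int,
                how: Literal["mean", "rms"] = "mean") -> np.ndarray:
    """Downsample each window to ``n_steps`` time steps by block mean or
    block RMS.  Block RMS preserves the amplitude envelope, which a
    zero-mean band-limited signal loses under plain block averaging."""
    n, L = windows.shape
    if L < n_steps:
        reps = -(-n_steps // L)
        windows = np.repeat(windows, reps, axis=1)
        L = windows.shape[1]
    usable = (L // n_steps) * n_steps
    blocks = windows[:, :usable].reshape(n, n_steps, -1)
    if how == "rms":
        return np.sqrt((blocks**2).mean(axis=2))
    return blocks.mean(axis=2)


def _val_carve(X: np.ndarray, y: np.ndarray, frac: float,
               rng: np.random.Generator):
    n = len(y)
    n_val = max(1, int(round(frac * n)))
    order = rng.permutation(n)
    val, tr = order[:n_val], order[n_val:]
    return X[tr], y[tr], X[val], y[val]


# ---------------------------------------------------------------------------
# LSTM (numpy)
# ---------------------------------------------------------------------------


class LSTMClassifier:
    """Single-layer LSTM over the downsampled raw window, ReLU dense stage,
    sigmoid output; trained with Adam and early stopping."""

    def __init__(self, config: TrainingConfig):
        self.config = config
        self.params: dict[str, np.ndarray] = {}
        self.scale_: float = 1.0
        self.stopped_epoch: int | None = None
        self.best_val_loss: float = np.inf
        self.final_val_loss: float = np.inf
        self.history: list[float] = []

    # -- internals ---------------------------------------------------------

    def _init_params(self, rng: np.random.Generator) -> None:
        H = self.config.hidden_units
        s = 1.0 / np.sqrt(H)
        self.params = {
            "Wx": rng.uniform(-s, s, size=(1, 4 * H)),
            "Wh": rng.uniform(-s, s, size=(H, 4 * H)),
            "b": np.zeros(4 * H),
            "W2": rng.uniform(-s, s, size=(H, 1)),
            "b2": np.zeros(1),
        }
        # forget-gate bias starts at 1 for stable early training
        self.params["b"][H: 2 * H] = 1.0

    def _forward(self, X: np.ndarray, cache: bool = False):
        """X: (B, T) normalized. Returns logits (B,) and optional cache."""
        p = self.params
        H = self.config.hidden_units
        B, T = X.shape
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        steps = []
        for t in range(T):
            z = X[:, t: t + 1] @ p["Wx"] + h @ p["Wh"] + p["b"]
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H: 2 * H])
            g = np.tanh(z[:, 2 * H: 3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            if cache:
                steps.append((h, c, i, f, g, o, c_new, tc))
            h, c = h_new, c_new
        a = np.maximum(h, 0.0)
        logits = (a @ p["W2"] + p["b2"]).ravel()
        if cache:
            return logits, (X, steps, h, a)
        return logits

    def _backward(self, logits: np.ndarray, y: np.ndarray, cache) -> dict:
        p = self.params
        H = self.config.hidden_units
        X, steps, h_T, a = cache
        B, T = X.shape
        dlogit = (_sigmoid(logits) - y)[:, None] / B
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        grads["W2"] = a.T @ dlogit
        grads["b2"] = dlogit.sum(0)
        dh = (dlogit @ p["W2"].T) * (h_T > 0)
        dc = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, c_new, tc = steps[t]
            do = dh * tc
            dc = dc + dh * o * (1 - tc**2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f),
                 dg * (1 - g**2), do * o * (1 - o)], axis=1)
            grads["Wx"] += X[:, t: t + 1].T @ dz
            grads["Wh"] += h_prev.T @ dz
            grads["b"] += dz.sum(0)
            dh = dz @ p["Wh"].T
            dc = dc * f
        return grads

    def _prep(self, windows: np.ndarray) -> np.ndarray:
        X = _downsample(np.asarray(windows, float), self.config.n_time_steps,
                        how="rms")
        return X / self.scale_

    # -- public API --------------------------------------------------------

    def fit(self, train: LabeledWindowSet) -> "LSTMClassifier":
        cfg = self.config
        if len(np.unique(train.labels)) < 2:
            raise ValueError("training set must contain both classes")
        rng = np.random.default_rng(cfg.seed)
        self._init_params(rng)
        X_all = _downsample(train.windows, cfg.n_time_steps, how="rms")
        self.scale_ = float(X_all.std()) or 1.0
        X_all = X_all / self.scale_
        y_all = train.labels.astype(float)
        X, y, Xv, yv = _val_carve(X_all, y_all, cfg.val_fraction, rng)

        opt = _Adam(self.params, cfg.learning_rate)
        best = {k: v.copy() for k, v in self.params.items()}
        best_loss, patience_left = np.inf, cfg.early_stopping_patience
        for epoch in range(1, cfg.max_epochs + 1):
            order = rng.permutation(len(y))
            for s in range(0, len(y), cfg.batch_size):
                idx = order[s: s + cfg.batch_size]
                logits, cache = self._forward(X[idx], cache=True)
                grads = self._backward(logits, y[idx], cache)
                _clip_grads(grads)
                opt.step(grads)
            val_loss = _bce_with_logits(self._forward(Xv), yv)
            self.history.append(val_loss)
            self.stopped_epoch = epoch
            if val_loss < best_loss - 1e-6:
                best_loss = val_loss
                best = {k: v.copy() for k, v in self.params.items()}
                patience_left = cfg.early_stopping_patience
            else:
                patience_left -= 1
                if patience_left == 0:
                    break
        self.final_val_loss = self.history[-1]
        self.best_val_loss = best_loss
        self.params = best
        return self

    def predict_proba(self, windows: np.ndarray) -> np.ndarray:
        return _sigmoid(self._forward(self._prep(windows)))

    def predict(self, windows: np.ndarray) -> np.ndarray:
        return (self.predict_proba(windows) >= 0.5).astype(int)


def train_lstm(train: LabeledWindowSet,
               config: TrainingConfig = TrainingConfig()) -> LSTMClassifier:
    """Train the LSTM fatigue classifier; returns a handle with ``predict``."""
    return LSTMClassifier(config).fit(train)


# ---------------------------------------------------------------------------
# baselines
# ---------------------------------------------------------------------------


def window_features(windows: np.ndarray, fs: float) -> np.ndarray:
    """(IEMG, RMS, MPF) per window — the classical feature triple."""
    feats = []
    for w in np.asarray(windows, float):
        win = Window(w, fs, 0.0)
        feats.append([iemg(win), rms(win), mpf(win, (20.0, min(500.0, fs / 2 * 0.999)))])
    return np.asarray(feats)


class MajorityClassModel:
    """Fallback for degenerate (constant-feature) training data."""

    degenerate = True

    def __init__(self, label: int):
        self.label = int(label)

    def predict(self, windows: np.ndarray) -> np.ndarray:
        return np.full(len(windows), self.label, dtype=int)


class FeatureModel:
    """SVM or BPNN on the (IEMG, RMS, MPF) triple."""

    degenerate = False

    def __init__(self, kind: Literal["svm", "bpnn"], fs: float, seed: int = 0):
        if kind == "svm":
            est = SVC(kernel="rbf", random_state=seed)
        else:
            est = MLPClassifier(hidden_layer_sizes=(32,), activation="relu",
                                solver="adam", max_iter=800, random_state=seed)
        self.kind = kind
        self.fs = fs
        self.pipe = make_pipeline(StandardScaler(), est)

    def fit_features(self, X: np.ndarray, y: np.ndarray) -> "FeatureModel":
        self.pipe.fit(X, y)
        return self

    def fit(self, train: LabeledWindowSet) -> "FeatureModel":
        X = window_features(train.windows, train.fs)
        self.fit_features(X, train.labels)
        return self

    def predict_features(self, X: np.ndarray) -> np.ndarray:
        return self.pipe.predict(X).astype(int)

    def predict(self, windows: np.ndarray) -> np.ndarray:
        return self.predict_features(window_features(windows, self.fs))


class CNNClassifier:
    """Small 1-D convolutional network on the block-RMS downsampled window
    (amplitude envelope): two strided conv+ReLU stages, global average
    pooling, sigmoid output."""

    degenerate = False

    def __init__(self, seed: int = 0, n_time_steps: int = 200,
                 learning_rate: float = 1e-2, batch_size: int = 70,
                 max_epochs: int = 60, patience: int = 10,
                 channels: tuple[int, int] = (8, 16),
                 kernels: tuple[int, int] = (9, 5),
                 strides: tuple[int, int] = (4, 4)):
        self.seed = seed
        self.n_time_steps = n_time_steps
        self.lr, self.batch_size = learning_rate, batch_size
        self.max_epochs, self.patience = max_epochs, patience
        self.channels, self.kernels, self.strides = channels, kernels, strides
        self.scale_ = 1.0
        self.params: dict[str, np.ndarray] = {}
        self.stopped_epoch: int | None = None

    def _init_params(self, rng: np.random.Generator) -> None:
        c1, c2 = self.channels
        k1, k2 = self.kernels
        self.params = {
            "K1": rng.normal(0, np.sqrt(2.0 / k1), size=(c1, 1, k1)),
            "b1": np.zeros(c1),
            "K2": rng.normal(0, np.sqrt(2.0 / (k2 * c1)), size=(c2, c1, k2)),
            "b2": np.zeros(c2),
            "W": rng.normal(0, np.sqrt(1.0 / c2), size=(c2, 1)),
            "b": np.zeros(1),
        }

    @staticmethod
    def _conv(x: np.ndarray, K: np.ndarray, b: np.ndarray, stride: int):
        k = K.shape[2]
        win = np.lib.stride_tricks.sliding_window_view(x, k, axis=2)[:, :, ::stride]
        y = np.einsum("bilk,oik->bol", win, K) + b[None, :, None]
        return y, win

    @staticmethod
    def _conv_back(dy: np.ndarray, win: np.ndarray, K: np.ndarray,
                   stride: int, in_len: int):
        dK = np.einsum("bol,bilk->oik", dy, win)
        db = dy.sum(axis=(0, 2))
        B, _, L_out = dy.shape
        dx = np.zeros((B, K.shape[1], in_len))
        for j in range(K.shape[2]):
            dx[:, :, j: j + stride * L_out: stride] += np.einsum(
                "bol,oi->bil", dy, K[:, :, j])
        return dK, db, dx

    def _forward(self, X: np.ndarray, cache: bool = False):
        p = self.params
        x = X[:, None, :]  # (B, 1, T)
        y1, win1 = self._conv(x, p["K1"], p["b1"], self.strides[0])
        a1 = np.maximum(y1, 0)
        y2, win2 = self._conv(a1, p["K2"], p["b2"], self.strides[1])
        a2 = np.maximum(y2, 0)
        pooled = a2.mean(axis=2)
        logits = (pooled @ p["W"] + p["b"]).ravel()
        if cache:
            return logits, (x, win1, y1, a1, win2, y2, a2, pooled)
        return logits

    def _backward(self, logits, y, cache):
        p = self.params
        x, win1, y1, a1, win2, y2, a2, pooled = cache
        B = len(y)
        dlogit = (_sigmoid(logits) - y)[:, None] / B
        grads = {}
        grads["W"] = pooled.T @ dlogit
        grads["b"] = dlogit.sum(0)
        dpool = dlogit @ p["W"].T  # (B, c2)
        da2 = dpool[:, :, None] * np.ones_like(a2) / a2.shape[2]
        dy2 = da2 * (y2 > 0)
        grads["K2"], grads["b2"], da1 = self._conv_back(
            dy2, win2, p["K2"], self.strides[1], a1.shape[2])
        dy1 = da1 * (y1 > 0)
        grads["K1"], grads["b1"], _ = self._conv_back(
            dy1, win1, p["K1"], self.strides[0], x.shape[2])
        return grads

    def fit(self, train: LabeledWindowSet) -> "CNNClassifier":
        if len(np.unique(train.labels)) < 2:
            raise ValueError("training set must contain both classes")
        rng = np.random.default_rng(self.seed)
        self._init_params(rng)
        X_all = _downsample(train.windows, self.n_time_steps, how="rms")
        self.scale_ = float(X_all.std()) or 1.0
        X_all = X_all / self.scale_
        y_all = train.labels.astype(float)
        X, y, Xv, yv = _val_carve(X_all, y_all, 0.1, rng)
        opt = _Adam(self.params, self.lr)
        best = {k: v.copy() for k, v in self.params.items()}
        best_loss, patience_left = np.inf, self.patience
        for epoch in range(1, self.max_epochs + 1):
            order = rng.permutation(len(y))
            for s in range(0, len(y), self.batch_size):
                idx = order[s: s + self.batch_size]
                logits, cache = self._forward(X[idx], cache=True)
                grads = self._backward(logits, y[idx], cache)
                _clip_grads(grads)
                opt.step(grads)
            val_loss = _bce_with_logits(self._forward(Xv), yv)
            self.stopped_epoch = epoch
            if val_loss < best_loss - 1e-6:
                best_loss = val_loss
                best = {k: v.copy() for k, v in self.params.items()}
                patience_left = self.patience
            else:
                patience_left -= 1
                if patience_left == 0:
                    break
        self.params = best
        return self

    def predict(self, windows: np.ndarray) -> np.ndarray:
        X = _downsample(np.asarray(windows, float), self.n_time_steps,
                        how="rms") / self.scale_
        return (_sigmoid(self._forward(X)) >= 0.5).astype(int)


def train_baseline(kind: BaselineKind, train: LabeledWindowSet, seed: int = 0,
                   **kwargs):
    """Train one of the baseline classifiers (svm, bpnn, cnn).

    Degenerate training sets (constant features / constant windows) yield a
    flagged majority-class predictor instead of a fit.
    """
    if len(np.unique(train.labels)) < 2:
        raise ValueError("training set must contain both classes")
    if kind in ("svm", "bpnn"):
        # constant windows have no spectrum (MPF undefined) and constant
        # features carry no signal: fall back to a flagged majority vote
        if np.allclose(train.windows.std(axis=1), 0):
            counts = np.bincount(train.labels, minlength=2)
            return MajorityClassModel(int(np.argmax(counts)))
        X = window_features(train.windows, train.fs)
        if np.allclose(X.std(axis=0), 0):
            counts = np.bincount(train.labels, minlength=2)
            return MajorityClassModel(int(np.argmax(counts)))
        return FeatureModel(kind, train.fs, seed=seed).fit(train)
    if kind == "cnn":
        if np.allclose(train.windows.std(), 0):
            counts = np.bincount(train.labels, minlength=2)
            return MajorityClassModel(int(np.argmax(counts)))
        return CNNClassifier(seed=seed, **kwargs).fit(train)
    raise ValueError(f"unknown baseline kind {kind!r}")
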
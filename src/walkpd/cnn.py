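"""1D convolutional network for per-event PD/HC classification.

Architecture: four convolutional blocks (5-point kernel, stride 2, "same"
padding, no pooling), each block = conv -> batch normalization -> ReLU, with
an L2 penalty on the convolution kernels; channel widths 8, 16, 32, 64. A
50% dropout layer follows the last block; the output is flattened into a
2-unit softmax head trained with cross-entropy (the two-class softmax form
of binary cross-entropy) using Adam. Temporal length halves at every layer
(100 -> 50 -> 25 -> 13 -> 7 for 5-s windows at 20 Hz), while the receptive
field of one final-layer step grows multiplicatively with stride and kernel
to 61 input samples.

The implementation is pure NumPy: forward/backward passes use im2col
convolutions, so training is deterministic given the seed. Per-channel
standardization statistics are computed on training windows only and stored
with the model.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from math import ceil

import numpy as np
import pandas as pd


class ConfigurationError(ValueError):
    pass


class TrainingError(RuntimeError):
    pass


@dataclass
class CNNConfig:
    n_layers: int = 4
    kernel: int = 5
    stride: int = 2
    channels: tuple[int, ...] = (8, 16, 32, 64)
    l2_coeff: float = 1e-4
    dropout_rate: float = 0.5
    padding: str = "same"
    batch_size: int = 64
    max_epochs: int = 50
    #: best-epoch selection on validation loss. The untrained initial state is
    #: a restoration candidate (its validation loss is the baseline): if no
    #: epoch improves on it, the restored model abstains rather than report a
    #: memorized fit. With patience == max_epochs training always runs its full
    #: course and the best epoch is restored afterwards; a smaller patience
    #: stops `patience` epochs after the last improvement (never before
    #: `warmup_epochs` — transferable features emerge late on small cohorts).
    patience: int = 50
    warmup_epochs: int = 30
    #: minimum validation-loss improvement to count as real signal; smaller
    #: fluctuations never displace the abstaining baseline
    min_delta: float = 0.02
    learning_rate: float = 1e-3
    #: orientation canonicalization of the input windows: per-channel mean
    #: removal, axes of each sensor sorted by detrended amplitude, sign fixed
    #: by skewness. Watch orientation differs per subject; without a canonical
    #: axis frame the network (and its batch-norm statistics) would fingerprint
    #: subjects by orientation instead of learning disease-related dynamics.
    canonicalize_orientation: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.channels) != self.n_layers:
            raise ConfigurationError("channels length must equal n_layers")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError("dropout_rate must be in [0, 1)")
        if self.padding != "same":
            raise ConfigurationError("only 'same' padding is supported")


def conv_output_length(length: int, stride: int) -> int:
    """Temporal length after one stride-s 'same' convolution."""
    return ceil(length / stride)


def layer_lengths(input_length: int, cfg: CNNConfig) -> list[int]:
    """Temporal length after each convolutional layer."""
    out, L = [], input_length
    for _ in range(cfg.n_layers):
        L = conv_output_length(L, cfg.stride)
        out.append(L)
    return out


def receptive_field(cfg: CNNConfig) -> int:
    """Input samples influencing one final-layer time step.

    Iterative recurrence r_l = r_{l-1} + (k - 1) * prod(strides before l).
    """
    r, jump = 1, 1
    for _ in range(cfg.n_layers):
        r += (cfg.kernel - 1) * jump
        jump *= cfg.stride
    return r


def _same_pad(L: int, k: int, s: int) -> tuple[int, int, int]:
    L_out = conv_output_length(L, s)
    pad = max((L_out - 1) * s + k - L, 0)
    return L_out, pad // 2, pad - pad // 2


class _Conv1D:
    """Strided same-padded 1D convolution via im2col."""

    def __init__(self, c_in: int, c_out: int, k: int, s: int, rng: np.random.Generator):
        fan_in = c_in * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k))
        self.b = np.zeros(c_out)
        self.k, self.s = k, s

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c_in, L = x.shape
        L_out, pl, pr = _same_pad(L, self.k, self.s)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        # im2col one kernel tap at a time: tap j reads the strided slice
        # xp[..., j::s], so no fancy indexing is needed
        cols = np.empty((n, c_in, L_out, self.k))
        for j in range(self.k):
            cols[:, :, :, j] = xp[:, :, j :: self.s][:, :, :L_out]
        cols = cols.transpose(0, 2, 1, 3).reshape(n * L_out, c_in * self.k)
        out = cols @ self.W.reshape(self.W.shape[0], -1).T + self.b
        self._cache = (cols, x.shape, xp.shape)
        return out.reshape(n, L_out, -1).transpose(0, 2, 1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, x_shape, xp_shape = self._cache
        n, c_in, L = x_shape
        c_out = self.W.shape[0]
        L_out = dout.shape[2]
        d2 = dout.transpose(0, 2, 1).reshape(n * L_out, c_out)
        self.dW = (d2.T @ cols).reshape(self.W.shape)
        self.db = d2.sum(axis=0)
        dcols = (
            (d2 @ self.W.reshape(c_out, -1))
            .reshape(n, L_out, c_in, self.k)
            .transpose(0, 2, 1, 3)
        )
        dxp = np.zeros(xp_shape)
        for j in range(self.k):  # tap positions are disjoint strided slices
            dxp[:, :, j :: self.s][:, :, :L_out] += dcols[:, :, :, j]
        _, pl, _ = _same_pad(L, self.k, self.s)
        return dxp[:, :, pl : pl + L]


class _BatchNorm1D:
    """Per-channel normalization over the batch and time axes."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        xhat = (x - mean[None, :, None]) / np.sqrt(var[None, :, None] + self.eps)
        self._cache = (xhat, var)
        return self.gamma[None, :, None] * xhat + self.beta[None, :, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        # standard batch-norm gradient with statistics over (batch, time)
        xhat, var = self._cache
        self.dgamma = (dout * xhat).sum(axis=(0, 2))
        self.dbeta = dout.sum(axis=(0, 2))
        inv_std = 1.0 / np.sqrt(var[None, :, None] + self.eps)
        dxhat = dout * self.gamma[None, :, None]
        return inv_std * (
            dxhat
            - dxhat.mean(axis=(0, 2), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2), keepdims=True)
        )


class ConvNet1D:
    """The event classifier network (weights, forward, backward, Adam)."""

    def __init__(self, cfg: CNNConfig, in_channels: int, input_length: int):
        if input_length < 16:
            raise ConfigurationError("input length must be at least 16 samples")
        self.cfg = cfg
        self.in_channels = in_channels
        self.input_length = input_length
        rng = np.random.default_rng(cfg.seed)
        self.convs: list[_Conv1D] = []
        self.bns: list[_BatchNorm1D] = []
        c_prev = in_channels
        for c in cfg.channels:
            self.convs.append(_Conv1D(c_prev, c, cfg.kernel, cfg.stride, rng))
            self.bns.append(_BatchNorm1D(c))
            c_prev = c
        self.flat_width = layer_lengths(input_length, cfg)[-1] * cfg.channels[-1]
        self.Wd = rng.normal(0.0, np.sqrt(2.0 / self.flat_width), size=(self.flat_width, 2))
        self.bd = np.zeros(2)
        self._adam_state: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        self._adam_t = 0

    # ---- parameter bookkeeping -------------------------------------------------
    def _param_refs(self):
        refs = []
        for conv in self.convs:
            refs.append((conv, "W"))
            refs.append((conv, "b"))
        for bn in self.bns:
            refs.append((bn, "gamma"))
            refs.append((bn, "beta"))
        refs.append((self, "Wd"))
        refs.append((self, "bd"))
        return refs

    def n_parameters(self) -> int:
        n = sum(getattr(o, a).size for o, a in self._param_refs())
        n += sum(bn.running_mean.size + bn.running_var.size for bn in self.bns)
        return n

    def get_weights(self) -> list[np.ndarray]:
        ws = [getattr(o, a).copy() for o, a in self._param_refs()]
        for bn in self.bns:
            ws.append(bn.running_mean.copy())
            ws.append(bn.running_var.copy())
        return ws

    def set_weights(self, ws: list[np.ndarray]) -> None:
        refs = self._param_refs()
        for (o, a), w in zip(refs, ws[: len(refs)]):
            setattr(o, a, w.copy())
        tail = ws[len(refs):]
        for i, bn in enumerate(self.bns):
            bn.running_mean = tail[2 * i].copy()
            bn.running_var = tail[2 * i + 1].copy()

    # ---- forward / backward ----------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False,
                dropout_rng: np.random.Generator | None = None) -> np.ndarray:
        """Class probabilities (n, 2); x is (n, channels, L)."""
        if x.shape[1:] != (self.in_channels, self.input_length):
            raise ConfigurationError(
                f"expected input (*, {self.in_channels}, {self.input_length}), got {x.shape}"
            )
        h = x
        self._relu_masks = []
        for conv, bn in zip(self.convs, self.bns):
            h = conv.forward(h)
            h = bn.forward(h, training)
            mask = h > 0
            self._relu_masks.append(mask)
            h = h * mask
        if training and self.cfg.dropout_rate > 0:
            keep = 1.0 - self.cfg.dropout_rate
            dmask = (dropout_rng.random(h.shape) < keep) / keep
            self._dropout_mask = dmask
            h = h * dmask
        else:
            self._dropout_mask = None
        self._flat_in_shape = h.shape
        flat = h.reshape(h.shape[0], -1)
        self._flat = flat
        logits = flat @ self.Wd + self.bd
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)
        self._probs = probs
        return probs

    def loss(self, probs: np.ndarray, y_onehot: np.ndarray) -> float:
        ce = -np.mean(np.sum(y_onehot * np.log(probs + 1e-12), axis=1))
        l2 = self.cfg.l2_coeff * sum(float((c.W**2).sum()) for c in self.convs)
        return float(ce + l2)

    def backward(self, y_onehot: np.ndarray) -> None:
        n = y_onehot.shape[0]
        dlogits = (self._probs - y_onehot) / n
        self.dWd = self._flat.T @ dlogits
        self.dbd = dlogits.sum(axis=0)
        dflat = dlogits @ self.Wd.T
        dh = dflat.reshape(self._flat_in_shape)
        if self._dropout_mask is not None:
            dh = dh * self._dropout_mask
        for conv, bn, mask in zip(
            reversed(self.convs), reversed(self.bns), reversed(self._relu_masks)
        ):
            dh = dh * mask
            dh = bn.backward(dh)
            dh = conv.backward(dh)
            conv.dW += 2.0 * self.cfg.l2_coeff * conv.W
        # dh is now the input gradient (unused)

    def _grad_refs(self):
        refs = []
        for conv in self.convs:
            refs.append((conv, "W", "dW"))
            refs.append((conv, "b", "db"))
        for bn in self.bns:
            refs.append((bn, "gamma", "dgamma"))
            refs.append((bn, "beta", "dbeta"))
        refs.append((self, "Wd", "dWd"))
        refs.append((self, "bd", "dbd"))
        return refs

    def adam_step(self, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                  eps: float = 1e-7) -> None:
        self._adam_t += 1
        t = self._adam_t
        for i, (obj, attr, gattr) in enumerate(self._grad_refs()):
            g = getattr(obj, gattr)
            m, v = self._adam_state.get(i, (np.zeros_like(g), np.zeros_like(g)))
            m = beta1 * m + (1 - beta1) * g
            v = beta2 * v + (1 - beta2) * g**2
            self._adam_state[i] = (m, v)
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            setattr(obj, attr, getattr(obj, attr) - lr * mhat / (np.sqrt(vhat) + eps))


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = -1


class EventClassifier:
    """Trained model plus the training-set standardization statistics."""

    def __init__(self, cfg: CNNConfig, in_channels: int = 6, input_length: int = 100):
        self.cfg = cfg
        self.model = ConvNet1D(cfg, in_channels, input_length)
        self.mu: np.ndarray | None = None
        self.sd: np.ndarray | None = None
        self.history: TrainingHistory | None = None

    def _sensor_groups(self) -> list[np.ndarray]:
        """Channel index groups sharing standardization statistics.

        Axes of one sensor are pooled so that scaling is invariant to how the
        watch's axes map onto the subject's movement.
        """
        c = self.model.in_channels
        if c == 6:
            return [np.arange(3), np.arange(3, 6)]
        return [np.arange(c)]

    def _canonicalize(self, X: np.ndarray) -> np.ndarray:
        """Map each window to a canonical axis frame.

        Per channel the window mean is removed (gravity on the accelerometer,
        bias on the gyroscope — both orientation fingerprints, not movement).
        Within each sensor triad the axes are then sorted by mean absolute
        value, dominant first, and each axis' sign is fixed so its third
        central moment is non-negative. Pure function of the window.
        """
        X = X - X.mean(axis=2, keepdims=True)
        out = np.empty_like(X)
        mav = np.abs(X).mean(axis=2)  # (n, c)
        for grp in self._sensor_groups():
            order = np.argsort(-mav[:, grp], axis=1, kind="stable")  # (n, 3)
            idx = np.asarray(grp)[order]
            out[:, grp, :] = np.take_along_axis(X, idx[:, :, None], axis=1)
        m3 = (out**3).mean(axis=2)
        out *= np.where(m3 < 0, -1.0, 1.0)[:, :, None]
        return out

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mu[None, :, None]) / self.sd[None, :, None]

    def fit(
        self,
        X_train: np.ndarray,
        y_train: np.ndarray,
        X_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
    ) -> TrainingHistory:
        """Train with Adam + early stopping on validation loss.

        y arrays are 0 (HC) / 1 (PD). Standardization statistics come from
        the training windows only.
        """
        y_train = np.asarray(y_train, dtype=int)
        if len(np.unique(y_train)) < 2:
            raise TrainingError("training set contains a single class")
        X_train = np.asarray(X_train, dtype=float)
        if self.cfg.canonicalize_orientation:
            X_train = self._canonicalize(X_train)
        c = X_train.shape[1]
        self.mu = np.empty(c)
        self.sd = np.empty(c)
        for grp in self._sensor_groups():
            self.mu[grp] = X_train[:, grp, :].mean()
            self.sd[grp] = X_train[:, grp, :].std()
        self.sd = np.where(self.sd > 0, self.sd, 1.0)
        Xs = self._standardize(X_train)
        Y = np.eye(2)[y_train]
        has_val = X_val is not None and len(X_val) > 0
        if has_val:
            Xv = np.asarray(X_val, dtype=float)
            if self.cfg.canonicalize_orientation:
                Xv = self._canonicalize(Xv)
            Xv = self._standardize(Xv)
            Yv = np.eye(2)[np.asarray(y_val, dtype=int)]

        cfg = self.cfg
        rng = np.random.default_rng(cfg.seed + 1)
        hist = TrainingHistory()
        best_loss, best_weights, stale = np.inf, None, 0
        if has_val:
            # the untrained state is the baseline candidate: a model that
            # never beats it on validation carries no transferable signal
            pv0 = self._predict_proba_std(Xv)
            best_loss = self.model.loss(pv0, Yv)
            best_weights = self.model.get_weights()
        n = Xs.shape[0]
        for epoch in range(cfg.max_epochs):
            perm = rng.permutation(n)
            losses = []
            for lo in range(0, n, cfg.batch_size):
                sel = perm[lo : lo + cfg.batch_size]
                probs = self.model.forward(Xs[sel], training=True, dropout_rng=rng)
                losses.append(self.model.loss(probs, Y[sel]))
                self.model.backward(Y[sel])
                self.model.adam_step(cfg.learning_rate)
            hist.train_loss.append(float(np.mean(losses)))
            if has_val:
                pv = self._predict_proba_std(Xv)
                vloss = self.model.loss(pv, Yv)
                hist.val_loss.append(vloss)
                hist.val_accuracy.append(
                    float(np.mean(pv.argmax(axis=1) == Yv.argmax(axis=1)))
                )
                monitored = vloss
            else:
                monitored = hist.train_loss[-1]
            if monitored < best_loss - cfg.min_delta:
                best_loss = monitored
                best_weights = self.model.get_weights()
                hist.best_epoch = epoch
                stale = 0
            else:
                stale += 1
                if epoch >= cfg.warmup_epochs and stale >= cfg.patience:
                    break
        if best_weights is not None:
            self.model.set_weights(best_weights)
        self.history = hist
        return hist

    def _predict_proba_std(self, Xs: np.ndarray, chunk: int = 4096) -> np.ndarray:
        outs = [
            self.model.forward(Xs[lo : lo + chunk], training=False)
            for lo in range(0, Xs.shape[0], chunk)
        ]
        return np.concatenate(outs) if outs else np.zeros((0, 2))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class probabilities (n, 2), columns (HC, PD). Deterministic."""
        if self.mu is None:
            raise TrainingError("classifier is not trained")
        X = np.asarray(X, dtype=float)
        if self.cfg.canonicalize_orientation:
            X = self._canonicalize(X)
        return self._predict_proba_std(self._standardize(X))

    def predict_events(self, X: np.ndarray, meta: pd.DataFrame) -> pd.DataFrame:
        """Per-event predictions: p_pd plus a 0.5-threshold class call."""
        probs = self.predict_proba(X)
        out = meta[["subject_id", "day_index", "start_time"]].reset_index(drop=True).copy()
        out["p_pd"] = probs[:, 1]
        out["predicted"] = np.where(out["p_pd"] >= 0.5, "PD", "HC")
        return out

    # ---- persistence -----------------------------------------------------------
    def save(self, directory: str) -> None:
        os.makedirs(directory, exist_ok=True)
        cfg = asdict(self.cfg)
        cfg["channels"] = list(cfg["channels"])
        meta = {
            "config": cfg,
            "in_channels": self.model.in_channels,
            "input_length": self.model.input_length,
        }
        with open(os.path.join(directory, "model.json"), "w") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True)
        for i, w in enumerate(self.model.get_weights()):
            np.save(os.path.join(directory, f"w{i:03d}.npy"), w)
        np.save(os.path.join(directory, "mu.npy"), self.mu)
        np.save(os.path.join(directory, "sd.npy"), self.sd)

    @classmethod
    def load(cls, directory: str) -> "EventClassifier":
        with open(os.path.join(directory, "model.json")) as fh:
            meta = json.load(fh)
        cfg = meta["config"]
        cfg["channels"] = tuple(cfg["channels"])
        obj = cls(CNNConfig(**cfg), meta["in_channels"], meta["input_length"])
        n = len(obj.model.get_weights())
        ws = [np.load(os.path.join(directory, f"w{i:03d}.npy")) for i in range(n)]
        obj.model.set_weights(ws)
        obj.mu = np.load(os.path.join(directory, "mu.npy"))
        obj.sd = np.load(os.path.join(directory, "sd.npy"))
        return obj


def build_model(cfg: CNNConfig, in_channels: int = 6, input_length: int = 100) -> ConvNet1D:
    """Construct the (untrained) network for the given input shape."""
    return ConvNet1D(cfg, in_channels, input_length)
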
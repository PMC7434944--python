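"""The shared "main model" and its two instantiations.

Both the error-type network (model 1, six classes A/C/G/T/I/D) and the
true-base network (model 2, four classes A/C/G/T) use the same topology:

* signal branch: a stem 1-D convolution (kernel 1x3, 8 filters, stride 1)
  with batch normalization and ReLU, followed by an identity block of three
  residual blocks (conv-BN-ReLU-conv-BN plus a shortcut connection), then
  mean-pooled per event position;
* read-feature branch: two Bi-LSTM layers (state 16, tanh) each followed by
  batch normalization;
* trunk: the two branch outputs concatenated per position, passed through
  Bi-LSTM layers (state 64) with dropout 0.2, then the centre position
  through two fully connected layers and a softmax.

Training minimizes softmax cross-entropy plus a center-loss term
``L = Ls + lambda * Lc`` with ``Lc = 1/2 sum_i ||x_i - c_{y_i}||^2`` over the
penultimate features ``x_i``; the class centers ``c_y`` are updated after
every mini-batch (``c_j <- c_j - alpha * dc_j``, Wen's scheme), which pulls
features of the rare insertion/deletion classes into tight clusters and
counters the heavy class imbalance. Losses are reported per sample (batch
means), so the logged total always equals ``Ls + lambda * Lc``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .nn import Adam, BatchNorm, BiLSTM, Conv1dSame, Dense, Dropout, ReLU
from .windows import WindowSet


@dataclass
class ModelConfig:
    num_classes: int = 6
    window: int = 13
    conv_kernel: int = 3
    conv_filters: int = 8
    conv_stride: int = 1
    read_branch_lstm_state: int = 16
    trunk_lstm_state: int = 64
    trunk_lstm_layers: int = 2
    dense_units: int = 64
    dropout_rate: float = 0.2
    lambda_center: float = 0.2
    center_alpha: float = 0.5
    batch_size: int = 256
    epochs: int = 50
    learning_rate: float = 0.002
    lr_decay: float = 0.05
    beta1: float = 0.9
    beta2: float = 0.999
    seed: int = 0
    feature_dim: int = 7
    sig_cap: int = 40
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.num_classes not in (4, 6):
            raise ValueError("num_classes must be 4 (bases) or 6 (error types)")
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be an odd integer >= 3")
        if self.lambda_center < 0:
            raise ValueError("lambda_center must be non-negative")
        if self.conv_stride != 1:
            raise ValueError("only stride 1 is supported")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")

    @classmethod
    def reduced(cls, num_classes: int, seed: int = 0, **overrides
                ) -> "ModelConfig":
        """Small configuration for desk-scale experiments: 8 filters,
        LSTM states 16/32, one trunk layer, 10 epochs, batch 64."""
        kwargs = dict(
            num_classes=num_classes, trunk_lstm_state=32, trunk_lstm_layers=1,
            epochs=10, batch_size=64, sig_cap=16, seed=seed)
        kwargs.update(overrides)
        return cls(**kwargs)

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)


class _ResBlock:
    """conv -> BN -> ReLU -> conv -> BN, plus the identity shortcut, then
    ReLU on the sum."""

    def __init__(self, rng, channels: int, kernel: int, dtype, name: str):
        self.conv1 = Conv1dSame(rng, channels, channels, kernel, dtype,
                                f"{name}.conv1")
        self.bn1 = BatchNorm(channels, dtype, name=f"{name}.bn1")
        self.relu1 = ReLU()
        self.conv2 = Conv1dSame(rng, channels, channels, kernel, dtype,
                                f"{name}.conv2")
        self.bn2 = BatchNorm(channels, dtype, name=f"{name}.bn2")
        self.relu_out = ReLU()

    def forward(self, x, train):
        y = self.relu1.forward(self.bn1.forward(self.conv1.forward(x), train))
        y = self.bn2.forward(self.conv2.forward(y), train)
        return self.relu_out.forward(x + y)

    def backward(self, g):
        g = self.relu_out.backward(g)
        gy = self.conv2.backward(self.bn2.backward(g))
        gy = self.conv1.backward(self.bn1.backward(self.relu1.backward(gy)))
        return g + gy

    def params(self):
        return (self.conv1.params() + self.bn1.params()
                + self.conv2.params() + self.bn2.params())

    def bn_layers(self):
        return [self.bn1, self.bn2]


class MainModel:
    """Trainable network with a deterministic predict contract."""

    def __init__(self, config: ModelConfig):
        self.config = config
        cfg = config
        dtype = cfg.np_dtype
        rng = np.random.default_rng(cfg.seed)
        F = cfg.conv_filters
        self.stem = Conv1dSame(rng, 1, F, cfg.conv_kernel, dtype, "stem")
        self.stem_bn = BatchNorm(F, dtype, name="stem.bn")
        self.stem_relu = ReLU()
        self.blocks = [_ResBlock(rng, F, cfg.conv_kernel, dtype, f"res{i}")
                       for i in range(3)]
        H = cfg.read_branch_lstm_state
        self.feat_lstm1 = BiLSTM(rng, cfg.feature_dim, H, dtype, "feat1")
        self.feat_bn1 = BatchNorm(2 * H, dtype, name="feat1.bn")
        self.feat_lstm2 = BiLSTM(rng, 2 * H, H, dtype, "feat2")
        self.feat_bn2 = BatchNorm(2 * H, dtype, name="feat2.bn")
        trunk_in = F + 2 * H
        self.trunk = []
        for i in range(cfg.trunk_lstm_layers):
            self.trunk.append(BiLSTM(rng, trunk_in, cfg.trunk_lstm_state,
                                     dtype, f"trunk{i}"))
            trunk_in = 2 * cfg.trunk_lstm_state
        self.dropout = Dropout(cfg.dropout_rate)
        self.fc1 = Dense(rng, trunk_in, cfg.dense_units, dtype, "fc1")
        self.fc1_relu = ReLU()
        self.fc2 = Dense(rng, cfg.dense_units, cfg.num_classes, dtype, "fc2")
        self.centers = np.zeros((cfg.num_classes, cfg.dense_units),
                                dtype=np.float64)

    # -- plumbing -----------------------------------------------------------
    def params(self):
        out = self.stem.params() + self.stem_bn.params()
        for blk in self.blocks:
            out += blk.params()
        out += (self.feat_lstm1.params() + self.feat_bn1.params()
                + self.feat_lstm2.params() + self.feat_bn2.params())
        for layer in self.trunk:
            out += layer.params()
        out += self.fc1.params() + self.fc2.params()
        return out

    def bn_layers(self):
        out = [self.stem_bn, self.feat_bn1, self.feat_bn2]
        for blk in self.blocks:
            out += blk.bn_layers()
        return out

    # -- forward / backward -------------------------------------------------
    def forward(self, signal: np.ndarray, features: np.ndarray,
                train: bool = False, rng: np.random.Generator | None = None
                ) -> tuple[np.ndarray, np.ndarray]:
        """Return (logits, penultimate features) for a batch.

        ``signal``: (B, window * sig_cap) normalized samples;
        ``features``: (B, window, feature_dim).
        """
        cfg = self.config
        B = signal.shape[0]
        W = cfg.window
        cap = signal.shape[1] // W
        dtype = cfg.np_dtype
        x = signal.astype(dtype, copy=False).reshape(B, W * cap, 1)
        x = self.stem_relu.forward(self.stem_bn.forward(self.stem.forward(x),
                                                        train))
        for blk in self.blocks:
            x = blk.forward(x, train)
        self._pool_cap = cap
        sig_feat = x.reshape(B, W, cap, -1).mean(axis=2)  # (B, W, F)

        f = features.astype(dtype, copy=False)
        f = self.feat_bn1.forward(self.feat_lstm1.forward(f), train)
        f = self.feat_bn2.forward(self.feat_lstm2.forward(f), train)

        z = np.concatenate([sig_feat, f], axis=2)
        self._split = sig_feat.shape[2]
        for layer in self.trunk:
            z = layer.forward(z)
        z = self.dropout.forward(z, train, rng)
        self._trunk_shape = z.shape
        center = z[:, W // 2, :]
        penult = self.fc1_relu.forward(self.fc1.forward(center))
        logits = self.fc2.forward(penult)
        return logits, penult

    def backward(self, dlogits: np.ndarray, dpenult: np.ndarray | None = None
                 ) -> None:
        cfg = self.config
        W = cfg.window
        g = self.fc2.backward(dlogits)
        if dpenult is not None:
            g = g + dpenult.astype(g.dtype)
        g = self.fc1.backward(self.fc1_relu.backward(g))
        gz = np.zeros(self._trunk_shape, dtype=g.dtype)
        gz[:, W // 2, :] = g
        gz = self.dropout.backward(gz)
        for layer in reversed(self.trunk):
            gz = layer.backward(gz)
        gs = gz[:, :, : self._split]
        gf = gz[:, :, self._split :]

        gf = self.feat_lstm2.backward(self.feat_bn2.backward(gf))
        self.feat_lstm1.backward(self.feat_bn1.backward(gf))

        B, W_, F = gs.shape
        cap = self._pool_cap
        gx = np.repeat(gs[:, :, None, :] / cap, cap, axis=2)
        gx = gx.reshape(B, W_ * cap, F)
        for blk in reversed(self.blocks):
            gx = blk.backward(gx)
        self.stem.backward(self.stem_bn.backward(self.stem_relu.backward(gx)))

    # -- prediction ---------------------------------------------------------
    def predict_proba(self, signal: np.ndarray, features: np.ndarray,
                      batch_size: int = 512) -> np.ndarray:
        """Per-example class distributions (rows sum to 1); eval mode, so the
        result is independent of batch composition and order."""
        outs = []
        for i in range(0, signal.shape[0], batch_size):
            logits, _ = self.forward(signal[i : i + batch_size],
                                     features[i : i + batch_size],
                                     train=False)
            outs.append(softmax(logits.astype(np.float64)))
        if not outs:
            return np.zeros((0, self.config.num_classes))
        return np.concatenate(outs, axis=0)


def build_main_model(config: ModelConfig) -> MainModel:
    return MainModel(config)


# -- losses ----------------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray
                          ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    m = logits.shape[0]
    z = logits.astype(np.float64) - logits.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1))
    ls = float(np.mean(logsumexp - z[np.arange(m), labels]))
    probs = softmax(logits.astype(np.float64))
    probs[np.arange(m), labels] -= 1.0
    return ls, probs / m


def center_loss(features: np.ndarray, labels: np.ndarray,
                centers: np.ndarray) -> float:
    """``Lc = 1/2 sum_i ||x_i - c_{y_i}||^2`` over the batch."""
    labels = np.asarray(labels)
    if features.shape[0] != labels.shape[0]:
        raise ValueError("features and labels must have the same batch size")
    if labels.size and (labels.min() < 0 or labels.max() >= centers.shape[0]):
        raise ValueError("label outside the center set")
    diff = features.astype(np.float64) - centers[labels]
    return float(0.5 * np.sum(diff * diff))


def total_loss(logits: np.ndarray, features: np.ndarray, labels: np.ndarray,
               centers: np.ndarray, lam: float) -> float:
    """Per-sample loss ``L = Ls + lam * Lc`` (both terms batch means)."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    m = logits.shape[0]
    ls, _ = softmax_cross_entropy(logits, labels)
    lc = center_loss(features, labels, centers) / m
    return ls + lam * lc


def _center_update(centers: np.ndarray, features: np.ndarray,
                   labels: np.ndarray, alpha: float) -> None:
    # Wen's per-batch update: dc_j = sum_{y_i=j} (c_j - x_i) / (1 + n_j)
    for j in np.unique(labels):
        sel = features[labels == j].astype(np.float64)
        delta = (centers[j] - sel).sum(axis=0) / (1.0 + sel.shape[0])
        centers[j] -= alpha * delta


# -- training --------------------------------------------------------------

def train_model(model: MainModel, windows: WindowSet,
                config: ModelConfig | None = None,
                label_key: str = "labels1",
                callback=None) -> list[dict]:
    """Run Adam on the total loss; returns the per-epoch loss trace
    (dicts with epoch, total, ls, lc — all per-sample means).

    The training set is reshuffled at the start of every epoch and the
    learning rate follows ``lr0 / (1 + decay * epoch)``.
    """
    cfg = config or model.config
    signal, features = windows.signal, windows.features
    labels = getattr(windows, label_key)
    if windows.trainable is not None:
        keep = windows.trainable
        signal, features, labels = signal[keep], features[keep], labels[keep]
    n = signal.shape[0]
    if n == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    drop_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    opt = Adam(model.params(), lr=cfg.learning_rate,
               beta1=cfg.beta1, beta2=cfg.beta2)
    trace: list[dict] = []
    for epoch in range(cfg.epochs):
        lr = cfg.learning_rate / (1.0 + cfg.lr_decay * epoch)
        order = rng.permutation(n)
        tot_sum = ls_sum = lc_sum = 0.0
        seen = 0
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            sig_b, feat_b, y = signal[idx], features[idx], labels[idx]
            m = y.shape[0]
            logits, penult = model.forward(sig_b, feat_b, train=True,
                                           rng=drop_rng)
            ls, dlogits = softmax_cross_entropy(logits, y)
            lc = center_loss(penult, y, model.centers) / m
            total = ls + cfg.lambda_center * lc
            if not np.isfinite(total):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} (ls={ls}, lc={lc}); "
                    "reduce the learning rate or inspect the inputs")
            dpenult = (cfg.lambda_center / m) * (
                penult.astype(np.float64) - model.centers[y])
            opt.zero_grad()
            model.backward(dlogits, dpenult)
            opt.step(lr)
            _center_update(model.centers, penult, y, cfg.center_alpha)
            tot_sum += total * m
            ls_sum += ls * m
            lc_sum += lc * m
            seen += m
        entry = {"epoch": epoch, "total": tot_sum / seen,
                 "ls": ls_sum / seen, "lc": lc_sum / seen}
        trace.append(entry)
        if callback is not None:
            callback(entry)
    return trace


def predict_events(model: MainModel, windows: WindowSet,
                   batch_size: int = 512) -> np.ndarray:
    """One probability distribution per window (= per base-level event)."""
    if windows.features.shape[2] != model.config.feature_dim:
        raise ValueError(
            f"feature dimension {windows.features.shape[2]} does not match "
            f"model config ({model.config.feature_dim})")
    return model.predict_proba(windows.signal, windows.features, batch_size)


# -- checkpointing ---------------------------------------------------------

CHECKPOINT_VERSION = 1


def save_checkpoint(model: MainModel, path: str) -> None:
    arrays = {f"param/{p.name}": p.value for p in model.params()}
    for i, bn in enumerate(model.bn_layers()):
        arrays[f"bn/{i}/mean"] = bn.running_mean
        arrays[f"bn/{i}/var"] = bn.running_var
    arrays["centers"] = model.centers
    meta = {"version": CHECKPOINT_VERSION, "config": asdict(model.config)}
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str) -> MainModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(
                f"unsupported checkpoint version {meta.get('version')}")
        config = ModelConfig(**meta["config"])
        model = MainModel(config)
        for p in model.params():
            p.value[...] = data[f"param/{p.name}"]
        for i, bn in enumerate(model.bn_layers()):
            bn.running_mean = data[f"bn/{i}/mean"]
            bn.running_var = data[f"bn/{i}/var"]
        model.centers = data["centers"]
    return model
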
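"""CNN -> ConvLSTM -> dense fall-detection classifier and a CNN baseline.

The proposed architecture: two conv(3x3)+maxpool(2x2) blocks treat the
M x N range-time sample as a one-channel image; the pooled feature map is
then read as a slow-time sequence (pooled time axis = ConvLSTM steps,
pooled range axis = its spatial dimension) driving a peephole ConvLSTM-1D
in return-last mode; a 64-unit dense layer with dropout and a K-way output
head finish the stack.  The baseline is a Lenet-5-style CNN (two conv+pool,
two dense) on the same input.

Heads: softmax (trained end to end), or KNN (K=3) / random forest fitted on
the 64-dimensional dense-layer features of the trained backbone.

Training: mini-batch Nadam on cross-entropy with L2 penalty on the dense
kernels, early stopping on validation loss with best-weight restore.
Deterministic given the config seed (single-threaded execution contract).
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import asdict, dataclass, field, replace

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier

from ._layers import (
    Conv2D,
    ConvLSTM1D,
    Dense,
    Dropout,
    MaxPool2,
    Nadam,
    ReLU,
    cross_entropy_grad,
    softmax,
)
from .preprocess import ProcessedSample


@dataclass
class ModelConfig:
    """Architecture and training hyper-parameters (defaults per the method).

    conv kernels 3x3 with 2x2 max pooling, 64 dense units, 6 classes,
    dropout 0.5, L2 penalty 0.1 (dense kernels), learning rate 0.001,
    batches of 100, up to 1000 epochs with early stopping (patience 20).
    Filter counts (16, 16) and ConvLSTM hidden channels 8 are package
    defaults sized for CPU training.
    """

    n_frames: int = 20
    n_bins: int = 800
    conv_filters: tuple = (16, 16)
    conv_kernel: int = 3
    convlstm_hidden: int = 8
    convlstm_kernel: int = 3
    peephole_mode: str = "full"
    dense_units: int = 64
    n_classes: int = 6
    dropout_rate: float = 0.5
    l2_penalty: float = 0.1
    learning_rate: float = 0.001
    batch_size: int = 100
    max_epochs: int = 1000
    patience: int = 20
    seed: int = 0
    dtype: str = "float32"

    def validate(self) -> None:
        if self.n_frames < 4 or self.n_bins < 4:
            raise ValueError("input must survive two 2x2 pooling stages (M, N >= 4)")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")


def _pooled(n: int) -> int:
    return (n // 2) // 2


class CNNConvLSTMNet:
    """The proposed network; forward/backward over the layer engine."""

    kind = "cnn_convlstm"

    def __init__(self, config: ModelConfig):
        config.validate()
        self.config = config
        dt = np.dtype(config.dtype).type
        f1, f2 = config.conv_filters
        s = config.seed
        self.seq_len = config.n_frames // 2 // 2
        self.spatial_len = config.n_bins // 2 // 2
        self.conv1 = Conv2D(1, f1, config.conv_kernel, seed=s + 1, dtype=dt)
        self.relu1 = ReLU()
        self.pool1 = MaxPool2()
        self.conv2 = Conv2D(f1, f2, config.conv_kernel, seed=s + 2, dtype=dt)
        self.relu2 = ReLU()
        self.pool2 = MaxPool2()
        self.clstm = ConvLSTM1D(
            f2,
            config.convlstm_hidden,
            config.convlstm_kernel,
            self.spatial_len,
            seed=s + 3,
            peephole_mode=config.peephole_mode,
            dtype=dt,
        )
        self.dense1 = Dense(self.spatial_len * config.convlstm_hidden, config.dense_units, seed=s + 4, dtype=dt)
        self.relu3 = ReLU()
        self.drop = Dropout(config.dropout_rate)
        self.dense2 = Dense(config.dense_units, config.n_classes, seed=s + 5, dtype=dt)
        self._layers = [
            self.conv1, self.relu1, self.pool1, self.conv2, self.relu2, self.pool2,
            self.clstm, self.dense1, self.relu3, self.drop, self.dense2,
        ]

    # L2 penalty applies to the dense kernels only
    def regularized(self):
        return [(self.dense1.w, self.dense1.dw), (self.dense2.w, self.dense2.dw)]

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        dt = np.dtype(self.config.dtype).type
        x = np.asarray(x, dtype=dt)
        a = self.pool1.forward(self.relu1.forward(self.conv1.forward(x[:, None, :, :])))
        a = self.pool2.forward(self.relu2.forward(self.conv2.forward(a)))
        seq = np.ascontiguousarray(a.transpose(0, 2, 3, 1))  # (B, T, L, C)
        h = self.clstm.forward(seq)
        flat = h.reshape(h.shape[0], -1)
        self._feat = self.relu3.forward(self.dense1.forward(flat))
        fd = self.drop.forward(self._feat, train, rng)
        return self.dense2.forward(fd)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.dense2.backward(dlogits)
        d = self.relu3.backward(self.drop.backward(d))
        d = self.dense1.backward(d)
        d = d.reshape(d.shape[0], self.spatial_len, self.config.convlstm_hidden)
        d = self.clstm.backward(d)
        d = np.ascontiguousarray(d.transpose(0, 3, 1, 2))
        d = self.conv2.backward(self.relu2.backward(self.pool2.backward(d)))
        self.conv1.backward(self.relu1.backward(self.pool1.backward(d)))

    def features(self, x: np.ndarray) -> np.ndarray:
        self.forward(x, train=False)
        return self._feat.copy()

    def params_and_grads(self):
        out = []
        for layer in self._layers:
            out.extend(layer.params_and_grads())
        return out

    def parameter_count(self) -> int:
        return int(sum(p.size for p, _ in self.params_and_grads()))

    def get_weights(self):
        return [p.copy() for p, _ in self.params_and_grads()]

    def set_weights(self, weights) -> None:
        for (p, _), w in zip(self.params_and_grads(), weights):
            p[...] = w

    def zero_grads(self) -> None:
        for _, g in self.params_and_grads():
            g[...] = 0.0


class LenetBaselineNet(CNNConvLSTMNet):
    """Lenet-5-style CNN baseline: conv5(6)-pool-conv5(16)-pool-dense-dense."""

    kind = "cnn_baseline"

    def __init__(self, config: ModelConfig):
        config.validate()
        self.config = config
        dt = np.dtype(config.dtype).type
        s = config.seed
        self.seq_len = config.n_frames // 2 // 2
        self.spatial_len = config.n_bins // 2 // 2
        self.conv1 = Conv2D(1, 6, 5, seed=s + 21, dtype=dt)
        self.relu1 = ReLU()
        self.pool1 = MaxPool2()
        self.conv2 = Conv2D(6, 16, 5, seed=s + 22, dtype=dt)
        self.relu2 = ReLU()
        self.pool2 = MaxPool2()
        flat = 16 * self.seq_len * self.spatial_len
        self.dense1 = Dense(flat, 120, seed=s + 23, dtype=dt)
        self.relu3 = ReLU()
        self.drop = Dropout(config.dropout_rate)
        self.dense2 = Dense(120, config.n_classes, seed=s + 24, dtype=dt)
        self._layers = [
            self.conv1, self.relu1, self.pool1, self.conv2, self.relu2, self.pool2,
            self.dense1, self.relu3, self.drop, self.dense2,
        ]

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        dt = np.dtype(self.config.dtype).type
        x = np.asarray(x, dtype=dt)
        a = self.pool1.forward(self.relu1.forward(self.conv1.forward(x[:, None, :, :])))
        a = self.pool2.forward(self.relu2.forward(self.conv2.forward(a)))
        flat = a.reshape(a.shape[0], -1)
        self._a_shape = a.shape
        self._feat = self.relu3.forward(self.dense1.forward(flat))
        fd = self.drop.forward(self._feat, train, rng)
        return self.dense2.forward(fd)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.dense2.backward(dlogits)
        d = self.relu3.backward(self.drop.backward(d))
        d = self.dense1.backward(d).reshape(self._a_shape)
        d = self.conv2.backward(self.relu2.backward(self.pool2.backward(d)))
        self.conv1.backward(self.relu1.backward(self.pool1.backward(d)))


def build_model(config: ModelConfig) -> CNNConvLSTMNet:
    """Assemble the untrained CNN-ConvLSTM network for the given input size."""
    return CNNConvLSTMNet(config)


def build_baseline_cnn(config: ModelConfig) -> LenetBaselineNet:
    """Assemble the untrained Lenet-5-style baseline CNN."""
    return LenetBaselineNet(config)


# ---------------------------------------------------------------------------
# training


def _stack(samples) -> tuple[np.ndarray, np.ndarray]:
    """Samples (list of ProcessedSample or (X, y) tuple) -> arrays."""
    if isinstance(samples, tuple):
        x, y = samples
        return np.asarray(x, dtype=float), np.asarray(y, dtype=int)
    if len(samples) == 0:
        raise ValueError("empty sample set")
    x = np.stack([s.matrix for s in samples])
    y = np.array([int(s.label) for s in samples])
    return x, y


@dataclass
class TrainedModel:
    """A fitted backbone plus classification head and training history."""

    net: CNNConvLSTMNet
    config: ModelConfig
    history: list = field(default_factory=list)
    head: str = "softmax"
    head_model: object = None
    environment_id: str | None = None
    class_labels: tuple = ()

    def predict_scores(self, samples) -> np.ndarray:
        x, _ = _stack(samples) if not isinstance(samples, np.ndarray) else (samples, None)
        if x.shape[1:] != (self.config.n_frames, self.config.n_bins):
            raise ValueError(
                f"sample shape {x.shape[1:]} does not match model input "
                f"({self.config.n_frames}, {self.config.n_bins})"
            )
        if self.head == "softmax":
            return softmax(self.net.forward(x, train=False))
        feats = self.net.features(x)
        return self.head_model.predict_proba(feats)

    def predict(self, samples) -> np.ndarray:
        """Argmax class labels (1..K); ties break to the lowest class index."""
        scores = self.predict_scores(samples)
        return scores.argmax(axis=1) + 1

    def extract_features(self, samples) -> np.ndarray:
        """64-dimensional dense-layer activations (inference mode)."""
        x, _ = _stack(samples) if not isinstance(samples, np.ndarray) else (samples, None)
        return self.net.features(x)

    def fit_head(self, head: str, train_samples, seed: int = 0) -> "TrainedModel":
        """Fit a KNN(K=3) or random-forest head on backbone features."""
        if head not in ("knn", "rf"):
            raise ValueError("head must be 'knn' or 'rf'")
        x, y = _stack(train_samples)
        feats = self.net.features(x)
        if head == "knn":
            clf = KNeighborsClassifier(n_neighbors=3)
        else:
            clf = RandomForestClassifier(n_estimators=100, random_state=seed)
        clf.fit(feats, y)
        return replace(self, head=head, head_model=clf)


def _eval_loss_acc(net, x, y0, batch: int) -> tuple[float, float]:
    losses, hits, n = 0.0, 0, len(y0)
    for i in range(0, n, batch):
        logits = net.forward(x[i : i + batch], train=False)
        loss, _ = cross_entropy_grad(logits, y0[i : i + batch])
        losses += loss * len(y0[i : i + batch])
        hits += int((logits.argmax(axis=1) == y0[i : i + batch]).sum())
    return losses / n, hits / n


def train(net, train_samples, val_samples, config: ModelConfig | None = None) -> TrainedModel:
    """Fit the network with Nadam + early stopping; returns a TrainedModel."""
    config = config or net.config
    x_tr, y_tr = _stack(train_samples)
    x_va, y_va = _stack(val_samples)
    if len(y_tr) == 0 or len(y_va) == 0:
        raise ValueError("training and validation sets must be non-empty")
    classes = np.unique(y_tr)
    if len(classes) < config.n_classes:
        warnings.warn(
            f"training set covers {len(classes)} of {config.n_classes} classes",
            stacklevel=2,
        )
    offset = int(y_tr.min())  # labels 1..K -> 0..K-1
    y0_tr = y_tr - offset
    y0_va = y_va - offset
    dt = np.dtype(config.dtype).type
    x_tr = np.asarray(x_tr, dtype=dt)
    x_va = np.asarray(x_va, dtype=dt)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, 37]))
    opt = Nadam(net.params_and_grads(), lr=config.learning_rate)
    history = []
    best_loss = np.inf
    best_weights = net.get_weights()
    best_epoch = -1
    n = len(y0_tr)
    for epoch in range(config.max_epochs):
        perm = rng.permutation(n)
        ep_loss, ep_hits = 0.0, 0
        for i in range(0, n, config.batch_size):
            idx = perm[i : i + config.batch_size]
            net.zero_grads()
            logits = net.forward(x_tr[idx], train=True, rng=rng)
            loss, dlogits = cross_entropy_grad(logits, y0_tr[idx])
            if config.l2_penalty > 0:
                for w, dw in net.regularized():
                    loss += config.l2_penalty * float((w.astype(float) ** 2).sum())
                    dw += 2.0 * config.l2_penalty * w
            net.backward(dlogits.astype(logits.dtype))
            opt.step()
            ep_loss += loss * len(idx)
            ep_hits += int((logits.argmax(axis=1) == y0_tr[idx]).sum())
        val_loss, val_acc = _eval_loss_acc(net, x_va, y0_va, config.batch_size)
        history.append(
            {
                "epoch": epoch,
                "train_loss": ep_loss / n,
                "train_accuracy": ep_hits / n,
                "val_loss": val_loss,
                "val_accuracy": val_acc,
            }
        )
        if val_loss < best_loss - 1e-9:
            best_loss = val_loss
            best_weights = net.get_weights()
            best_epoch = epoch
        elif epoch - best_epoch >= config.patience:
            break
    net.set_weights(best_weights)
    labels = tuple(range(offset, offset + config.n_classes))
    return TrainedModel(net=net, config=config, history=history, class_labels=labels)


# ---------------------------------------------------------------------------
# persistence: .npz container with an embedded JSON config


def save_model(model: TrainedModel, path) -> None:
    arrays = {f"w{i}": p for i, (p, _) in enumerate(model.net.params_and_grads())}
    meta = {
        "config": asdict(model.config),
        "kind": model.net.kind,
        "head": model.head,
        "environment_id": model.environment_id,
        "class_labels": list(model.class_labels),
        "format_version": 1,
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_model(path) -> TrainedModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("format_version") != 1:
            raise ValueError("unsupported model container version")
        cfg_dict = meta["config"]
        cfg_dict["conv_filters"] = tuple(cfg_dict["conv_filters"])
        config = ModelConfig(**cfg_dict)
        net = build_model(config) if meta["kind"] == "cnn_convlstm" else build_baseline_cnn(config)
        weights = [data[f"w{i}"] for i in range(len(net.params_and_grads()))]
        net.set_weights(weights)
    model = TrainedModel(net=net, config=config, head="softmax", class_labels=tuple(meta["class_labels"]))
    model.environment_id = meta.get("environment_id")
    return model
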
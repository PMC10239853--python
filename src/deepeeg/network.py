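"""Seeded NumPy training engine for the fixed 1D convolutional network.

The network is small enough (about 1.16 M parameters for the canonical
4,097-sample geometry) that explicit im2col convolutions routed through
BLAS matrix products train it in minutes on one CPU core.  All layers are
implemented with exact analytic gradients; optimisation is Adam on a
softmax cross-entropy loss with an L2 penalty on the first dense layer's
kernel, matching the architecture definition.

Every source of randomness — weight initialisation, epoch shuffling,
dropout masks — is drawn from a single generator seeded by
``TrainingConfig.seed``, so two runs with identical data and config
produce bit-identical weights and histories.

Compute is float32 throughout; reported losses/accuracies are float.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .architecture import ArchitectureError, ArchitectureSpec, LayerSpec
from .data import LabeledDataset

BN_EPS = 1e-3
ADAM_BETA1 = 0.9
ADAM_BETA2 = 0.999
ADAM_EPS = 1e-7


class TrainingDivergedError(RuntimeError):
    """The loss became non-finite during training."""

    def __init__(self, epoch: int):
        super().__init__(f"training diverged (non-finite loss) at epoch {epoch}")
        self.epoch = epoch


@dataclass(frozen=True)
class TrainingConfig:
    """Optimisation settings. Defaults follow the published protocol:
    Adam at learning rate 1e-4, batches of 50, 300 epochs (tests and the
    bundled experiments use shorter schedules)."""

    learning_rate: float = 1e-4
    batch_size: int = 50
    epochs: int = 300
    seed: int = 0
    validation_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if self.validation_fraction is not None and not (
            0 < self.validation_fraction < 1
        ):
            raise ValueError("validation_fraction must be in (0, 1)")


@dataclass
class TrainingHistory:
    """Per-epoch training (and optional validation) accuracy and loss."""

    accuracy: list[float] = field(default_factory=list)
    loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.loss)


# ---------------------------------------------------------------------------
# layers


class _Layer:
    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator
                ) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def l2_loss(self) -> float:
        return 0.0


def _im2col(x: np.ndarray, kernel: int) -> np.ndarray:
    """(B, L, C) -> (B, L-k+1, k*C) patch matrix (contiguous copy)."""
    view = np.lib.stride_tricks.sliding_window_view(x, kernel, axis=1)
    # view: (B, Lout, C, k) -> (B, Lout, k, C)
    return np.ascontiguousarray(view.transpose(0, 1, 3, 2)).reshape(
        x.shape[0], x.shape[1] - kernel + 1, kernel * x.shape[2]
    )


class Conv1D(_Layer):
    def __init__(self, spec: LayerSpec, in_channels: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.kernel = spec.kernel_size
        self.in_channels = in_channels
        self.filters = spec.filters
        fan_in = self.kernel * in_channels
        fan_out = self.kernel * self.filters
        limit = np.sqrt(6.0 / (fan_in + fan_out))  # Glorot uniform
        self.params["W"] = rng.uniform(
            -limit, limit, size=(fan_in, self.filters)
        ).astype(np.float32)
        self.params["b"] = np.zeros(self.filters, dtype=np.float32)
        self._col: np.ndarray | None = None

    def forward(self, x, training, rng):
        if x.shape[1] < self.kernel:
            raise ArchitectureError(
                f"conv kernel {self.kernel} exceeds input length {x.shape[1]}"
            )
        col = _im2col(x, self.kernel)
        self._col = col if training else None
        self._in_length = x.shape[1]
        return col @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        col = self._col
        assert col is not None
        self.grads["W"] = np.tensordot(col, dy, axes=([0, 1], [0, 1]))
        self.grads["b"] = dy.sum(axis=(0, 1))
        dcol = dy @ self.params["W"].T  # (B, Lout, k*Cin)
        B, Lout, _ = dcol.shape
        dcol = dcol.reshape(B, Lout, self.kernel, self.in_channels)
        dx = np.zeros((B, self._in_length, self.in_channels), dtype=dy.dtype)
        for i in range(self.kernel):
            dx[:, i : i + Lout, :] += dcol[:, :, i, :]
        self._col = None
        return dx


class BatchNorm(_Layer):
    """Per-channel normalisation with momentum-0.9 moving statistics."""

    def __init__(self, channels: int, momentum: float = 0.9) -> None:
        super().__init__()
        self.momentum = momentum
        self.params["gamma"] = np.ones(channels, dtype=np.float32)
        self.params["beta"] = np.zeros(channels, dtype=np.float32)
        # moving statistics: updated during training, used at inference
        self.moving_mean = np.zeros(channels, dtype=np.float32)
        self.moving_var = np.ones(channels, dtype=np.float32)

    def forward(self, x, training, rng):
        if training:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.moving_mean = (
                self.momentum * self.moving_mean + (1 - self.momentum) * mean
            ).astype(np.float32)
            self.moving_var = (
                self.momentum * self.moving_var + (1 - self.momentum) * var
            ).astype(np.float32)
            self._inv_std = 1.0 / np.sqrt(var + BN_EPS)
            self._xhat = (x - mean) * self._inv_std
            return self.params["gamma"] * self._xhat + self.params["beta"]
        inv_std = 1.0 / np.sqrt(self.moving_var + BN_EPS)
        return self.params["gamma"] * (x - self.moving_mean) * inv_std + self.params[
            "beta"
        ]

    def backward(self, dy):
        xhat, inv_std = self._xhat, self._inv_std
        n = dy.shape[0] * dy.shape[1]
        self.grads["gamma"] = (dy * xhat).sum(axis=(0, 1))
        self.grads["beta"] = dy.sum(axis=(0, 1))
        dxhat = dy * self.params["gamma"]
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 1))
            - xhat * (dxhat * xhat).mean(axis=(0, 1))
        ) * inv_std
        del self._xhat
        return dx.astype(dy.dtype)

    def _state(self):
        return {"moving_mean": self.moving_mean, "moving_var": self.moving_var}


class ReLU(_Layer):
    def forward(self, x, training, rng):
        mask = x > 0
        self._mask = mask if training else None
        return x * mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool1D(_Layer):
    """Valid max pooling; pool window equals stride (non-overlapping)."""

    def __init__(self, spec: LayerSpec) -> None:
        super().__init__()
        if spec.pool_size != spec.stride:
            raise ArchitectureError("only pool_size == stride pooling is implemented")
        self.pool = spec.pool_size

    def forward(self, x, training, rng):
        B, L, C = x.shape
        if self.pool > L:
            raise ArchitectureError(f"pool {self.pool} exceeds input length {L}")
        Lout = (L - self.pool) // self.pool + 1
        trimmed = x[:, : Lout * self.pool, :].reshape(B, Lout, self.pool, C)
        if training:
            self._argmax = trimmed.argmax(axis=2)
            self._in_shape = (B, L, C)
        return trimmed.max(axis=2)

    def backward(self, dy):
        B, L, C = self._in_shape
        Lout = dy.shape[1]
        dtrim = np.zeros((B, Lout, self.pool, C), dtype=dy.dtype)
        np.put_along_axis(dtrim, self._argmax[:, :, None, :], dy[:, :, None, :], axis=2)
        dx = np.zeros((B, L, C), dtype=dy.dtype)
        dx[:, : Lout * self.pool, :] = dtrim.reshape(B, Lout * self.pool, C)
        return dx


class Flatten(_Layer):
    def forward(self, x, training, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(_Layer):
    def __init__(self, spec: LayerSpec, in_features: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.units = spec.units
        self.activation = spec.activation
        self.l2 = spec.l2
        limit = np.sqrt(6.0 / (in_features + spec.units))
        self.params["W"] = rng.uniform(
            -limit, limit, size=(in_features, spec.units)
        ).astype(np.float32)
        self.params["b"] = np.zeros(spec.units, dtype=np.float32)

    def forward(self, x, training, rng):
        self._x = x if training else None
        z = x @ self.params["W"] + self.params["b"]
        if self.activation == "relu":
            self._pre_mask = z > 0
            return z * self._pre_mask
        return z  # softmax is applied by the loss / predict_proba

    def backward(self, dy):
        if self.activation == "relu":
            dy = dy * self._pre_mask
        self.grads["W"] = self._x.T @ dy
        if self.l2 > 0:
            self.grads["W"] += 2.0 * self.l2 * self.params["W"]
        self.grads["b"] = dy.sum(axis=0)
        dx = dy @ self.params["W"].T
        self._x = None
        return dx

    def l2_loss(self) -> float:
        if self.l2 > 0:
            return float(self.l2 * np.sum(self.params["W"].astype(np.float64) ** 2))
        return 0.0


class Dropout(_Layer):
    """Inverted dropout: active only in training mode."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        self.rate = rate

    def forward(self, x, training, rng):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


# ---------------------------------------------------------------------------
# network


class NumpyNetwork:
    """Instantiated layers for an :class:`ArchitectureSpec`, seeded init."""

    def __init__(self, arch: ArchitectureSpec, rng: np.random.Generator) -> None:
        self.arch = arch
        self.layers: list[_Layer] = []
        shape: tuple[int, ...] = (arch.input_length, arch.input_channels)
        from .architecture import layer_output_shape

        for spec in arch.layers:
            if spec.kind == "conv1d":
                self.layers.append(Conv1D(spec, shape[1], rng))
            elif spec.kind == "batchnorm":
                self.layers.append(BatchNorm(shape[-1], spec.momentum))
            elif spec.kind == "activation":
                self.layers.append(ReLU())
            elif spec.kind == "maxpool1d":
                self.layers.append(MaxPool1D(spec))
            elif spec.kind == "flatten":
                self.layers.append(Flatten())
            elif spec.kind == "dense":
                self.layers.append(Dense(spec, shape[0], rng))
            elif spec.kind == "dropout":
                self.layers.append(Dropout(spec.rate))
            else:  # pragma: no cover
                raise ArchitectureError(f"unknown layer kind {spec.kind}")
            shape = layer_output_shape(shape, spec)

    def forward(
        self,
        x: np.ndarray,
        training: bool,
        rng: np.random.Generator,
        stop_after: int | None = None,
    ) -> np.ndarray:
        out = x
        for i, layer in enumerate(self.layers):
            out = layer.forward(out, training, rng)
            if stop_after is not None and i == stop_after:
                return out
        return out

    def backward(self, dlogits: np.ndarray) -> None:
        grad = dlogits
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def parameters(self) -> list[tuple[_Layer, str]]:
        return [(layer, name) for layer in self.layers for name in layer.params]

    def l2_loss(self) -> float:
        return sum(layer.l2_loss() for layer in self.layers)


class Adam:
    def __init__(self, net: NumpyNetwork, lr: float) -> None:
        self.lr = lr
        self.t = 0
        self.slots = [
            (layer, name, np.zeros_like(layer.params[name]),
             np.zeros_like(layer.params[name]))
            for layer, name in net.parameters()
        ]

    def step(self) -> None:
        self.t += 1
        bias1 = 1 - ADAM_BETA1**self.t
        bias2 = 1 - ADAM_BETA2**self.t
        for layer, name, m, v in self.slots:
            g = layer.grads[name]
            m *= ADAM_BETA1
            m += (1 - ADAM_BETA1) * g
            v *= ADAM_BETA2
            v += (1 - ADAM_BETA2) * g * g
            layer.params[name] -= (
                self.lr * (m / bias1) / (np.sqrt(v / bias2) + ADAM_EPS)
            ).astype(layer.params[name].dtype)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class TrainedNetwork:
    """A trained feature extractor/classifier with its provenance."""

    architecture: ArchitectureSpec
    net: NumpyNetwork
    config: TrainingConfig

    @property
    def feature_tap(self) -> int:
        return self.architecture.feature_tap_index

    def _check_length(self, x: np.ndarray) -> None:
        if x.shape[1] != self.architecture.input_length:
            raise ValueError(
                f"epoch length {x.shape[1]} != network input length "
                f"{self.architecture.input_length}"
            )

    def _batched(self, x: np.ndarray, stop_after: int | None,
                 batch_size: int = 50) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 2:
            x = x[:, :, None]
        self._check_length(x)
        rng = np.random.default_rng(0)  # unused in inference mode
        outs = [
            self.net.forward(x[i : i + batch_size], False, rng, stop_after)
            for i in range(0, x.shape[0], batch_size)
        ]
        return np.concatenate(outs, axis=0)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities in inference mode (dropout off, moving BN stats)."""
        return softmax(self._batched(x, None).astype(np.float64))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)

    def feature_maps(self, x: np.ndarray) -> np.ndarray:
        """(N, T, C) activations at the last pooling layer, inference mode."""
        return self._batched(x, self.feature_tap).astype(np.float64)

    # -- serialization ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Single-file .npz archive with a JSON manifest entry."""
        arrays: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.net.layers):
            for name, value in layer.params.items():
                arrays[f"layer{i}:{name}"] = value
            if isinstance(layer, BatchNorm):
                for name, value in layer._state().items():
                    arrays[f"layer{i}:{name}"] = value
        manifest = {
            "input_length": self.architecture.input_length,
            "n_classes": self.architecture.n_classes,
            "scaled": self.architecture.layers[0].kernel_size
            != 3,  # canonical geometry marker
            "config": {
                "learning_rate": self.config.learning_rate,
                "batch_size": self.config.batch_size,
                "epochs": self.config.epochs,
                "seed": self.config.seed,
            },
        }
        arrays["manifest"] = np.frombuffer(
            json.dumps(manifest).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedNetwork":
        from .architecture import build_architecture, build_scaled_architecture

        with np.load(path) as data:
            manifest = json.loads(bytes(data["manifest"]).decode())
            builder = (
                build_scaled_architecture if manifest["scaled"] else build_architecture
            )
            arch = builder(manifest["input_length"], manifest["n_classes"])
            config = TrainingConfig(**manifest["config"])
            trained = cls(arch, NumpyNetwork(arch, np.random.default_rng(0)), config)
            for i, layer in enumerate(trained.net.layers):
                for name in layer.params:
                    layer.params[name] = data[f"layer{i}:{name}"]
                if isinstance(layer, BatchNorm):
                    layer.moving_mean = data[f"layer{i}:moving_mean"]
                    layer.moving_var = data[f"layer{i}:moving_var"]
        return trained


def _one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((labels.size, n_classes), dtype=np.float32)
    out[np.arange(labels.size), labels] = 1.0
    return out


def train_network(
    arch: ArchitectureSpec,
    dataset: LabeledDataset,
    config: TrainingConfig,
) -> tuple[TrainedNetwork, TrainingHistory]:
    """Train the network on a labeled dataset; fully seeded and deterministic.

    Per-epoch training accuracy and loss are averaged over the shuffled
    mini-batches of that epoch (i.e. computed in training mode, as the
    optimiser saw them).  With ``validation_fraction`` set, a stratified
    tail of each class is held out and scored in inference mode after
    each epoch.
    """
    x = dataset.signal_matrix().astype(np.float32)[:, :, None]
    if x.shape[1] != arch.input_length:
        raise ValueError(
            f"dataset epoch length {x.shape[1]} != architecture input length "
            f"{arch.input_length}"
        )
    labels = dataset.labels
    if labels.max() >= arch.n_classes:
        raise ValueError("labels exceed architecture n_classes")

    rng = np.random.Generator(np.random.PCG64(config.seed))
    net = NumpyNetwork(arch, rng)

    if config.validation_fraction:
        train_idx, val_idx = _stratified_holdout(
            labels, config.validation_fraction, rng
        )
    else:
        train_idx, val_idx = np.arange(labels.size), None

    y = _one_hot(labels, arch.n_classes)
    optimizer = Adam(net, config.learning_rate)
    history = TrainingHistory()
    n_train = train_idx.size

    for epoch in range(config.epochs):
        order = train_idx[rng.permutation(n_train)]
        epoch_loss = 0.0
        epoch_correct = 0
        for start in range(0, n_train, config.batch_size):
            batch = order[start : start + config.batch_size]
            xb, yb = x[batch], y[batch]
            logits = net.forward(xb, True, rng)
            probs = softmax(logits.astype(np.float64))
            ce = -np.mean(
                np.log(np.clip(probs[np.arange(len(batch)), labels[batch]], 1e-12, None))
            )
            loss = ce + net.l2_loss()
            if not np.isfinite(loss):
                raise TrainingDivergedError(epoch)
            epoch_loss += loss * len(batch)
            epoch_correct += int((probs.argmax(axis=1) == labels[batch]).sum())
            dlogits = ((probs - yb) / len(batch)).astype(np.float32)
            net.backward(dlogits)
            optimizer.step()
        history.loss.append(epoch_loss / n_train)
        history.accuracy.append(epoch_correct / n_train)
        if val_idx is not None:
            trained_view = TrainedNetwork(arch, net, config)
            val_probs = trained_view.predict_proba(x[val_idx, :, 0])
            val_ce = -np.mean(
                np.log(
                    np.clip(val_probs[np.arange(val_idx.size), labels[val_idx]],
                            1e-12, None)
                )
            )
            history.val_loss.append(float(val_ce + net.l2_loss()))
            history.val_accuracy.append(
                float((val_probs.argmax(axis=1) == labels[val_idx]).mean())
            )

    return TrainedNetwork(arch, net, config), history


def _stratified_holdout(
    labels: np.ndarray, fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    train, val = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = idx[rng.permutation(idx.size)]
        n_val = max(1, int(round(fraction * idx.size)))
        val.append(idx[:n_val])
        train.append(idx[n_val:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(val))
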
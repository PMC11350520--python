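"""Single-output convolutional regression network for one fluctuation parameter.

Architecture: five [3x3 conv (same, ReLU) -> 2x2 max pool] blocks with
8/16/32/64/128 filters, batch normalization, flatten, dense(512, ReLU),
dropout(0.5), dense(1, linear).  Trained with Adam (lr 5e-4, beta1 0.9,
beta2 0.999, eps 1e-7) on mean-squared error; the weights from the epoch with
the lowest validation loss are restored after training.

One network is trained per target parameter (correlation length or
fluctuation extent); inputs are contrast-stretched signals divided by 255 and
labels stay on their natural scales.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _nn
from ._nn import F32
from .errors import DivergenceError, ParameterError, DataError

__all__ = [
    "RegressorConfig",
    "CNNRegressor",
    "TrainedRegressor",
    "build_architecture",
    "train_regressor",
    "predict_parameters",
    "save_regressor",
    "load_regressor",
]

TARGET_CORR_LENGTH = "corr_length"
TARGET_FLUCT_STD = "fluct_std"


@dataclass(frozen=True)
class RegressorConfig:
    """Hyperparameters of the regression network and its training loop."""

    target: str = TARGET_CORR_LENGTH
    conv_filters: tuple[int, ...] = (8, 16, 32, 64, 128)
    kernel: tuple[int, int] = (3, 3)
    pool: tuple[int, int] = (2, 2)
    dense_units: int = 512
    dropout_rate: float = 0.5
    learning_rate: float = 5e-4
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-7
    epochs: int = 200
    batch_size: int = 16
    seed: int = 0
    input_shape: tuple[int, int] = (181, 361)

    def __post_init__(self) -> None:
        if self.target not in (TARGET_CORR_LENGTH, TARGET_FLUCT_STD):
            raise ParameterError(f"unknown target {self.target!r}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ParameterError("dropout_rate must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ParameterError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ParameterError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ParameterError("batch_size must be >= 1")
        if self.kernel != (3, 3) or self.pool != (2, 2):
            raise ParameterError("only 3x3 kernels and 2x2 pools are supported")
        object.__setattr__(self, "conv_filters", tuple(self.conv_filters))
        object.__setattr__(self, "input_shape", tuple(self.input_shape))


class CNNRegressor:
    """The assembled network: an ordered layer stack plus seeded RNG state."""

    def __init__(self, config: RegressorConfig):
        rows, cols = config.input_shape
        n_pools = len(config.conv_filters)
        if rows < 2**n_pools or cols < 2**n_pools:
            raise ParameterError(
                f"input {rows}x{cols} too small to survive {n_pools} 2x2 pools "
                f"(need >= {2**n_pools} per side)"
            )
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.layers: list[_nn.Layer] = []
        c_in = 1
        r, c = rows, cols
        for i, c_out in enumerate(config.conv_filters):
            self.layers.append(_nn.Conv3x3(rng, c_in, c_out, first_layer=(i == 0)))
            self.layers.append(_nn.MaxPool2())
            c_in = c_out
            r, c = r // 2, c // 2
        self.feature_shape = (r, c, c_in)  # rows, cols, channels after block 5
        self.layers.append(_nn.BatchNorm(c_in))
        self.layers.append(_nn.Flatten())
        flat = r * c * c_in
        self.layers.append(_nn.Dense(rng, flat, config.dense_units, relu=True))
        self.layers.append(_nn.Dropout(config.dropout_rate, rng))
        self.layers.append(_nn.Dense(rng, config.dense_units, 1, relu=False))

    # -- plumbing ----------------------------------------------------------
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def state_arrays(self) -> list[np.ndarray]:
        return [s for layer in self.layers for s in layer.state()]

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params())

    def snapshot(self) -> list[np.ndarray]:
        return [s.copy() for s in self.state_arrays()]

    def restore(self, snapshot: Sequence[np.ndarray]) -> None:
        for dst, src in zip(self.state_arrays(), snapshot, strict=True):
            dst[...] = src

    # -- compute -----------------------------------------------------------
    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=F32)
        if x.ndim == 2:
            x = x[None]
        if x.ndim != 3 or x.shape[1:] != self.config.input_shape:
            raise DataError(
                f"expected inputs of shape (n, {self.config.input_shape[0]}, "
                f"{self.config.input_shape[1]}), got {x.shape}"
            )
        return x[:, None, :, :]  # NCHW with one channel

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)

    def predict(self, signals: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Inference-mode predictions, one scalar per input signal."""
        x = self._check_input(signals)
        out = np.empty(len(x), dtype=np.float64)
        for i in range(0, len(x), batch_size):
            out[i:i + batch_size] = self.forward(x[i:i + batch_size], False)[:, 0]
        return out


@dataclass
class TrainedRegressor:
    """Training result: best-epoch weights, config, and per-epoch loss history."""

    model: CNNRegressor
    config: RegressorConfig
    history: dict[str, list[float]]
    best_epoch: int

    @property
    def weights(self) -> list[np.ndarray]:
        return self.model.state_arrays()


def build_architecture(config: RegressorConfig) -> CNNRegressor:
    """Build the untrained network with seeded weight initialization."""
    return CNNRegressor(config)


def train_regressor(
    model: CNNRegressor,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray],
    config: RegressorConfig | None = None,
) -> TrainedRegressor:
    """Minimize MSE with Adam; keep the weights with the lowest validation loss.

    ``train_set``/``val_set`` are ``(signals, labels)`` pairs with signals
    already scaled to [0, 1] (stretched values / 255) and labels on the raw
    parameter scale.  The output bias starts at the mean training label so the
    network spends its epochs learning deviations, not the absolute offset.
    """
    config = config or model.config
    x_train, y_train = train_set
    x_val, y_val = val_set
    if len(x_train) == 0 or len(x_val) == 0:
        raise ParameterError("train and validation sets must be non-empty")
    x_train = model._check_input(x_train)
    x_val_arr = np.asarray(x_val, dtype=F32)
    y_train = np.asarray(y_train, dtype=np.float64)
    y_val = np.asarray(y_val, dtype=np.float64)

    model.layers[-1].b[...] = np.float32(np.mean(y_train))

    opt = _nn.Adam(model.params(), config.learning_rate, config.beta1,
                   config.beta2, config.epsilon)
    shuffle_rng = np.random.default_rng([config.seed, 1])

    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_epoch = -1
    best_snapshot = model.snapshot()

    n = len(x_train)
    for epoch in range(1, config.epochs + 1):
        order = shuffle_rng.permutation(n)
        total, seen = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            pred = model.forward(xb, True)[:, 0]
            loss = _nn.mse(pred, yb)
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite training loss at epoch {epoch}")
            dloss = (2.0 / len(idx)) * (pred - yb)
            model.backward(dloss.astype(F32)[:, None])
            opt.step(model.grads())
            total += loss * len(idx)
            seen += len(idx)
        train_loss = total / seen
        val_pred = model.predict(x_val_arr)
        val_loss = _nn.mse(val_pred, y_val)
        if not np.isfinite(val_loss):
            raise DivergenceError(f"non-finite validation loss at epoch {epoch}")
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_epoch = epoch
            best_snapshot = model.snapshot()

    model.restore(best_snapshot)
    return TrainedRegressor(model=model, config=config, history=history,
                            best_epoch=best_epoch)


def predict_parameters(trained: TrainedRegressor, signals: np.ndarray) -> np.ndarray:
    """Predictions on the raw parameter scale, in input order."""
    return trained.model.predict(signals)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_regressor(trained: TrainedRegressor, path: str | Path) -> None:
    """Persist weights + config + history into a single ``.npz`` archive."""
    arrays = {f"arr_{i}": a for i, a in enumerate(trained.model.state_arrays())}
    meta = json.dumps(
        {
            "config": asdict(trained.config),
            "history": trained.history,
            "best_epoch": trained.best_epoch,
        }
    )
    np.savez(path, __meta__=np.frombuffer(meta.encode("utf-8"), dtype=np.uint8),
             **arrays)


def load_regressor(path: str | Path) -> TrainedRegressor:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode("utf-8"))
        cfg_dict = meta["config"]
        for key in ("conv_filters", "kernel", "pool", "input_shape"):
            cfg_dict[key] = tuple(cfg_dict[key])
        config = RegressorConfig(**cfg_dict)
        model = CNNRegressor(config)
        n = len(model.state_arrays())
        model.restore([data[f"arr_{i}"] for i in range(n)])
    return TrainedRegressor(model=model, config=config, history=meta["history"],
                            best_epoch=meta["best_epoch"])
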
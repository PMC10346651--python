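"""Hourglass MLP mapping 9 accelerometer channels to 27 curve coordinates.

The regressor takes the concatenated (x, y, z) readings of the three strip
accelerometers and outputs the normalized base-relative coordinates of
markers 2..10 (marker 1 is the fixed origin and is not predicted).  The
dense layers form an hourglass 9 -> 27 -> 18 -> 9 -> 18 -> 27 with ReLU
hidden activations and a linear output (targets may exceed +-1), trained
with mini-batch RMSprop on mean squared error.

Implemented directly on NumPy: the network is small (1638 parameters) and
a hand-written forward/backward keeps the package dependency-light while
making every training detail (initialization, shuffling, the RMSprop
accumulator) explicit and seedable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .stream_processing import NormalizationSpec

DEFAULT_WIDTHS = (9, 27, 18, 9, 18, 27)


@dataclass(frozen=True)
class ModelConfig:
    layer_widths: tuple[int, ...] = DEFAULT_WIDTHS
    init_seed: int = 0

    def __post_init__(self) -> None:
        w = tuple(self.layer_widths)
        if w[0] != 9 or w[-1] != 27:
            raise ValueError(
                f"layer_widths must start at 9 inputs and end at 27 outputs, got {w}"
            )
        if any(x <= 0 for x in w):
            raise ValueError("all layer widths must be > 0")


@dataclass(frozen=True)
class TrainingConfig:
    """RMSprop recipe: lr 1e-4, rho 0.9, momentum 0, 250 epochs, batch 512,
    MSE loss.  ``epsilon`` is the framework-conventional denominator fuzz
    (not part of the recipe's stated hyperparameters)."""

    learning_rate: float = 1e-4
    rho: float = 0.9
    momentum: float = 0.0
    epochs: int = 250
    batch_size: int = 512
    epsilon: float = 1e-7
    shuffle_seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("learning_rate, epochs and batch_size must be > 0")
        if not (0.0 < self.rho < 1.0):
            raise ValueError("rho must lie in (0, 1)")
        if self.momentum < 0:
            raise ValueError("momentum must be >= 0")


@dataclass(frozen=True)
class SplitSpec:
    proportions: tuple[float, float, float] = (0.50, 0.25, 0.25)
    split_seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("split proportions must sum to 1")


@dataclass
class MLP:
    """Plain dense network: weights[i] is (fan_in, fan_out)."""

    widths: tuple[int, ...]
    weights: list[np.ndarray]
    biases: list[np.ndarray]

    @property
    def n_parameters(self) -> int:
        return int(sum(w.size for w in self.weights) + sum(b.size for b in self.biases))

    def forward(self, x: np.ndarray) -> np.ndarray:
        a = np.atleast_2d(np.asarray(x, float))
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            a = np.maximum(a @ w + b, 0.0)
        return a @ self.weights[-1] + self.biases[-1]

    def _forward_cached(self, x: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        acts = [x]
        a = x
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            a = np.maximum(a @ w + b, 0.0)
            acts.append(a)
        return a @ self.weights[-1] + self.biases[-1], acts

    def _backward(
        self, acts: list[np.ndarray], dout: np.ndarray
    ) -> tuple[list[np.ndarray], list[np.ndarray]]:
        gw = [np.empty(0)] * len(self.weights)
        gb = [np.empty(0)] * len(self.biases)
        delta = dout
        for i in range(len(self.weights) - 1, -1, -1):
            gw[i] = acts[i].T @ delta
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.weights[i].T) * (acts[i] > 0)
        return gw, gb


def build_model(config: ModelConfig = ModelConfig()) -> MLP:
    """Glorot-uniform-initialized hourglass network, deterministic in
    ``init_seed``; the default widths carry exactly 1638 parameters."""
    rng = np.random.default_rng(config.init_seed)
    w = list(config.layer_widths)
    weights, biases = [], []
    for fan_in, fan_out in zip(w[:-1], w[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return MLP(widths=tuple(w), weights=weights, biases=biases)


@dataclass
class TrainedModel:
    net: MLP
    model_config: ModelConfig
    training_config: TrainingConfig
    norm_spec: NormalizationSpec
    history: dict[str, list[float]] = field(default_factory=dict)


def mse(net: MLP, x: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean((net.forward(x) - y) ** 2))


def train(
    net: MLP,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    config: TrainingConfig = TrainingConfig(),
    norm_spec: NormalizationSpec = NormalizationSpec(),
    model_config: ModelConfig = ModelConfig(),
) -> TrainedModel:
    """Mini-batch RMSprop training of the hourglass regressor.

    The RMSprop accumulator follows the standard recursion
    ``E <- rho * E + (1 - rho) * g**2`` with update
    ``w <- w - lr * g / (sqrt(E) + epsilon)`` (momentum 0 by default).
    Data are reshuffled every epoch from ``shuffle_seed``; the per-epoch
    mean train batch loss and the validation MSE are recorded.
    """
    x_train = np.asarray(x_train, float)
    y_train = np.asarray(y_train, float)
    if len(x_train) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.shuffle_seed)
    acc_w = [np.zeros_like(w) for w in net.weights]
    acc_b = [np.zeros_like(b) for b in net.biases]
    mom_w = [np.zeros_like(w) for w in net.weights]
    mom_b = [np.zeros_like(b) for b in net.biases]
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    n = len(x_train)
    for _epoch in range(config.epochs):
        perm = rng.permutation(n)
        batch_losses = []
        for start in range(0, n, config.batch_size):
            sel = perm[start : start + config.batch_size]
            xb, yb = x_train[sel], y_train[sel]
            pred, acts = net._forward_cached(xb)
            resid = pred - yb
            loss = float(np.mean(resid**2))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training loss became non-finite ({loss}) at epoch {_epoch}"
                )
            batch_losses.append(loss)
            dout = 2.0 * resid / resid.size
            gw, gb = net._backward(acts, dout)
            for i in range(len(net.weights)):
                acc_w[i] = config.rho * acc_w[i] + (1 - config.rho) * gw[i] ** 2
                acc_b[i] = config.rho * acc_b[i] + (1 - config.rho) * gb[i] ** 2
                step_w = config.learning_rate * gw[i] / (np.sqrt(acc_w[i]) + config.epsilon)
                step_b = config.learning_rate * gb[i] / (np.sqrt(acc_b[i]) + config.epsilon)
                if config.momentum > 0:
                    mom_w[i] = config.momentum * mom_w[i] + step_w
                    mom_b[i] = config.momentum * mom_b[i] + step_b
                    step_w, step_b = mom_w[i], mom_b[i]
                net.weights[i] -= step_w
                net.biases[i] -= step_b
        history["train_loss"].append(float(np.mean(batch_losses)))
        if x_val is not None and len(x_val):
            history["val_loss"].append(mse(net, x_val, y_val))
    return TrainedModel(
        net=net,
        model_config=model_config,
        training_config=config,
        norm_spec=norm_spec,
        history=history,
    )


def split_sessions(
    session_sizes: dict[str, int], spec: SplitSpec = SplitSpec()
) -> dict[str, str]:
    """Assign whole sessions to train/validation/test.

    Sessions are shuffled (``split_seed``), then greedily assigned: each
    session goes to the part whose frame-count deficit against its target
    proportion is currently largest, tie-broken train > validation > test.
    No session is ever divided between parts.
    """
    if len(session_sizes) < 3:
        raise ValueError("need at least 3 sessions to populate train/validation/test")
    ids = list(session_sizes)
    rng = np.random.default_rng(spec.split_seed)
    rng.shuffle(ids)
    total = sum(session_sizes.values())
    parts = ["train", "validation", "test"]
    target = {p: total * q for p, q in zip(parts, spec.proportions)}
    assigned = {p: 0 for p in parts}
    out: dict[str, str] = {}
    for sid in ids:
        deficits = [(target[p] - assigned[p], -k) for k, p in enumerate(parts)]
        part = parts[int(np.argmax([d for d, _ in deficits]))]
        # np.argmax returns the first maximum -> train > validation > test ties
        out[sid] = part
        assigned[part] += session_sizes[sid]
    return out


def make_training_pairs(
    imu9: np.ndarray, curves_normalized: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(input, target) pairs from a processed, synchronized session.

    ``imu9`` is (F, 9) accelerometer channels at the mocap timestamps;
    ``curves_normalized`` is (F, 10, 3).  Targets are markers 2..10 only —
    27 values; the first marker is the fixed origin by construction.
    """
    imu9 = np.asarray(imu9, float).reshape(len(imu9), -1)
    curves = np.asarray(curves_normalized, float)
    if imu9.shape[0] != curves.shape[0]:
        raise ValueError(
            "IMU and mocap frame counts differ — synchronize the streams first"
        )
    if imu9.shape[1] != 9:
        raise ValueError(f"expected 9 IMU channels, got {imu9.shape[1]}")
    return imu9, curves[:, 1:, :].reshape(len(curves), 27)


def predict_curve(model: TrainedModel, imu9: np.ndarray) -> np.ndarray:
    """Reconstruct the 10-point curve (mm, base-relative) from one or more
    9-channel accelerometer frames: forward pass, prepend the fixed origin,
    undo the anisotropic normalization."""
    x = np.atleast_2d(np.asarray(imu9, float))
    if x.shape[1] != 9:
        raise ValueError(f"expected 9 IMU channels, got {x.shape[1]}")
    out = model.net.forward(x).reshape(len(x), 9, 3)
    curves = np.concatenate([np.zeros((len(x), 1, 3)), out], axis=1)
    curves = curves * model.norm_spec.divisors
    return curves if np.asarray(imu9).ndim > 1 else curves[0]


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialize as .npz: weight/bias arrays + a JSON metadata string."""
    meta = {
        "widths": list(model.net.widths),
        "model_config": {"layer_widths": list(model.model_config.layer_widths),
                         "init_seed": model.model_config.init_seed},
        "training_config": dataclasses.asdict(model.training_config),
        "norm_spec": {"horizontal_scale": model.norm_spec.horizontal_scale,
                      "vertical_scale": model.norm_spec.vertical_scale},
        "history": model.history,
    }
    arrays = {f"w{i}": w for i, w in enumerate(model.net.weights)}
    arrays.update({f"b{i}": b for i, b in enumerate(model.net.biases)})
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_model(path: str | Path) -> TrainedModel:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        nw = len(meta["widths"]) - 1
        net = MLP(
            widths=tuple(meta["widths"]),
            weights=[data[f"w{i}"] for i in range(nw)],
            biases=[data[f"b{i}"] for i in range(nw)],
        )
    return TrainedModel(
        net=net,
        model_config=ModelConfig(
            layer_widths=tuple(meta["model_config"]["layer_widths"]),
            init_seed=meta["model_config"]["init_seed"],
        ),
        training_config=TrainingConfig(**meta["training_config"]),
        norm_spec=NormalizationSpec(**meta["norm_spec"]),
        history=meta["history"],
    )
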
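"""Training, inference and hyperparameter tuning for the GRF estimator.

One independent model is trained per force component (vertical or
anteroposterior).  Targets are force traces in bodyweight units (force /
(mass * g)), which removes mass-scale variance from the regression target;
training on raw Newtons is available via ``ModelConfig.target_units``.

Hyperparameter defaults are the selections found by a five-group
cross-validated search for the vertical-force model (hidden 512, learning
rate 5e-4, batch 8, ReLU, ...); desk-scale work typically overrides the
hidden size downward.  :func:`tune` performs a random search over the same
spaces (a sequential model-based optimiser is not required for the search
sizes used here).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from grfest.features import (
    FeatureMatrix,
    Standardizer,
    apply_standardizer,
    fit_standardizer,
)
from grfest.nn import ACTIVATIONS, Adam, BiLSTMRegressor, rmse_loss

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of one force-component estimator."""

    learning_rate: float = 5e-4
    n_epochs: int = 1
    batch_size: int = 8
    lstm_hidden: int = 512
    input_dropout: float = 0.2
    linear_dropout: float = 0.2
    linear2_size: int = 64
    linear3_size: int = 32
    activation: str = "relu"
    target: str = "grf_v"
    target_units: str = "bw"  # "bw" or "newton"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if not (0.0 <= self.input_dropout < 1.0 and 0.0 <= self.linear_dropout < 1.0):
            raise ValueError("dropout rates must lie in [0, 1)")
        if min(self.n_epochs, self.batch_size, self.lstm_hidden, self.linear2_size, self.linear3_size) < 1:
            raise ValueError("sizes and counts must be >= 1")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"activation must be one of {ACTIVATIONS}")
        if self.target not in ("grf_v", "grf_ap"):
            raise ValueError("target must be 'grf_v' or 'grf_ap'")


# reduced configuration for desk-scale experiments: hidden size 64 and a
# larger learning rate / epoch count suited to cohorts of a few hundred
# contacts rather than tens of thousands
REDUCED_CONFIG = ModelConfig(
    learning_rate=2e-3,
    n_epochs=10,
    batch_size=32,
    lstm_hidden=64,
    input_dropout=0.1,
    linear_dropout=0.1,
    linear2_size=64,
    linear3_size=32,
    activation="relu",
)

# the hyperparameter selections for the anteroposterior model
GRF_AP_CONFIG = ModelConfig(
    learning_rate=2e-5,
    n_epochs=8,
    batch_size=8,
    lstm_hidden=512,
    input_dropout=0.5,
    linear_dropout=0.4,
    linear2_size=512,
    linear3_size=512,
    activation="leaky_relu",
    target="grf_ap",
)


@dataclass
class TrainedEstimator:
    """A fitted sequence regressor plus its provenance."""

    net: BiLSTMRegressor
    config: ModelConfig
    standardizer_fingerprint: str = ""
    loss_history: list[float] = field(default_factory=list)

    def describe(self) -> str:
        c = self.config
        return (
            f"input dropout -> biLSTM(H={c.lstm_hidden} per direction) -> "
            f"linear(2H->{c.linear2_size}) -> {c.activation} -> dropout -> "
            f"linear({c.linear2_size}->{c.linear3_size}) -> {c.activation} -> dropout -> "
            f"linear({c.linear3_size}->1), per timestep"
        )


def build_model(config: ModelConfig, input_size: int = 26, dtype: str = "float64") -> TrainedEstimator:
    """Construct an untrained estimator with seeded weight initialization."""
    net = BiLSTMRegressor(
        input_size=input_size,
        hidden_size=config.lstm_hidden,
        linear2_size=config.linear2_size,
        linear3_size=config.linear3_size,
        activation=config.activation,
        input_dropout=config.input_dropout,
        linear_dropout=config.linear_dropout,
        seed=config.seed,
        dtype=dtype,
    )
    return TrainedEstimator(net=net, config=config)


def expected_parameter_count(config: ModelConfig, input_size: int = 26) -> int:
    """Closed-form weight + bias count for the architecture."""
    h, d = config.lstm_hidden, input_size
    lstm = 2 * (4 * h * (d + h + 1))
    head = (
        2 * h * config.linear2_size + config.linear2_size
        + config.linear2_size * config.linear3_size + config.linear3_size
        + config.linear3_size + 1
    )
    return lstm + head


def train(
    estimator: TrainedEstimator,
    train_features: FeatureMatrix,
    train_targets: np.ndarray,
    config: ModelConfig | None = None,
) -> TrainedEstimator:
    """Mini-batch Adam on batch RMSE for ``n_epochs``; deterministic given seed.

    ``train_features`` must be standardized; ``train_targets`` is [n x 400]
    in the units declared by the config.  Batch order is reshuffled once per
    epoch from the config seed.  A non-finite loss aborts with a diagnostic.
    """
    cfg = config or estimator.config
    if not train_features.standardized:
        raise ValueError("train() requires standardized features")
    x = train_features.values
    y = np.asarray(train_targets, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise ValueError("features and targets must align row-wise")
    net = estimator.net
    rng = np.random.default_rng(cfg.seed + 1)
    opt = Adam(net.params, lr=cfg.learning_rate)
    n = x.shape[0]
    for epoch in range(cfg.n_epochs):
        perm = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            pred, cache = net.forward(x[idx], train=True, rng=rng)
            loss, dpred = rmse_loss(pred, y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}, batch {start // cfg.batch_size}: "
                    f"lr={cfg.learning_rate}, batch_size={cfg.batch_size}"
                )
            grads = net.backward(dpred, cache)
            opt.step(net.params, grads)
            epoch_losses.append(loss)
        estimator.loss_history.append(float(np.mean(epoch_losses)))
    return estimator


def predict(estimator: TrainedEstimator, features: FeatureMatrix) -> np.ndarray:
    """Deterministic inference (dropout disabled): [n x 400] force traces."""
    if not features.standardized:
        raise ValueError("predict() requires standardized features")
    return estimator.net.predict(features.values)


def fit_fold(
    train_raw: FeatureMatrix,
    train_targets: np.ndarray,
    config: ModelConfig,
    dtype: str = "float64",
) -> tuple[TrainedEstimator, Standardizer]:
    """Fit the standardizer and the model on one training split."""
    std = fit_standardizer(train_raw)
    est = build_model(config, input_size=len(train_raw.channel_names), dtype=dtype)
    est.standardizer_fingerprint = std.fingerprint
    train(est, apply_standardizer(std, train_raw), train_targets, config)
    return est, std


# --------------------------------------------------------------------------
# hyperparameter search
# --------------------------------------------------------------------------


def default_search_space() -> dict:
    """The tuned search spaces: log-uniform learning rate, categorical sizes."""
    return {
        "learning_rate": ("loguniform", 1e-5, 1e-1),
        "n_epochs": ("int", 1, 15),
        "batch_size": ("choice", [8, 16, 32, 64, 128]),
        "lstm_hidden": ("choice", [32, 64, 128, 256, 512]),
        "input_dropout": ("uniform", 0.1, 0.5),
        "linear_dropout": ("uniform", 0.1, 0.5),
        "linear2_size": ("choice", [32, 64, 128, 256, 512]),
        "linear3_size": ("choice", [32, 64, 128, 256, 512]),
        "activation": ("choice", list(ACTIVATIONS)),
    }


def _sample_config(space: dict, base: ModelConfig, rng: np.random.Generator) -> ModelConfig:
    updates = {}
    for name, spec in space.items():
        kind = spec[0]
        if kind == "choice":
            values = spec[1]
            updates[name] = values[rng.integers(len(values))]
        elif kind == "uniform":
            updates[name] = float(rng.uniform(spec[1], spec[2]))
        elif kind == "loguniform":
            updates[name] = float(np.exp(rng.uniform(np.log(spec[1]), np.log(spec[2]))))
        elif kind == "int":
            updates[name] = int(rng.integers(spec[1], spec[2] + 1))
        else:
            raise ValueError(f"unknown space kind {kind!r} for {name!r}")
    return replace(base, **updates)


def cross_val_rmse(
    features: FeatureMatrix,
    targets: np.ndarray,
    groups: np.ndarray,
    config: ModelConfig,
    dtype: str = "float64",
) -> float:
    """Mean validation RMSE across group folds (each group held out once).

    Groups must be subject-disjoint; leak-free standardization is refitted
    inside every fold.
    """
    groups = np.asarray(groups)
    fold_ids = np.unique(groups)
    if len(fold_ids) < 2:
        raise ValueError("need at least 2 subject-disjoint groups")
    losses = []
    for gid in fold_ids:
        val_mask = groups == gid
        tr = FeatureMatrix(
            values=features.values[~val_mask],
            channel_names=features.channel_names,
            standardized=False,
        )
        va = FeatureMatrix(
            values=features.values[val_mask],
            channel_names=features.channel_names,
            standardized=False,
        )
        est, std = fit_fold(tr, targets[~val_mask], config, dtype=dtype)
        pred = predict(est, apply_standardizer(std, va))
        losses.append(float(np.sqrt(np.mean((pred - targets[val_mask]) ** 2))))
    return float(np.mean(losses))


def tune(
    features: FeatureMatrix,
    targets: np.ndarray,
    groups: np.ndarray,
    search_space: dict | None = None,
    n_trials: int = 25,
    seed: int = 0,
    base_config: ModelConfig | None = None,
    dtype: str = "float64",
    log_path: str | Path | None = None,
) -> tuple[ModelConfig, list[dict]]:
    """Random search over the hyperparameter spaces.

    The objective is the mean validation RMSE across the subject-group
    folds.  Returns the best config and the full trial log; the log is also
    written as JSON-lines when ``log_path`` is given.
    """
    space = default_search_space() if search_space is None else search_space
    if not space:
        raise ValueError("search space must be non-empty")
    base = base_config or ModelConfig()
    rng = np.random.default_rng(seed)
    log: list[dict] = []
    best: tuple[float, ModelConfig] | None = None
    for trial in range(n_trials):
        cfg = _sample_config(space, base, rng)
        objective = cross_val_rmse(features, targets, groups, cfg, dtype=dtype)
        log.append({"trial": trial, "objective": objective, "config": asdict(cfg)})
        if best is None or objective < best[0]:
            best = (objective, cfg)
    if log_path is not None:
        with open(log_path, "w") as fh:
            for entry in log:
                fh.write(json.dumps(entry) + "\n")
    assert best is not None
    return best[1], log


# --------------------------------------------------------------------------
# checkpoints
# --------------------------------------------------------------------------


def save_checkpoint(estimator: TrainedEstimator, path: str | Path) -> None:
    """Persist weights + config + standardizer fingerprint in one archive."""
    path = Path(path)
    meta = {
        "config": asdict(estimator.config),
        "standardizer_fingerprint": estimator.standardizer_fingerprint,
        "loss_history": estimator.loss_history,
        "dtype": str(estimator.net.dtype),
        "input_size": estimator.net.D,
    }
    np.savez(
        path,
        __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        **estimator.net.params,
    )


def load_checkpoint(path: str | Path) -> TrainedEstimator:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        params = {k: archive[k] for k in archive.files if k != "__meta__"}
    config = ModelConfig(**meta["config"])
    est = build_model(config, input_size=meta["input_size"], dtype=meta["dtype"])
    est.net.params = params
    est.standardizer_fingerprint = meta["standardizer_fingerprint"]
    est.loss_history = list(meta["loss_history"])
    return est
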
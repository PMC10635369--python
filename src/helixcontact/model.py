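"""Feed-forward contact classifier.

Architecture: an optional frozen linear projection lifting 40-d structurally
derived feature vectors to 192 dimensions (coordinate vectors enter at 192-d
directly), followed by six leaky-ReLU hidden layers and a single sigmoid
output.  Training uses Adam on mean binary cross-entropy with per-parameter
gradient clipping to [-1, 1]; trainable weights are Xavier-uniform
initialized and the projection is drawn once (Xavier-uniform, no bias) from
its own seed and never updated.

The network is small enough that a NumPy implementation is both fast on one
CPU core and exactly reproducible across runs given fixed seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from helixcontact.features import (
    CF_LENGTH,
    SDF_LENGTH,
    FeatureMatrix,
    ScalingParams,
    apply_scaler,
    fit_scaler,
)

__all__ = [
    "ModelConfig",
    "TrainedModel",
    "ModelError",
    "DegenerateTrainingSetError",
    "projection_matrix",
    "static_projection",
    "train",
    "predict_scores",
    "save_model",
    "load_model",
]

CHECKPOINT_FORMAT_VERSION = "helixcontact-checkpoint-1"

_HIDDEN_DEFAULT = (512, 256, 128, 64, 32, 16)


class ModelError(ValueError):
    pass


class DegenerateTrainingSetError(ModelError):
    """Training labels contain only one class."""


@dataclass
class ModelConfig:
    hidden_sizes: tuple[int, ...] = _HIDDEN_DEFAULT
    leaky_slope: float = 0.01
    learning_rate: float = 0.0001
    batch_size: int = 256
    epochs: int = 400
    grad_clip: float = 1.0
    seed: int = 0
    projection_seed: int = 0
    class_weighting: bool = False

    def __post_init__(self):
        self.hidden_sizes = tuple(int(h) for h in self.hidden_sizes)
        if len(self.hidden_sizes) != 6 or any(h <= 0 for h in self.hidden_sizes):
            raise ModelError("exactly 6 positive hidden layer sizes required")
        if self.leaky_slope <= 0:
            raise ModelError("leaky_slope must be > 0")


def _xavier_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def projection_matrix(projection_seed: int) -> np.ndarray:
    """The frozen 40 -> 192 projection (Xavier-uniform, no bias)."""
    rng = np.random.default_rng(projection_seed)
    return _xavier_uniform(rng, SDF_LENGTH, CF_LENGTH)


def static_projection(v: np.ndarray, projection_seed: int) -> np.ndarray:
    """Apply the frozen projection to a 40-vector (or a matrix of rows)."""
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != SDF_LENGTH:
        raise ModelError(f"projection input must have width {SDF_LENGTH}, got {v.shape}")
    return v @ projection_matrix(projection_seed)


@dataclass
class TrainedModel:
    config: ModelConfig
    input_kind: str
    scaler: ScalingParams
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    projection: np.ndarray | None
    training_log: list[float] = field(default_factory=list)


def _leaky(z: np.ndarray, slope: float) -> np.ndarray:
    return np.where(z > 0, z, slope * z)


def _leaky_grad(z: np.ndarray, slope: float) -> np.ndarray:
    return np.where(z > 0, 1.0, slope)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _forward(
    x: np.ndarray,
    weights: list[np.ndarray],
    biases: list[np.ndarray],
    slope: float,
) -> tuple[np.ndarray, list[np.ndarray], list[np.ndarray]]:
    """Returns (probabilities, pre-activations, activations per layer)."""
    zs, activations = [], [x]
    h = x
    for w, b in zip(weights[:-1], biases[:-1]):
        z = h @ w + b
        h = _leaky(z, slope)
        zs.append(z)
        activations.append(h)
    z_out = h @ weights[-1] + biases[-1]
    zs.append(z_out)
    p = _sigmoid(z_out[:, 0])
    return p, zs, activations


def _bce(p: np.ndarray, y: np.ndarray, sample_weight: np.ndarray | None) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    losses = -(y * np.log(p) + (1 - y) * np.log(1 - p))
    if sample_weight is None:
        return float(losses.mean())
    return float((losses * sample_weight).sum() / sample_weight.sum())


def train(
    features: FeatureMatrix,
    labels: np.ndarray,
    config: ModelConfig,
    scaler: ScalingParams | None = None,
) -> TrainedModel:
    """Fit the classifier on one feature matrix.

    ``scaler`` defaults to min/max fitted on ``features`` itself; pass the
    params fitted on the full experimental training set when training folds
    share a frame.  The scaler is stored in the model and re-applied at
    prediction time, so raw (unscaled) matrices are expected everywhere.
    """
    labels = np.asarray(labels, dtype=float)
    if labels.shape != (len(features),):
        raise ModelError("labels must align with feature rows")
    if labels.min() == labels.max():
        raise DegenerateTrainingSetError(
            "training labels contain a single class"
        )

    if scaler is None:
        scaler = fit_scaler(features)
    x = apply_scaler(scaler, features).vectors

    projection = None
    if features.kind == "SDF":
        projection = projection_matrix(config.projection_seed)
        x = x @ projection
    elif x.shape[1] != CF_LENGTH:
        raise ModelError(f"CF input must have width {CF_LENGTH}")

    rng = np.random.default_rng(config.seed)
    sizes = [CF_LENGTH, *config.hidden_sizes, 1]
    weights = [_xavier_uniform(rng, a, b) for a, b in zip(sizes, sizes[1:])]
    biases = [np.zeros(b) for b in sizes[1:]]

    sample_weight = None
    if config.class_weighting:
        n_pos = labels.sum()
        n_neg = len(labels) - n_pos
        sample_weight = np.where(labels == 1, n_neg / n_pos, 1.0)

    # Adam state
    m = [np.zeros_like(w) for w in weights] + [np.zeros_like(b) for b in biases]
    v = [np.zeros_like(w) for w in weights] + [np.zeros_like(b) for b in biases]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    n = len(labels)
    log: list[float] = []

    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for lo in range(0, n, config.batch_size):
            idx = order[lo: lo + config.batch_size]
            xb, yb = x[idx], labels[idx]
            wb = sample_weight[idx] if sample_weight is not None else None
            p, zs, activations = _forward(xb, weights, biases, config.leaky_slope)
            loss = _bce(p, yb, wb)
            if not np.isfinite(loss):
                raise ModelError(
                    f"non-finite loss at epoch {_epoch}, batch offset {lo}: {loss}"
                )
            epoch_loss += loss * len(idx)

            # dL/dz_out for mean BCE through the sigmoid
            if wb is None:
                delta = ((p - yb) / len(idx))[:, None]
            else:
                delta = ((p - yb) * wb / wb.sum())[:, None]
            grads_w, grads_b = [], []
            for layer in range(len(weights) - 1, -1, -1):
                grads_w.append(activations[layer].T @ delta)
                grads_b.append(delta.sum(axis=0))
                if layer > 0:
                    delta = (delta @ weights[layer].T) * _leaky_grad(
                        zs[layer - 1], config.leaky_slope
                    )
            grads_w.reverse()
            grads_b.reverse()

            step += 1
            params = weights + biases
            grads = grads_w + grads_b
            for k, (param, grad) in enumerate(zip(params, grads)):
                grad = np.clip(grad, -config.grad_clip, config.grad_clip)
                m[k] = beta1 * m[k] + (1 - beta1) * grad
                v[k] = beta2 * v[k] + (1 - beta2) * grad * grad
                m_hat = m[k] / (1 - beta1 ** step)
                v_hat = v[k] / (1 - beta2 ** step)
                param -= config.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
        log.append(epoch_loss / n)

    return TrainedModel(
        config=config,
        input_kind=features.kind,
        scaler=scaler,
        weights=weights,
        biases=biases,
        projection=projection,
        training_log=log,
    )


def predict_scores(model: TrainedModel, features: FeatureMatrix) -> np.ndarray:
    """Contact probabilities in (0, 1), aligned with ``features.pair_index``."""
    if features.kind != model.input_kind:
        raise ModelError(
            f"feature kind {features.kind!r} does not match model kind "
            f"{model.input_kind!r}"
        )
    x = apply_scaler(model.scaler, features).vectors
    if model.projection is not None:
        x = x @ model.projection
    p, _, _ = _forward(x, model.weights, model.biases, model.config.leaky_slope)
    return np.clip(p, 1e-12, 1 - 1e-12)


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Versioned npz checkpoint bundling weights, config, kind and scaler."""
    meta = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "config": asdict(model.config),
        "input_kind": model.input_kind,
        "scaler_kind": model.scaler.kind,
        "n_layers": len(model.weights),
        "has_projection": model.projection is not None,
    }
    arrays = {
        "meta_json": np.array(json.dumps(meta)),
        "scaler_min": model.scaler.minimum,
        "scaler_max": model.scaler.maximum,
        "training_log": np.asarray(model.training_log, dtype=float),
    }
    for k, (w, b) in enumerate(zip(model.weights, model.biases)):
        arrays[f"w{k}"] = w
        arrays[f"b{k}"] = b
    if model.projection is not None:
        arrays["projection"] = model.projection
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_model(path: str | Path) -> TrainedModel:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta_json"]))
        if meta["format_version"] != CHECKPOINT_FORMAT_VERSION:
            raise ModelError(
                f"unsupported checkpoint format {meta['format_version']!r}"
            )
        config = ModelConfig(**{
            **meta["config"],
            "hidden_sizes": tuple(meta["config"]["hidden_sizes"]),
        })
        scaler = ScalingParams(
            kind=meta["scaler_kind"],
            minimum=data["scaler_min"],
            maximum=data["scaler_max"],
        )
        weights = [data[f"w{k}"] for k in range(meta["n_layers"])]
        biases = [data[f"b{k}"] for k in range(meta["n_layers"])]
        projection = data["projection"] if meta["has_projection"] else None
        return TrainedModel(
            config=config,
            input_kind=meta["input_kind"],
            scaler=scaler,
            weights=weights,
            biases=biases,
            projection=projection,
            training_log=list(data["training_log"]),
        )
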
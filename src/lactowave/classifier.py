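"""Self-normalizing neural network (SNN) pregnancy classifier.

Samples are classified PREGNANT / NONPREGNANT from their four fitted
dielectric parameters (delta_eps, tau, alpha, sigma_dc).  The network is a
fully connected SNN: eight hidden layers of 50 units with SELU activation,
alpha dropout (p = 0.01) after each, and a single sigmoid output trained
with binary cross-entropy.  SELU with LeCun-normal initialisation
(zero-mean weights, variance 1/fan_in) keeps activations near zero mean
and unit variance through depth, which is what lets a network this deep
train on a few hundred points without batch normalisation; alpha dropout
saturates dropped units to the SELU negative limit instead of zero so the
self-normalizing property survives regularisation.

The training protocol mirrors a small-cohort study: the majority class is
randomly down-sampled to the minority size, features are scaled to order 1
by fixed reference scales (no statistics leak across the split), a fixed
number of test points per class is held out, and the Adam optimiser runs
20 epochs full-batch with beta1 = 0.9, beta2 = 0.999, epsilon = 1e-5.
Everything — balancing, split, initialisation, dropout masks — draws from
one seed, so runs are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model import ValidationError

__all__ = [
    "SELU_LAMBDA",
    "SELU_ALPHA",
    "FeatureSet",
    "SNNSpec",
    "TrainConfig",
    "LearningCurves",
    "SNNModel",
    "TrainingError",
    "selu",
    "balance_downsample",
    "scale_features",
    "holdout_split",
    "build_snn",
    "train",
    "evaluate",
    "features_from_table",
    "DEFAULT_FEATURE_SCALES",
]

# fixed SELU constants of the self-normalizing formulation
SELU_LAMBDA = 1.0507009873554805
SELU_ALPHA = 1.6732632423543772
# alpha dropout saturates to the SELU negative limit -lambda*alpha
_ALPHA_PRIME = -SELU_LAMBDA * SELU_ALPHA

LABEL_PREGNANT = "PREGNANT"
LABEL_NONPREGNANT = "NONPREGNANT"

#: Fixed reference scales bringing each feature to order 1:
#: delta_eps/70, tau/10 ps, alpha/1, sigma_dc/1 S/m.
DEFAULT_FEATURE_SCALES = (70.0, 10.0, 1.0, 1.0)

#: Fixed reference centers and deviation scales used when preparing
#: classifier features from a fitted cohort: the physiological information
#: lives in small deviations around a common milk baseline, so features are
#: centred at reference values (delta_eps 68, tau 9 ps, alpha 0.985,
#: sigma_dc 0.9 S/m) and scaled by typical day-to-day deviations.  These are
#: configuration constants fixed before any split — nothing is estimated
#: from the data, so no statistics leak between train and test.
DEFAULT_FEATURE_CENTERS = (68.0, 9.0, 0.985, 0.9)
DEFAULT_DEVIATION_SCALES = (0.5, 1.0, 0.003, 0.015)


class TrainingError(RuntimeError):
    """Training diverged (non-finite loss)."""


@dataclass
class FeatureSet:
    """Feature matrix (n x 4), binary labels, and provenance ids."""

    features: np.ndarray
    labels: np.ndarray  # strings PREGNANT / NONPREGNANT
    ids: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        self.ids = np.asarray(self.ids)
        if self.features.ndim != 2:
            raise ValidationError("features must be 2-D (n_samples x n_features)")
        n = self.features.shape[0]
        if not (self.labels.shape == (n,) == self.ids.shape):
            raise ValidationError("features, labels and ids must align")
        bad = set(np.unique(self.labels)) - {LABEL_PREGNANT, LABEL_NONPREGNANT}
        if bad:
            raise ValidationError(f"labels must be binary, found {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return int(self.features.shape[0])

    def y(self) -> np.ndarray:
        """0/1 target vector (1 = pregnant)."""
        return (self.labels == LABEL_PREGNANT).astype(float)

    def subset(self, idx: np.ndarray) -> "FeatureSet":
        return FeatureSet(self.features[idx], self.labels[idx], self.ids[idx])


@dataclass
class SNNSpec:
    """Architecture of the classifier network."""

    n_inputs: int = 4
    n_layers: int = 8
    width: int = 50
    dropout_p: float = 0.01

    def validate(self) -> "SNNSpec":
        if self.n_inputs < 1 or self.n_layers < 1 or self.width < 1:
            raise ValidationError("n_inputs, n_layers and width must be >= 1")
        if not 0 <= self.dropout_p < 1:
            raise ValidationError("dropout_p must lie in [0, 1)")
        return self


@dataclass
class TrainConfig:
    """Optimiser settings: Adam with the stated moments, 20 epochs, full batch."""

    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-5
    n_epochs: int = 20
    batch_size: int | None = None  # None = full batch
    seed: int = 0


@dataclass
class LearningCurves:
    """Per-epoch train/validation loss and accuracy."""

    train_loss: np.ndarray
    train_accuracy: np.ndarray
    validation_loss: np.ndarray
    validation_accuracy: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": np.arange(1, self.train_loss.size + 1),
            "train_loss": self.train_loss,
            "train_accuracy": self.train_accuracy,
            "validation_loss": self.validation_loss,
            "validation_accuracy": self.validation_accuracy,
        })


def selu(x: np.ndarray) -> np.ndarray:
    """Scaled exponential linear unit, lambda*x for x>0 else lambda*alpha*(e^x-1)."""
    x = np.asarray(x, dtype=float)
    return SELU_LAMBDA * np.where(x > 0, x, SELU_ALPHA * np.expm1(np.minimum(x, 0.0)))


def _selu_grad(x: np.ndarray) -> np.ndarray:
    return SELU_LAMBDA * np.where(x > 0, 1.0, SELU_ALPHA * np.exp(np.minimum(x, 0.0)))


def balance_downsample(fs: FeatureSet, seed: int = 0) -> FeatureSet:
    """Randomly down-sample the majority class to the minority size.

    Sampling is without replacement and seeded; an already balanced set is
    returned unchanged up to ordering.
    """
    rng = np.random.default_rng(seed)
    idx_p = np.flatnonzero(fs.labels == LABEL_PREGNANT)
    idx_n = np.flatnonzero(fs.labels == LABEL_NONPREGNANT)
    if idx_p.size == 0 or idx_n.size == 0:
        raise ValidationError("both classes must be present to balance")
    k = min(idx_p.size, idx_n.size)
    keep_p = rng.choice(idx_p, size=k, replace=False) if idx_p.size > k else idx_p
    keep_n = rng.choice(idx_n, size=k, replace=False) if idx_n.size > k else idx_n
    keep = np.sort(np.concatenate([keep_p, keep_n]))
    return fs.subset(keep)


def scale_features(
    features: np.ndarray,
    scales: Sequence[float] = DEFAULT_FEATURE_SCALES,
    centers: Sequence[float] | None = None,
) -> np.ndarray:
    """Scale features to order 1 by fixed reference constants.

    Each column is divided by its reference scale; with ``centers`` given,
    the reference center is subtracted first.  Scales and centers are
    configuration, fixed before any train/test split, so no statistics can
    leak from test to train.
    """
    scales = np.asarray(scales, dtype=float)
    if np.any(scales <= 0) or not np.all(np.isfinite(scales)):
        raise ValidationError(f"reference scales must be positive, got {scales}")
    features = np.asarray(features, dtype=float)
    if features.shape[1] != scales.size:
        raise ValidationError(
            f"{features.shape[1]} feature columns vs {scales.size} scales"
        )
    if centers is not None:
        centers = np.asarray(centers, dtype=float)
        if centers.size != scales.size or not np.all(np.isfinite(centers)):
            raise ValidationError("centers must be finite and align with scales")
        features = features - centers
    return features / scales


def holdout_split(
    fs: FeatureSet, test_per_class: int = 15, seed: int = 0
) -> tuple[FeatureSet, FeatureSet]:
    """Hold out exactly ``test_per_class`` random samples per class.

    Returns ``(train, test)``; the two partition the input.
    """
    if test_per_class < 0:
        raise ValidationError("test_per_class must be >= 0")
    rng = np.random.default_rng(seed)
    test_idx: list[np.ndarray] = []
    for label in (LABEL_PREGNANT, LABEL_NONPREGNANT):
        idx = np.flatnonzero(fs.labels == label)
        if idx.size < test_per_class:
            raise ValidationError(
                f"class {label} has {idx.size} samples, "
                f"fewer than test_per_class={test_per_class}"
            )
        if test_per_class:
            test_idx.append(rng.choice(idx, size=test_per_class, replace=False))
    test = np.sort(np.concatenate(test_idx)) if test_idx else np.array([], dtype=int)
    mask = np.ones(fs.n_samples, dtype=bool)
    mask[test] = False
    return fs.subset(np.flatnonzero(mask)), fs.subset(test)


@dataclass
class SNNModel:
    """Weights and architecture of the SNN; forward pass lives here."""

    spec: SNNSpec
    weights: list[np.ndarray]
    biases: list[np.ndarray]

    @property
    def n_parameters(self) -> int:
        return int(sum(w.size for w in self.weights) + sum(b.size for b in self.biases))

    def forward(
        self,
        x: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, dict]:
        """Sigmoid output probabilities; caches intermediates for backprop.

        Alpha dropout is applied only when ``train=True`` (inference is
        deterministic and dropout-free).
        """
        x = np.atleast_2d(np.asarray(x, dtype=float))
        p = self.spec.dropout_p
        cache: dict = {"inputs": [], "pre": [], "masks": []}
        h = x
        for layer in range(self.spec.n_layers):
            cache["inputs"].append(h)
            z = h @ self.weights[layer] + self.biases[layer]
            cache["pre"].append(z)
            h = selu(z)
            if train and p > 0:
                if rng is None:
                    raise ValidationError("training forward pass needs an rng for dropout")
                q = 1.0 - p
                mask = rng.random(h.shape) < q
                a = (q + _ALPHA_PRIME**2 * p * q) ** -0.5
                b = -a * p * _ALPHA_PRIME
                h = a * (np.where(mask, h, _ALPHA_PRIME)) + b
                cache["masks"].append((mask, a))
            else:
                cache["masks"].append(None)
        cache["inputs"].append(h)
        z_out = h @ self.weights[-1] + self.biases[-1]
        prob = 1.0 / (1.0 + np.exp(-z_out[:, 0]))
        return prob, cache

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        prob, _ = self.forward(x, train=False)
        return prob


def build_snn(spec: SNNSpec | None = None, seed: int = 0) -> SNNModel:
    """Initialise an SNN with zero-mean, variance-1/fan_in normal weights."""
    spec = (spec or SNNSpec()).validate()
    rng = np.random.default_rng(seed)
    sizes = [spec.n_inputs] + [spec.width] * spec.n_layers + [1]
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        weights.append(rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return SNNModel(spec=spec, weights=weights, biases=biases)


def _bce(prob: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(prob, eps, 1 - eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _backward(model: SNNModel, cache: dict, prob: np.ndarray, y: np.ndarray
              ) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Gradients of mean BCE w.r.t. all weights and biases."""
    n = y.size
    grads_w = [np.zeros_like(w) for w in model.weights]
    grads_b = [np.zeros_like(b) for b in model.biases]
    delta = ((prob - y) / n)[:, None]          # d loss / d z_out
    h_last = cache["inputs"][-1]
    grads_w[-1] = h_last.T @ delta
    grads_b[-1] = delta.sum(axis=0)
    dh = delta @ model.weights[-1].T
    for layer in range(model.spec.n_layers - 1, -1, -1):
        mask_entry = cache["masks"][layer]
        if mask_entry is not None:
            mask, a = mask_entry
            dh = dh * a * mask
        dz = dh * _selu_grad(cache["pre"][layer])
        grads_w[layer] = cache["inputs"][layer].T @ dz
        grads_b[layer] = dz.sum(axis=0)
        if layer:
            dh = dz @ model.weights[layer].T
    return grads_w, grads_b


def train(
    model: SNNModel,
    train_set: FeatureSet,
    config: TrainConfig | None = None,
    validation_set: FeatureSet | None = None,
) -> LearningCurves:
    """Train in place with Adam + BCE, recording per-epoch learning curves.

    Metrics are evaluated dropout-free on the train set and on the
    validation set (if given) after every epoch.  Raises
    :class:`TrainingError` on divergence.
    """
    config = config or TrainConfig()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    x, y = train_set.features, train_set.y()
    n = x.shape[0]
    batch = n if config.batch_size is None else min(config.batch_size, n)

    params = model.weights + model.biases
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    t = 0
    tr_loss, tr_acc, va_loss, va_acc = [], [], [], []
    for _ in range(config.n_epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch):
            idx = order[start:start + batch]
            prob, cache = model.forward(x[idx], train=True, rng=rng)
            if not np.all(np.isfinite(prob)):
                raise TrainingError("non-finite activations during training")
            gw, gb = _backward(model, cache, prob, y[idx])
            grads = gw + gb
            t += 1
            for k, (p_arr, g) in enumerate(zip(params, grads)):
                m[k] = config.beta1 * m[k] + (1 - config.beta1) * g
                v[k] = config.beta2 * v[k] + (1 - config.beta2) * g * g
                mhat = m[k] / (1 - config.beta1**t)
                vhat = v[k] / (1 - config.beta2**t)
                p_arr -= config.learning_rate * mhat / (np.sqrt(vhat) + config.epsilon)
        loss, acc = evaluate(model, train_set)
        if not np.isfinite(loss):
            raise TrainingError(f"training loss diverged (loss={loss})")
        tr_loss.append(loss)
        tr_acc.append(acc)
        if validation_set is not None:
            vl, va = evaluate(model, validation_set)
            va_loss.append(vl)
            va_acc.append(va)
        else:
            va_loss.append(float("nan"))
            va_acc.append(float("nan"))
    return LearningCurves(
        train_loss=np.array(tr_loss), train_accuracy=np.array(tr_acc),
        validation_loss=np.array(va_loss), validation_accuracy=np.array(va_acc),
    )


def evaluate(model: SNNModel, fs: FeatureSet) -> tuple[float, float]:
    """(mean binary cross-entropy, accuracy at the 0.5 threshold)."""
    if fs.n_samples == 0:
        raise ValidationError("cannot evaluate on an empty feature set")
    prob = model.predict_proba(fs.features)
    y = fs.y()
    acc = float(np.mean((prob >= 0.5) == (y == 1.0)))
    return _bce(prob, y), acc


def features_from_table(
    table: pd.DataFrame,
    feature_columns: Sequence[str] = ("delta_eps", "tau", "alpha", "sigma_dc"),
    stage_column: str | None = None,
    scales: Sequence[float] = DEFAULT_DEVIATION_SCALES,
    centers: Sequence[float] | None = DEFAULT_FEATURE_CENTERS,
) -> FeatureSet:
    """Scaled FeatureSet from a fitted cohort table.

    A sample is labelled PREGNANT when it was taken during an established
    or developing pregnancy (stage2/stage3); pre-insemination samples and
    samples from nonpregnant cows are NONPREGNANT.  Features are centred
    at the fixed milk reference values and scaled by typical deviations,
    because the pregnancy signal lives in small excursions around a common
    baseline.
    """
    from .variability import assign_stages

    stages = table[stage_column] if stage_column else assign_stages(table)
    labels = np.where(stages.isin(["stage2", "stage3"]),
                      LABEL_PREGNANT, LABEL_NONPREGNANT)
    feats = scale_features(table[list(feature_columns)].to_numpy(float),
                           scales, centers)
    ids = (table["spectrum_ref"].to_numpy()
           if "spectrum_ref" in table.columns else table.index.to_numpy())
    return FeatureSet(features=feats, labels=labels, ids=ids)
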
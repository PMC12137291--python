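"""Trainable patch classifiers.

The training regime is fixed by :class:`TrainingConfig`: Adam at learning
rate 0.001, batch size 16, 50 epochs, with a step learning-rate schedule
(×0.1 every 10 epochs).  The backbone contract is deliberately small — any
estimator mapping a ``p × p × 3`` patch to a probability vector over its
label subset fits — and the default backbone shipped here is
:class:`PatchNetClassifier`, a compact fully-connected softmax network
sized for 10×10×3 inputs.  Ten-pixel patches are dominated by color and
coarse texture, which a two-layer network on raw pixels separates well;
larger pretrained backbones can be plugged in behind the same estimator
interface.

Class imbalance is handled by the weighted with-replacement sampler from
:mod:`plantpatch.annotation`, not by loss weighting.  The final-epoch model
is returned; per-epoch loss (and learning rate) are logged on the estimator
so the trajectory is auditable.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .annotation import ClassWeights

__all__ = ["TrainingConfig", "PatchNetClassifier", "train", "save_model", "load_model"]


@dataclasses.dataclass
class TrainingConfig:
    """Hyperparameters for patch-classifier training."""

    learning_rate: float = 0.001
    optimizer: str = "adam"
    batch_size: int = 16
    epochs: int = 50
    scheduler_step_size: int = 10
    scheduler_gamma: float = 0.1
    patch_size: int = 10
    seed: int = 0
    hidden_units: int = 64
    epoch_length: int | None = None  # weighted-sampler draws per epoch

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrainingConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def lr_at_epoch(self, epoch: int) -> float:
        """Learning rate used during 0-based *epoch* under the step schedule."""
        return self.learning_rate * self.scheduler_gamma ** (
            epoch // self.scheduler_step_size
        )


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class PatchNetClassifier(ClassifierMixin, BaseEstimator):
    """A small fully-connected softmax network for RGB patches.

    Architecture: flatten → dense(hidden_units, ReLU) → dense(n_classes,
    softmax), trained with mini-batch Adam under a step learning-rate
    schedule.  Deterministic for a fixed ``seed``.

    Parameters
    ----------
    hidden_units : int
        Width of the single hidden layer.
    learning_rate, batch_size, epochs, step_size, gamma
        Optimization schedule; the learning rate decays by ``gamma`` every
        ``step_size`` epochs.
    seed : int
        Seeds weight initialization and batch shuffling.

    Attributes
    ----------
    classes_ : ndarray
        Sorted class labels seen in ``fit``.
    loss_curve_ : list of float
        Mean cross-entropy per epoch.
    lr_schedule_ : list of float
        Learning rate used in each epoch.
    input_shape_ : tuple
        Expected per-patch shape at prediction time.
    """

    def __init__(
        self,
        hidden_units: int = 64,
        learning_rate: float = 0.001,
        batch_size: int = 16,
        epochs: int = 50,
        step_size: int = 10,
        gamma: float = 0.1,
        seed: int = 0,
    ):
        self.hidden_units = hidden_units
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.step_size = step_size
        self.gamma = gamma
        self.seed = seed

    # -- internals ---------------------------------------------------------

    def _flatten(self, X: np.ndarray, fitting: bool = False) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim == 2:  # already flat
            shape = (X.shape[1],)
        else:
            shape = tuple(X.shape[1:])
        if fitting:
            self.input_shape_ = shape
        elif shape != self.input_shape_:
            raise ValueError(
                f"patch shape {shape} does not match training shape "
                f"{self.input_shape_}"
            )
        return X.reshape(X.shape[0], -1).astype(np.float64) / 255.0

    def fit(self, X: np.ndarray, y: Sequence) -> "PatchNetClassifier":
        """Train on patches *X* (n × p × p × 3, uint8) with labels *y*."""
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError(
                f"degenerate training set: only one label present "
                f"({self.classes_[0]!r})"
            )
        Xf = self._flatten(X, fitting=True)
        n, d = Xf.shape
        k = len(self.classes_)
        rng = np.random.default_rng(self.seed)

        W1 = rng.normal(0.0, np.sqrt(2.0 / d), size=(d, self.hidden_units))
        b1 = np.zeros(self.hidden_units)
        W2 = rng.normal(0.0, np.sqrt(2.0 / self.hidden_units), size=(self.hidden_units, k))
        b2 = np.zeros(k)

        params = [W1, b1, W2, b2]
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0

        Y = np.eye(k)[y_idx]
        self.loss_curve_ = []
        self.lr_schedule_ = []
        for epoch in range(self.epochs):
            lr = self.learning_rate * self.gamma ** (epoch // self.step_size)
            self.lr_schedule_.append(lr)
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = Xf[idx], Y[idx]
                h_pre = xb @ W1 + b1
                h = np.maximum(h_pre, 0.0)
                probs = _softmax(h @ W2 + b2)
                losses.append(
                    -np.mean(np.log(np.clip((probs * yb).sum(axis=1), 1e-12, None)))
                )
                # backprop
                dz2 = (probs - yb) / len(idx)
                grads = [
                    xb.T @ ((dz2 @ W2.T) * (h_pre > 0)),
                    ((dz2 @ W2.T) * (h_pre > 0)).sum(axis=0),
                    h.T @ dz2,
                    dz2.sum(axis=0),
                ]
                t += 1
                for p, g, mi, vi in zip(params, grads, m, v):
                    mi *= beta1
                    mi += (1 - beta1) * g
                    vi *= beta2
                    vi += (1 - beta2) * g * g
                    m_hat = mi / (1 - beta1**t)
                    v_hat = vi / (1 - beta2**t)
                    p -= lr * m_hat / (np.sqrt(v_hat) + eps)
            self.loss_curve_.append(float(np.mean(losses)))
        self.coefs_ = (W1, b1, W2, b2)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Probability vector over ``classes_`` for each patch (rows sum to 1)."""
        check_is_fitted(self, "coefs_")
        Xf = self._flatten(X)
        W1, b1, W2, b2 = self.coefs_
        h = np.maximum(Xf @ W1 + b1, 0.0)
        return _softmax(h @ W2 + b2)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def confidence(self, X: np.ndarray) -> np.ndarray:
        """Max class probability (multiclass) per patch."""
        return self.predict_proba(X).max(axis=1)


def train(
    X: np.ndarray,
    y: Sequence,
    config: TrainingConfig | None = None,
    weights: ClassWeights | None = None,
) -> PatchNetClassifier:
    """Fit a :class:`PatchNetClassifier` under *config*.

    If *weights* are given, each epoch's examples are drawn with
    replacement with probability proportional to the patch's class weight
    (the imbalance-aware sampler); otherwise the raw set is used.
    """
    config = config or TrainingConfig()
    y = np.asarray(y)
    X = np.asarray(X)
    if weights is not None:
        n_draw = config.epoch_length or len(y)
        w = np.asarray([weights[c] for c in y], dtype=np.float64)
        rng = np.random.default_rng(config.seed)
        # one resample reused across epochs keeps expected class balance
        # while letting the epoch shuffle vary batches
        idx = rng.choice(len(y), size=n_draw, replace=True, p=w / w.sum())
        X, y = X[idx], y[idx]
    clf = PatchNetClassifier(
        hidden_units=config.hidden_units,
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        epochs=config.epochs,
        step_size=config.scheduler_step_size,
        gamma=config.scheduler_gamma,
        seed=config.seed,
    )
    return clf.fit(X, y)


def save_model(model: PatchNetClassifier, path: str | Path) -> None:
    """Serialize a fitted model to ``<path>.npz`` plus a JSON sidecar."""
    check_is_fitted(model, "coefs_")
    path = Path(path)
    W1, b1, W2, b2 = model.coefs_
    np.savez(
        path.with_suffix(".npz"),
        W1=W1,
        b1=b1,
        W2=W2,
        b2=b2,
        classes=np.asarray(model.classes_, dtype=str),
        input_shape=np.asarray(model.input_shape_),
    )
    sidecar = {
        "backbone_id": "patchnet-mlp",
        "params": model.get_params(),
        "label_subset": [str(c) for c in model.classes_],
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path: str | Path) -> PatchNetClassifier:
    path = Path(path)
    data = np.load(path.with_suffix(".npz"), allow_pickle=False)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    model = PatchNetClassifier(**sidecar["params"])
    model.coefs_ = (data["W1"], data["b1"], data["W2"], data["b2"])
    classes = data["classes"]
    # binary models are trained on integer 0/1 labels
    model.classes_ = (
        classes.astype(int) if all(c.isdigit() for c in classes) else classes
    )
    model.input_shape_ = tuple(int(v) for v in data["input_shape"])
    return model
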
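"""Feed-forward neural classifier from feature vectors to D1-D4.

The network has four input neurons (one per anatomical feature, each
ordinal score scaled to [0, 1] by its per-feature maximum), rectified
hidden layers (default 16 and 8 units) and a four-way softmax output.
Training minimizes cross-entropy with Adam; a held-out fraction of the
training data drives early stopping on validation log-loss (stop after
``early_stop_patience`` epochs without improvement, restore the best
weights). Everything is seeded: two runs with identical inputs and seed
produce identical predictions.

The optimization itself is delegated to scikit-learn's multilayer
perceptron, driven one epoch at a time so the loss history and the
early-stopping criterion are under this module's control.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import log_loss
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier

from .score import CLASSES, CLASS_LABELS, DifficultyClass, FeatureVector

__all__ = ["ClassifierConfig", "TrainedModel", "train", "predict"]

#: per-feature score maxima used to scale inputs into [0, 1]
FEATURE_MAXIMA = np.array([4.0, 3.0, 3.0, 4.0])

MODEL_FORMAT_VERSION = 1
MIN_TRAIN_SIZE = 20
_LOSS_TOL = 1e-6


@dataclass(frozen=True)
class ClassifierConfig:
    hidden_layers: tuple[int, ...] = (16, 8)
    activation: str = "relu"
    max_epochs: int = 800
    early_stop_patience: int = 40
    learning_rate: float = 0.01
    seed: int = 0
    validation_fraction: float = 0.1
    batch_size: int = 32

    def __post_init__(self) -> None:
        if len(self.hidden_layers) < 1 or any(w < 1 for w in self.hidden_layers):
            raise ValueError("need at least one hidden layer, all widths >= 1")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        object.__setattr__(self, "hidden_layers", tuple(self.hidden_layers))


@dataclass
class TrainedModel:
    config: ClassifierConfig
    mlp: MLPClassifier
    class_order: tuple[str, ...] = CLASS_LABELS
    #: per-epoch records: epoch, train_loss, val_loss, val_accuracy
    training_history: list[dict] = field(default_factory=list)
    stopped_early: bool = False

    @property
    def n_epochs(self) -> int:
        return len(self.training_history)

    def predict(self, fv: FeatureVector) -> tuple[DifficultyClass, np.ndarray]:
        return predict(self, fv)

    def predict_batch(
        self, fvs: Sequence[FeatureVector]
    ) -> tuple[list[DifficultyClass], np.ndarray]:
        X = _encode([_as_fv(fv) for fv in fvs])
        probs = _full_proba(self.mlp, X, np.arange(4))
        # argmax breaks ties toward the lower class index
        idx = probs.argmax(axis=1)
        return [CLASSES[int(i)] for i in idx], probs

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        joblib.dump(
            {
                "format_version": MODEL_FORMAT_VERSION,
                "config": asdict(self.config),
                "class_order": self.class_order,
                "training_history": self.training_history,
                "stopped_early": self.stopped_early,
                "mlp": self.mlp,
            },
            path,
        )
        return path

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        blob = joblib.load(path)
        if blob.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"unsupported model format {blob.get('format_version')!r}"
            )
        return cls(
            config=ClassifierConfig(**blob["config"]),
            mlp=blob["mlp"],
            class_order=tuple(blob["class_order"]),
            training_history=blob["training_history"],
            stopped_early=blob["stopped_early"],
        )


def _as_fv(fv) -> FeatureVector:
    return fv if isinstance(fv, FeatureVector) else FeatureVector(*fv)


def _encode(fvs: Sequence[FeatureVector]) -> np.ndarray:
    X = np.array([fv.as_tuple() for fv in fvs], dtype=float)
    return X / FEATURE_MAXIMA


def _class_index(label_or_class) -> int:
    label = getattr(label_or_class, "label", label_or_class)
    return CLASS_LABELS.index(label)


def train(
    features: Sequence[FeatureVector],
    labels: Sequence[DifficultyClass | str],
    cfg: ClassifierConfig | None = None,
) -> TrainedModel:
    """Train the difficulty classifier with seeded early stopping."""
    cfg = cfg or ClassifierConfig()
    if len(features) != len(labels):
        raise ValueError(
            f"features ({len(features)}) and labels ({len(labels)}) differ in length"
        )
    if len(features) < MIN_TRAIN_SIZE:
        raise ValueError(f"need at least {MIN_TRAIN_SIZE} training cases")
    X = _encode([_as_fv(fv) for fv in features])
    y = np.array([_class_index(lab) for lab in labels])
    absent = [CLASS_LABELS[i] for i in range(4) if i not in set(y)]
    if absent:
        raise ValueError(f"classes absent from training labels: {absent}")

    try:
        X_tr, X_val, y_tr, y_val = train_test_split(
            X,
            y,
            test_size=cfg.validation_fraction,
            random_state=cfg.seed,
            stratify=y,
        )
    except ValueError:  # a class too rare to stratify the hold-out
        X_tr, X_val, y_tr, y_val = train_test_split(
            X, y, test_size=cfg.validation_fraction, random_state=cfg.seed
        )

    mlp = MLPClassifier(
        hidden_layer_sizes=cfg.hidden_layers,
        activation=cfg.activation,
        solver="adam",
        learning_rate_init=cfg.learning_rate,
        batch_size=min(cfg.batch_size, len(X_tr)),
        max_iter=1,
        warm_start=True,
        shuffle=True,
        random_state=cfg.seed,
        alpha=1e-4,
    )

    all_idx = np.arange(4)
    history: list[dict] = []
    best_loss = np.inf
    best_params: tuple | None = None
    stale = 0
    stopped_early = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for epoch in range(cfg.max_epochs):
            mlp.fit(X_tr, y_tr)
            val_probs = _full_proba(mlp, X_val, all_idx)
            val_loss = log_loss(y_val, val_probs, labels=all_idx)
            val_acc = float((val_probs.argmax(axis=1) == y_val).mean())
            history.append(
                {
                    "epoch": epoch,
                    "train_loss": float(mlp.loss_),
                    "val_loss": float(val_loss),
                    "val_accuracy": val_acc,
                }
            )
            if val_loss < best_loss - _LOSS_TOL:
                best_loss = val_loss
                best_params = (
                    copy.deepcopy(mlp.coefs_),
                    copy.deepcopy(mlp.intercepts_),
                )
                stale = 0
            else:
                stale += 1
                if stale >= cfg.early_stop_patience:
                    stopped_early = True
                    break
    if best_params is not None:
        mlp.coefs_, mlp.intercepts_ = best_params

    return TrainedModel(
        config=cfg,
        mlp=mlp,
        training_history=history,
        stopped_early=stopped_early,
    )


def _full_proba(mlp: MLPClassifier, X: np.ndarray, all_idx: np.ndarray) -> np.ndarray:
    """predict_proba expanded to all four classes (the optimizer may have
    seen fewer in its shuffled first batch — classes_ still covers y_tr)."""
    probs = mlp.predict_proba(X)
    if probs.shape[1] == 4:
        return probs
    full = np.zeros((len(X), 4))
    for j, cls in enumerate(mlp.classes_):
        full[:, int(cls)] = probs[:, j]
    return full


def predict(
    model: TrainedModel, fv: FeatureVector
) -> tuple[DifficultyClass, np.ndarray]:
    """Predicted class (argmax, ties toward the lower class) and the
    four softmax probabilities in D1..D4 order."""
    fv = _as_fv(fv)
    X = _encode([fv])
    probs = _full_proba(model.mlp, X, np.arange(4))[0]
    return CLASSES[int(probs.argmax())], probs
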
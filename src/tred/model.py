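"""Trajectory classifier: a 14-layer 1D residual network with a sklearn API.

:class:`ResNetTrajectoryClassifier` follows the scikit-learn estimator
contract (``fit`` / ``predict`` / ``predict_proba`` / ``get_params``),
so it composes with sklearn model selection; fitted state lives in
trailing-underscore attributes.  Samples are reassembled trajectories:
arrays of shape ``(n_samples, length, 2)`` holding (x, y) positions in µm.

By default each trajectory is encoded as its sequence of per-step
displacements (Δx, Δy), standardized per channel with statistics learned
from the training split only.  Displacement encoding makes predictions
exactly invariant to a constant translation of the input.  A ``positions``
encoding (start-anchored coordinates) is retained for ablation.

Training uses stochastic gradient descent with momentum, a constant
learning rate, L2 weight decay and categorical cross-entropy, with early
stopping on validation loss.  The tuned default hyperparameters are
learning rate 5e-4, weight decay 5e-4, dropout 0.4 and batch size 32.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .nn import (
    F32,
    ResNet14,
    TrainingHistory,
    fit_network,
    predict_logits,
    softmax,
)
from .preprocess import ReassembledDataset, ReassembledTrajectory

Encoding = Literal["displacements", "positions"]


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the trajectory classifier.

    Defaults are the tuned values: learning rate 5e-4, weight decay 5e-4,
    dropout rate 0.4, batch size 32, SGD momentum 0.9.
    """

    n_classes: int = 6
    learning_rate: float = 5e-4
    weight_decay: float = 5e-4
    dropout_rate: float = 0.4
    batch_size: int = 32
    max_epochs: int = 100
    early_stop_patience: int = 10
    momentum: float = 0.9
    base_channels: int = 64
    seed: int = 0
    input_encoding: Encoding = "displacements"

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise ValueError("learning_rate must be > 0 and weight_decay >= 0")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if min(self.batch_size, self.max_epochs, self.early_stop_patience) < 1:
            raise ValueError("batch_size, max_epochs, early_stop_patience must be >= 1")
        if self.input_encoding not in ("displacements", "positions"):
            raise ValueError(f"unknown input_encoding {self.input_encoding!r}")


@dataclass
class NormalizationStats:
    """Per-channel standardization statistics, learned from training data only."""

    mean: np.ndarray  # (2,)
    scale: np.ndarray  # (2,)

    @classmethod
    def identity(cls) -> "NormalizationStats":
        return cls(mean=np.zeros(2), scale=np.ones(2))

    @classmethod
    def from_training(cls, encoded: np.ndarray) -> "NormalizationStats":
        mean = encoded.mean(axis=(0, 2))
        scale = encoded.std(axis=(0, 2))
        scale = np.where(scale > 0, scale, 1.0)
        return cls(mean=mean, scale=scale)


def as_position_array(
    X: np.ndarray | ReassembledDataset | Sequence[ReassembledTrajectory],
) -> np.ndarray:
    """Coerce inputs to a (n, length, 2) position array."""
    if isinstance(X, ReassembledDataset):
        return X.to_array()
    if isinstance(X, np.ndarray):
        arr = X
    else:
        arr = np.stack([t.positions for t in X])
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 2:
        raise ValueError(f"expected positions of shape (n, length, 2), got {arr.shape}")
    return arr


def encode_input(
    X: np.ndarray,
    encoding: Encoding = "displacements",
    stats: NormalizationStats | None = None,
) -> np.ndarray:
    """Encode (n, length, 2) positions into (n, 2, steps) network channels.

    ``displacements``: consecutive differences per axis (length − 1 steps).
    ``positions``: coordinates re-anchored to each trajectory's start.
    Either is standardized per channel with ``stats`` (identity if None).
    """
    X = as_position_array(X)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite positions in input")
    if encoding == "displacements":
        chan = np.diff(X, axis=1)
    elif encoding == "positions":
        chan = X - X[:, :1, :]
    else:
        raise ValueError(f"unknown encoding {encoding!r}")
    chan = chan.transpose(0, 2, 1)  # (n, 2, steps)
    if stats is None:
        stats = NormalizationStats.identity()
    out = (chan - stats.mean[None, :, None]) / stats.scale[None, :, None]
    return out.astype(F32)


class ResNetTrajectoryClassifier(BaseEstimator, ClassifierMixin):
    """Cell-of-origin classifier for reassembled receptor trajectories.

    Parameters mirror :class:`ModelConfig`; see the module docstring for
    the encoding and training procedure.  ``fit`` accepts an optional
    explicit validation split; otherwise ``validation_fraction`` of the
    training data (stratified) is held out for early stopping.

    Attributes
    ----------
    classes_ : ndarray
        Sorted class labels.
    network_ : ResNet14
        The trained network (best validation-loss weights).
    norm_stats_ : NormalizationStats
        Channel standardization fitted on the training split only.
    history_ : TrainingHistory
        Per-epoch train/validation loss and accuracy.
    input_length_ : int
        Trajectory length (positions) the model was fitted on.
    """

    def __init__(
        self,
        learning_rate: float = 5e-4,
        weight_decay: float = 5e-4,
        dropout_rate: float = 0.4,
        batch_size: int = 32,
        max_epochs: int = 100,
        early_stop_patience: int = 10,
        momentum: float = 0.9,
        base_channels: int = 64,
        seed: int = 0,
        input_encoding: Encoding = "displacements",
        validation_fraction: float = 0.2,
    ):
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.dropout_rate = dropout_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.early_stop_patience = early_stop_patience
        self.momentum = momentum
        self.base_channels = base_channels
        self.seed = seed
        self.input_encoding = input_encoding
        self.validation_fraction = validation_fraction

    @classmethod
    def from_config(cls, config: ModelConfig, **overrides) -> "ResNetTrajectoryClassifier":
        kw = dict(
            learning_rate=config.learning_rate,
            weight_decay=config.weight_decay,
            dropout_rate=config.dropout_rate,
            batch_size=config.batch_size,
            max_epochs=config.max_epochs,
            early_stop_patience=config.early_stop_patience,
            momentum=config.momentum,
            base_channels=config.base_channels,
            seed=config.seed,
            input_encoding=config.input_encoding,
        )
        kw.update(overrides)
        return cls(**kw)

    # -- fitting ------------------------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None):
        """Train the network; ``X`` is (n, length, 2) positions.

        ``X_val`` / ``y_val`` give an explicit early-stopping split that
        is excluded from both gradient updates and normalization
        statistics.  Without one, a stratified ``validation_fraction`` of
        (X, y) is held out.
        """
        X = as_position_array(X)
        y = np.asarray(y)
        if len(X) != len(y):
            raise ValueError("X and y lengths differ")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes to fit")
        counts = np.bincount(y_idx, minlength=len(self.classes_))
        missing = [str(c) for c, n in zip(self.classes_, counts) if n == 0]
        if missing:
            raise ValueError(f"classes with no training samples: {missing}")

        if X_val is not None:
            if y_val is None:
                raise ValueError("y_val required when X_val is given")
            X_tr, y_tr = X, y_idx
            X_va = as_position_array(X_val)
            y_va = np.searchsorted(self.classes_, np.asarray(y_val))
            unknown = np.asarray(y_val)[
                ~np.isin(np.asarray(y_val), self.classes_)
            ]
            if len(unknown):
                raise ValueError(f"validation labels unseen in training: {set(unknown)}")
        else:
            from sklearn.model_selection import train_test_split

            X_tr, X_va, y_tr, y_va = train_test_split(
                X, y_idx, test_size=self.validation_fraction,
                stratify=y_idx, random_state=self.seed,
            )

        self.input_length_ = X_tr.shape[1]
        enc_tr_raw = encode_input(X_tr, self.input_encoding, stats=None)
        self.norm_stats_ = NormalizationStats.from_training(enc_tr_raw)
        enc_tr = encode_input(X_tr, self.input_encoding, self.norm_stats_)
        enc_va = encode_input(X_va, self.input_encoding, self.norm_stats_)

        self.network_ = ResNet14(
            n_channels=2,
            n_classes=len(self.classes_),
            base_channels=self.base_channels,
            dropout_rate=self.dropout_rate,
            seed=self.seed,
        )
        self.history_ = fit_network(
            self.network_,
            enc_tr, np.asarray(y_tr), enc_va, np.asarray(y_va),
            lr=self.learning_rate,
            momentum=self.momentum,
            weight_decay=self.weight_decay,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            patience=self.early_stop_patience,
            seed=self.seed + 7919,
        )
        return self

    # -- inference ----------------------------------------------------------
    def _check_fitted(self) -> None:
        if not hasattr(self, "network_"):
            raise RuntimeError("classifier is not fitted")

    def _encode(self, X) -> np.ndarray:
        X = as_position_array(X)
        if X.shape[1] != self.input_length_:
            raise ValueError(
                f"input length {X.shape[1]} != fitted length {self.input_length_}"
            )
        return encode_input(X, self.input_encoding, self.norm_stats_)

    def predict_proba(self, X) -> np.ndarray:
        """Class-probability rows (softmax outputs), summing to 1."""
        self._check_fitted()
        logits = predict_logits(self.network_, self._encode(X), batch_size=64)
        return softmax(logits.astype(np.float64))

    def predict(self, X) -> np.ndarray:
        """Arg-max class per sample; ties resolve to the lowest class index."""
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    def extract_features(self, X) -> np.ndarray:
        """Penultimate (global-pooled) representation, shape (n, feature_dim)."""
        self._check_fitted()
        _, feats = predict_logits(
            self.network_, self._encode(X), batch_size=64, return_features=True
        )
        return feats

    def history_frame(self) -> pd.DataFrame:
        """Training history as a tidy per-epoch table."""
        self._check_fitted()
        h = self.history_
        return pd.DataFrame(
            {
                "epoch": np.arange(h.n_epochs),
                "train_loss": h.train_loss,
                "train_acc": h.train_acc,
                "val_loss": h.val_loss,
                "val_acc": h.val_acc,
            }
        )

    # -- persistence --------------------------------------------------------
    def save(self, path: str | Path) -> Path:
        """Save weights, normalization statistics and config to a .npz file."""
        self._check_fitted()
        path = Path(path)
        meta = {
            "params": self.get_params(),
            "classes": [str(c) for c in self.classes_],
            "input_length": int(self.input_length_),
            "history": asdict(self.history_),
        }
        arrays = {f"state/{k}": v for k, v in self.network_.state_dict().items()}
        np.savez(
            path,
            __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            norm_mean=self.norm_stats_.mean,
            norm_scale=self.norm_stats_.scale,
            **arrays,
        )
        return path

    @classmethod
    def load(cls, path: str | Path) -> "ResNetTrajectoryClassifier":
        with np.load(Path(path)) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            est = cls(**meta["params"])
            est.classes_ = np.array(meta["classes"])
            est.input_length_ = meta["input_length"]
            est.norm_stats_ = NormalizationStats(
                mean=data["norm_mean"], scale=data["norm_scale"]
            )
            est.history_ = TrainingHistory(**meta["history"])
            est.network_ = ResNet14(
                n_channels=2,
                n_classes=len(est.classes_),
                base_channels=est.base_channels,
                dropout_rate=est.dropout_rate,
                seed=est.seed,
            )
            est.network_.load_state_dict(
                {k[len("state/"):]: data[k] for k in data.files if k.startswith("state/")}
            )
        return est


def build_network(config: ModelConfig) -> ResNet14:
    """Construct the (untrained) 14-layer residual network for a config."""
    return ResNet14(
        n_channels=2,
        n_classes=config.n_classes,
        base_channels=config.base_channels,
        dropout_rate=config.dropout_rate,
        seed=config.seed,
    )
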
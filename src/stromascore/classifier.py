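"""Nine-class tile classifier with a two-stage pretrain → fine-tune scheme.

The training topology mirrors transfer learning for histology tile
classification: a network is first trained from random initialization on
one tile corpus (the "pretrain" stage), then the same weights are trained
further on a second corpus with a small fixed learning rate (the
"fine-tune" stage, SGD with momentum, defaults lr 3e-4 / batch 64 /
10 epochs). The architecture is pluggable; the default desk-scale model is
a small multilayer perceptron over downsampled tile features, which is
sufficient for the statistically separable synthetic corpus while keeping
seeded training bit-reproducible on CPU.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import joblib
import numpy as np
from scipy.stats import beta as beta_dist
from skimage.transform import resize
from sklearn.metrics import confusion_matrix, log_loss
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .taxonomy import CLASS_NAMES, N_CLASSES, TileClass

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters shared by both training stages.

    Fine-tuning defaults: SGD with momentum, fixed learning rate 3e-4,
    mini-batch 64, 10 epochs. The pretrain stage reuses the same optimizer
    family with a validation split of 10% to monitor training.
    """

    batch_size: int = 64
    epochs: int = 10
    learning_rate: float = 3e-4
    momentum: float = 0.9
    val_fraction: float = 0.10
    seed: int = 0
    hidden_layers: tuple[int, ...] = (64,)
    feature_side: int = 16  # tiles are downsampled to feature_side² RGB features


def pretrain_defaults(seed: int = 0, **overrides) -> TrainConfig:
    """Pretrain-stage defaults: longer schedule and a larger learning rate
    than the fine-tune stage, since training starts from random weights."""
    params = {"epochs": 80, "learning_rate": 0.01, "seed": seed}
    params.update(overrides)
    return TrainConfig(**params)


@dataclass
class TileDataset:
    """Labeled RGB tiles with a provenance tag (pretrain/finetune/test)."""

    tiles: list[np.ndarray]
    labels: np.ndarray
    tag: str = "pretrain"

    def __post_init__(self) -> None:
        if len(self.tiles) == 0:
            raise ValueError("dataset is empty")
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.tiles):
            raise ValueError("tiles and labels differ in length")
        if self.labels.min() < 0 or self.labels.max() >= N_CLASSES:
            raise ValueError("labels must be valid class indices 0–8")
        shapes = {t.shape for t in self.tiles}
        if len(shapes) > 1:
            raise ValueError(f"tiles have inconsistent shapes: {shapes}")

    def __len__(self) -> int:
        return len(self.tiles)


@dataclass(frozen=True)
class EvalReport:
    accuracy: float
    ci_low: float
    ci_high: float
    confusion: np.ndarray  # rows true class, columns predicted
    n: int


def featurize(tile: np.ndarray, feature_side: int) -> np.ndarray:
    """Tile → feature vector: a ``feature_side²`` RGB downsample plus
    per-channel texture statistics (std and mean gradient magnitudes),
    which survive the downsampling that erases fine texture."""
    tile = np.asarray(tile)
    if tile.ndim != 3 or tile.shape[-1] != 3:
        raise ValueError("tile must be an RGB image of shape (H, W, 3)")
    if tile.shape[0] < 2 or tile.shape[1] < 2:
        raise ValueError("tile is too small to featurize")
    small = resize(
        tile, (feature_side, feature_side), anti_aliasing=True, preserve_range=False
    ).astype(np.float64)
    full = tile.astype(np.float64) / 255.0
    std = full.std(axis=(0, 1))
    dx = np.abs(np.diff(full, axis=1)).mean(axis=(0, 1))
    dy = np.abs(np.diff(full, axis=0)).mean(axis=(0, 1))
    return np.concatenate([small.ravel(), std, dx, dy])


class ClassifierModel:
    """Trained nine-class predictor plus provenance metadata."""

    def __init__(
        self,
        mlp: MLPClassifier,
        config: TrainConfig,
        architecture: str = "mlp",
        scaler: StandardScaler | None = None,
    ):
        self.mlp = mlp
        self.config = config
        self.architecture = architecture
        self.scaler = scaler  # input standardization frozen at pretrain time
        self.class_names = CLASS_NAMES
        self.history: list[dict] = []

    def _transform(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(features)
        return self.scaler.transform(features) if self.scaler is not None else features

    @property
    def config_hash(self) -> str:
        payload = json.dumps(asdict(self.config), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        proba = self.mlp.predict_proba(self._transform(features))
        if proba.shape[1] != N_CLASSES:  # pragma: no cover - partial_fit fixes classes
            raise RuntimeError("model does not cover all nine classes")
        return proba

    def save(self, path: str | Path) -> None:
        payload = {
            "mlp": self.mlp,
            "scaler": self.scaler,
            "config": asdict(self.config),
            "architecture": self.architecture,
            "class_names": list(self.class_names),
            "history": self.history,
        }
        joblib.dump(payload, path)

    @classmethod
    def load(cls, path: str | Path) -> "ClassifierModel":
        payload = joblib.load(path)
        cfg = payload["config"]
        cfg["hidden_layers"] = tuple(cfg["hidden_layers"])
        model = cls(
            payload["mlp"], TrainConfig(**cfg), payload["architecture"],
            scaler=payload.get("scaler"),
        )
        model.history = payload.get("history", [])
        if tuple(payload["class_names"]) != CLASS_NAMES:
            raise ValueError("checkpoint class order does not match this package")
        return model


def _dataset_features(dataset: TileDataset, cfg: TrainConfig) -> np.ndarray:
    return np.stack([featurize(t, cfg.feature_side) for t in dataset.tiles])


def _check_class_coverage(labels: np.ndarray) -> None:
    present = set(np.unique(labels).tolist())
    missing = [CLASS_NAMES[i] for i in range(N_CLASSES) if i not in present]
    if missing:
        warnings.warn(
            f"classes absent from training data (weight zero): {', '.join(missing)}",
            stacklevel=3,
        )


def _epoch_loop(
    mlp: MLPClassifier,
    x: np.ndarray,
    y: np.ndarray,
    x_val: np.ndarray | None,
    y_val: np.ndarray | None,
    cfg: TrainConfig,
    epochs: int,
    rng: np.random.Generator,
) -> list[dict]:
    """Minibatch SGD epochs via partial_fit; returns per-epoch history."""
    history = []
    classes = np.arange(N_CLASSES)
    for epoch in range(epochs):
        order = rng.permutation(len(x))
        for start in range(0, len(x), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            mlp.batch_size = len(idx)  # one gradient step per minibatch
            mlp.partial_fit(x[idx], y[idx], classes=classes)
        train_loss = log_loss(y, mlp.predict_proba(x), labels=classes)
        entry = {"epoch": epoch, "train_loss": float(train_loss)}
        if x_val is not None and len(x_val):
            entry["val_accuracy"] = float(np.mean(mlp.predict(x_val) == y_val))
        history.append(entry)
        logger.info("epoch %d: %s", epoch, entry)
    return history


def _new_mlp(cfg: TrainConfig) -> MLPClassifier:
    return MLPClassifier(
        hidden_layer_sizes=cfg.hidden_layers,
        solver="sgd",
        learning_rate="constant",
        learning_rate_init=cfg.learning_rate,
        momentum=cfg.momentum,
        nesterovs_momentum=False,
        batch_size=cfg.batch_size,
        random_state=cfg.seed,
        alpha=0.0,
    )


def pretrain(dataset: TileDataset, config: TrainConfig | None = None) -> ClassifierModel:
    """Train a fresh model from random initialization.

    A ``val_fraction`` split of the corpus is held out to monitor training;
    per-epoch training loss and validation accuracy are kept on
    ``model.history``.
    """
    cfg = config or pretrain_defaults()
    _check_class_coverage(dataset.labels)
    x = _dataset_features(dataset, cfg)
    y = dataset.labels

    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(10,)))
    n_val = int(round(cfg.val_fraction * len(x)))
    perm = rng.permutation(len(x))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    if len(train_idx) == 0:
        raise ValueError("validation split leaves no training samples")

    scaler = StandardScaler().fit(x[train_idx])
    x = scaler.transform(x)
    mlp = _new_mlp(cfg)
    history = _epoch_loop(
        mlp, x[train_idx], y[train_idx], x[val_idx], y[val_idx], cfg,
        max(cfg.epochs, 1), rng,
    )
    model = ClassifierModel(
        mlp, cfg, architecture=f"mlp-{cfg.feature_side}x{cfg.feature_side}", scaler=scaler
    )
    model.history = history
    return model


def fine_tune(
    model: ClassifierModel, dataset: TileDataset, config: TrainConfig | None = None
) -> ClassifierModel:
    """Continue training a copy of ``model`` on a new corpus.

    The input model is left untouched. Defaults mirror the transfer-
    learning recipe (SGD+momentum, lr 3e-4, batch 64, 10 epochs); 0 epochs
    returns an unchanged copy.
    """
    cfg = config or TrainConfig()
    if tuple(model.class_names) != CLASS_NAMES:
        raise ValueError("model class order does not match this package")
    new = ClassifierModel(
        copy.deepcopy(model.mlp), cfg, model.architecture, scaler=model.scaler
    )
    new.history = list(model.history)
    if cfg.epochs == 0:
        return new
    expected = model.config.feature_side
    if cfg.feature_side != expected:
        raise ValueError(
            f"architecture mismatch: model expects feature_side {expected}, "
            f"config requests {cfg.feature_side}"
        )
    _check_class_coverage(dataset.labels)
    x = new._transform(_dataset_features(dataset, cfg))
    y = dataset.labels
    # the optimizer persists across partial_fit calls; apply the fine-tune lr
    new.mlp.learning_rate_init = cfg.learning_rate
    if getattr(new.mlp, "_optimizer", None) is not None:
        new.mlp._optimizer.learning_rate = cfg.learning_rate
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(11,)))
    new.history += _epoch_loop(new.mlp, x, y, None, None, cfg, cfg.epochs, rng)
    return new


def predict_tile(model: ClassifierModel, tile: np.ndarray) -> tuple[TileClass, np.ndarray]:
    """Classify one RGB tile; returns (argmax class, probability vector).

    Ties at the maximum probability resolve to the lowest class index
    (numpy argmax convention, documented as the package rule).
    """
    feats = featurize(tile, model.config.feature_side)
    proba = model.predict_proba(feats)[0]
    return TileClass(int(np.argmax(proba))), proba


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial (Clopper–Pearson) confidence interval for k/n."""
    if not 0 <= k <= n or n <= 0:
        raise ValueError("need 0 ≤ k ≤ n with n > 0")
    lo = 0.0 if k == 0 else float(beta_dist.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(beta_dist.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def evaluate(model: ClassifierModel, dataset: TileDataset) -> EvalReport:
    """Accuracy with exact binomial 95% CI and a 9×9 confusion matrix."""
    if len(dataset) == 0:
        raise ValueError("empty test set")
    x = _dataset_features(dataset, model.config)
    proba = model.predict_proba(x)
    preds = np.argmax(proba, axis=1)
    correct = int(np.sum(preds == dataset.labels))
    n = len(dataset)
    lo, hi = clopper_pearson(correct, n)
    conf = confusion_matrix(dataset.labels, preds, labels=np.arange(N_CLASSES))
    return EvalReport(accuracy=correct / n, ci_low=lo, ci_high=hi, confusion=conf, n=n)
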
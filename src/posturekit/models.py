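"""The three posture classifiers, training, persistence and grid search.

Random forest, decision tree and k-nearest neighbours with the tuned
hyperparameters found best for this task:

====  =====================================================
RF    max_depth=30, n_estimators=25, criterion=gini
DT    criterion=gini, max_depth=19
KNN   n_neighbors=13, Minkowski p=2, distance weights
====  =====================================================

KNN consumes features standardized with training-set statistics (distance
metrics need comparable scales); the tree models consume raw features.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum

import joblib
import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier
from sklearn.ensemble import RandomForestClassifier

from .errors import (
    ConfigurationError,
    DegenerateLabelsError,
    ModelIOError,
    SchemaError,
    ValidationError,
)
from .features import FeatureMatrix

MODEL_FORMAT_VERSION = "posturekit-model-1"


class PostureLabel(str, Enum):
    """The four recognized chest postures."""

    STANDING = "standing"
    SITTING = "sitting"
    BENDING = "bending"
    LYING = "lying"


#: Canonical class order used by confusion matrices and reports.
LABEL_ORDER = tuple(p.value for p in PostureLabel)

DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "RF": {"max_depth": 30, "n_estimators": 25, "criterion": "gini"},
    "DT": {"criterion": "gini", "max_depth": 19},
    "KNN": {"n_neighbors": 13, "metric": "minkowski", "p": 2, "weights": "distance"},
}

#: Small default grids for hyperparameter search, centred on the defaults.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "RF": {"max_depth": [10, 19, 30], "n_estimators": [10, 25, 50]},
    "DT": {"max_depth": [5, 19, 30]},
    "KNN": {"n_neighbors": [5, 13, 21]},
}


@dataclass
class ModelConfig:
    """A classifier kind plus hyperparameters and a seed."""

    kind: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in DEFAULT_HYPERPARAMETERS:
            raise ConfigurationError(
                f"unknown model kind {self.kind!r}; expected one of "
                f"{sorted(DEFAULT_HYPERPARAMETERS)}"
            )
        merged = dict(DEFAULT_HYPERPARAMETERS[self.kind])
        merged.update(self.hyperparameters)
        self.hyperparameters = merged

    @classmethod
    def default(cls, kind: str, seed: int = 0) -> "ModelConfig":
        return cls(kind=kind, seed=seed)


def _build_estimator(config: ModelConfig):
    hp = config.hyperparameters
    if config.kind == "RF":
        return RandomForestClassifier(
            max_depth=hp["max_depth"],
            n_estimators=hp["n_estimators"],
            criterion=hp["criterion"],
            random_state=config.seed,
            n_jobs=1,
        )
    if config.kind == "DT":
        return DecisionTreeClassifier(
            criterion=hp["criterion"],
            max_depth=hp["max_depth"],
            random_state=config.seed,
        )
    knn = KNeighborsClassifier(
        n_neighbors=hp["n_neighbors"],
        metric=hp["metric"],
        p=hp.get("p", 2),
        weights=hp["weights"],
    )
    # distance models need comparable feature scales
    return Pipeline([("scale", StandardScaler()), ("knn", knn)])


@dataclass
class TrainedModel:
    """A fitted classifier bound to a feature-column schema."""

    config: ModelConfig
    estimator: object
    schema: tuple[str, ...]
    classes: tuple[str, ...]
    n_samples: int

    def _align(self, matrix) -> np.ndarray:
        if isinstance(matrix, FeatureMatrix):
            cols = matrix.feature_names
            if set(cols) != set(self.schema):
                raise SchemaError(
                    f"feature columns {sorted(set(cols) ^ set(self.schema))} "
                    "do not match the training schema"
                )
            return matrix.data[list(self.schema)].to_numpy(dtype=float)
        X = np.asarray(matrix, dtype=float)
        if X.ndim != 2 or (X.size and X.shape[1] != len(self.schema)):
            raise SchemaError(
                f"expected {len(self.schema)} feature columns, got array {X.shape}"
            )
        return X


def _as_xy(matrix, labels):
    if isinstance(matrix, FeatureMatrix):
        X = matrix.X
        cols = tuple(matrix.feature_names)
        y = labels if labels is not None else matrix.labels
    else:
        X = np.asarray(matrix, dtype=float)
        cols = tuple(f"f{i}" for i in range(X.shape[1]))
        y = labels
    if y is None:
        raise ValidationError("training requires labels")
    y = np.asarray(y)
    return X, np.asarray(y), cols


def train(matrix, labels=None, config: ModelConfig | None = None) -> TrainedModel:
    """Fit a classifier; deterministic given ``config.seed``."""
    config = config or ModelConfig.default("RF")
    X, y, cols = _as_xy(matrix, labels)
    if len(X) != len(y):
        raise ValidationError("feature matrix and labels have different lengths")
    if not np.isfinite(X).all():
        raise ValidationError("feature matrix contains NaN or infinite values")
    classes = np.unique(y)
    if len(classes) < 2:
        raise DegenerateLabelsError("training needs at least two classes")
    if config.kind == "KNN" and config.hyperparameters["n_neighbors"] > len(X):
        raise ConfigurationError(
            f"n_neighbors={config.hyperparameters['n_neighbors']} exceeds "
            f"{len(X)} training samples"
        )
    est = _build_estimator(config)
    est.fit(X, y)
    return TrainedModel(
        config=config,
        estimator=est,
        schema=cols,
        classes=tuple(str(c) for c in classes),
        n_samples=len(X),
    )


def predict(model: TrainedModel, matrix) -> np.ndarray:
    """One label per row; columns are aligned to the training schema by name."""
    X = model._align(matrix)
    if X.shape[0] == 0:
        return np.array([], dtype=object)
    return np.asarray(model.estimator.predict(X))


def grid_search(
    matrix,
    labels=None,
    kind: str = "RF",
    grid: dict[str, list] | None = None,
    folds: int = 3,
    seed: int = 0,
) -> ModelConfig:
    """Exhaustive search maximizing mean validation accuracy over folds.

    Candidates are enumerated in documented grid order (itertools product of
    the grid's insertion order); ties keep the first maximizer.
    """
    grid = grid if grid is not None else DEFAULT_GRIDS[kind]
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ConfigurationError("grid must be non-empty")
    X, y, _ = _as_xy(matrix, labels)
    keys = list(grid)
    best_cfg, best_score = None, -np.inf
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    for combo in itertools.product(*(grid[k] for k in keys)):
        cfg = ModelConfig(kind=kind, hyperparameters=dict(zip(keys, combo)), seed=seed)
        scores = []
        for tr, va in splits:
            est = _build_estimator(cfg)
            est.fit(X[tr], y[tr])
            scores.append(float(np.mean(est.predict(X[va]) == y[va])))
        score = float(np.mean(scores))
        if score > best_score:
            best_cfg, best_score = cfg, score
    return best_cfg


def save_model(model: TrainedModel, path) -> None:
    """Persist a trained model in a self-describing container."""
    joblib.dump(
        {
            "format": MODEL_FORMAT_VERSION,
            "config": {
                "kind": model.config.kind,
                "hyperparameters": model.config.hyperparameters,
                "seed": model.config.seed,
            },
            "schema": list(model.schema),
            "classes": list(model.classes),
            "n_samples": model.n_samples,
            "estimator": model.estimator,
        },
        path,
    )


def load_model(path) -> TrainedModel:
    """Load a model saved by :func:`save_model`; validates the format tag."""
    try:
        doc = joblib.load(path)
    except Exception as exc:  # corrupt or non-joblib file
        raise ModelIOError(f"cannot load model from {path}: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("format") != MODEL_FORMAT_VERSION:
        raise ModelIOError(
            f"{path}: unrecognized model container "
            f"(format tag {doc.get('format') if isinstance(doc, dict) else None!r}, "
            f"expected {MODEL_FORMAT_VERSION!r})"
        )
    cfg = ModelConfig(**doc["config"])
    return TrainedModel(
        config=cfg,
        estimator=doc["estimator"],
        schema=tuple(doc["schema"]),
        classes=tuple(doc["classes"]),
        n_samples=int(doc["n_samples"]),
    )
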
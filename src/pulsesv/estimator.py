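"""Gradient-boosting stroke-volume regressor.

A gradient-boosted ensemble of regression trees maps the 9-element
non-invasive feature vector (age, gender, weight, height, brachial
SBP/DBP/PP/MAP, cfPWV) to stroke volume. Hyperparameters are selected by
exhaustive grid search with shuffled 5-fold cross-validation scored by
R^2, then the winning combination is refit on the full training set.
No fine-tuning on clinical data ever happens at prediction time.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.model_selection import GridSearchCV, KFold

from .cohort import FEATURE_COLUMNS

_SCHEMA_VERSION = 1
_GENDER_CODE = {"M": 0.0, "F": 1.0}


class SchemaError(ValueError):
    """Feature-schema mismatch between a model and a prediction table."""


@dataclass(frozen=True)
class HyperparameterGrid:
    """Search grid for the gradient-boosting regressor."""

    n_estimators: tuple[int, ...] = (60, 80, 100, 120)
    learning_rate: tuple[float, ...] = (0.2, 0.4, 0.6)
    max_depth: tuple[int, ...] = (3, 5, 8, 10)
    max_features: tuple[str, ...] = ("sqrt",)
    min_samples_leaf: tuple[int, ...] = (1, 3, 5)

    def __post_init__(self) -> None:
        for name in (
            "n_estimators", "learning_rate", "max_depth", "max_features",
            "min_samples_leaf",
        ):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"empty grid for {name}")

    def as_param_grid(self) -> dict[str, list]:
        return {
            "n_estimators": list(self.n_estimators),
            "learning_rate": list(self.learning_rate),
            "max_depth": list(self.max_depth),
            "max_features": list(self.max_features),
            "min_samples_leaf": list(self.min_samples_leaf),
        }

    def size(self) -> int:
        return int(np.prod([len(v) for v in self.as_param_grid().values()]))

    def points(self):
        keys = list(self.as_param_grid())
        for combo in product(*self.as_param_grid().values()):
            yield dict(zip(keys, combo))


@dataclass
class TrainedEstimator:
    """A fitted stroke-volume regressor plus its provenance."""

    model: GradientBoostingRegressor
    selected_params: dict
    cv_score: float
    feature_schema: list[str] = field(
        default_factory=lambda: list(FEATURE_COLUMNS)
    )
    gender_encoding: dict[str, float] = field(
        default_factory=lambda: dict(_GENDER_CODE)
    )
    seed: int = 0
    config_hash: str = ""
    schema_version: int = _SCHEMA_VERSION


@dataclass
class PredictionResult:
    sv_pred: np.ndarray
    model_id: str


def encode_features(
    records: pd.DataFrame, schema: list[str] | None = None
) -> np.ndarray:
    """Validate a feature table against the schema and return the numeric
    design matrix (gender mapped M->0, F->1)."""
    schema = schema or list(FEATURE_COLUMNS)
    missing = [c for c in schema if c not in records.columns]
    if missing:
        raise SchemaError(f"missing feature columns: {missing}")
    X = records[schema].copy()
    if "gender" in schema:
        bad = ~X["gender"].isin(_GENDER_CODE)
        if bad.any():
            raise SchemaError(
                f"unencodable gender values: {sorted(X.loc[bad, 'gender'].unique())}"
            )
        X["gender"] = X["gender"].map(_GENDER_CODE)
    arr = X.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        rows, cols = np.nonzero(~np.isfinite(arr))
        raise SchemaError(
            f"non-finite feature value at record {rows[0]}, "
            f"field {schema[cols[0]]!r}"
        )
    return arr


def _training_hash(grid: HyperparameterGrid, seed: int, schema: list[str]) -> str:
    payload = json.dumps(
        {"grid": grid.as_param_grid(), "seed": seed, "schema": schema},
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def train_with_grid_search(
    dataset: pd.DataFrame,
    grid: HyperparameterGrid | None = None,
    seed: int = 0,
    n_folds: int = 5,
    min_records: int = 100,
) -> TrainedEstimator:
    """Exhaustive grid search with shuffled K-fold CV scored by R^2,
    followed by a refit of the winner on the full dataset."""
    grid = grid or HyperparameterGrid()
    if len(dataset) < min_records:
        raise ValueError(
            f"need at least {min_records} records, have {len(dataset)}"
        )
    X = encode_features(dataset)
    y = dataset["sv"].to_numpy(dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("non-finite stroke-volume target")
    if np.ptp(y) == 0:
        raise ValueError("degenerate target: zero variance in stroke volume")
    cv = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(
        GradientBoostingRegressor(random_state=seed),
        grid.as_param_grid(),
        scoring="r2",
        cv=cv,
        n_jobs=1,
        refit=True,
    )
    search.fit(X, y)
    return TrainedEstimator(
        model=search.best_estimator_,
        selected_params={
            k: search.best_params_[k] for k in sorted(search.best_params_)
        },
        cv_score=float(search.best_score_),
        feature_schema=list(FEATURE_COLUMNS),
        seed=seed,
        config_hash=_training_hash(grid, seed, list(FEATURE_COLUMNS)),
    )


def predict_sv(
    model: TrainedEstimator, records: pd.DataFrame
) -> PredictionResult:
    """Predict stroke volume (mL) for each record; inputs are left
    untouched and the model is never updated."""
    extra = [
        c for c in records.columns
        if c not in model.feature_schema and c not in ("sv", "id")
    ]
    if extra:
        raise SchemaError(f"unexpected feature columns: {extra}")
    X = encode_features(records, model.feature_schema)
    return PredictionResult(
        sv_pred=model.model.predict(X),
        model_id=model.config_hash,
    )


def save_model(model: TrainedEstimator, path: str | Path) -> None:
    """Persist the estimator with its schema and provenance metadata."""
    bundle = {
        "schema_version": model.schema_version,
        "feature_schema": model.feature_schema,
        "gender_encoding": model.gender_encoding,
        "selected_params": model.selected_params,
        "cv_score": model.cv_score,
        "seed": model.seed,
        "config_hash": model.config_hash,
        "model": model.model,
    }
    joblib.dump(bundle, path)


def load_model(path: str | Path) -> TrainedEstimator:
    try:
        bundle = joblib.load(path)
    except Exception as exc:  # noqa: BLE001 - joblib raises various types
        raise ValueError(f"cannot read model bundle {path}: {exc}") from exc
    required = {
        "schema_version", "feature_schema", "gender_encoding",
        "selected_params", "cv_score", "seed", "config_hash", "model",
    }
    if not isinstance(bundle, dict) or not required.issubset(bundle):
        raise SchemaError("model bundle is missing metadata fields")
    if bundle["schema_version"] != _SCHEMA_VERSION:
        raise SchemaError(
            f"model schema version {bundle['schema_version']} "
            f"incompatible with {_SCHEMA_VERSION}"
        )
    if list(bundle["feature_schema"]) != list(FEATURE_COLUMNS):
        raise SchemaError(
            f"model feature schema {bundle['feature_schema']} does not "
            f"match the expected {FEATURE_COLUMNS}"
        )
    return TrainedEstimator(
        model=bundle["model"],
        selected_params=bundle["selected_params"],
        cv_score=bundle["cv_score"],
        feature_schema=list(bundle["feature_schema"]),
        gender_encoding=dict(bundle["gender_encoding"]),
        seed=bundle["seed"],
        config_hash=bundle["config_hash"],
    )
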
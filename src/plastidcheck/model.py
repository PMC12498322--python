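"""Regression models mapping module coverage to genome completeness.

Three scikit-learn regressors are supported — AdaBoost, gradient
boosting and random forest — each trained with library-default
hyperparameters on module-coverage feature vectors labeled with the
nominal completeness (percent) of the subsampled genome they came from.
Splitting and cross-validation operate at the level of *source genomes*,
never individual simulated examples, so all completeness levels of one
reference stay on the same side of every split and the held-out
evaluation is free of leakage.

Model selection follows the smallest absolute median discrepancy between
expected and predicted completeness, with Pearson correlation as the
tie-break.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
from scipy import stats
from sklearn.ensemble import (
    AdaBoostRegressor,
    GradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.model_selection import KFold

from . import __version__
from .kegg_modules import ModuleCoverageVector
from .simulator import LabeledDataset, derive_seed

__all__ = [
    "ALGORITHMS",
    "TrainedCompletenessModel",
    "EvaluationReport",
    "TrainingResult",
    "split_train_test",
    "train_model",
    "predict_completeness",
    "predict_batch",
    "evaluate_model",
    "select_best_model",
    "contrast_organelles",
    "save_model",
    "load_model",
]

# fixed name order also serves as the last-resort tie-break in selection
ALGORITHMS: tuple[str, ...] = ("ada_boost", "gradient_boost", "random_forest")

_ESTIMATORS = {
    "ada_boost": AdaBoostRegressor,
    "gradient_boost": GradientBoostingRegressor,
    "random_forest": RandomForestRegressor,
}


class FeatureOrderError(ValueError):
    """Feature vector does not match the model's training catalog."""


class ModelArtifactError(ValueError):
    """Persisted model artifact is incompatible with this package/catalog."""


@dataclass
class TrainedCompletenessModel:
    algorithm: str
    feature_order: tuple[str, ...]
    estimator: object
    seed: int
    training_provenance: dict = field(default_factory=dict)


@dataclass
class EvaluationReport:
    """Per-level medians plus global agreement statistics.

    ``median_difference`` is median(expected − predicted): positive
    values mean the model underestimates completeness, negative values
    mean it overestimates.  ``mse`` is computed on labels rescaled to
    [0, 1].  ``linear_fit`` is None when the test labels are constant
    (slope undefined) and ``pearson_r`` is None when predictions are
    constant (zero variance).
    """

    per_level: dict[float, tuple[float, float]]  # level -> (median, sd)
    linear_fit: dict | None
    pearson_r: float | None
    pearson_p: float | None
    mse: float
    median_difference: float
    n: int

    def to_json_dict(self) -> dict:
        return {
            "per_level": {str(k): list(v) for k, v in sorted(self.per_level.items())},
            "linear_fit": self.linear_fit,
            "pearson_r": self.pearson_r,
            "pearson_p": self.pearson_p,
            "mse": self.mse,
            "median_difference": self.median_difference,
            "n": self.n,
        }


@dataclass
class TrainingResult:
    fold_models: list[TrainedCompletenessModel]
    final_model: TrainedCompletenessModel
    cv_summary: list[dict]


def split_train_test(
    dataset: LabeledDataset,
    train_fraction: float = 0.9,
    seed: int = 0,
) -> tuple[LabeledDataset, LabeledDataset]:
    """Genome-level train/test split (default 90:10).

    All simulated completeness levels of one source genome land on the
    same side.  Both sides are guaranteed non-empty.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be strictly between 0 and 1")
    genomes = dataset.source_genome_ids
    if len(genomes) < 2:
        raise ValueError("need at least 2 source genomes to split")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(genomes)))
    n_train = int(np.floor(train_fraction * len(genomes) + 0.5))
    n_train = min(max(n_train, 1), len(genomes) - 1)
    train_ids = [genomes[i] for i in order[:n_train]]
    test_ids = [genomes[i] for i in order[n_train:]]
    return dataset.subset(train_ids), dataset.subset(test_ids)


def _fit_estimator(algorithm: str, X: np.ndarray, y: np.ndarray, seed: int):
    if algorithm not in _ESTIMATORS:
        raise ValueError(
            f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}"
        )
    est = _ESTIMATORS[algorithm](random_state=seed)
    est.fit(X, y)
    return est


def train_model(
    train: LabeledDataset,
    algorithm: str = "gradient_boost",
    n_folds: int = 5,
    shuffle: bool = True,
    seed: int = 0,
) -> TrainingResult:
    """K-fold cross-validated training with genome-level folds.

    Returns one model per fold (fitted on the fold's training portion,
    evaluated on the held-out genomes) plus a final model refitted on
    all training data.
    """
    genomes = train.source_genome_ids
    if len(genomes) < n_folds:
        raise ValueError(
            f"{len(genomes)} source genomes < n_folds={n_folds}; "
            "cross-validation folds are genome-level"
        )
    provenance = {
        "n_folds": n_folds,
        "shuffle": shuffle,
        "seed": int(seed),
        "n_train_genomes": len(genomes),
        "grid": dict(train.provenance),
        "hyperparameters": "library defaults",
    }
    kf = KFold(n_splits=n_folds, shuffle=shuffle, random_state=seed if shuffle else None)
    fold_models: list[TrainedCompletenessModel] = []
    cv_summary: list[dict] = []
    order = train.module_order
    for fold_idx, (tr_idx, va_idx) in enumerate(kf.split(genomes)):
        tr_ids = [genomes[i] for i in tr_idx]
        va_ids = [genomes[i] for i in va_idx]
        sub_tr = train.subset(tr_ids)
        sub_va = train.subset(va_ids)
        fold_seed = derive_seed(seed, algorithm, "fold", fold_idx)
        est = _fit_estimator(algorithm, sub_tr.feature_matrix(), sub_tr.labels(), fold_seed)
        model = TrainedCompletenessModel(
            algorithm, order, est, fold_seed, {**provenance, "fold": fold_idx}
        )
        rep = evaluate_model(model, sub_va)
        fold_models.append(model)
        cv_summary.append(
            {
                "fold": fold_idx,
                "n_validation_genomes": len(va_ids),
                "mse": rep.mse,
                "median_difference": rep.median_difference,
                "pearson_r": rep.pearson_r,
            }
        )
    final_seed = derive_seed(seed, algorithm, "final")
    final_est = _fit_estimator(algorithm, train.feature_matrix(), train.labels(), final_seed)
    final_model = TrainedCompletenessModel(
        algorithm, order, final_est, final_seed, {**provenance, "fold": None}
    )
    return TrainingResult(fold_models, final_model, cv_summary)


def predict_batch(
    model: TrainedCompletenessModel, X: np.ndarray
) -> np.ndarray:
    """Raw regressor predictions clamped to [0, 100]."""
    raw = np.asarray(model.estimator.predict(np.asarray(X, dtype=float)))
    return np.clip(raw, 0.0, 100.0)


def predict_completeness(
    model: TrainedCompletenessModel, features: ModuleCoverageVector
) -> float:
    """Predict percent completeness for a single coverage vector.

    The vector's module order must equal the model's training order;
    silent reordering would corrupt the features, so a mismatch raises.
    """
    if tuple(features.module_order) != tuple(model.feature_order):
        raise FeatureOrderError(
            "feature order does not match model catalog: "
            f"model has {len(model.feature_order)} modules starting "
            f"{model.feature_order[:3]}, input has {len(features.module_order)} "
            f"starting {features.module_order[:3]}"
        )
    return float(predict_batch(model, np.asarray([features.values]))[0])


def _pooled_predictions(
    models: TrainedCompletenessModel | Sequence[TrainedCompletenessModel],
    test: LabeledDataset,
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(models, TrainedCompletenessModel):
        models = [models]
    X = test.feature_matrix()
    y = test.labels()
    preds = []
    labels = []
    for m in models:
        if tuple(test.module_order) != tuple(m.feature_order):
            raise FeatureOrderError("test set module order does not match model")
        preds.append(predict_batch(m, X))
        labels.append(y)
    return np.concatenate(labels), np.concatenate(preds)


def evaluate_model(
    models: TrainedCompletenessModel | Sequence[TrainedCompletenessModel],
    test: LabeledDataset,
) -> EvaluationReport:
    """Evaluate one model (or pool a list of fold models) on a test grid."""
    if len(test) == 0:
        raise ValueError("test dataset is empty")
    expected, predicted = _pooled_predictions(models, test)

    per_level: dict[float, tuple[float, float]] = {}
    for level in sorted(set(expected)):
        sel = predicted[expected == level]
        per_level[float(level)] = (float(np.median(sel)), float(np.std(sel)))

    diffs = expected - predicted
    mse = float(np.mean((diffs / 100.0) ** 2))
    median_difference = float(np.median(diffs))

    linear_fit = None
    pearson_r = None
    pearson_p = None
    if len(set(expected)) >= 2:
        if np.std(predicted) > 0:
            fit = stats.linregress(expected, predicted)
            n = len(expected)
            r2 = fit.rvalue**2
            adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n > 2 else r2
            linear_fit = {
                "slope": float(fit.slope),
                "intercept": float(fit.intercept),
                "adjusted_r2": float(adj_r2),
                "p_value": float(fit.pvalue),
            }
            pr = stats.pearsonr(expected, predicted)
            pearson_r = float(pr.statistic)
            pearson_p = float(pr.pvalue)
    return EvaluationReport(
        per_level=per_level,
        linear_fit=linear_fit,
        pearson_r=pearson_r,
        pearson_p=pearson_p,
        mse=mse,
        median_difference=median_difference,
        n=len(expected),
    )


def select_best_model(reports: Mapping[str, EvaluationReport]) -> str:
    """Pick the algorithm with the smallest |median(expected − predicted)|.

    Ties break toward larger Pearson r, then by fixed algorithm-name
    order.  Returns the winning algorithm name; the full criterion trail
    is available from the reports themselves.
    """
    if len(reports) < 1:
        raise ValueError("no evaluation reports supplied")

    def rank(alg: str):
        rep = reports[alg]
        r = rep.pearson_r if rep.pearson_r is not None else -np.inf
        order = ALGORITHMS.index(alg) if alg in ALGORITHMS else len(ALGORITHMS)
        return (abs(rep.median_difference), -r, order, alg)

    return min(reports, key=rank)


def contrast_organelles(
    models: TrainedCompletenessModel | Sequence[TrainedCompletenessModel],
    plastid_test: LabeledDataset,
    mito_test: LabeledDataset,
) -> tuple[float, float]:
    """Median predicted completeness for plastid vs mitochondrial profiles.

    Both inputs should hold full (100%-complete) profiles; the returned
    pair's difference is the discrimination margin in percentage points.
    """
    if len(plastid_test) == 0 or len(mito_test) == 0:
        raise ValueError("both organelle test sets must be non-empty")
    _, p_pred = _pooled_predictions(models, plastid_test)
    _, m_pred = _pooled_predictions(models, mito_test)
    return float(np.median(p_pred)), float(np.median(m_pred))


# --- persistence ----------------------------------------------------------

def save_model(model: TrainedCompletenessModel, path: str | Path) -> None:
    """Persist the fitted regressor with an embedded metadata block."""
    payload = {
        "metadata": {
            "format": "plastidcheck-model",
            "version": __version__,
            "algorithm": model.algorithm,
            "feature_order": list(model.feature_order),
            "seed": int(model.seed),
            "training_provenance": json.loads(
                json.dumps(model.training_provenance, default=str)
            ),
        },
        "estimator": model.estimator,
    }
    joblib.dump(payload, path)


def load_model(
    path: str | Path, expected_feature_order: Sequence[str] | None = None
) -> TrainedCompletenessModel:
    payload = joblib.load(path)
    meta = payload.get("metadata", {}) if isinstance(payload, dict) else {}
    if meta.get("format") != "plastidcheck-model":
        raise ModelArtifactError(f"{path} is not a plastidcheck model artifact")
    if meta.get("version", "").split(".")[0] != __version__.split(".")[0]:
        raise ModelArtifactError(
            f"artifact version {meta.get('version')} incompatible with {__version__}"
        )
    order = tuple(meta["feature_order"])
    if expected_feature_order is not None and tuple(expected_feature_order) != order:
        raise ModelArtifactError(
            "model artifact was trained on a different module catalog"
        )
    return TrainedCompletenessModel(
        algorithm=meta["algorithm"],
        feature_order=order,
        estimator=payload["estimator"],
        seed=int(meta["seed"]),
        training_provenance=meta.get("training_provenance", {}),
    )
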
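"""Gradient-boosted age regression with an age-normalized objective.

The model predicts chronological age from the biomarker columns of a
cohort table. Plain squared-error boosting concentrates its error
budget on well-populated ages; the age-normalized objective rescales
each individual's gradient by the ratio of its age group's mean absolute
residual to the overall mean absolute residual, so age groups that are
currently predicted poorly (typically the sparse extremes) receive
proportionally larger updates:

    grad_i = (yhat_i - y_i) * mean|r|_{age(i)} / (mean|r|_overall + eps)

with unit Hessian. When every age group has the same mean absolute
residual the ratio is 1 and the objective coincides with the plain
squared-error gradient direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.metrics import mean_absolute_error, r2_score
from sklearn.model_selection import KFold, StratifiedKFold

from .cohort import AGE, CohortError, biomarker_columns

_ALLOWED_HYPERPARAMETERS = {
    "max_depth", "eta", "learning_rate", "subsample", "colsample_bytree",
    "colsample_bylevel", "min_child_weight", "gamma", "reg_lambda", "lambda",
    "reg_alpha", "alpha", "n_estimators", "tree_method", "max_bin",
}

DEFAULT_HYPERPARAMETERS: dict = {
    "max_depth": 4,
    "eta": 0.1,
    "subsample": 0.9,
    "colsample_bytree": 0.9,
    "min_child_weight": 5,
    "n_estimators": 200,
}

OBJECTIVES = ("standard", "age_normalized")


@dataclass
class ResidualBatch:
    """Targets and current predictions partitioned by integer age."""

    y: np.ndarray
    y_hat: np.ndarray
    ages: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.y_hat = np.asarray(self.y_hat, dtype=float)
        self.ages = np.asarray(self.ages)
        if not (len(self.y) == len(self.y_hat) == len(self.ages)):
            raise ValueError("y, y_hat and ages must have equal length")
        if len(self.y) == 0:
            raise ValueError("empty residual batch")


@dataclass
class ModelMetrics:
    r2: float
    mae: float
    r2_sd: float | None = None
    mae_sd: float | None = None


@dataclass
class TrainedAgeModel:
    booster: xgb.Booster
    selected_variables: list[str]
    objective: str
    hyperparameters: dict
    seed: int
    train_metrics: ModelMetrics | None = None
    test_metrics: ModelMetrics | None = None

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.selected_variables if c not in data.columns]
        if missing:
            raise CohortError(f"data lacks model variables: {missing}")
        X = data[self.selected_variables].to_numpy(dtype=np.float32)
        return self.booster.predict(xgb.DMatrix(X, feature_names=self.selected_variables))

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.booster.save_model(path)
        meta = {
            "selected_variables": self.selected_variables,
            "objective": self.objective,
            "hyperparameters": self.hyperparameters,
            "seed": self.seed,
        }
        path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedAgeModel":
        path = Path(path)
        booster = xgb.Booster()
        booster.load_model(path)
        meta = json.loads(path.with_suffix(".meta.json").read_text())
        return cls(booster=booster, train_metrics=None, test_metrics=None, **meta)


def custom_gradient(batch: ResidualBatch, epsilon: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Age-normalized gradient and (unit) Hessian.

    Residual magnitudes are averaged within each integer-age group and
    overall; each residual is scaled by the group-to-overall ratio.
    Single-member groups use their own magnitude as the group mean.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    resid = batch.y_hat - batch.y
    abs_resid = np.abs(resid)
    overall = abs_resid.mean()
    df = pd.Series(abs_resid).groupby(pd.Series(batch.ages)).transform("mean")
    ratio = df.to_numpy() / (overall + epsilon)
    grad = resid * ratio
    hess = np.ones_like(grad)
    return grad, hess


def _make_objective(ages: np.ndarray, epsilon: float = 1e-8):
    ages = np.asarray(ages)

    def objective(predt: np.ndarray, dtrain: xgb.DMatrix):
        batch = ResidualBatch(dtrain.get_label(), predt, ages)
        return custom_gradient(batch, epsilon)

    return objective


def _xgb_params(hyperparameters: dict, seed: int) -> tuple[dict, int]:
    unknown = set(hyperparameters) - _ALLOWED_HYPERPARAMETERS
    if unknown:
        raise CohortError(f"unknown hyperparameters: {sorted(unknown)}")
    hp = {**DEFAULT_HYPERPARAMETERS, **hyperparameters}
    n_rounds = int(hp.pop("n_estimators"))
    params = dict(hp)
    params.update({"nthread": 1, "seed": int(seed), "tree_method": params.get("tree_method", "hist")})
    return params, n_rounds


def fit_age_model(
    train: pd.DataFrame,
    hyperparameters: dict | None = None,
    objective: str = "age_normalized",
    seed: int = 0,
    variables: list[str] | None = None,
    evaluate_train: bool = True,
) -> TrainedAgeModel:
    """Fit the boosted-tree age model on the biomarker columns of ``train``.

    Missing biomarker values are routed natively by the trees; no
    imputation is required. Training is deterministic for a fixed seed
    (single-threaded histogram updates).
    """
    if objective not in OBJECTIVES:
        raise CohortError(f"objective must be one of {OBJECTIVES}")
    if train.empty:
        raise CohortError("training cohort is empty")
    variables = list(variables) if variables is not None else biomarker_columns(train)
    if not variables:
        raise CohortError("no biomarker variables to train on")
    y = train[AGE].to_numpy(dtype=float)
    if np.unique(y).size < 2:
        raise CohortError("target age is constant")
    X = train[variables].to_numpy(dtype=np.float32)
    params, n_rounds = _xgb_params(hyperparameters or {}, seed)
    params["base_score"] = float(y.mean())
    dtrain = xgb.DMatrix(X, label=y, feature_names=variables)
    if objective == "age_normalized":
        booster = xgb.train(params, dtrain, num_boost_round=n_rounds,
                            obj=_make_objective(train[AGE].to_numpy()))
    else:
        params["objective"] = "reg:squarederror"
        booster = xgb.train(params, dtrain, num_boost_round=n_rounds)
    model = TrainedAgeModel(
        booster=booster,
        selected_variables=variables,
        objective=objective,
        hyperparameters={**(hyperparameters or {})},
        seed=seed,
    )
    if evaluate_train:
        model.train_metrics = evaluate(model, train)
    return model


def evaluate(model: TrainedAgeModel, data: pd.DataFrame) -> ModelMetrics:
    """R^2 and MAE of the model's age predictions on ``data``."""
    y = data[AGE].to_numpy(dtype=float)
    pred = model.predict(data)
    return ModelMetrics(r2=float(r2_score(y, pred)), mae=float(mean_absolute_error(y, pred)))


def cross_validate(
    train: pd.DataFrame,
    hyperparameters: dict | None = None,
    k: int = 5,
    objective: str = "age_normalized",
    seed: int = 0,
) -> ModelMetrics:
    """K-fold cross-validated metrics, folds stratified by age decade.

    Falls back to unstratified folds when a decade stratum is smaller
    than ``k`` (e.g. leave-one-out).
    """
    n = len(train)
    if k < 2:
        raise CohortError("k must be >= 2")
    if k > n:
        raise CohortError("k exceeds the number of individuals")
    decade = (train[AGE] // 10).to_numpy()
    counts = pd.Series(decade).value_counts()
    if (counts < k).any():
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        folds = splitter.split(np.arange(n))
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = splitter.split(np.arange(n), decade)
    r2s, maes = [], []
    for fold_train, fold_val in folds:
        sub = train.iloc[fold_train]
        model = fit_age_model(sub, hyperparameters, objective=objective, seed=seed,
                              evaluate_train=False)
        m = evaluate(model, train.iloc[fold_val])
        r2s.append(m.r2)
        maes.append(m.mae)
    return ModelMetrics(
        r2=float(np.mean(r2s)),
        mae=float(np.mean(maes)),
        r2_sd=float(np.std(r2s, ddof=1)) if len(r2s) > 1 else 0.0,
        mae_sd=float(np.std(maes, ddof=1)) if len(maes) > 1 else 0.0,
    )


def compare_models(
    train: pd.DataFrame,
    test: pd.DataFrame,
    seed: int = 0,
) -> pd.DataFrame:
    """Thin comparison harness: classical regressors vs the boosted tree.

    The scikit-learn baselines require a complete table (impute first);
    they are provided for orientation only and use stock settings.
    """
    from sklearn.ensemble import RandomForestRegressor
    from sklearn.linear_model import ElasticNet
    from sklearn.neural_network import MLPRegressor
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.tree import DecisionTreeRegressor

    variables = biomarker_columns(train)
    X_train = train[variables].to_numpy(dtype=float)
    X_test = test[variables].to_numpy(dtype=float)
    if np.isnan(X_train).any() or np.isnan(X_test).any():
        raise CohortError("baseline comparison requires imputed cohorts")
    y_train = train[AGE].to_numpy(dtype=float)
    y_test = test[AGE].to_numpy(dtype=float)
    baselines = {
        "decision_tree": DecisionTreeRegressor(max_depth=8, random_state=seed),
        "random_forest": RandomForestRegressor(n_estimators=100, n_jobs=1, random_state=seed),
        "elastic_net": make_pipeline(StandardScaler(), ElasticNet(alpha=0.1, random_state=seed)),
        "mlp": make_pipeline(
            StandardScaler(),
            MLPRegressor(hidden_layer_sizes=(64, 32), max_iter=300, random_state=seed),
        ),
    }
    rows = []
    for name, est in baselines.items():
        est.fit(X_train, y_train)
        pred = est.predict(X_test)
        rows.append((name, float(r2_score(y_test, pred)),
                     float(mean_absolute_error(y_test, pred))))
    for objective in OBJECTIVES:
        model = fit_age_model(train, objective=objective, seed=seed, evaluate_train=False)
        m = evaluate(model, test)
        rows.append((f"xgboost_{objective}", m.r2, m.mae))
    return pd.DataFrame(rows, columns=["model", "r2", "mae"]).sort_values(
        "mae"
    ).reset_index(drop=True)


def tune_hyperparameters(
    train: pd.DataFrame,
    budget: int = 8,
    objective: str = "age_normalized",
    seed: int = 0,
    k: int = 3,
) -> dict:
    """Small randomized hyperparameter search scored by CV MAE."""
    rng = np.random.default_rng(seed)
    best, best_mae = dict(DEFAULT_HYPERPARAMETERS), np.inf
    for _ in range(budget):
        cand = {
            "max_depth": int(rng.integers(3, 7)),
            "eta": float(rng.choice([0.05, 0.1, 0.2])),
            "subsample": float(rng.choice([0.7, 0.9, 1.0])),
            "colsample_bytree": float(rng.choice([0.7, 0.9, 1.0])),
            "min_child_weight": int(rng.choice([1, 5, 20])),
            "n_estimators": int(rng.choice([100, 200, 300])),
        }
        mae = cross_validate(train, cand, k=k, objective=objective, seed=seed).mae
        if mae < best_mae:
            best, best_mae = cand, mae
    return best
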
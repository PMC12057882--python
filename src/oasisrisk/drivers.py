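"""Driver-importance analysis of the ecological risk surface.

The contribution of candidate drivers (terrain, climate, soil erosion,
and socioeconomic pressure) to the per-cell ecological risk index is
quantified with a bagged ensemble of regression trees with per-split
random feature selection — a random forest with explicit per-tree
bootstrap bookkeeping, which the importance score requires.

The importance score of predictor *j* is the mean, over the N trees, of
the increase in out-of-bag (OOB) squared error when predictor *j* is
scrambled among each tree's OOB rows:

    IS_j = mean_t ( errOOB2_{t,j} - errOOB1_t )

where ``errOOB1`` is the tree's OOB mean squared error and ``errOOB2``
its OOB error after the interference.  Scrambling is a within-OOB
permutation by default; an additive Gaussian-noise variant is available.

Model quality on held-out cells is summarised by R^2, RMSE and the ratio
of performance to deviation RPD = sd(y) / RMSE-like deviation, with the
conventional reading: excellent when RPD >= 2, fair when 1.4 <= RPD < 2,
low below 1.4.  Because both are built from the same sums of squares,
RPD = 1 / sqrt(1 - R^2) identically whenever R^2 < 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import BaggingRegressor
from sklearn.metrics import mean_squared_error
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.tree import DecisionTreeRegressor

from .synthetic import DRIVER_NAMES

__all__ = [
    "DEFAULT_GRID",
    "FULL_GRID",
    "FitReport",
    "normalize_and_split",
    "make_forest",
    "fit_and_validate",
    "importance_scores",
    "rpd",
    "regression_metrics",
]

#: Reduced hyperparameter grid: tunes in minutes, spans the useful range.
DEFAULT_GRID = {
    "n_estimators": [10, 20, 30, 40, 50],
    "max_depth": [3, 6, 10, 15, 20],
    "max_features": [2, 4, 6, 8],
}

#: Exhaustive grid (n_estimators 5-50, max_depth 1-20, max_features 1-9).
FULL_GRID = {
    "n_estimators": list(range(5, 51)),
    "max_depth": list(range(1, 21)),
    "max_features": list(range(1, 10)),
}

#: Default split: 484 training / 162 validation rows out of 646.
DEFAULT_TRAIN_FRACTION = 484 / 646


def normalize_and_split(
    table: pd.DataFrame,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    seed: int = 0,
    predictors: tuple[str, ...] = DRIVER_NAMES,
    response: str = "eri",
) -> pd.DataFrame:
    """Min-max normalize predictors and add a seeded train/validation split.

    Normalization bounds come from the training rows only and are applied
    to all rows, so no validation information leaks into the scaling.  A
    constant predictor maps to 0 with a warning.  At the default fraction
    a 646-row table splits into exactly 484 training and 162 validation
    rows.
    """
    import warnings

    if len(table) < 20:
        raise ValueError("need at least 20 rows to split")
    missing = [c for c in (*predictors, response) if c not in table.columns]
    if missing:
        raise ValueError(f"table is missing columns: {missing}")
    out = table.copy()
    rng = np.random.default_rng(seed)
    n = len(out)
    n_train = int(round(train_fraction * n))
    perm = rng.permutation(n)
    split = np.full(n, "validation", dtype=object)
    split[perm[:n_train]] = "train"
    out["split"] = split
    train_mask = out["split"].to_numpy() == "train"
    for col in predictors:
        vals = out[col].to_numpy(dtype=float)
        lo, hi = vals[train_mask].min(), vals[train_mask].max()
        if hi <= lo:
            warnings.warn(f"predictor {col!r} is constant; mapped to 0", stacklevel=2)
            out[col] = 0.0
        else:
            out[col] = (vals - lo) / (hi - lo)
    return out


def make_forest(
    n_estimators: int = 50,
    max_depth: int | None = 10,
    max_features: int | float | None = None,
    seed: int = 0,
) -> BaggingRegressor:
    """Bootstrap ensemble of regression trees with per-split feature draw.

    Built on :class:`~sklearn.ensemble.BaggingRegressor` so each tree's
    bootstrap rows are exposed (``estimators_samples_``), which the OOB
    importance score needs.
    """
    tree = DecisionTreeRegressor(
        max_depth=max_depth, max_features=max_features, random_state=seed
    )
    return BaggingRegressor(
        estimator=tree,
        n_estimators=n_estimators,
        bootstrap=True,
        random_state=seed,
    )


@dataclass
class FitReport:
    """Validation metrics, chosen hyperparameters and driver importances."""

    R2: float
    RMSE: float
    RPD: float
    category: str
    importance: dict[str, float]
    importance_normalized: dict[str, float]
    hyperparameters: dict
    model: BaggingRegressor = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "R2": self.R2,
            "RMSE": self.RMSE,
            "RPD": self.RPD,
            "category": self.category,
            "importance": self.importance,
            "importance_normalized": self.importance_normalized,
            "hyperparameters": self.hyperparameters,
        }


def rpd(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    """R^2, RMSE, RPD and the performance category of a prediction.

    RPD = sqrt(sum (y - ybar)^2) / sqrt(sum (yhat - y)^2); a model no
    better than the mean has R^2 = 0 and RPD = 1, a perfect fit has
    RPD = +inf (category excellent).
    """
    y = np.asarray(y_true, dtype=float)
    yhat = np.asarray(y_pred, dtype=float)
    if y.size < 2:
        raise ValueError("need at least two observations")
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError("response variance is zero")
    sse = float(((yhat - y) ** 2).sum())
    r2 = 1.0 - sse / sst
    rmse = float(np.sqrt(sse / y.size))
    ratio = np.inf if sse == 0 else float(np.sqrt(sst) / np.sqrt(sse))
    if ratio >= 2.0:
        category = "excellent"
    elif ratio >= 1.4:
        category = "fair"
    else:
        category = "low"
    return {"R2": r2, "RMSE": rmse, "RPD": ratio, "category": category}


# companion alias: rpd() already returns R2 and RMSE alongside
regression_metrics = rpd


def importance_scores(
    model: BaggingRegressor,
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    seed: int = 0,
    method: str = "permute",
    noise_sd: float = 1.0,
) -> dict[str, float]:
    """OOB interference importance, IS_j = mean_t(errOOB2 - errOOB1).

    ``method="permute"`` scrambles the predictor among each tree's OOB
    rows; ``"noise"`` adds Gaussian noise (sd = ``noise_sd`` times the
    predictor's sd) instead.
    """
    if method not in {"permute", "noise"}:
        raise ValueError(f"unknown method {method!r}")
    if not getattr(model, "bootstrap", False) or not hasattr(
        model, "estimators_samples_"
    ):
        raise ValueError(
            "model has no out-of-bag bookkeeping; fit a bootstrap ensemble "
            "(make_forest) before computing importances"
        )
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"x{j}" for j in range(np.asarray(X).shape[1])
    ]
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float)
    n = Xa.shape[0]
    rng = np.random.default_rng(seed)
    deltas = np.zeros((len(model.estimators_), len(names)))
    n_used = 0
    for t, (tree, sampled) in enumerate(
        zip(model.estimators_, model.estimators_samples_)
    ):
        oob = np.setdiff1d(np.arange(n), np.unique(sampled))
        if oob.size < 2:
            continue
        n_used += 1
        X_oob = Xa[oob]
        err1 = mean_squared_error(ya[oob], tree.predict(X_oob))
        for j in range(len(names)):
            X_pert = X_oob.copy()
            if method == "permute":
                X_pert[:, j] = rng.permutation(X_pert[:, j])
            else:
                X_pert[:, j] = X_pert[:, j] + rng.normal(
                    0.0, noise_sd * X_pert[:, j].std() + 1e-12, size=oob.size
                )
            err2 = mean_squared_error(ya[oob], tree.predict(X_pert))
            deltas[t, j] = err2 - err1
    if n_used == 0:
        raise ValueError("no tree had out-of-bag rows; increase sample size")
    raw = deltas.sum(axis=0) / n_used
    return dict(zip(names, (float(v) for v in raw)))


def _normalize_importance(raw: dict[str, float]) -> dict[str, float]:
    """Relative influence: negatives clipped to 0, values sum to 1."""
    clipped = {k: max(v, 0.0) for k, v in raw.items()}
    total = sum(clipped.values())
    if total == 0:
        return {k: 1.0 / len(raw) for k in raw}
    return {k: v / total for k, v in clipped.items()}


def fit_and_validate(
    table: pd.DataFrame,
    grid: dict | None = None,
    folds: int = 4,
    seed: int = 0,
    predictors: tuple[str, ...] = DRIVER_NAMES,
    response: str = "eri",
) -> FitReport:
    """Grid-search a tree ensemble on the training rows, score on validation.

    Hyperparameters are chosen by exhaustive search over ``grid`` (the
    reduced :data:`DEFAULT_GRID` by default) with ``folds``-fold
    cross-validation on the training rows; the report's metrics and
    importances are computed on the validation rows.
    """
    if "split" not in table.columns:
        raise ValueError("table has no split column; run normalize_and_split first")
    grid = DEFAULT_GRID if grid is None else grid
    train = table[table["split"] == "train"]
    valid = table[table["split"] == "validation"]
    if len(train) < folds:
        raise ValueError(f"{len(train)} training rows is fewer than {folds} folds")
    X_train = train[list(predictors)]
    y_train = train[response].to_numpy(dtype=float)
    param_grid = {
        "n_estimators": grid.get("n_estimators", [50]),
        "estimator__max_depth": grid.get("max_depth", [10]),
        "estimator__max_features": [
            min(m, len(predictors)) for m in grid.get("max_features", [None])
        ],
    }
    search = GridSearchCV(
        make_forest(seed=seed),
        param_grid,
        cv=KFold(n_splits=folds, shuffle=True, random_state=seed),
        scoring="neg_mean_squared_error",
        n_jobs=None,
    )
    search.fit(X_train, y_train)
    best = search.best_estimator_
    chosen = {
        "n_estimators": search.best_params_["n_estimators"],
        "max_depth": search.best_params_["estimator__max_depth"],
        "max_features": search.best_params_["estimator__max_features"],
    }
    y_valid = valid[response].to_numpy(dtype=float)
    metrics = rpd(y_valid, best.predict(valid[list(predictors)]))
    raw = importance_scores(best, X_train, y_train, seed=seed)
    return FitReport(
        R2=metrics["R2"],
        RMSE=metrics["RMSE"],
        RPD=metrics["RPD"],
        category=metrics["category"],
        importance=raw,
        importance_normalized=_normalize_importance(raw),
        hyperparameters=chosen,
        model=best,
    )
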
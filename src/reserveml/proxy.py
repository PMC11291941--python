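"""Tiered gradient-boosted surrogates of the reserve criterion.

The criterion standard (standardised RRI factor scores) is approximated from
clinical features by XGBoost regressors, one per feature tier.  Protocol:

* a simple random 75/25 train/test split of the cohort;
* hyperparameter search scored by mean out-of-fold RMSE over a fixed 10-fold
  partition of the training set;
* surrogate-guided ("Bayesian-style") search: space-filling initial design,
  then lower-confidence-bound proposals from a random-forest surrogate over
  the normalised search space, with an early-discontinuation rule after a
  configurable number of consecutive non-improvements;
* a final ensemble refit on all training rows with the winning
  hyperparameters.

Missing feature values are never imputed: the boosted trees learn default
split directions for them natively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy.stats import qmc
from sklearn.ensemble import RandomForestRegressor

from .features import TierSpec

__all__ = [
    "SplitSpec",
    "SearchDimension",
    "TunerConfig",
    "TrainedProxy",
    "EvaluationReport",
    "default_search_space",
    "split_train_test",
    "make_folds",
    "cv_rmse",
    "tune",
    "fit_final",
    "predict",
    "evaluate",
]


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class SearchDimension:
    low: float
    high: float
    scale: str = "linear"  # 'linear' | 'log' | 'int'

    def __post_init__(self) -> None:
        if self.high < self.low:
            raise ValueError("high must be >= low")
        if self.scale not in ("linear", "log", "int"):
            raise ValueError("scale must be linear/log/int")

    def from_unit(self, u: float) -> float:
        if self.scale == "log":
            return float(np.exp(np.log(self.low) + u * (np.log(self.high) - np.log(self.low))))
        value = self.low + u * (self.high - self.low)
        if self.scale == "int":
            return int(round(value))
        return float(value)


def default_search_space() -> dict[str, SearchDimension]:
    return {
        "max_depth": SearchDimension(2, 8, "int"),
        "learning_rate": SearchDimension(1e-2, 0.3, "log"),
        "min_child_weight": SearchDimension(1, 20, "linear"),
        "subsample": SearchDimension(0.5, 1.0, "linear"),
        "colsample_bytree": SearchDimension(0.5, 1.0, "linear"),
        "n_estimators": SearchDimension(100, 1500, "int"),
        "reg_lambda": SearchDimension(1e-3, 10.0, "log"),
    }


@dataclass(frozen=True)
class TunerConfig:
    n_folds: int = 10
    max_iterations: int = 200
    patience: int = 100
    search_space: dict[str, SearchDimension] = field(default_factory=default_search_space)
    seed: int = 0
    n_initial: int = 8

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.patience > self.max_iterations:
            raise ValueError("patience must be <= max_iterations")
        if not self.search_space:
            raise ValueError("search_space must not be empty")


@dataclass
class TrainedProxy:
    tier: TierSpec
    hyperparameters: dict[str, float]
    model: xgb.XGBRegressor
    feature_order: tuple[str, ...]
    cv_rmse: float
    training_meta: dict = field(default_factory=dict)


@dataclass
class EvaluationReport:
    rmse: float
    pearson_r: float
    n: int
    split: str
    r_undefined: bool = False


def split_train_test(
    cohort: pd.DataFrame, spec: SplitSpec | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint/exhaustive id partition, reproducible given the seed."""
    spec = spec or SplitSpec()
    ids = cohort["id"].to_numpy()
    if len(ids) < 8:
        raise ValueError("need at least 8 participants to split")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(len(ids))
    n_train = int(round(spec.train_fraction * len(ids)))
    return np.sort(ids[perm[:n_train]]), np.sort(ids[perm[n_train:]])


def make_folds(n: int, n_folds: int, seed: int) -> np.ndarray:
    """Fold label per row: a fixed random partition into ``n_folds`` folds."""
    rng = np.random.default_rng(seed)
    labels = np.arange(n) % n_folds
    return labels[rng.permutation(n)]


def _xgb_params(hyper: dict[str, float], seed: int) -> dict:
    params = dict(hyper)
    params.setdefault("n_estimators", 300)
    return dict(
        objective="reg:squarederror",
        missing=np.nan,
        random_state=seed,
        n_jobs=1,
        tree_method="hist",
        **params,
    )


def cv_rmse(
    X: pd.DataFrame,
    y: np.ndarray,
    hyper: dict[str, float],
    folds: np.ndarray,
    seed: int = 0,
) -> float:
    """Mean out-of-fold RMSE of one hyperparameter candidate."""
    rmses = []
    for k in np.unique(folds):
        held = folds == k
        model = xgb.XGBRegressor(**_xgb_params(hyper, seed))
        model.fit(X[~held], y[~held])
        pred = model.predict(X[held])
        rmses.append(float(np.sqrt(np.mean((pred - y[held]) ** 2))))
    return float(np.mean(rmses))


def tune(
    X: pd.DataFrame,
    y: np.ndarray,
    cfg: TunerConfig,
) -> tuple[dict[str, float], float, pd.DataFrame]:
    """Surrogate-guided hyperparameter search minimising out-of-fold RMSE.

    Runs up to ``cfg.max_iterations`` candidates over a fixed fold partition,
    stopping early after ``cfg.patience`` consecutive non-improvements.
    Returns the argmin candidate, its CV RMSE, and the full iteration log.
    """
    if len(y) < 2 * cfg.n_folds:
        raise ValueError("need at least 2 rows per fold to tune")
    names = list(cfg.search_space)
    dims = [cfg.search_space[n] for n in names]
    folds = make_folds(len(y), cfg.n_folds, cfg.seed)
    rng = np.random.default_rng(cfg.seed)

    n_init = min(cfg.n_initial, cfg.max_iterations)
    sobol = qmc.Sobol(d=len(names), seed=cfg.seed, scramble=True)
    n_pow2 = 1 << max(0, (n_init - 1).bit_length())
    unit_points = list(sobol.random_base2(int(np.log2(n_pow2)))[:n_init])

    log_rows = []
    evaluated_units: list[np.ndarray] = []
    best_rmse = np.inf
    stall = 0
    it = 0
    while it < cfg.max_iterations:
        if it < len(unit_points):
            u = np.asarray(unit_points[it], dtype=float)
        else:
            u = _propose(evaluated_units, [row["cv_rmse"] for row in log_rows],
                         len(names), rng)
        candidate = {n: d.from_unit(float(ui)) for n, d, ui in zip(names, dims, u)}
        rmse = cv_rmse(X, y, candidate, folds, seed=cfg.seed)
        it += 1
        if not np.isfinite(rmse):
            warnings.warn(f"discarding candidate with non-finite CV RMSE: {candidate}")
            continue
        evaluated_units.append(u)
        log_rows.append({"iteration": it, "cv_rmse": rmse, **candidate})
        if rmse < best_rmse - 1e-12:
            best_rmse = rmse
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break

    if not log_rows:
        raise RuntimeError("tuning produced no finite candidate")
    log = pd.DataFrame(log_rows)
    best_row = log.loc[log["cv_rmse"].idxmin()]
    best = {n: best_row[n] for n in names}
    for n, d in zip(names, dims):
        if d.scale == "int":
            best[n] = int(best[n])
    return best, float(best_row["cv_rmse"]), log


def _propose(units, scores, d, rng: np.random.Generator) -> np.ndarray:
    """Lower-confidence-bound proposal from a random-forest surrogate."""
    pool = rng.random((128, d))
    if len(units) < 4:
        return pool[0]
    surrogate = RandomForestRegressor(
        n_estimators=30, random_state=int(rng.integers(2**31)), n_jobs=1
    )
    surrogate.fit(np.vstack(units), np.asarray(scores))
    per_tree = np.stack([t.predict(pool) for t in surrogate.estimators_])
    lcb = per_tree.mean(axis=0) - per_tree.std(axis=0)
    return pool[int(np.argmin(lcb))]


def fit_final(
    X: pd.DataFrame,
    y: np.ndarray,
    tier: TierSpec,
    hyperparameters: dict[str, float],
    cv_rmse_value: float = np.nan,
    seed: int = 0,
    training_meta: dict | None = None,
) -> TrainedProxy:
    """Fit the final ensemble on all training rows.

    Feature columns that are entirely missing are retained (with a warning):
    the trees simply never split on them, and prediction-time missingness is
    handled by default-direction routing.
    """
    X = X[list(tier.feature_names)]
    all_missing = [c for c in X.columns if X[c].isna().all()]
    if all_missing:
        warnings.warn(f"features entirely missing in training data: {all_missing}")
    model = xgb.XGBRegressor(**_xgb_params(hyperparameters, seed))
    model.fit(X, y)
    return TrainedProxy(
        tier=tier,
        hyperparameters=dict(hyperparameters),
        model=model,
        feature_order=tuple(tier.feature_names),
        cv_rmse=float(cv_rmse_value),
        training_meta=dict(training_meta or {}, seed=seed),
    )


def predict(proxy: TrainedProxy, features: pd.DataFrame) -> pd.Series:
    """Predicted surrogate reserve score per row; finite even when every
    feature is missing (default-path routing)."""
    unknown = set(features.columns) - set(proxy.feature_order) - {"id"}
    if unknown:
        raise KeyError(f"unknown feature columns: {sorted(unknown)}")
    missing_cols = set(proxy.feature_order) - set(features.columns)
    if missing_cols:
        raise KeyError(f"feature columns absent from input: {sorted(missing_cols)}")
    X = features[list(proxy.feature_order)]
    scores = proxy.model.predict(X)
    return pd.Series(scores.astype(float), index=features.index, name="approx_cr")


def evaluate(
    proxy: TrainedProxy,
    features: pd.DataFrame,
    criterion: pd.Series,
    split: str = "held_out",
) -> EvaluationReport:
    """RMSE and Pearson correlation of predictions against the criterion."""
    pred = predict(proxy, features)
    aligned = pd.concat([pred, criterion.rename("crit").reindex(pred.index)], axis=1).dropna()
    n = len(aligned)
    if n < 3:
        raise ValueError("need at least 3 aligned rows to evaluate")
    err = aligned["approx_cr"] - aligned["crit"]
    rmse = float(np.sqrt(np.mean(err**2)))
    undefined = (
        float(aligned["approx_cr"].std(ddof=0)) == 0
        or float(aligned["crit"].std(ddof=0)) == 0
    )
    if undefined:
        r = 0.0
    else:
        r = float(np.corrcoef(aligned["approx_cr"], aligned["crit"])[0, 1])
    return EvaluationReport(rmse=rmse, pearson_r=r, n=n, split=split, r_undefined=undefined)
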
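"""PLS regression of log10(IC50) on peptide encodings, with cross-validation.

The response is the base-10 logarithm of the IC50 in nanomolar (lower IC50 =
stronger binding), modeled from the 100-dimensional chemistry encoding by
partial least squares (PLS1).  PLS projects the predictors onto a small
number of latent components chosen to maximize covariance with the
response — the component count is the single hyperparameter, selected by a
seeded 5-fold cross-validated scan.  A pluggable benchmark harness evaluates
arbitrary fit/predict regressors on the identical fold splits.

The PLS fit itself is delegated to scikit-learn's NIPALS implementation and
collapsed to an explicit linear predictor (coefficients + intercept) for
serving and serialization.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# target transform

def transform_target(ic50_nM):
    """log10 of IC50 in nM; the modeling scale for binding affinity."""
    arr = np.asarray(ic50_nM, dtype=float)
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise ValueError("IC50 values must be finite and strictly positive (nM)")
    out = np.log10(arr)
    return float(out) if np.isscalar(ic50_nM) or arr.ndim == 0 else out


def back_transform(log10_ic50):
    """Inverse of :func:`transform_target`: predicted IC50 in nM."""
    arr = np.asarray(log10_ic50, dtype=float)
    out = np.power(10.0, arr)
    return float(out) if np.isscalar(log10_ic50) or arr.ndim == 0 else out


# --------------------------------------------------------------------------
# PLS model

@dataclass
class AffinityModel:
    """A fitted PLS1 model collapsed to a linear predictor.

    ``predict`` applies ``X @ coefficients + intercept`` on the raw (uncentered,
    unscaled) encoding scale; centering and scaling used during fitting are
    already folded into the coefficients.
    """

    n_components: int
    coefficients: np.ndarray  # (n_features,)
    intercept: float
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    y_scale: float
    training_meta: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.coefficients.shape[0]:
            raise ValueError(
                f"encoding width {X.shape} incompatible with model "
                f"({self.coefficients.shape[0]} features)"
            )
        return X @ self.coefficients + self.intercept

    def predict_ic50(self, X: np.ndarray) -> np.ndarray:
        return back_transform(self.predict(X))

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "n_components": self.n_components,
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "x_mean": self.x_mean.tolist(),
            "x_scale": self.x_scale.tolist(),
            "y_mean": self.y_mean,
            "y_scale": self.y_scale,
            "training_meta": self.training_meta,
        }
        blob = json.dumps(payload, sort_keys=True)
        digest = hashlib.sha256(blob.encode()).hexdigest()
        return json.dumps({"content_sha256": digest, **payload}, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AffinityModel":
        d = json.loads(text)
        return cls(
            n_components=int(d["n_components"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            intercept=float(d["intercept"]),
            x_mean=np.asarray(d["x_mean"], dtype=float),
            x_scale=np.asarray(d["x_scale"], dtype=float),
            y_mean=float(d["y_mean"]),
            y_scale=float(d["y_scale"]),
            training_meta=d.get("training_meta", {}),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "AffinityModel":
        return cls.from_json(Path(path).read_text())


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int = 3,
    scale_x: bool = True,
    training_meta: dict | None = None,
) -> AffinityModel:
    """Fit PLS1 (NIPALS deflation) on centered, optionally unit-scaled X.

    Zero-variance predictor columns — e.g. the padding block of an
    all-9-mer dataset — receive unit scale and contribute nothing.  The
    fitted latent model is collapsed to raw-scale coefficients and an
    intercept, so serving needs no transform state.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y disagree on sample count")
    if X.shape[0] <= n_components:
        raise ValueError(
            f"need more than n_components={n_components} samples, got {X.shape[0]}"
        )
    pls = PLSRegression(n_components=n_components, scale=scale_x)
    pls.fit(X, y)
    coefficients = pls.coef_.ravel().copy()
    # fold the predictor centering into the intercept: the fitted estimator
    # predicts (X - x_mean) @ coef + intercept_
    model = AffinityModel(
        n_components=n_components,
        coefficients=coefficients,
        intercept=float(np.ravel(pls.intercept_)[0] - pls._x_mean @ coefficients),
        x_mean=pls._x_mean.copy(),
        x_scale=pls._x_std.copy(),
        y_mean=float(np.ravel(pls._y_mean)[0]),
        y_scale=float(np.ravel(pls._y_std)[0]),
        training_meta=dict(training_meta or {}),
    )
    # latent scores kept on the instance for diagnostics (not serialized)
    model._x_scores = pls.x_scores_.copy()
    return model


def _pls_factory(n_components: int, scale_x: bool) -> Callable[[], object]:
    def factory():
        return PLSRegression(n_components=n_components, scale=scale_x)

    return factory


# --------------------------------------------------------------------------
# cross-validation harness

@dataclass(frozen=True)
class RegressorSpec:
    """A named estimator constructor honoring fit(X, y) / predict(X)."""

    name: str
    factory: Callable[[], object]
    hyperparameters: Mapping = field(default_factory=dict)

    def build(self):
        est = self.factory()
        if self.hyperparameters:
            est.set_params(**dict(self.hyperparameters))
        return est


@dataclass
class CVResult:
    """Per-fold and averaged held-out metrics for one estimator."""

    per_fold: list[dict]
    seed: int
    k_folds: int

    @property
    def mean_r2(self) -> float:
        return float(np.mean([f["test_r2"] for f in self.per_fold]))

    @property
    def mean_rmse(self) -> float:
        return float(np.mean([f["test_rmse"] for f in self.per_fold]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_fold)


def make_folds(n: int, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded shuffle, then k contiguous near-equal blocks as test folds."""
    if n < k:
        raise ValueError(f"cannot make {k} folds from {n} samples")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    folds = []
    start = 0
    for size in sizes:
        test = np.sort(perm[start : start + size])
        train = np.sort(np.concatenate([perm[:start], perm[start + size :]]))
        folds.append((train, test))
        start += size
    return folds


def _r2(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    sst = float(np.sum((y_true - y_true.mean()) ** 2))
    sse = float(np.sum((y_true - y_pred) ** 2))
    if sst == 0:
        raise ValueError("R^2 undefined: zero variance in the evaluation fold")
    return 1.0 - sse / sst


def _rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    estimator_factory: Callable[[], object] | None = None,
    *,
    n_components: int = 3,
    scale_x: bool = True,
    k: int = 5,
    seed: int = 0,
    folds: Sequence[tuple[np.ndarray, np.ndarray]] | None = None,
) -> CVResult:
    """Seeded k-fold CV; R^2 uses the held-out fold's own mean in SST.

    With no *estimator_factory*, a PLS model with *n_components* is used.
    Metrics are in log10(IC50) units.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if estimator_factory is None:
        estimator_factory = _pls_factory(n_components, scale_x)
    if folds is None:
        folds = make_folds(len(y), k, seed)
    per_fold = []
    for i, (train, test) in enumerate(folds):
        if len(test) < 2:
            raise ValueError(f"fold {i} has {len(test)} test samples; R^2 undefined")
        est = estimator_factory()
        est.fit(X[train], y[train])
        pred_test = np.ravel(est.predict(X[test]))
        pred_train = np.ravel(est.predict(X[train]))
        per_fold.append(
            {
                "fold": i,
                "test_r2": _r2(y[test], pred_test),
                "test_rmse": _rmse(y[test], pred_test),
                "train_r2": _r2(y[train], pred_train),
                "train_rmse": _rmse(y[train], pred_train),
                "n_test": int(len(test)),
            }
        )
    return CVResult(per_fold=per_fold, seed=seed, k_folds=len(folds))


def scan_components(
    X: np.ndarray,
    y: np.ndarray,
    component_range: Sequence[int] = range(2, 11),
    k: int = 5,
    seed: int = 0,
    scale_x: bool = True,
) -> pd.DataFrame:
    """Cross-validate PLS over a component range on identical folds.

    Returns a table of {components, mean_r2, mean_rmse, best}; the best row
    maximizes mean R^2 with ties broken toward fewer components.
    """
    folds = make_folds(len(np.ravel(y)), k, seed)
    rows = []
    for c in component_range:
        cv = cross_validate(
            X, y, _pls_factory(c, scale_x), k=k, seed=seed, folds=folds
        )
        rows.append({"components": c, "mean_r2": cv.mean_r2, "mean_rmse": cv.mean_rmse})
    table = pd.DataFrame(rows)
    best_idx = int(table["mean_r2"].idxmax())  # idxmax takes the first maximum
    table["best"] = False
    table.loc[best_idx, "best"] = True
    logger.info(
        "component scan: best=%d components (mean R^2 %.3f, RMSE %.3f)",
        table.loc[best_idx, "components"],
        table.loc[best_idx, "mean_r2"],
        table.loc[best_idx, "mean_rmse"],
    )
    return table


def default_regressor_specs(seed: int = 0) -> list[RegressorSpec]:
    """A registry of commonly used classical regressors for the benchmark."""
    from sklearn.ensemble import (
        AdaBoostRegressor,
        BaggingRegressor,
        ExtraTreesRegressor,
        GradientBoostingRegressor,
        RandomForestRegressor,
    )
    from sklearn.linear_model import (
        BayesianRidge,
        ElasticNet,
        Lasso,
        LinearRegression,
        Ridge,
        TweedieRegressor,
    )
    from sklearn.neighbors import KNeighborsRegressor
    from sklearn.svm import SVR, NuSVR
    from sklearn.tree import DecisionTreeRegressor

    seeded = {"random_state": seed}
    return [
        RegressorSpec("ExtraTrees", ExtraTreesRegressor, seeded),
        RegressorSpec("RandomForest", RandomForestRegressor, seeded),
        RegressorSpec("GradientBoosting", GradientBoostingRegressor, seeded),
        RegressorSpec("AdaBoost", AdaBoostRegressor, seeded),
        RegressorSpec("Bagging", BaggingRegressor, seeded),
        RegressorSpec("DecisionTree", DecisionTreeRegressor, seeded),
        RegressorSpec("Linear", LinearRegression),
        RegressorSpec("Ridge", Ridge),
        RegressorSpec("Lasso", Lasso),
        RegressorSpec("ElasticNet", ElasticNet),
        RegressorSpec("BayesianRidge", BayesianRidge),
        RegressorSpec("Tweedie", TweedieRegressor),
        RegressorSpec("SVR", SVR),
        RegressorSpec("NuSVR", NuSVR),
        RegressorSpec("KNeighbors", KNeighborsRegressor),
    ]


def benchmark_regressors(
    X: np.ndarray,
    y: np.ndarray,
    specs: Sequence[RegressorSpec] | None = None,
    k: int = 5,
    seed: int = 0,
    pls_components: int = 3,
    scale_x: bool = True,
) -> pd.DataFrame:
    """Evaluate every spec plus PLS on identical fold splits.

    Returns a long-form table (cycle, regressor, test_r2, test_rmse, rank)
    ranked by held-out R^2 within each cycle; individual estimator failures
    are recorded with an ``error`` entry rather than aborting the harness.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if specs is None:
        specs = default_regressor_specs(seed)
    all_specs = list(specs) + [
        RegressorSpec("PLS", _pls_factory(pls_components, scale_x))
    ]
    folds = make_folds(len(y), k, seed)
    rows = []
    for cycle, (train, test) in enumerate(folds, start=1):
        for spec in all_specs:
            row = {"cycle": cycle, "regressor": spec.name}
            try:
                est = spec.build()
                est.fit(X[train], y[train])
                pred = np.ravel(est.predict(X[test]))
                row["test_r2"] = _r2(y[test], pred)
                row["test_rmse"] = _rmse(y[test], pred)
                row["error"] = ""
            except Exception as exc:
                logger.warning("regressor %s failed in cycle %d: %s", spec.name, cycle, exc)
                row.update({"test_r2": np.nan, "test_rmse": np.nan, "error": str(exc)})
            rows.append(row)
    table = pd.DataFrame(rows)
    table["rank"] = (
        table.groupby("cycle")["test_r2"].rank(ascending=False, method="min").astype("Int64")
    )
    return table.sort_values(["cycle", "rank"]).reset_index(drop=True)
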
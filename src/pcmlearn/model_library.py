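"""Model library construction under a fixed stratified cross-validation split.

The dataset is split once into six folds by stratified sampling of the pIC50
response; one designated fold is the held-out test set and is never touched by
preprocessing, hyperparameter search or fitting. Each library member is a
regression model (gradient-boosted trees, random forest, linear/radial SVR,
elastic net or ordinary linear) trained per-fold over the five training folds
so that every training datapoint carries exactly one out-of-fold prediction;
that aligned cross-validation prediction matrix is what the ensemble builders
consume. All members share the same fold assignment, which makes their
cross-validated errors directly comparable.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import ElasticNet, LinearRegression
from sklearn.svm import SVR

__all__ = [
    "FoldAssignment",
    "ModelSpec",
    "TrainedModel",
    "ModelLibrary",
    "make_folds",
    "grid_search_cv",
    "train_library",
    "predict",
    "default_library_specs",
]

#: algorithm family name -> (estimator factory, whether fits are seeded)
_FAMILIES = {
    "gbm": (GradientBoostingRegressor, True),
    "rf": (RandomForestRegressor, True),
    "svr_linear": (lambda **kw: SVR(kernel="linear", **kw), False),
    "svr_radial": (lambda **kw: SVR(kernel="rbf", **kw), False),
    "elastic_net": (ElasticNet, False),
    "linear": (LinearRegression, False),
}


@dataclass(frozen=True)
class FoldAssignment:
    """Per-datapoint fold labels in 1..k with one designated test fold."""

    labels: np.ndarray
    k: int
    test_fold: int
    seed: int

    @property
    def train_mask(self) -> np.ndarray:
        return self.labels != self.test_fold

    @property
    def test_mask(self) -> np.ndarray:
        return self.labels == self.test_fold

    @property
    def train_folds(self) -> list[int]:
        return [f for f in range(1, self.k + 1) if f != self.test_fold]

    def restrict(self, mask: np.ndarray) -> "FoldAssignment":
        """Fold assignment over a row subset (labels subset, same folds)."""
        return FoldAssignment(
            labels=self.labels[mask], k=self.k, test_fold=self.test_fold, seed=self.seed
        )


@dataclass(frozen=True)
class ModelSpec:
    """An algorithm family plus a hyperparameter assignment."""

    family: str
    params: tuple[tuple[str, object], ...] = ()
    name: str | None = None

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(
                f"unknown model family {self.family!r}; expected one of {sorted(_FAMILIES)}"
            )

    @classmethod
    def make(cls, family: str, name: str | None = None, **params) -> "ModelSpec":
        return cls(family=family, params=tuple(sorted(params.items())), name=name)

    @property
    def label(self) -> str:
        if self.name:
            return self.name
        kv = ",".join(f"{k}={v}" for k, v in self.params)
        return f"{self.family}({kv})"

    def build(self, random_state: int | None = None):
        factory, seeded = _FAMILIES[self.family]
        kwargs = dict(self.params)
        if seeded and random_state is not None:
            kwargs.setdefault("random_state", random_state)
        return factory(**kwargs)


@dataclass
class TrainedModel:
    """A library member: spec, refitted estimator, aligned OOF predictions."""

    spec: ModelSpec
    estimator: object
    cv_predictions: np.ndarray
    cv_rmse: float


@dataclass
class ModelLibrary:
    """Trained members sharing one fold assignment and one response vector."""

    models: list[TrainedModel]
    folds: FoldAssignment
    response: np.ndarray

    def __len__(self) -> int:
        return len(self.models)

    @property
    def labels(self) -> list[str]:
        return [m.spec.label for m in self.models]

    @property
    def cv_matrix(self) -> pd.DataFrame:
        """Out-of-fold prediction matrix (training rows x members)."""
        return pd.DataFrame(
            np.column_stack([m.cv_predictions for m in self.models]),
            columns=self.labels,
        )

    @property
    def cv_rmses(self) -> np.ndarray:
        return np.array([m.cv_rmse for m in self.models])

    def predict(self, X) -> pd.DataFrame:
        """Per-member predictions on new rows (rows x members)."""
        X = np.asarray(X, dtype=float)
        preds = np.column_stack([m.estimator.predict(X) for m in self.models]) if len(
            X
        ) else np.empty((0, len(self.models)))
        return pd.DataFrame(preds, columns=self.labels)

    def manifest(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "seed": self.folds.seed,
                "k": self.folds.k,
                "test_fold": self.folds.test_fold,
                "models": [
                    {"label": m.spec.label, "family": m.spec.family,
                     "params": dict(m.spec.params), "cv_rmse": m.cv_rmse}
                    for m in self.models
                ],
            },
            indent=2,
            default=str,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def _rmse(y, y_pred) -> float:
    y = np.asarray(y, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    return float(np.sqrt(np.mean((y - y_pred) ** 2)))


def make_folds(
    response: Sequence[float],
    k: int = 6,
    seed: int = 0,
    test_fold: int = 6,
    n_strata: int = 10,
) -> FoldAssignment:
    """Stratified k-fold assignment on the response distribution.

    Responses are binned into ``n_strata`` quantile strata; within each
    stratum points are shuffled (seeded) and dealt round-robin to folds, with
    the dealing pointer carried across strata so fold sizes differ by at most
    the number of strata.
    """
    response = np.asarray(response, dtype=float)
    n = len(response)
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} datapoints")
    if not 1 <= test_fold <= k:
        raise ValueError(f"test_fold {test_fold} outside 1..{k}")

    rng = np.random.default_rng(seed)
    n_bins = min(n_strata, n)
    edges = np.quantile(response, np.linspace(0, 1, n_bins + 1)[1:-1])
    strata = np.searchsorted(edges, response, side="right")

    labels = np.zeros(n, dtype=int)
    pointer = 0
    for stratum in np.unique(strata):
        members = np.flatnonzero(strata == stratum)
        rng.shuffle(members)
        for idx in members:
            labels[idx] = pointer % k + 1
            pointer += 1
    return FoldAssignment(labels=labels, k=k, test_fold=test_fold, seed=seed)


def _oof_predictions(
    estimator, X: np.ndarray, y: np.ndarray, fold_labels: np.ndarray, folds: list[int]
) -> np.ndarray:
    """Out-of-fold predictions over rows whose label is in ``folds``."""
    oof = np.full(len(y), np.nan)
    for held_out in folds:
        fit_mask = np.isin(fold_labels, [f for f in folds if f != held_out])
        out_mask = fold_labels == held_out
        model = clone(estimator)
        model.fit(X[fit_mask], y[fit_mask])
        oof[out_mask] = model.predict(X[out_mask])
    return oof


def grid_search_cv(
    spec_grid: Sequence[ModelSpec] | Mapping[str, Sequence],
    design,
    response,
    folds: FoldAssignment,
    random_state: int | None = None,
) -> tuple[ModelSpec, pd.DataFrame]:
    """Pick the hyperparameter combination with lowest mean held-out RMSE.

    Each combination is fitted five times over the training folds, each time
    holding out a different fold; the test fold never participates. Ties are
    broken by grid order. ``spec_grid`` is either a list of specs or a dict
    ``{"family": ..., "param": [values...]}`` expanded to its product.
    """
    if isinstance(spec_grid, Mapping):
        family = spec_grid["family"]
        names = [k for k in spec_grid if k != "family"]
        spec_grid = [
            ModelSpec.make(family, **dict(zip(names, combo)))
            for combo in itertools.product(*(spec_grid[k] for k in names))
        ]
    if not spec_grid:
        raise ValueError("empty specification grid")

    X = np.asarray(design, dtype=float)
    y = np.asarray(response, dtype=float)
    train_mask = folds.train_mask
    rows = []
    best_spec, best_rmse = None, np.inf
    for spec in spec_grid:
        fold_rmses = []
        for held_out in folds.train_folds:
            fit_mask = train_mask & ~np.isin(folds.labels, [held_out, folds.test_fold])
            out_mask = folds.labels == held_out
            model = spec.build(random_state)
            model.fit(X[fit_mask], y[fit_mask])
            fold_rmses.append(_rmse(y[out_mask], model.predict(X[out_mask])))
        mean_rmse = float(np.mean(fold_rmses))
        rows.append({"spec": spec.label, "mean_cv_rmse": mean_rmse})
        if mean_rmse < best_rmse:
            best_spec, best_rmse = spec, mean_rmse
    return best_spec, pd.DataFrame(rows)


def train_library(
    spec_list: Sequence[ModelSpec],
    design,
    response,
    folds: FoldAssignment,
    random_state: int | None = None,
) -> ModelLibrary:
    """Train every spec per-fold (for OOF predictions) and refit on all folds.

    The returned library's ``cv_matrix`` holds, for each member, the
    prediction of each training datapoint by the model trained without that
    datapoint's fold; ``estimator`` is the member refitted on all five
    training folds for test-time prediction.
    """
    if not spec_list:
        raise ValueError("empty model specification list")
    for spec in spec_list:
        if spec.family not in _FAMILIES:  # pragma: no cover - guarded by ModelSpec
            raise ValueError(f"unknown family {spec.family!r}")

    X = np.asarray(design, dtype=float)
    y = np.asarray(response, dtype=float)
    train_mask = folds.train_mask
    X_train, y_train = X[train_mask], y[train_mask]
    train_labels = folds.labels[train_mask]

    models = []
    for spec in spec_list:
        estimator = spec.build(random_state)
        oof = _oof_predictions(estimator, X_train, y_train, train_labels, folds.train_folds)
        refit = clone(estimator)
        refit.fit(X_train, y_train)
        models.append(
            TrainedModel(
                spec=spec,
                estimator=refit,
                cv_predictions=oof,
                cv_rmse=_rmse(y_train, oof),
            )
        )
    return ModelLibrary(models=models, folds=folds, response=y_train)


def predict(model_or_library, design_rows) -> np.ndarray | pd.DataFrame:
    """Predict pIC50 for preprocessed design rows (per member for a library)."""
    X = np.asarray(design_rows, dtype=float)
    if isinstance(model_or_library, ModelLibrary):
        return model_or_library.predict(X)
    if X.shape[0] == 0:
        return np.empty(0)
    return np.asarray(model_or_library.predict(X), dtype=float)


def default_library_specs(
    size: str = "test", random_state: int | None = None
) -> list[ModelSpec]:
    """A default hetero-library grid over GBM, RF and SVR members.

    ``size="test"`` yields a compact ~30-member library for scaled-down runs;
    ``size="full"`` expands the same family grids toward a few hundred
    members for full benchmarks.
    """
    if size == "test":
        gbm = {"n_estimators": [25, 50, 100], "max_depth": [2, 3], "learning_rate": [0.05, 0.1]}
        rf = {"n_estimators": [25, 50, 100], "max_features": [0.3, 0.6, 1.0]}
        svr = {"C": [0.1, 1.0, 10.0], "epsilon": [0.1]}
        rbf_gamma = ["scale"]
    elif size == "full":
        gbm = {"n_estimators": [50, 100, 250, 500], "max_depth": [2, 3, 5, 7],
               "learning_rate": [0.01, 0.05, 0.1, 0.2]}
        rf = {"n_estimators": [100, 250, 500, 1000],
              "max_features": [0.1, 0.2, 0.33, 0.5, 0.75, 1.0]}
        svr = {"C": [0.01, 0.1, 1.0, 10.0, 100.0], "epsilon": [0.01, 0.1, 0.5]}
        rbf_gamma = ["scale", 0.01, 0.1]
    else:
        raise ValueError(f"unknown library size {size!r}")

    specs: list[ModelSpec] = []
    for combo in itertools.product(*gbm.values()):
        specs.append(ModelSpec.make("gbm", **dict(zip(gbm, combo))))
    for combo in itertools.product(*rf.values()):
        specs.append(ModelSpec.make("rf", **dict(zip(rf, combo))))
    for combo in itertools.product(*svr.values()):
        specs.append(ModelSpec.make("svr_linear", **dict(zip(svr, combo))))
    for combo in itertools.product(*svr.values()):
        for gamma in rbf_gamma:
            specs.append(ModelSpec.make("svr_radial", gamma=gamma, **dict(zip(svr, combo))))
    return specs
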
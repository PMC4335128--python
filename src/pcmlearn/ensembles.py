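"""Combining a model library into weighted and stacked ensembles.

Two combination schemes operate on the library's aligned out-of-fold
cross-validation prediction matrix:

* *Greedy weight optimization* (after Caruana's ensemble selection): integer
  member weights start at zero and, for a fixed number of iterations, the
  single-weight increment whose normalized weighted average best matches the
  observed response (lowest RMSE) is applied. Selection is with replacement,
  an increment that would worsen the fit is not applied, and the final weight
  vector is normalized to sum to one.

* *Model stacking*: a meta-learner is fitted with the member predictions as
  features. Members trained with one algorithm family form a homo-ensemble;
  members spanning two or more families form a hetero-ensemble.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import ElasticNet, LinearRegression
from sklearn.svm import SVR
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "GreedyEnsembleRegressor",
    "StackingEnsembleRegressor",
    "greedy_optimize",
    "greedy_predict",
    "stack_fit",
    "stack_predict",
    "META_FAMILIES",
]


def _rmse(y, y_pred) -> float:
    y = np.asarray(y, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    return float(np.sqrt(np.mean((y - y_pred) ** 2)))


class GreedyEnsembleRegressor(BaseEstimator, RegressorMixin):
    """Greedy integer-weight ensemble over precomputed member predictions.

    ``fit(P, y)`` takes the member prediction matrix ``P`` (rows = datapoints,
    columns = library members, typically out-of-fold cross-validation
    predictions) and optimizes the member weights; ``predict(P)`` returns the
    weighted average of member predictions for new rows.

    Attributes
    ----------
    weights_ : ndarray, normalized member weights (sum to one)
    raw_weights_ : ndarray, integer increment counts before normalization
    rmse_trace_ : ndarray, ensemble RMSE after each iteration (non-increasing)
    """

    def __init__(self, n_iter: int = 1000):
        self.n_iter = n_iter

    def fit(self, P, y) -> "GreedyEnsembleRegressor":
        P = np.asarray(P, dtype=float)
        y = np.asarray(y, dtype=float)
        if P.ndim != 2 or P.shape[1] == 0:
            raise ValueError("member prediction matrix must have at least one column")
        if P.shape[0] != len(y):
            raise ValueError(f"{P.shape[0]} rows vs {len(y)} responses")

        n_members = P.shape[1]
        weights = np.zeros(n_members, dtype=int)
        weighted_sum = np.zeros(P.shape[0])
        total = 0
        best_rmse = np.inf
        best_weights = None
        trace = []
        for _ in range(self.n_iter):
            # RMSE of every candidate single-weight increment, vectorized
            cand = (weighted_sum[:, None] + P) / (total + 1)
            cand_rmse = np.sqrt(np.mean((y[:, None] - cand) ** 2, axis=0))
            j = int(np.argmin(cand_rmse))  # ties -> lowest column index
            weights[j] += 1
            weighted_sum += P[:, j]
            total += 1
            # the kept ensemble is the best normalized vector seen so far, so
            # a forced step through a worse mixture cannot degrade the result
            if cand_rmse[j] < best_rmse:
                best_rmse = float(cand_rmse[j])
                best_weights = weights.copy()
            trace.append(best_rmse)

        self.n_members_ = n_members
        self.raw_weights_ = best_weights
        self.weights_ = best_weights / best_weights.sum()
        self.rmse_trace_ = np.asarray(trace)
        self.cv_rmse_ = best_rmse
        return self

    def predict(self, P) -> np.ndarray:
        check_is_fitted(self, "weights_")
        P = np.asarray(P, dtype=float)
        if P.ndim == 1:
            P = P[None, :]
        if P.shape[1] != self.n_members_:
            raise ValueError(f"expected {self.n_members_} member predictions, got {P.shape[1]}")
        return P @ self.weights_

    def manifest(self, path: str | Path | None = None, member_labels=None) -> str:
        check_is_fitted(self, "weights_")
        payload = json.dumps(
            {
                "type": "greedy",
                "n_iter": self.n_iter,
                "members": list(member_labels) if member_labels is not None else None,
                "weights": self.weights_.tolist(),
                "cv_rmse": self.cv_rmse_,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


#: meta-learner family -> (factory, hyperparameter grid for internal tuning)
META_FAMILIES = {
    "linear": (LinearRegression, [{}]),
    "elastic_net": (
        ElasticNet,
        [
            {"alpha": a, "l1_ratio": r, "max_iter": 50000}
            for a in (0.001, 0.01, 0.1, 1.0)
            for r in (0.1, 0.5, 0.9)
        ],
    ),
    "svr_linear": (
        lambda **kw: SVR(kernel="linear", **kw),
        [{"C": c} for c in (0.1, 1.0, 10.0)],
    ),
    "svr_radial": (
        lambda **kw: SVR(kernel="rbf", **kw),
        [{"C": c} for c in (0.1, 1.0, 10.0)],
    ),
    "random_forest": (
        RandomForestRegressor,
        [{"n_estimators": 100, "max_features": f} for f in (0.33, 1.0)],
    ),
}


class StackingEnsembleRegressor(BaseEstimator, RegressorMixin):
    """Meta-learner over member predictions (model stacking).

    ``fit(P, y)`` trains the meta-learner on the member prediction matrix
    (one feature per library member, order fixed). If ``fold_labels`` are
    supplied, meta hyperparameters are tuned by cross-validation over those
    same folds (reusing the library's split avoids optimistically leaking the
    fold structure); otherwise the first grid entry is used.

    For coefficient-exposing meta families (linear, elastic net) the fitted
    member-weight vector is available as ``weights_``.
    """

    def __init__(
        self,
        meta_family: str = "linear",
        fold_labels: Sequence[int] | None = None,
        random_state: int | None = None,
    ):
        self.meta_family = meta_family
        self.fold_labels = fold_labels
        self.random_state = random_state

    def _build(self, params: dict):
        factory, _ = META_FAMILIES[self.meta_family]
        model = factory(**params)
        if "random_state" in model.get_params():
            model.set_params(random_state=self.random_state)
        return model

    def fit(self, P, y) -> "StackingEnsembleRegressor":
        if self.meta_family not in META_FAMILIES:
            raise ValueError(
                f"unknown meta family {self.meta_family!r}; expected one of {sorted(META_FAMILIES)}"
            )
        P = np.asarray(P, dtype=float)
        y = np.asarray(y, dtype=float)
        if P.shape[0] != len(y):
            raise ValueError(f"{P.shape[0]} rows vs {len(y)} responses")
        _, grid = META_FAMILIES[self.meta_family]

        best_params = grid[0]
        if self.fold_labels is not None and len(grid) > 1:
            labels = np.asarray(self.fold_labels)
            folds = np.unique(labels)
            best_rmse = np.inf
            for params in grid:
                oof = np.full(len(y), np.nan)
                for held in folds:
                    fit_mask = labels != held
                    model = self._build(params)
                    model.fit(P[fit_mask], y[fit_mask])
                    oof[~fit_mask] = model.predict(P[~fit_mask])
                rmse = _rmse(y, oof)
                if rmse < best_rmse:
                    best_params, best_rmse = params, rmse

        self.meta_params_ = best_params
        self.meta_model_ = self._build(best_params)
        self.meta_model_.fit(P, y)
        self.n_members_ = P.shape[1]
        if hasattr(self.meta_model_, "coef_"):
            self.weights_ = np.asarray(self.meta_model_.coef_, dtype=float).ravel()
        return self

    def predict(self, P) -> np.ndarray:
        check_is_fitted(self, "meta_model_")
        P = np.asarray(P, dtype=float)
        if P.ndim == 1:
            P = P[None, :]
        if P.shape[0] == 0:
            return np.empty(0)
        if P.shape[1] != self.n_members_:
            raise ValueError(f"expected {self.n_members_} member predictions, got {P.shape[1]}")
        return np.asarray(self.meta_model_.predict(P), dtype=float)


def greedy_optimize(cv_matrix, response, n: int = 1000) -> GreedyEnsembleRegressor:
    """Fit a greedy weighted ensemble on the library's OOF prediction matrix."""
    return GreedyEnsembleRegressor(n_iter=n).fit(cv_matrix, response)


def greedy_predict(ensemble: GreedyEnsembleRegressor, member_predictions) -> np.ndarray:
    """Weighted sum of member predictions under the optimized weights."""
    return ensemble.predict(member_predictions)


def stack_fit(
    cv_matrix,
    response,
    meta_family: str = "linear",
    fold_labels: Sequence[int] | None = None,
    random_state: int | None = None,
) -> StackingEnsembleRegressor:
    """Fit a stacking meta-learner on the library's OOF prediction matrix."""
    return StackingEnsembleRegressor(
        meta_family=meta_family, fold_labels=fold_labels, random_state=random_state
    ).fit(cv_matrix, response)


def stack_predict(ensemble: StackingEnsembleRegressor, member_predictions) -> np.ndarray:
    """Meta-learner output on the member-prediction feature vector(s)."""
    return ensemble.predict(member_predictions)
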
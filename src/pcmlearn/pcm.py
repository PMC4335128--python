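"""End-to-end proteochemometric regressors over raw design matrices.

:class:`PCMRegressor` bundles the frozen design preprocessing
(near-zero-variance filter then center/scale, both fitted on training rows
only) with any scikit-learn regressor, so callers — in particular the
substructure-attribution routines, which zero raw counts — can predict
directly from raw descriptor rows. :class:`PCMEnsemble` does the same for a
trained model library combined by a greedy or stacking ensemble, and exposes
the member spread used by the applicability-domain module.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.linear_model import LinearRegression
from sklearn.utils.validation import check_is_fitted

from .applicability import ensemble_std
from .descriptors import CenterScaler, NearZeroVarianceFilter
from .model_library import FoldAssignment, ModelSpec, train_library

__all__ = ["PCMRegressor", "PCMEnsemble", "SparseLinearRegressor"]


class SparseLinearRegressor(BaseEstimator, RegressorMixin):
    """L1 support selection followed by an unpenalized refit (relaxed lasso).

    Keyed circular-fingerprint designs contain exact linear identities (every
    environment's count equals the sum of its higher-radius refinements), so
    an L2 fit spreads a substructure's effect over its relatives and
    count-zeroing attribution then sees only a fraction of it. The L1 stage
    picks the cheapest — sparsest — representation of the signal, which
    concentrates each effect on the substructure actually carrying it; the
    ordinary-least-squares refit on the selected support removes the lasso's
    shrinkage bias.
    """

    def __init__(self, alpha: float = 0.02, max_iter: int = 20000):
        self.alpha = alpha
        self.max_iter = max_iter

    def fit(self, X, y) -> "SparseLinearRegressor":
        from sklearn.linear_model import Lasso

        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        selector = Lasso(alpha=self.alpha, max_iter=self.max_iter)
        selector.fit(X, y)
        support = np.flatnonzero(selector.coef_ != 0)
        coef = np.zeros(X.shape[1])
        if len(support):
            refit = LinearRegression().fit(X[:, support], y)
            coef[support] = refit.coef_
            self.intercept_ = float(refit.intercept_)
        else:
            self.intercept_ = float(y.mean())
        self.coef_ = coef
        self.support_ = support
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_


class PCMRegressor(BaseEstimator, RegressorMixin):
    """Near-zero-variance filter + center/scale + regressor, as one estimator.

    Parameters
    ----------
    estimator : scikit-learn regressor fitted on the preprocessed design
        (default ordinary linear regression).
    nzv_cutoff : frequency-ratio cut-off of the near-zero-variance filter;
        ``None`` disables the filter (useful for tiny toy designs).
    scale : whether to center/scale the kept columns.
    """

    def __init__(self, estimator=None, nzv_cutoff: float | None = 30.0, scale: bool = True):
        self.estimator = estimator
        self.nzv_cutoff = nzv_cutoff
        self.scale = scale

    def _preprocess(self, X: pd.DataFrame) -> pd.DataFrame:
        if self.filter_ is not None:
            X = self.filter_.transform(X)
        if self.scaler_ is not None:
            X = self.scaler_.transform(X)
        return X

    def fit(self, X: pd.DataFrame, y) -> "PCMRegressor":
        X = pd.DataFrame(X)
        self.filter_ = (
            NearZeroVarianceFilter(ratio_cutoff=self.nzv_cutoff).fit(X)
            if self.nzv_cutoff is not None
            else None
        )
        X_kept = self.filter_.transform(X) if self.filter_ is not None else X
        self.scaler_ = CenterScaler().fit(X_kept) if self.scale else None
        X_proc = self.scaler_.transform(X_kept) if self.scaler_ is not None else X_kept
        self.model_ = clone(self.estimator) if self.estimator is not None else LinearRegression()
        self.model_.fit(X_proc.to_numpy(), np.asarray(y, dtype=float))
        self.feature_names_in_ = np.asarray(X.columns)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = pd.DataFrame(X)
        return np.asarray(self.model_.predict(self._preprocess(X).to_numpy()), dtype=float)


class PCMEnsemble(BaseEstimator, RegressorMixin):
    """A trained library plus an ensemble combiner, applied to raw rows.

    ``fit`` preprocesses the raw design (training rows only set the
    statistics), trains the member library over the shared fold assignment,
    and fits the combiner on the members' out-of-fold prediction matrix.
    ``predict`` returns combined predictions; ``predict_with_std`` adds the
    unweighted member spread E_std per row for applicability-domain use.
    """

    def __init__(
        self,
        specs: list[ModelSpec],
        combiner,
        nzv_cutoff: float | None = 30.0,
        random_state: int | None = None,
    ):
        self.specs = specs
        self.combiner = combiner
        self.nzv_cutoff = nzv_cutoff
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y, folds: FoldAssignment) -> "PCMEnsemble":
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float)
        train_rows = folds.train_mask
        self.filter_ = (
            NearZeroVarianceFilter(ratio_cutoff=self.nzv_cutoff).fit(X.loc[train_rows])
            if self.nzv_cutoff is not None
            else None
        )
        X_kept = self.filter_.transform(X) if self.filter_ is not None else X
        self.scaler_ = CenterScaler().fit(X_kept.loc[train_rows])
        X_proc = self.scaler_.transform(X_kept)

        self.library_ = train_library(
            self.specs, X_proc.to_numpy(), y, folds, random_state=self.random_state
        )
        self.combiner_ = clone(self.combiner)
        self.combiner_.fit(self.library_.cv_matrix.to_numpy(), self.library_.response)
        self.folds_ = folds
        return self

    def _member_predictions(self, X: pd.DataFrame) -> np.ndarray:
        X = pd.DataFrame(X)
        if self.filter_ is not None:
            X = self.filter_.transform(X)
        X = self.scaler_.transform(X)
        return self.library_.predict(X.to_numpy()).to_numpy()

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "combiner_")
        return np.asarray(self.combiner_.predict(self._member_predictions(X)), dtype=float)

    def predict_with_std(self, X: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        check_is_fitted(self, "combiner_")
        member = self._member_predictions(X)
        return (
            np.asarray(self.combiner_.predict(member), dtype=float),
            ensemble_std(member),
        )
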
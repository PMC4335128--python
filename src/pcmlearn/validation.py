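"""Statistical validation of bioactivity regression models.

Implements the metric set and validation procedures used to judge a
proteochemometric model: RMSE, the cross-validated/external coefficient of
determination q², the through-origin determination coefficient R²₀ (observed
regressed on predicted with intercept fixed at zero, slope
s = Σyỹ / Σỹ²), Lin's concordance correlation coefficient, threshold-based
soundness checks (q²_int > 0.5; q²_test and R²₀_test > 0.6), bootstrap
standard deviations of any metric, response scrambling (y-randomization), and
a noise-injection simulation that bounds the best achievable test metrics
given the experimental uncertainty of public IC50 data (default SD 0.68 pIC50
units).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone

__all__ = [
    "MetricsReport",
    "NoiseSimulationResult",
    "ScramblingCurve",
    "TropshaResult",
    "rmse",
    "q2",
    "r2_zero",
    "ccc",
    "metrics_report",
    "tropsha_check",
    "bootstrap_sd",
    "simulate_max_performance",
    "y_scrambling_curve",
    "selectivity_metrics",
]


def _check_pair(y, y_pred) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {y_pred.shape}")
    if y.size == 0:
        raise ValueError("empty input")
    return y, y_pred


def rmse(y, y_pred) -> float:
    """Root mean squared error sqrt(mean((y - ỹ)²))."""
    y, y_pred = _check_pair(y, y_pred)
    return float(np.sqrt(np.mean((y - y_pred) ** 2)))


def q2(y, y_pred) -> float:
    """1 - SSres/SStot with the mean taken over the evaluated set itself."""
    y, y_pred = _check_pair(y, y_pred)
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("q2 undefined for a constant observed vector")
    return float(1.0 - np.sum((y - y_pred) ** 2) / ss_tot)


def r2_zero(y, y_pred) -> tuple[float, float]:
    """Through-origin determination coefficient and its slope.

    The regression of observed on predicted is forced through the origin:
    s = Σ(y·ỹ)/Σ(ỹ²) and R²₀ = 1 - Σ(y - s·ỹ)²/Σ(y - ȳ)². Asymmetric in its
    arguments (y is truth) and may be negative.
    """
    y, y_pred = _check_pair(y, y_pred)
    denom = np.sum(y_pred**2)
    if denom == 0:
        raise ValueError("R²₀ undefined for all-zero predictions")
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("R²₀ undefined for a constant observed vector")
    s = float(np.sum(y * y_pred) / denom)
    r2_0 = float(1.0 - np.sum((y - s * y_pred) ** 2) / ss_tot)
    return r2_0, s


def ccc(y, y_pred) -> float:
    """Lin's concordance correlation coefficient (population moments).

    2·cov(y,ỹ) / (var(y) + var(ỹ) + (mean(y) - mean(ỹ))²): penalizes both
    dispersion around the identity line and location shift, so a perfectly
    correlated but offset prediction scores near zero.
    """
    y, y_pred = _check_pair(y, y_pred)
    var_y = np.var(y)
    var_p = np.var(y_pred)
    if var_y == 0 or var_p == 0:
        raise ValueError("CCC undefined when either vector is constant")
    cov = np.mean((y - y.mean()) * (y_pred - y_pred.mean()))
    return float(2 * cov / (var_y + var_p + (y.mean() - y_pred.mean()) ** 2))


@dataclass(frozen=True)
class MetricsReport:
    """RMSE / q² / R²₀ / CCC of one prediction set."""

    rmse: float
    q2: float
    r2_zero: float
    ccc: float
    slope: float
    n: int
    context: str = "test"


def metrics_report(y, y_pred, context: str = "test") -> MetricsReport:
    """All validation metrics for one (observed, predicted) pair."""
    r2_0, s = r2_zero(y, y_pred)
    return MetricsReport(
        rmse=rmse(y, y_pred),
        q2=q2(y, y_pred),
        r2_zero=r2_0,
        ccc=ccc(y, y_pred),
        slope=s,
        n=len(np.asarray(y)),
        context=context,
    )


@dataclass(frozen=True)
class TropshaResult:
    passed: bool
    reasons: tuple[str, ...]


def tropsha_check(
    internal: MetricsReport,
    test: MetricsReport,
    q2_int_min: float = 0.5,
    q2_test_min: float = 0.6,
    r2_zero_test_min: float = 0.6,
) -> TropshaResult:
    """Threshold soundness rules: q²_int > 0.5; q²_test and R²₀_test > 0.6.

    Thresholds are strict inequalities and configurable (they are guidelines,
    to be tailored per dataset).
    """
    reasons = []
    if not internal.q2 > q2_int_min:
        reasons.append(f"q2_int {internal.q2:.3f} <= {q2_int_min}")
    if not test.q2 > q2_test_min:
        reasons.append(f"q2_test {test.q2:.3f} <= {q2_test_min}")
    if not test.r2_zero > r2_zero_test_min:
        reasons.append(f"r2_zero_test {test.r2_zero:.3f} <= {r2_zero_test_min}")
    return TropshaResult(passed=not reasons, reasons=tuple(reasons))


def bootstrap_sd(
    metric_fn: Callable,
    y,
    y_pred,
    reps: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean and SD of a metric over paired bootstrap resamples."""
    if reps < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    y, y_pred = _check_pair(y, y_pred)
    rng = np.random.default_rng(seed)
    values = np.empty(reps)
    for i in range(reps):
        idx = rng.integers(0, len(y), size=len(y))
        out = metric_fn(y[idx], y_pred[idx])
        values[i] = out[0] if isinstance(out, tuple) else out
    return float(values.mean()), float(values.std(ddof=1))


@dataclass(frozen=True)
class NoiseSimulationResult:
    """Distributions of best-achievable metrics under bioactivity noise."""

    sigma: float
    sample_size: int
    reps: int
    rmse_values: np.ndarray
    q2_values: np.ndarray
    r2_zero_values: np.ndarray

    @property
    def mean_min_rmse(self) -> float:
        return float(self.rmse_values.mean())

    @property
    def mean_max_q2(self) -> float:
        return float(self.q2_values.mean())

    @property
    def mean_max_r2_zero(self) -> float:
        return float(self.r2_zero_values.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rmse": self.rmse_values, "q2": self.q2_values, "r2_zero": self.r2_zero_values}
        )


def simulate_max_performance(
    y_pool,
    sigma: float = 0.68,
    sample_size: int | None = None,
    reps: int = 1000,
    seed: int = 0,
    replace: bool = False,
) -> NoiseSimulationResult:
    """Best achievable test metrics given noisy measurements.

    Per replicate, a sample A of ``sample_size`` values (defaulting to a
    sixth of the pool, the test-set share of a 6-fold split) is drawn from
    the pIC50 pool without replacement, Gaussian noise of SD ``sigma`` is
    added to give A_noisy, and the metrics of A (truth) against A_noisy
    (prediction) are recorded. A model whose test metrics beat these
    distributions is suspect: it is fitting the noise floor of the data.
    """
    if sigma < 0:
        raise ValueError(f"noise SD must be non-negative, got {sigma}")
    y_pool = np.asarray(y_pool, dtype=float)
    if sample_size is None:
        sample_size = int(np.ceil(len(y_pool) / 6))
    if sample_size > len(y_pool) and not replace:
        raise ValueError(
            f"sample_size {sample_size} exceeds pool size {len(y_pool)}; "
            "pass replace=True to sample with replacement"
        )
    rng = np.random.default_rng(seed)
    rmses = np.empty(reps)
    q2s = np.empty(reps)
    r2_0s = np.empty(reps)
    for i in range(reps):
        a = rng.choice(y_pool, size=sample_size, replace=replace)
        a_noisy = a + rng.normal(0.0, sigma, size=sample_size)
        rmses[i] = rmse(a, a_noisy)
        q2s[i] = q2(a, a_noisy)
        r2_0s[i] = r2_zero(a, a_noisy)[0]
    return NoiseSimulationResult(
        sigma=sigma,
        sample_size=sample_size,
        reps=reps,
        rmse_values=rmses,
        q2_values=q2s,
        r2_zero_values=r2_0s,
    )


@dataclass
class ScramblingCurve:
    """Test metrics after retraining with partly permuted training responses."""

    fractions: list[float]
    reports: list[MetricsReport]
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"fraction": f, "rmse": r.rmse, "q2": r.q2, "r2_zero": r.r2_zero, "ccc": r.ccc}
                for f, r in zip(self.fractions, self.reports)
            ]
        )


def y_scrambling_curve(
    estimator,
    X_train,
    y_train,
    X_test,
    y_test,
    fractions: Sequence[float] = (0.0, 0.25, 0.5, 0.75, 1.0),
    seed: int = 0,
) -> ScramblingCurve:
    """Retrain with an increasing share of training responses permuted.

    For each fraction f, a seeded random f-share of the training responses is
    permuted among themselves (preserving the marginal distribution), the
    estimator is refitted, and its test metrics recorded. Test responses are
    never scrambled. Fraction 0 reproduces the unscrambled model; with real
    signal present, metrics collapse as f grows.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    rng = np.random.default_rng(seed)
    reports = []
    for f in fractions:
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"fraction {f} outside [0, 1]")
        y_scrambled = y_train.copy()
        n_scramble = int(round(f * len(y_train)))
        if n_scramble >= 2:
            idx = rng.choice(len(y_train), size=n_scramble, replace=False)
            y_scrambled[idx] = y_scrambled[rng.permutation(idx)]
        model = clone(estimator)
        model.fit(X_train, y_scrambled)
        reports.append(metrics_report(y_test, model.predict(np.asarray(X_test, dtype=float))))
    return ScramblingCurve(fractions=list(fractions), reports=reports, seed=seed)


def selectivity_metrics(table, target_a: str, target_b: str) -> tuple[float, float, int]:
    """RMSE and R²₀ between two targets' pIC50 over dual-annotated compounds.

    Quantifies how (un)correlated the bioactivity profiles on two targets
    are: a large RMSE and a low (even negative) R²₀ indicate the dataset
    contains strongly selective compounds. Returns (rmse, r2_zero, n_shared).
    """
    a_vals, b_vals = [], []
    by_target: dict[str, dict[str, float]] = {target_a: {}, target_b: {}}
    for (cid, tid), v in table.entries.items():
        if tid in by_target:
            by_target[tid][cid] = v
    shared = sorted(set(by_target[target_a]) & set(by_target[target_b]))
    if not shared:
        raise ValueError(f"no compounds annotated on both {target_a!r} and {target_b!r}")
    a_vals = np.array([by_target[target_a][c] for c in shared])
    b_vals = np.array([by_target[target_b][c] for c in shared])
    return rmse(a_vals, b_vals), r2_zero(a_vals, b_vals)[0], len(shared)
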
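"""Per-prediction confidence intervals from ensemble spread.

The disagreement among the member models of an ensemble about a single
datapoint — the sample standard deviation of their predictions, E_std — is an
applicability-domain signal: points the library agrees on tend to be predicted
more reliably. Scaling E_std by a factor β > 0 gives a symmetric interval
ỹ ± β·E_std per prediction; the coverage curve (fraction of observed values
falling inside their intervals as β grows) calibrates β against a desired
confidence level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PredictionWithCI",
    "CoverageCurve",
    "ensemble_std",
    "confidence_interval",
    "coverage_curve",
    "beta_for_confidence",
    "DEFAULT_BETA_GRID",
]

#: β grid spanning the open interval (0, 4] in steps of 0.1.
DEFAULT_BETA_GRID = np.round(np.arange(0.1, 4.01, 0.1), 10)


@dataclass(frozen=True)
class PredictionWithCI:
    """A point prediction with its spread-scaled symmetric interval."""

    y_pred: float
    e_std: float
    beta: float

    @property
    def lower(self) -> float:
        return self.y_pred - self.beta * self.e_std

    @property
    def upper(self) -> float:
        return self.y_pred + self.beta * self.e_std

    @property
    def width(self) -> float:
        return 2.0 * self.beta * self.e_std

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


def ensemble_std(member_predictions) -> np.ndarray | float:
    """Unweighted sample SD (n-1) of member predictions per datapoint.

    Accepts a 1-D vector (one datapoint) or a rows-x-members matrix. All
    members are included unweighted, regardless of their ensemble weight.
    """
    P = np.asarray(member_predictions, dtype=float)
    single = P.ndim == 1
    if single:
        P = P[None, :]
    if P.shape[1] < 2:
        raise ValueError("ensemble spread needs at least 2 member predictions")
    stds = P.std(axis=1, ddof=1)
    return float(stds[0]) if single else stds


def confidence_interval(y_pred: float, e_std: float, beta: float) -> PredictionWithCI:
    """Interval ỹ ± β·E_std; zero-width when the members fully agree."""
    if not beta > 0:
        raise ValueError(f"beta must be positive, got {beta}")
    if e_std < 0:
        raise ValueError(f"ensemble SD must be non-negative, got {e_std}")
    return PredictionWithCI(y_pred=float(y_pred), e_std=float(e_std), beta=float(beta))


@dataclass
class CoverageCurve:
    """Fraction of observations inside their interval, per β."""

    betas: np.ndarray
    coverage: np.ndarray
    context: str = "test"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"beta": self.betas, "coverage": self.coverage, "context": self.context}
        )


def coverage_curve(
    y, y_pred, e_std, beta_grid=None, context: str = "test"
) -> CoverageCurve:
    """Coverage |y - ỹ| <= β·E_std for each β on the grid (closed boundary)."""
    y = np.asarray(y, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    e_std = np.asarray(e_std, dtype=float)
    if not (y.shape == y_pred.shape == e_std.shape):
        raise ValueError("y, y_pred and e_std must be aligned")
    betas = np.asarray(DEFAULT_BETA_GRID if beta_grid is None else beta_grid, dtype=float)
    residuals = np.abs(y - y_pred)
    coverage = np.array([(residuals <= b * e_std).mean() for b in betas])
    return CoverageCurve(betas=betas, coverage=coverage, context=context)


def beta_for_confidence(curve: CoverageCurve, level: float) -> float:
    """Smallest grid β whose coverage reaches the requested confidence level."""
    if not 0 <= level <= 1:
        raise ValueError(f"confidence level {level} outside (0, 1]")
    reached = np.flatnonzero(curve.coverage >= level)
    if len(reached) == 0:
        raise ValueError(
            f"confidence level {level} unattainable on the grid "
            f"(maximum coverage {curve.coverage.max():.3f})"
        )
    return float(curve.betas[reached[0]])
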
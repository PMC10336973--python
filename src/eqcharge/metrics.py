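"""Prediction-error metrics and normal fits of error distributions."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ContractError

__all__ = ["MetricsReport", "error_metrics", "fit_error_distribution"]


@dataclass
class MetricsReport:
    """MAE, RMSE and Pearson correlation of predictions against a
    reference, in the property's units.

    ``pearson_defined`` is False when either input has zero variance (or
    fewer than two points), in which case ``pearson_r``/``r_squared``
    are NaN while MAE/RMSE remain valid.
    """

    mae: float
    rmse: float
    pearson_r: float
    r_squared: float
    n: int
    pearson_defined: bool = True

    def summary(self, label: str = "", units: str = "e") -> str:
        r = f"{self.pearson_r:.6f}" if self.pearson_defined else "undefined"
        head = f"{label}: " if label else ""
        return (
            f"{head}MAE = {self.mae:.6e} {units}, RMSE = {self.rmse:.6e} {units}, "
            f"r = {r} (n = {self.n})"
        )

    def as_row(self) -> dict[str, float | int]:
        return {
            "mae": self.mae,
            "rmse": self.rmse,
            "pearson_r": self.pearson_r,
            "r_squared": self.r_squared,
            "n": self.n,
        }


def error_metrics(pred: Sequence[float], ref: Sequence[float]) -> MetricsReport:
    """Mean absolute error, root-mean-square error and Pearson r of
    ``pred`` against ``ref``."""
    p = np.asarray(pred, dtype=float)
    r = np.asarray(ref, dtype=float)
    if p.shape != r.shape or p.ndim != 1:
        raise ContractError(f"shape mismatch: pred {p.shape} vs ref {r.shape}")
    if p.size == 0:
        raise ContractError("need at least one value")
    diff = p - r
    mae = float(np.mean(np.abs(diff)))
    rmse = float(np.sqrt(np.mean(diff * diff)))
    if p.size < 2 or np.ptp(p) == 0 or np.ptp(r) == 0:
        return MetricsReport(mae, rmse, math.nan, math.nan, p.size, False)
    pr = float(np.corrcoef(p, r)[0, 1])
    return MetricsReport(mae, rmse, pr, pr * pr, p.size, True)


def fit_error_distribution(
    errors: Sequence[float], ddof: int = 0
) -> tuple[float, float]:
    """Normal fit (μ, σ) of an error sample.

    Defaults to the maximum-likelihood 1/n standard deviation; pass
    ``ddof=1`` for the unbiased sample convention.
    """
    e = np.asarray(errors, dtype=float)
    if e.size < 2:
        raise ContractError("need at least two errors to fit a distribution")
    if ddof not in (0, 1):
        raise ContractError(f"ddof must be 0 or 1, got {ddof}")
    return float(np.mean(e)), float(np.std(e, ddof=ddof))
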
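"""Regression metrics and the per-run report container."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ..errors import DataError

__all__ = ["r2_score", "rmse", "MetricReport"]


def _check_pair(y, yhat, min_len):
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise DataError(f"length mismatch: {y.shape[0]} vs {yhat.shape[0]}")
    if y.shape[0] < min_len:
        raise DataError(f"need at least {min_len} samples")
    return y, yhat


def r2_score(y, yhat) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot."""
    y, yhat = _check_pair(y, yhat, 2)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise DataError("R^2 undefined for a constant reference vector")
    return 1.0 - float(np.sum((yhat - y) ** 2)) / ss_tot


def rmse(y, yhat) -> float:
    """Root-mean-square error."""
    y, yhat = _check_pair(y, yhat, 1)
    return float(np.sqrt(np.mean((yhat - y) ** 2)))


@dataclass
class MetricReport:
    """Metrics of one evaluation cell, possibly averaged over runs.

    ``rmse_scale`` labels whether the RMSE values are on the
    standardized-target scale (the default reporting convention here) or
    raw target units.
    """

    r2_runs: list[float] = field(default_factory=list)
    rmse_runs: list[float] = field(default_factory=list)
    n_test: int = 0
    rmse_scale: str = "standardized"

    def add_run(self, y, yhat, y_scale: Optional[float] = None) -> None:
        self.n_test = len(np.asarray(y).ravel())
        self.r2_runs.append(r2_score(y, yhat))
        e = rmse(y, yhat)
        if self.rmse_scale == "standardized":
            scale = y_scale if y_scale else float(np.std(np.asarray(y, dtype=float)))
            e = e / (scale or 1.0)
        self.rmse_runs.append(e)

    @property
    def n_runs(self) -> int:
        return len(self.r2_runs)

    @property
    def r2(self) -> float:
        return float(np.mean(self.r2_runs))

    @property
    def rmse(self) -> float:
        return float(np.mean(self.rmse_runs))

    def to_dict(self) -> dict:
        return {
            "r2": self.r2,
            "rmse": self.rmse,
            "rmse_scale": self.rmse_scale,
            "n_test": self.n_test,
            "n_runs": self.n_runs,
            "r2_runs": list(self.r2_runs),
            "rmse_runs": list(self.rmse_runs),
        }
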
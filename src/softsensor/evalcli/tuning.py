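"""Exhaustive k-fold cross-validated hyperparameter search."""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from ..dataset import ProcessDataset
from ..errors import DataError, SoftSensorError
from ..models import ModelConfig, fit_model
from .metrics import r2_score, rmse

__all__ = ["GridSpec", "cv_grid_search", "DEFAULT_GRID"]

log = logging.getLogger(__name__)

#: Small default search grid used by the experiment presets.
DEFAULT_GRID: Mapping[str, Sequence] = {
    "nodes_per_group": [20],
    "sigma_scale": [0.25, 0.5, 1.0],
    "gamma": [1e-8, 1e-6],
}


@dataclass(frozen=True)
class GridSpec:
    """Candidate lists per hyperparameter plus the CV protocol."""

    candidates: Mapping[str, Sequence] = field(
        default_factory=lambda: dict(DEFAULT_GRID)
    )
    n_folds: int = 5
    scoring: str = "r2"
    seed: int = 0

    def validate(self) -> None:
        if not self.candidates or any(len(v) == 0 for v in self.candidates.values()):
            raise DataError("grid candidate lists must be non-empty")
        if self.n_folds < 2:
            raise DataError("fold count must be >= 2")
        if self.scoring not in ("r2", "rmse"):
            raise DataError("scoring must be 'r2' or 'rmse'")


def cv_grid_search(
    data: ProcessDataset,
    mode: str = "akbls",
    grid: Optional[GridSpec] = None,
    base: Optional[ModelConfig] = None,
) -> tuple[ModelConfig, pd.DataFrame]:
    """Exhaustive grid search with shuffled seeded k-fold CV.

    Returns the winning config (ties broken by smaller ``m_fourier``,
    then smaller ``nodes_per_group``, then grid order) and the full CV
    table; failed cells are marked and excluded from selection.
    """
    grid = grid or GridSpec()
    grid.validate()
    if len(data) < grid.n_folds:
        raise DataError("fewer samples than folds")
    base = replace(base or ModelConfig(), mode=mode)

    keys = list(grid.candidates)
    cells = list(itertools.product(*(grid.candidates[k] for k in keys)))
    kf = KFold(n_splits=grid.n_folds, shuffle=True, random_state=grid.seed)
    splits = list(kf.split(np.arange(len(data))))

    records = []
    for order, values in enumerate(cells):
        cfg = replace(base, **dict(zip(keys, values)))
        scores = []
        failed = False
        try:
            cfg.validate()
            for train_idx, val_idx in splits:
                model = fit_model(data.take(train_idx), cfg)
                yhat = model.predict(data.X[val_idx])
                scores.append(
                    r2_score(data.y[val_idx], yhat)
                    if grid.scoring == "r2"
                    else -rmse(data.y[val_idx], yhat)
                )
        except SoftSensorError as exc:
            failed = True
            log.warning("grid cell %s failed: %s", dict(zip(keys, values)), exc)
        records.append(
            {
                **dict(zip(keys, values)),
                "order": order,
                "failed": failed,
                "cv_score": float(np.mean(scores)) if scores and not failed else np.nan,
                "m_fourier": cfg.m_fourier,
                "nodes_per_group": cfg.nodes_per_group,
            }
        )

    table = pd.DataFrame.from_records(records)
    ok = table[~table["failed"]]
    if ok.empty:
        raise DataError("every grid cell failed to fit")
    ranked = ok.sort_values(
        by=["cv_score", "m_fourier", "nodes_per_group", "order"],
        ascending=[False, True, True, True],
        kind="mergesort",
    )
    winner = ranked.iloc[0]
    best = replace(base, **{k: winner[k] for k in keys})
    # restore python ints where pandas upcast them
    best = replace(
        best,
        n_groups=int(best.n_groups),
        nodes_per_group=int(best.nodes_per_group),
        m_fourier=int(best.m_fourier),
        n_enhance=int(best.n_enhance),
    )
    return best, table
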
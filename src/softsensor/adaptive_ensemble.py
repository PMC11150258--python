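"""Stacking ensemble and moving-window adaptive driver.

Three base soft-sensor models (akbls by default, with perturbed
hyperparameters and distinct seeds for diversity) are combined by a
meta-learner trained on out-of-fold base predictions.  The moving-window
driver re-fits the stack on a sliding slice of the training database
while a test stream is consumed chunk by chunk, optionally feeding
predictions (or delayed true labels) back into the database.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.linear_model import LinearRegression

from .dataset import ProcessDataset
from .errors import DataError, WindowExhaustedError
from .models import ModelConfig, SoftSensorModel, fit_model

__all__ = [
    "StackConfig",
    "StackModel",
    "MWRunResult",
    "default_stack_config",
    "fit_stacking",
    "predict_stacking",
    "window_slice",
    "run_mw_stacking",
    "DEFAULT_WINDOW",
    "DEFAULT_STEP",
]

log = logging.getLogger(__name__)

#: Default moving-window length and step, in samples.
DEFAULT_WINDOW = 1200
DEFAULT_STEP = 200


@dataclass(frozen=True)
class StackConfig:
    """Configuration of the stacking ensemble."""

    base_configs: tuple[ModelConfig, ...]
    n_folds: int = 3
    meta: str = "gpr"              # "gpr" | "linear"
    meta_max_points: int = 600     # subsample cap for the GPR meta fit
    shuffle_folds: bool = False
    seed: int = 0

    def validate(self) -> None:
        if len(self.base_configs) < 2:
            raise DataError("stacking needs at least two base learners")
        if len(self.base_configs) != 3:
            log.info("stack uses %d base learners (default is 3)", len(self.base_configs))
        if self.n_folds < 2:
            raise DataError("fold count must be >= 2")
        if self.meta not in ("gpr", "linear"):
            raise DataError("meta must be 'gpr' or 'linear'")


def default_stack_config(
    base: Optional[ModelConfig] = None,
    seed: int = 0,
    n_folds: int = 3,
    meta: str = "gpr",
) -> StackConfig:
    """Three perturbed copies of ``base``: +/-25% on capacity parameters
    (nodes per group, Fourier components, bandwidth) and distinct seeds."""
    base = base or ModelConfig(mode="akbls")
    bases = []
    for i, factor in enumerate((1.0, 0.75, 1.25)):
        bases.append(
            replace(
                base,
                nodes_per_group=max(1, round(base.nodes_per_group * factor)),
                m_fourier=max(1, round(base.m_fourier * factor)),
                sigma=None if base.sigma is None else base.sigma * factor,
                sigma_scale=base.sigma_scale * (factor if base.sigma is None else 1.0),
                seed=seed + i,
            )
        )
    return StackConfig(base_configs=tuple(bases), n_folds=n_folds, meta=meta, seed=seed)


def _fold_indices(n: int, k: int, shuffle: bool, seed: int) -> list[np.ndarray]:
    """Contiguous-in-time blocks by default (process data is serially
    correlated); shuffled folds restore i.i.d.-style CV."""
    order = np.arange(n)
    if shuffle:
        order = np.random.default_rng(seed).permutation(n)
    folds = np.array_split(order, k)
    for f in folds:
        if len(f) < 2:
            raise DataError(f"a fold would contain {len(f)} sample(s); reduce n_folds")
    return folds


def _fit_meta(meta_X, y, cfg: StackConfig):
    if cfg.meta == "linear":
        return LinearRegression().fit(meta_X, y)
    n = meta_X.shape[0]
    if n > cfg.meta_max_points:
        idx = np.sort(
            np.random.default_rng(cfg.seed).choice(n, cfg.meta_max_points, replace=False)
        )
        meta_X, y = meta_X[idx], y[idx]
    kernel = (
        ConstantKernel(1.0, (1e-3, 1e3)) * RBF(1.0, (1e-2, 1e3))
        + WhiteKernel(1e-5, (1e-12, 1e1))
    )
    gpr = GaussianProcessRegressor(
        kernel=kernel, normalize_y=True, n_restarts_optimizer=0, random_state=cfg.seed
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            gpr.fit(meta_X, y)
        if not np.isfinite(gpr.predict(meta_X[:2])).all():
            raise ValueError("non-finite meta predictions")
        return gpr
    except Exception as exc:
        log.warning("GPR meta-learner failed (%s); falling back to linear", exc)
        return LinearRegression().fit(meta_X, y)


@dataclass
class StackModel:
    """Fitted stacking ensemble."""

    bases: list[SoftSensorModel]
    meta_model: object
    meta_features: np.ndarray      # (N, n_bases) out-of-fold predictions
    fold_of_row: np.ndarray        # (N,) fold index used for each row
    config: StackConfig

    def predict(self, X) -> np.ndarray:
        preds = np.column_stack([b.predict(X) for b in self.bases])
        return np.asarray(self.meta_model.predict(preds)).ravel()


def fit_stacking(data: ProcessDataset, cfg: StackConfig) -> StackModel:
    """Fit the base learners and the meta-learner.

    Meta-features are strictly out-of-fold: for every row, each base
    contributing a meta-feature was trained with that row's fold held
    out.  The bases are then refit on the full dataset.
    """
    cfg.validate()
    n = len(data)
    if n < cfg.n_folds:
        raise DataError("fewer samples than folds")
    folds = _fold_indices(n, cfg.n_folds, cfg.shuffle_folds, cfg.seed)
    fold_of_row = np.empty(n, dtype=int)
    for i, f in enumerate(folds):
        fold_of_row[f] = i

    meta_X = np.empty((n, len(cfg.base_configs)))
    for b, bc in enumerate(cfg.base_configs):
        for i, fold in enumerate(folds):
            train_rows = np.concatenate([f for j, f in enumerate(folds) if j != i])
            model = fit_model(data.take(train_rows), bc)
            meta_X[fold, b] = model.predict(data.X[fold])

    meta_model = _fit_meta(meta_X, data.y, cfg)
    bases = [fit_model(data, bc) for bc in cfg.base_configs]
    return StackModel(
        bases=bases,
        meta_model=meta_model,
        meta_features=meta_X,
        fold_of_row=fold_of_row,
        config=cfg,
    )


def predict_stacking(model: StackModel, X_new) -> np.ndarray:
    return model.predict(X_new)


def window_slice(db: ProcessDataset, m: int, w_m: int, l: int) -> ProcessDataset:
    """Rows [m*l, m*l + w_m] of the database (inclusive: w_m + 1 rows).

    Raises :class:`WindowExhaustedError` when the window runs past the
    end of the database and :class:`DataError` for invalid parameters.
    """
    if w_m < 1 or l < 1 or m < 0:
        raise DataError("window parameters must satisfy w_m >= 1, l >= 1, m >= 0")
    start = m * l
    end = start + w_m  # inclusive
    if end >= len(db):
        raise WindowExhaustedError(
            f"window {m} spans rows {start}..{end} but the database has {len(db)} rows"
        )
    return db.take(np.arange(start, end + 1))


@dataclass
class MWRunResult:
    """Output of one moving-window run."""

    predictions: np.ndarray
    windows: list[dict]
    overall_r2: Optional[float]
    overall_rmse: float
    overall_rmse_std: float
    n_windows: int
    feedback: str
    w_m: int
    l: int


def _chunk_metrics(y, yhat, y_scale):
    rmse = float(np.sqrt(np.mean((yhat - y) ** 2)))
    r2 = None
    if len(y) >= 2 and np.var(y) > 0:
        r2 = float(1.0 - np.sum((yhat - y) ** 2) / np.sum((y - np.mean(y)) ** 2))
    return r2, rmse, rmse / y_scale


def run_mw_stacking(
    train_db: ProcessDataset,
    test_stream: ProcessDataset,
    w_m: int = DEFAULT_WINDOW,
    l: int = DEFAULT_STEP,
    cfg: Optional[StackConfig] = None,
    feedback: str = "predicted",
    start: str = "latest",
) -> MWRunResult:
    """Moving-window stacking over a time-ordered test stream.

    Each iteration fits a stacking model on the current window, predicts
    the next ``l`` test rows, appends feedback rows to the database
    (``predicted``: the model's own outputs, self-labeling; ``true``:
    delayed reference labels; ``none``: no update) and advances the
    window by one step.  A final partial chunk is predicted with the
    last fitted model.  ``start='latest'`` places the first window at
    the most recent end of the database; ``start='begin'`` at row 0.
    """
    if feedback not in ("predicted", "true", "none"):
        raise DataError("feedback must be 'predicted', 'true' or 'none'")
    if start not in ("latest", "begin"):
        raise DataError("start must be 'latest' or 'begin'")
    if len(train_db) < w_m + 1:
        raise DataError(
            f"window length {w_m} (+1) exceeds the training database ({len(train_db)} rows)"
        )
    cfg = cfg or default_stack_config()
    log.info(
        "moving-window run: w_m=%d l=%d feedback=%s (feedback semantics: "
        "'predicted' self-labels the database, 'true' assumes delayed labels)",
        w_m, l, feedback,
    )

    db = train_db.copy()
    y_scale = float(np.std(train_db.y)) or 1.0
    m = (len(db) - 1 - w_m) // l if start == "latest" else 0
    pos = 0
    model: Optional[StackModel] = None
    predictions = np.empty(len(test_stream))
    windows: list[dict] = []
    n_windows = 0
    n_test = len(test_stream)

    while pos < n_test:
        chunk_idx = np.arange(pos, min(pos + l, n_test))
        partial = len(chunk_idx) < l
        refit = False
        if not (partial and model is not None):
            try:
                window = window_slice(db, m, w_m, l)
                model = fit_stacking(window, cfg)
                n_windows += 1
                refit = True
            except WindowExhaustedError:
                if model is None:
                    raise
                log.info("window %d exhausted; reusing the last fitted model", m)
        assert model is not None
        chunk = test_stream.take(chunk_idx)
        yhat = model.predict(chunk.X)
        predictions[chunk_idx] = yhat
        r2, rmse, rmse_std = _chunk_metrics(chunk.y, yhat, y_scale)
        windows.append(
            {
                "window_index": m,
                "train_rows": w_m + 1,
                "test_rows": len(chunk_idx),
                "r2": r2,
                "rmse": rmse,
                "rmse_std": rmse_std,
                "refit": refit,
            }
        )
        if feedback == "predicted":
            db = db.append_rows(chunk.X, yhat, batch_id=-1)
        elif feedback == "true":
            db = db.append_rows(chunk.X, chunk.y, batch_id=-1)
        m += 1
        pos += len(chunk_idx)

    overall_r2, overall_rmse, overall_rmse_std = _chunk_metrics(
        test_stream.y, predictions, y_scale
    )
    return MWRunResult(
        predictions=predictions,
        windows=windows,
        overall_r2=overall_r2,
        overall_rmse=overall_rmse,
        overall_rmse_std=overall_rmse_std,
        n_windows=n_windows,
        feedback=feedback,
        w_m=w_m,
        l=l,
    )
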
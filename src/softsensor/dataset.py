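"""Tabular process-data container used throughout the package.

A :class:`ProcessDataset` is an N x M input matrix, a length-N target
vector (product concentration for the fermentation data), per-sample
batch ids and column metadata.  CSV round-trips keep 6 significant
digits and LF line endings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = ["ProcessDataset"]


@dataclass
class ProcessDataset:
    X: np.ndarray
    y: np.ndarray
    variable_names: list[str]
    batch_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    sample_period: float = 1.0
    target_name: str = "target"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.X.ndim != 2:
            raise DataError(f"X must be 2-D, got shape {self.X.shape}")
        if self.X.shape[0] != self.y.shape[0]:
            raise DataError(
                f"row mismatch: X has {self.X.shape[0]} rows, y has {self.y.shape[0]}"
            )
        if self.X.shape[0] < 1:
            raise DataError("dataset must contain at least one sample")
        if len(self.variable_names) != self.X.shape[1]:
            raise DataError(
                f"{len(self.variable_names)} variable names for {self.X.shape[1]} columns"
            )
        self.variable_names = list(self.variable_names)
        if self.batch_ids is None:
            self.batch_ids = np.zeros(len(self.y), dtype=int)
        self.batch_ids = np.asarray(self.batch_ids, dtype=int).ravel()
        if self.batch_ids.shape[0] != self.y.shape[0]:
            raise DataError("batch_ids length does not match the number of rows")
        if not np.isfinite(self.X).all() or not np.isfinite(self.y).all():
            raise DataError("dataset contains non-finite values")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def n_variables(self) -> int:
        return self.X.shape[1]

    def take(self, idx) -> "ProcessDataset":
        """Row-subset as a new dataset (accepts any numpy fancy index)."""
        idx = np.asarray(idx)
        return replace(
            self,
            X=self.X[idx].copy(),
            y=self.y[idx].copy(),
            batch_ids=self.batch_ids[idx].copy(),
        )

    def copy(self) -> "ProcessDataset":
        return self.take(np.arange(len(self)))

    def append_rows(self, X, y, batch_id: int = -1) -> "ProcessDataset":
        """New dataset with extra rows appended (used by feedback loops)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[1] != self.n_variables:
            raise DataError(
                f"appended rows have {X.shape[1]} columns, expected {self.n_variables}"
            )
        ids = np.full(len(y), batch_id, dtype=int)
        return replace(
            self,
            X=np.vstack([self.X, X]),
            y=np.concatenate([self.y, y]),
            batch_ids=np.concatenate([self.batch_ids, ids]),
        )

    @classmethod
    def concat(cls, parts: Sequence["ProcessDataset"]) -> "ProcessDataset":
        if not parts:
            raise DataError("cannot concatenate an empty list of datasets")
        names = parts[0].variable_names
        for p in parts[1:]:
            if p.variable_names != names:
                raise DataError("datasets have differing variable names")
        return cls(
            X=np.vstack([p.X for p in parts]),
            y=np.concatenate([p.y for p in parts]),
            variable_names=list(names),
            batch_ids=np.concatenate([p.batch_ids for p in parts]),
            sample_period=parts[0].sample_period,
            target_name=parts[0].target_name,
        )

    # ------------------------------------------------------------------ I/O
    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.variable_names)
        df[self.target_name] = self.y
        df["batch_id"] = self.batch_ids
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(
            path, index=False, float_format="%.6g", lineterminator="\n"
        )

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, target_col: str = "target", sample_period: float = 1.0
    ) -> "ProcessDataset":
        if target_col not in df.columns:
            raise DataError(f"target column {target_col!r} not found in table")
        if df.isna().any().any():
            raise DataError("table contains missing values")
        ids = (
            df["batch_id"].to_numpy(dtype=int)
            if "batch_id" in df.columns
            else np.zeros(len(df), dtype=int)
        )
        names = [c for c in df.columns if c not in (target_col, "batch_id")]
        return cls(
            X=df[names].to_numpy(dtype=float),
            y=df[target_col].to_numpy(dtype=float),
            variable_names=names,
            batch_ids=ids,
            sample_period=sample_period,
            target_name=target_col,
        )

    @classmethod
    def from_csv(
        cls, path, target_col: str = "target", sample_period: float = 1.0
    ) -> "ProcessDataset":
        try:
            df = pd.read_csv(path)
        except FileNotFoundError as exc:
            raise DataError(str(exc)) from exc
        return cls.from_frame(df, target_col=target_col, sample_period=sample_period)
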
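"""Experiment presets over the simulated penicillin campaigns.

Three presets mirror the package's benchmark designs:

``table3_akbls_vs_kbls_vs_bls``
    CV-tuned bls/kbls/akbls on shuffled 80/20 splits of the fixed-size
    penicillin datasets, averaged over seeded runs.
``framework_ablation``
    {plain, moving-window, stacking, moving-window + stacking} crossed
    with the three model modes on a multi-batch campaign.
``headline_mw_stacking``
    Moving-window stacking on a 20-train-batch campaign evaluated on
    five held-out test batches (the fifth with shifted initials).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .. import fermsim
from ..adaptive_ensemble import (
    DEFAULT_STEP,
    DEFAULT_WINDOW,
    default_stack_config,
    fit_stacking,
    run_mw_stacking,
    window_slice,
)
from ..dataset import ProcessDataset
from ..errors import DataError, WindowExhaustedError
from ..models import ModelConfig, fit_model
from .metrics import MetricReport, r2_score, rmse
from .tuning import DEFAULT_GRID, GridSpec, cv_grid_search

__all__ = [
    "PRESETS",
    "run_experiment",
    "train_test_split_dataset",
    "penicillin_campaign",
]

log = logging.getLogger(__name__)

PRESETS = (
    "table3_akbls_vs_kbls_vs_bls",
    "framework_ablation",
    "headline_mw_stacking",
)

_BLS_GRID: Mapping[str, Sequence] = {"nodes_per_group": [10, 20], "n_enhance": [100, 200]}


def train_test_split_dataset(
    data: ProcessDataset, test_fraction: float = 0.2, seed: int = 0
) -> tuple[ProcessDataset, ProcessDataset]:
    """Shuffled row split (the convention used for the fixed-size tables)."""
    if not 0 < test_fraction < 1:
        raise DataError("test_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(data))
    n_test = max(1, int(round(test_fraction * len(data))))
    return data.take(np.sort(perm[n_test:])), data.take(np.sort(perm[:n_test]))


def _aged_params(base: fermsim.KineticParams, batch: int, drift: float):
    """Compound per-batch slowdown of growth and product formation
    (equipment aging / process drift)."""
    f = (1.0 - drift) ** batch
    return replace(base, mu_max=base.mu_max * f, k_prod=base.k_prod * f)


def penicillin_campaign(
    n_train_batches: int = 20,
    n_test_batches: int = 1,
    batch_hours: float = 400.0,
    seed: int = 0,
    train_noise_snr: Optional[float] = 40.0,
    shift_last_test: bool = False,
    kinetic_drift: float = 0.0,
) -> tuple[ProcessDataset, list[ProcessDataset]]:
    """Simulate a training campaign plus held-out test batches.

    Training batches get the standard batch-to-batch variation and
    (optionally) measurement noise; test batches are clean.  With
    ``shift_last_test`` the final test batch starts well outside the
    training initial-condition range.  ``kinetic_drift`` compounds a
    per-batch slowdown of the kinetics across the campaign (and into the
    test batches), emulating a time-varying process.
    """
    base = fermsim.BatchSimConfig(duration=batch_hours)
    kin = fermsim.KineticParams()
    parts = [
        fermsim.simulate_campaign(
            1,
            base,
            seed=seed + 17 * b,
            params=_aged_params(kin, b, kinetic_drift),
            first_batch_id=b,
        )
        for b in range(n_train_batches)
    ]
    train = ProcessDataset.concat(parts)
    if train_noise_snr is not None:
        train = fermsim.add_measurement_noise(train, train_noise_snr, seed=seed + 1)
    tests = []
    for b in range(n_test_batches):
        shifted = shift_last_test and b == n_test_batches - 1
        cfg = base
        if shifted:
            cfg = replace(
                base,
                substrate_init=base.substrate_init * 1.25,
                volume_init=base.volume_init * 1.12,
            )
        tests.append(
            fermsim.simulate_campaign(
                1,
                cfg,
                variation=None if not shifted else {},
                seed=seed + 1000 + b,
                params=_aged_params(kin, n_train_batches + b, kinetic_drift),
                first_batch_id=n_train_batches + b,
            )
        )
    return train, tests


def _run_mw_single(train_db, test, cfg: ModelConfig, w_m: int, l: int):
    """Moving-window loop around a single model (no stacking)."""
    db = train_db.copy()
    m = max(0, (len(db) - 1 - w_m) // l)
    pos, model = 0, None
    preds = np.empty(len(test))
    while pos < len(test):
        idx = np.arange(pos, min(pos + l, len(test)))
        if not (len(idx) < l and model is not None):
            try:
                model = fit_model(window_slice(db, m, w_m, l), cfg)
            except WindowExhaustedError:
                if model is None:
                    raise
        yhat = model.predict(test.X[idx])
        preds[idx] = yhat
        db = db.append_rows(test.X[idx], yhat, batch_id=-1)
        m += 1
        pos += len(idx)
    return preds


def _resolve_outdir(outdir) -> Optional[Path]:
    if outdir is None:
        return None
    p = Path(outdir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def run_experiment(
    preset: str,
    seed: int = 0,
    outdir=None,
    runs: int = 10,
    batch_hours: float = 400.0,
    dataset_presets: Sequence[str] = ("table3_1", "table3_2"),
    n_train_batches: int = 20,
    w_m: Optional[int] = None,
    l: Optional[int] = None,
    grid: Optional[GridSpec] = None,
) -> dict:
    """Run one experiment preset and return (and optionally write) a report.

    ``runs`` seeds are ``seed .. seed+runs-1`` ("average accuracy of
    ten runs" convention at the default ``runs=10``; reduce for CI).
    """
    if preset not in PRESETS:
        raise DataError(f"unknown preset {preset!r}; choose from {PRESETS}")
    out = _resolve_outdir(outdir)
    report: dict = {
        "preset": preset,
        "seed": seed,
        "runs": runs,
        "batch_hours": batch_hours,
        "rmse_scale": "standardized",
    }
    rows = []

    if preset == "table3_akbls_vs_kbls_vs_bls":
        for ds_name in dataset_presets:
            cells = {mode: MetricReport() for mode in ("bls", "kbls", "akbls")}
            n_rows = 0
            for run in range(runs):
                run_seed = seed + run
                data = fermsim.make_preset(ds_name, seed=run_seed, batch_hours=int(batch_hours))
                n_rows = len(data)
                train, test = train_test_split_dataset(data, 0.2, seed=run_seed)
                for mode in cells:
                    g = grid or GridSpec(
                        candidates=dict(_BLS_GRID if mode == "bls" else DEFAULT_GRID),
                        seed=run_seed,
                    )
                    best, _ = cv_grid_search(
                        train, mode=mode, grid=g, base=ModelConfig(seed=run_seed)
                    )
                    model = fit_model(train, best)
                    cells[mode].add_run(test.y, model.predict(test.X))
            for mode, rep in cells.items():
                rows.append({"dataset": ds_name, "n": n_rows, "model": mode, **rep.to_dict()})
        report["cells"] = rows

    elif preset == "framework_ablation":
        w_m = w_m or DEFAULT_WINDOW
        l = l or DEFAULT_STEP
        train, tests = penicillin_campaign(
            n_train_batches, 1, batch_hours, seed=seed, kinetic_drift=0.015
        )
        test = tests[0]
        y_scale = float(np.std(train.y)) or 1.0
        for mode in ("bls", "kbls", "akbls"):
            base = ModelConfig(mode=mode, seed=seed)
            preds = {
                "plain": fit_model(train, base).predict(test.X),
                "mw": _run_mw_single(train, test, base, w_m, l),
                "stacking": fit_stacking(
                    train, default_stack_config(base, seed=seed)
                ).predict(test.X),
                "mw_stacking": run_mw_stacking(
                    train, test, w_m, l, default_stack_config(base, seed=seed)
                ).predictions,
            }
            for framework, yhat in preds.items():
                rows.append(
                    {
                        "model": mode,
                        "framework": framework,
                        "r2": r2_score(test.y, yhat),
                        "rmse": rmse(test.y, yhat) / y_scale,
                    }
                )
        report["cells"] = rows
        report["w_m"], report["l"] = w_m, l

    else:  # headline_mw_stacking
        w_m = w_m or DEFAULT_WINDOW
        l = l or DEFAULT_STEP
        train, tests = penicillin_campaign(
            n_train_batches, 5, batch_hours, seed=seed, shift_last_test=True
        )
        cfg = default_stack_config(ModelConfig(mode="akbls", seed=seed), seed=seed)
        per_batch = []
        for b, test in enumerate(tests):
            result = run_mw_stacking(train, test, w_m, l, cfg)
            per_batch.append(
                {
                    "test_batch": b + 1,
                    "r2": result.overall_r2,
                    "rmse": result.overall_rmse_std,
                    "n_windows": result.n_windows,
                }
            )
        rows = per_batch
        report["cells"] = per_batch
        report["average"] = {
            "r2": float(np.mean([c["r2"] for c in per_batch])),
            "rmse": float(np.mean([c["rmse"] for c in per_batch])),
        }
        report["w_m"], report["l"] = w_m, l
        report["stack_config"] = {
            "n_folds": cfg.n_folds,
            "meta": cfg.meta,
            "bases": [dataclasses.asdict(b) for b in cfg.base_configs],
        }

    if out is not None:
        pd.DataFrame.from_records(rows).to_csv(
            out / f"{preset}_results.csv", index=False, float_format="%.6g",
            lineterminator="\n",
        )
        with open(out / f"{preset}_report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        log.info("wrote %s results to %s", preset, out)
    return report
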
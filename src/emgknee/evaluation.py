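"""Evaluation metrics and the sample-size-sweep experimental protocol.

Metrics (angles in degrees):

    MAE  = mean |y_hat - y|
    RMSE = sqrt(mean (y - y_hat)^2)
    R^2  = 1 - SS_res / SS_tot

MAE and RMSE are 0 for a perfect prediction; R^2 is 1 for a perfect
prediction, 0 when predicting the target mean, and negative when the model
is worse than the mean.  RMSE >= MAE always (power-mean inequality).

The sweep protocol mirrors the sample-size experiment: starting from a
single gait cycle, training sets grow by five cycles up to sixty (13 sizes);
for each random seed a fixed set of cycles is held out, the remaining cycles
are shuffled once, and nested training subsets are taken from that order so
size effects are not confounded by resampling.  Metrics are pooled over all
phase points of the held-out cycles ("continuous global" scores).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .kernels import MultiKernelSpec
from .lssvr import fit_lssvr, predict_lssvr
from .recordings import DegenerateInputError, GaitCycleDataset
from .rvr import RvrFitConfig, fit_rvr, predict_rvr

#: 1, 5, 10, ..., 60 gait cycles — the 13 training sizes of the protocol.
DEFAULT_GRID = (1,) + tuple(range(5, 61, 5))

#: Cap on training samples per fit: small training sets use every phase
#: point; larger ones are phase-subsampled to bound the cubic cost of the
#: dense Bayesian solve.  Held-out evaluation always uses all phase points.
DEFAULT_TRAIN_POINT_BUDGET = 1000


@dataclass(frozen=True)
class MetricsReport:
    """MAE/RMSE/R^2 of one train/test evaluation over n samples."""

    mae: float
    rmse: float
    r2: float
    n: int

    def __post_init__(self) -> None:
        if self.mae < 0 or self.rmse < 0:
            raise ValueError("errors must be non-negative")
        if self.rmse < self.mae - 1e-12:
            raise ValueError("RMSE cannot be below MAE")
        if self.r2 > 1 + 1e-12:
            raise ValueError("R^2 cannot exceed 1")


def _check_pair(y, yhat):
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("empty series")
    if y.size != yhat.size:
        raise ValueError("length mismatch between true and predicted series")
    return y, yhat


def mae(y, yhat) -> float:
    """Mean absolute error (degrees)."""
    y, yhat = _check_pair(y, yhat)
    return float(np.mean(np.abs(yhat - y)))


def rmse(y, yhat) -> float:
    """Root mean square error (degrees)."""
    y, yhat = _check_pair(y, yhat)
    return float(np.sqrt(np.mean(np.square(y - yhat))))


def r2_score(y_true, y_pred) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot."""
    y_true, y_pred = _check_pair(y_true, y_pred)
    ss_tot = float(np.sum(np.square(y_true - y_true.mean())))
    if ss_tot == 0:
        raise DegenerateInputError("R^2 undefined for constant true values")
    ss_res = float(np.sum(np.square(y_true - y_pred)))
    return 1.0 - ss_res / ss_tot


def evaluate(y_true, y_pred) -> MetricsReport:
    """All three metrics for one prediction series."""
    y_true, y_pred = _check_pair(y_true, y_pred)
    return MetricsReport(
        mae=mae(y_true, y_pred),
        rmse=rmse(y_true, y_pred),
        r2=r2_score(y_true, y_pred),
        n=int(y_true.size),
    )


def _fit_predict_mkrvr(X, t, X_test, seed):
    model = fit_rvr(X, t, MultiKernelSpec(), RvrFitConfig(seed=seed))
    return predict_rvr(model, X_test)[0]


def _fit_predict_rvr_gaussian(X, t, X_test, seed):
    model = fit_rvr(X, t, MultiKernelSpec.gaussian_only(), RvrFitConfig(seed=seed))
    return predict_rvr(model, X_test)[0]


def _fit_predict_lssvr(X, t, X_test, seed):
    model = fit_lssvr(X, t, MultiKernelSpec(), reg_gamma=100.0)
    return predict_lssvr(model, X_test)


METHODS: dict[str, Callable] = {
    "mkrvr": _fit_predict_mkrvr,
    "rvr_gaussian": _fit_predict_rvr_gaussian,
    "lssvr": _fit_predict_lssvr,
}


def sample_size_sweep(
    dataset: GaitCycleDataset,
    grid: Sequence[int] = DEFAULT_GRID,
    methods: Iterable[str] = ("mkrvr", "lssvr"),
    holdout_gc_count: int = 10,
    seeds: Sequence[int] = range(10),
    train_phase_stride: int | None = None,
    train_point_budget: int = DEFAULT_TRAIN_POINT_BUDGET,
) -> pd.DataFrame:
    """Run the sample-size experiment; one row per (size, method, seed).

    Columns: ``train_gcs, method, seed, mae_deg, rmse_deg, r2, n_test``.
    Deterministic per seed.  Training subsets are nested within each seed.
    ``train_phase_stride`` fixes the per-cycle phase subsampling explicitly;
    by default it is chosen per size as the smallest stride keeping the
    training set within ``train_point_budget`` samples.
    """
    grid = sorted(int(g) for g in grid)
    methods = list(methods)
    unknown = [m for m in methods if m not in METHODS]
    if unknown:
        raise ValueError(f"unknown methods: {unknown}; choose from {sorted(METHODS)}")
    if grid[0] < 1:
        raise ValueError("training sizes must be >= 1")
    needed = grid[-1] + holdout_gc_count
    if dataset.n_cycles < needed:
        raise ValueError(
            f"dataset has {dataset.n_cycles} cycles; "
            f"{needed} required for grid max {grid[-1]} plus "
            f"{holdout_gc_count} held-out cycles"
        )

    rows = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        order = rng.permutation(dataset.n_cycles)
        test_idx = order[:holdout_gc_count]
        train_order = order[holdout_gc_count:]
        X_test, t_test = dataset.pooled(test_idx)
        for size in grid:
            if train_phase_stride is not None:
                stride = train_phase_stride
            else:
                stride = max(
                    1,
                    -(-size * dataset.points_per_cycle // train_point_budget),
                )
            X_train, t_train = dataset.pooled(
                train_order[:size], phase_stride=stride
            )
            for method in methods:
                y_pred = METHODS[method](X_train, t_train, X_test, int(seed))
                report = evaluate(t_test, y_pred)
                rows.append(
                    {
                        "train_gcs": size,
                        "method": method,
                        "seed": int(seed),
                        "mae_deg": report.mae,
                        "rmse_deg": report.rmse,
                        "r2": report.r2,
                        "n_test": report.n,
                    }
                )
    return pd.DataFrame(rows)


def summarize_sweep(sweep: pd.DataFrame) -> pd.DataFrame:
    """Median metrics per (method, training size) across seeds."""
    return (
        sweep.groupby(["method", "train_gcs"])[["mae_deg", "rmse_deg", "r2"]]
        .median()
        .reset_index()
    )
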
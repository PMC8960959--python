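"""Successive regression: growing-window evaluation with enforced extrapolation.

The protocol orders a dataset (shuffled for interpolation; responses sorted
descending/ascending for extrapolation), then walks a growing training
window over it.  Starting from the first 20% of rows, it (1) selects one
meta-parameter set per engine by Monte Carlo cross-validation within the
window (11 random 75/25 splits), (2) refits on the whole window and predicts
the next ~10% block — rows the model has never seen, and for sorted
orderings rows whose responses lie entirely outside the training range —
then absorbs the block and repeats, eight times in total.  The quality
measure is the relative error of each test block.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .regressors import (
    ModelSpec,
    NIPALSPLS,
    boxcox,
    complexity_key,
    fit,
    inverse_boxcox,
    normalize_engine,
    param_grid,
    predict,
)

log = logging.getLogger(__name__)

ORDERINGS = ("SHUFFLED", "HIGH2LOW", "LOW2HIGH")
TRAIN_FRACTIONS = tuple(round(0.2 + 0.1 * i, 1) for i in range(8))


def _derive_seed(*parts: int) -> int:
    """Deterministic child seed below 2**31."""
    return int(np.random.SeedSequence([int(p) & 0x7FFFFFFF for p in parts]).generate_state(1)[0] % (2**31))


@dataclass
class SuccessiveDataset:
    """Descriptor matrix row-aligned with a response vector, plus ordering."""

    X: np.ndarray
    y: np.ndarray
    ordering: str
    meta: dict = field(default_factory=dict)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.ndim != 2 or len(self.X) != len(self.y):
            raise ValueError("X must be 2-D and row-aligned with y")
        if self.ordering not in ORDERINGS:
            raise ValueError(f"unknown ordering {self.ordering!r}")


def order_dataset(
    X: np.ndarray,
    y: np.ndarray,
    ordering: str,
    rng_seed: int = 0,
    meta: dict | None = None,
) -> SuccessiveDataset:
    """Co-permute X and y by the requested ordering.

    Sorts are stable (ties keep input order); SHUFFLED applies a seeded
    uniform permutation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    ordering = ordering.upper()
    if ordering == "SHUFFLED":
        perm = np.random.default_rng(rng_seed).permutation(len(y))
    elif ordering == "HIGH2LOW":
        perm = np.argsort(-y, kind="stable")
    elif ordering == "LOW2HIGH":
        perm = np.argsort(y, kind="stable")
    else:
        raise ValueError(f"unknown ordering {ordering!r}")
    return SuccessiveDataset(X[perm], y[perm], ordering, dict(meta or {}), rng_seed)


def blocks(n: int) -> list[tuple[int, int, int]]:
    """The 8 growing-window (train_end, test_start, test_end) index triples.

    Train windows end at floor(0.2 n) .. floor(0.9 n); each test block runs
    to the next boundary (the last one to n), so the blocks partition all
    rows beyond the initial window.
    """
    if n < 20:
        raise ValueError(f"need at least 20 rows for the successive protocol, got {n}")
    bounds = [int(np.floor(f * n)) for f in TRAIN_FRACTIONS] + [n]
    return [(bounds[i], bounds[i], bounds[i + 1]) for i in range(8)]


def relative_error(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean absolute error divided by the mean absolute true response.

    Scale-free; a response block with (near-)zero mean magnitude falls back
    to the plain mean absolute error with a warning.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("relative_error needs two equal-length non-empty vectors")
    mae = float(np.mean(np.abs(y_pred - y_true)))
    denom = float(np.mean(np.abs(y_true)))
    if denom < 1e-12:
        log.warning("mean |y| below 1e-12; returning unnormalized MAE")
        return mae
    return mae / denom


def _cv_splits(n: int, splits: int, holdout: float, rng_seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    rng = np.random.default_rng(rng_seed)
    n_val = max(1, int(np.floor(holdout * n)))
    out = []
    for _ in range(splits):
        perm = rng.permutation(n)
        out.append((perm[n_val:], perm[:n_val]))
    return out


def _pls_family_cv_errors(
    engine: str,
    grid: list[dict],
    X: np.ndarray,
    y: np.ndarray,
    split_idx: list[tuple[np.ndarray, np.ndarray]],
) -> np.ndarray:
    """CV errors for PLS/PLSP grids using nested-factor evaluation.

    PLS factors are nested: a single NIPALS fit at the grid's largest factor
    count yields predictions for every smaller count, so the factor axis of
    the grid costs one fit per split (per Box-Cox lambda for PLSP).
    """
    errors = np.zeros(len(grid))
    lam_groups: dict[float | None, list[int]] = {}
    for gi, params in enumerate(grid):
        lam_groups.setdefault(params.get("lam"), []).append(gi)
    for lam, indices in lam_groups.items():
        max_f = max(grid[gi]["factors"] for gi in indices)
        for tr, val in split_idx:
            Xtr, ytr, Xval, yval = X[tr], y[tr], X[val], y[val]
            if lam is None:
                pls = NIPALSPLS(max_f).fit(Xtr, ytr)
                for gi in indices:
                    pred = pls.predict_at(Xval, grid[gi]["factors"])
                    errors[gi] += relative_error(yval, pred)
            else:
                shift = float(ytr.min())
                pls = NIPALSPLS(max_f).fit(Xtr, boxcox(ytr - shift + 1.0, lam))
                for gi in indices:
                    z = pls.predict_at(Xval, grid[gi]["factors"])
                    pred = inverse_boxcox(z, lam) + shift - 1.0
                    errors[gi] += relative_error(yval, pred)
    return errors / len(split_idx)


def monte_carlo_cv(
    X: np.ndarray,
    y: np.ndarray,
    engine: str,
    grid: list[dict] | None = None,
    splits: int = 11,
    holdout: float = 0.25,
    rng_seed: int = 0,
    grid_mode: str = "reduced",
    return_errors: bool = False,
):
    """Select the grid point with minimum average validation error.

    The same seeded random splits are reused for every grid point so the
    comparison is paired.  Ties (within 1e-12) are broken toward the simpler
    model, then toward grid order.  A grid point whose engine fails on any
    split is penalized with +inf.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 8:
        raise ValueError(f"Monte Carlo CV needs at least 8 rows, got {n}")
    engine = normalize_engine(engine)
    if grid is None:
        grid = param_grid(engine, X.shape[1], grid_mode)
    split_idx = _cv_splits(n, splits, holdout, rng_seed)
    if engine in ("PLS", "PLSP") and all("factors" in g for g in grid):
        errors = _pls_family_cv_errors(engine, grid, X, y, split_idx)
    else:
        errors = np.zeros(len(grid))
        for gi, params in enumerate(grid):
            spec = ModelSpec.make(engine, params)
            total = 0.0
            for si, (tr, val) in enumerate(split_idx):
                try:
                    model = fit(spec, X[tr], y[tr], rng_seed=_derive_seed(rng_seed, gi, si))
                    total += relative_error(y[val], predict(model, X[val]))
                except Exception as exc:
                    log.warning("engine %s failed in CV at %s: %s", engine, params, exc)
                    total = np.inf
                    break
            errors[gi] = total if np.isinf(total) else total / splits
    best = float(np.min(errors))
    tied = [gi for gi in range(len(grid)) if errors[gi] <= best + 1e-12]
    tied.sort(key=lambda gi: (complexity_key(engine, grid[gi]), gi))
    chosen = ModelSpec.make(engine, grid[tied[0]])
    if return_errors:
        return chosen, errors
    return chosen


@dataclass
class StepRecord:
    train_frac: float
    spec: ModelSpec
    error: float
    n_train: int
    n_test: int
    train_fingerprint: str = ""
    cv_error: float = float("nan")


@dataclass
class SuccessiveResult:
    """Per-fraction test-block errors for one (set, descriptor, response,
    ordering, engine) cell."""

    meta: dict
    engine: str
    records: list[StepRecord]

    def errors(self) -> np.ndarray:
        return np.array([r.error for r in self.records])

    def error_at(self, train_frac: float) -> float:
        for r in self.records:
            if abs(r.train_frac - train_frac) < 1e-9:
                return r.error
        raise KeyError(f"no record at train fraction {train_frac}")


def run_successive(
    dataset: SuccessiveDataset,
    engine: str,
    grid: list[dict] | None = None,
    grid_mode: str = "reduced",
    splits: int = 11,
    holdout: float = 0.25,
) -> SuccessiveResult:
    """Run the two-step successive protocol over all 8 growing windows.

    Meta-parameter selection and refitting see only rows strictly before the
    test block; each block's rows join the training window only after being
    predicted.  A failed step records a NaN error and the run continues.
    """
    engine = normalize_engine(engine)
    X, y = dataset.X, dataset.y
    records: list[StepRecord] = []
    for step, (train_end, t0, t1) in enumerate(blocks(len(y))):
        frac = TRAIN_FRACTIONS[step]
        Xtr, ytr = X[:train_end], y[:train_end]
        try:
            seed = _derive_seed(dataset.rng_seed, step)
            spec, errors = monte_carlo_cv(
                Xtr, ytr, engine, grid=grid, splits=splits, holdout=holdout,
                rng_seed=seed, grid_mode=grid_mode, return_errors=True,
            )
            model = fit(spec, Xtr, ytr, rng_seed=_derive_seed(dataset.rng_seed, step, 1))
            err = relative_error(y[t0:t1], predict(model, X[t0:t1]))
            records.append(
                StepRecord(
                    frac, spec, err, train_end, t1 - t0,
                    train_fingerprint=model.train_fingerprint,
                    cv_error=float(np.min(errors)),
                )
            )
        except Exception as exc:
            log.warning("successive step %.1f failed for %s: %s", frac, engine, exc)
            records.append(StepRecord(frac, ModelSpec.make(engine), float("nan"), train_end, t1 - t0))
    return SuccessiveResult(dict(dataset.meta), engine, records)
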
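"""Length grading, dataset splitting, evaluation metrics and summary statistics.

Grading follows the five-class scheme used for stipe length (all bounds in
mm, upper bounds inclusive):

    extremely_short  <= 11.56
    short            <= 27.69
    middle           <= 43.83
    long             <= 59.96
    extremely_long   above

Dataset splitting reproduces a 7:2:1 train/test/validation partition with
floor / round-half-up / remainder rounding, so 985 samples split into
(689, 197, 99).

Evaluation metrics are the standard detection (precision, recall) and
regression (R², RMSE, MSE, MAE) measures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

GRADE_LABELS = (
    "extremely_short",
    "short",
    "middle",
    "long",
    "extremely_long",
)

#: Upper bounds (mm, inclusive) of the first four length grades.
DEFAULT_GRADE_BOUNDS = (11.56, 27.69, 43.83, 59.96)


@dataclass(frozen=True)
class GradingConfig:
    """Ordered inclusive upper bounds for the first four grades plus labels."""

    bounds_mm: tuple[float, float, float, float] = DEFAULT_GRADE_BOUNDS
    labels: tuple[str, ...] = GRADE_LABELS

    def __post_init__(self) -> None:
        if len(self.labels) != 5:
            raise ValueError("grading requires exactly 5 labels")
        if len(self.bounds_mm) != 4:
            raise ValueError("grading requires exactly 4 upper bounds")
        if not all(a < b for a, b in zip(self.bounds_mm, self.bounds_mm[1:])):
            raise ValueError("grade bounds must be strictly increasing")


@dataclass(frozen=True)
class SplitSpec:
    """Train/test/validation ratios; must sum to 1."""

    train: float = 0.7
    test: float = 0.2
    val: float = 0.1

    def __post_init__(self) -> None:
        for r in (self.train, self.test, self.val):
            if not 0 < r < 1:
                raise ValueError("each split ratio must lie in (0, 1)")
        if abs(self.train + self.test + self.val - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary detection counts."""

    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class EvalPairs:
    """Paired predicted/true values for regression evaluation."""

    predicted: tuple[float, ...]
    true: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.predicted) != len(self.true):
            raise ValueError("predicted and true values must have equal length")
        if len(self.true) < 1:
            raise ValueError("evaluation requires at least one pair")

    @property
    def m(self) -> int:
        return len(self.true)

    @property
    def true_mean(self) -> float:
        return float(np.mean(self.true))


def grade_length(length_mm: float, config: GradingConfig | None = None) -> str:
    """Assign a length grade.

    The label is the first grade whose inclusive upper bound is >= the
    length; lengths above the last bound are ``extremely_long``.
    """
    if length_mm < 0:
        raise ValueError(f"length must be non-negative, got {length_mm}")
    cfg = config if config is not None else GradingConfig()
    for bound, label in zip(cfg.bounds_mm, cfg.labels):
        if length_mm <= bound:
            return label
    return cfg.labels[-1]


def split_dataset(n: int, spec: SplitSpec | None = None) -> tuple[int, int, int]:
    """Partition ``n`` samples into (train, test, val) counts.

    train = floor(r_train * n); test = floor(r_test * n + 0.5) (round half
    up); val takes the remainder, so the counts always sum to ``n``.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    s = spec if spec is not None else SplitSpec()
    train = math.floor(s.train * n)
    test = math.floor(s.test * n + 0.5)
    val = n - train - test
    if val < 0:
        raise ValueError(f"split of n={n} produced a negative validation count")
    return train, test, val


def precision_recall(c: ConfusionCounts) -> tuple[float, float]:
    """Precision = TP/(TP+FP) and recall = TP/(TP+FN)."""
    if c.tp + c.fp == 0:
        raise ZeroDivisionError("precision undefined: TP + FP == 0")
    if c.tp + c.fn == 0:
        raise ZeroDivisionError("recall undefined: TP + FN == 0")
    return c.tp / (c.tp + c.fp), c.tp / (c.tp + c.fn)


def eval_metrics(pairs: EvalPairs) -> tuple[float, float, float, float]:
    """Regression agreement metrics ``(R², RMSE, MSE, MAE)``.

    R² = 1 - Σ(ŷ−y)² / Σ(ȳ−y)²;  RMSE = sqrt(MSE);
    MSE = Σ(y−ŷ)²/m;  MAE = Σ|y−ŷ|/m.

    Raises
    ------
    ZeroDivisionError
        When the true values are constant (R² denominator vanishes).  MSE,
        RMSE and MAE remain well defined and can be computed by catching the
        error and calling with non-constant data, or directly via numpy.
    """
    y = np.asarray(pairs.true, dtype=float)
    yhat = np.asarray(pairs.predicted, dtype=float)
    sse = float(np.sum((yhat - y) ** 2))
    mse = sse / pairs.m
    rmse = math.sqrt(mse)
    mae = float(np.mean(np.abs(y - yhat)))
    sst = float(np.sum((y.mean() - y) ** 2))
    if sst == 0:
        raise ZeroDivisionError(
            f"R² undefined for constant true values (RMSE={rmse:.6g}, "
            f"MSE={mse:.6g}, MAE={mae:.6g})"
        )
    r2 = 1.0 - sse / sst
    return r2, rmse, mse, mae


def summary_stats(values: Sequence[float]) -> tuple[float, float, float, float, float]:
    """Summary row ``(mean, max, min, std, median)`` for one trait.

    The standard deviation is the sample estimator (divisor m−1) and
    requires at least two values.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("summary_stats requires at least one value")
    if v.size < 2:
        raise ValueError("sample standard deviation requires at least two values")
    return (
        float(v.mean()),
        float(v.max()),
        float(v.min()),
        float(v.std(ddof=1)),
        float(np.median(v)),
    )
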
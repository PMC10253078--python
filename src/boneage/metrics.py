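"""Evaluation statistics for bone-age prediction.

MAE and RMSE in months, per-age-group tables over half-open 1-year bins
[k, k+1) on the *true* age, and cumulative-accuracy curves: the fraction of
samples whose absolute error is <= t months, traced for t = 0..24.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MONTHS_PER_YEAR = 12.0
DEFAULT_THRESHOLDS = tuple(range(25))  # 0..24 months


def _validate(y_true, y_pred) -> tuple[np.ndarray, np.ndarray]:
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    if y_true.size == 0:
        raise ValueError("empty input")
    return y_true, y_pred


def mae(y_true, y_pred) -> float:
    """Mean absolute error in months."""
    y_true, y_pred = _validate(y_true, y_pred)
    return float(np.mean(np.abs(y_true - y_pred)))


def rmse(y_true, y_pred) -> float:
    """Root mean squared error in months."""
    y_true, y_pred = _validate(y_true, y_pred)
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


@dataclass
class GroupRow:
    """Per-age-bin statistics; the bin is [year, year+1) on true age."""

    year: int
    n: int
    mae: float
    rmse: float


@dataclass
class EvalReport:
    """Overall and per-group accuracy plus the cumulative-accuracy curve."""

    mae: float
    rmse: float
    n: int
    groups: list[GroupRow] = field(default_factory=list)
    thresholds_months: tuple[int, ...] = DEFAULT_THRESHOLDS
    cumulative_accuracy: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mae_months": self.mae,
            "rmse_months": self.rmse,
            "groups": [
                {"age_years": f"[{g.year}, {g.year + 1})", "n": g.n,
                 "mae": g.mae, "rmse": g.rmse}
                for g in self.groups
            ],
            "cumulative_accuracy": {
                str(t): a
                for t, a in zip(self.thresholds_months, self.cumulative_accuracy)
            },
        }


def group_by_age(y_true, y_pred) -> list[GroupRow]:
    """Per-bin MAE/RMSE over half-open 1-year bins of the true age.

    Only populated bins are returned (empty bins are simply absent, the
    tabular analogue of printing "/").
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    if y_true.size == 0:
        return []
    years = np.floor(y_true / MONTHS_PER_YEAR).astype(int)
    rows: list[GroupRow] = []
    for year in np.unique(years):
        sel = years == year
        rows.append(
            GroupRow(
                year=int(year),
                n=int(sel.sum()),
                mae=mae(y_true[sel], y_pred[sel]),
                rmse=rmse(y_true[sel], y_pred[sel]),
            )
        )
    return rows


def cumulative_accuracy(
    y_true, y_pred, thresholds=DEFAULT_THRESHOLDS
) -> list[float]:
    """Fraction of samples with |error| <= t for each threshold t (months).

    The comparison is inclusive; the curve is nondecreasing in t and reaches
    1 at any threshold >= the maximum absolute error.
    """
    y_true, y_pred = _validate(y_true, y_pred)
    err = np.abs(y_true - y_pred)
    return [float(np.mean(err <= t)) for t in thresholds]


def evaluate(y_true, y_pred, thresholds=DEFAULT_THRESHOLDS) -> EvalReport:
    """Full evaluation report: overall MAE/RMSE, group table, accuracy curve."""
    y_true, y_pred = _validate(y_true, y_pred)
    return EvalReport(
        mae=mae(y_true, y_pred),
        rmse=rmse(y_true, y_pred),
        n=int(y_true.size),
        groups=group_by_age(y_true, y_pred),
        thresholds_months=tuple(thresholds),
        cumulative_accuracy=cumulative_accuracy(y_true, y_pred, thresholds),
    )


__all__ = [
    "mae",
    "rmse",
    "GroupRow",
    "EvalReport",
    "group_by_age",
    "cumulative_accuracy",
    "evaluate",
    "DEFAULT_THRESHOLDS",
]
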
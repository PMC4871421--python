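"""Reading, validation, imputation and writing of daily diary datasets.

A diary dataset is a per-patient multivariate daily series of visual
analogue scale (VAS) items on [0, 100].  Days absent from the input file
become all-missing rows so that every dataset lives on an equally spaced
daily grid (a prerequisite for lagged time-series models).

Missing cells are replaced by deterministic regression imputation: each
item is regressed, on the complete rows, on all other same-day items plus
a linear day-index term, and missing cells are replaced by the fitted
conditional mean.  An optional seeded residual draw can be added.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    FormatError,
    ImputationError,
    ValidationError,
)

#: Canonical item order used wherever a deterministic ordering is needed.
CANONICAL_ITEMS: tuple[str, ...] = (
    "emotional_intolerance",
    "food_impact",
    "restraint",
    "weight_concern",
    "fear_losing_control",
    "preoccupation_food",
)

VAS_MIN = 0.0
VAS_MAX = 100.0

_KEY_COLUMNS = ("patient_id", "group", "day")


@dataclass
class DiaryDataset:
    """Per-patient daily multivariate VAS series on a gap-free day grid.

    Attributes
    ----------
    patient_id : str
        Identifier of the patient the series belongs to.
    group : str
        Severity-group label, ``"HSS"`` or ``"LSS"``.
    items : tuple of str
        Ordered item names; columns of ``values``.
    values : ndarray, shape (T, n_items)
        Daily values in [0, 100]; missing cells are ``NaN``.  Row ``t``
        corresponds to day ``t + 1`` (1-based consecutive days).
    """

    patient_id: str
    group: str
    items: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.items = tuple(self.items)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.items):
            raise ValidationError(
                f"values must be (T, {len(self.items)}), got {self.values.shape}"
            )
        if self.values.shape[0] < 1:
            raise ValidationError("dataset must contain at least one day")
        if self.group not in ("HSS", "LSS"):
            raise ValidationError(f"group must be HSS or LSS, got {self.group!r}")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < VAS_MIN or finite.max() > VAS_MAX):
            raise ValidationError("non-missing values must lie in [0, 100]")

    @property
    def T(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def days(self) -> np.ndarray:
        """1-based consecutive day index."""
        return np.arange(1, self.T + 1)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (T, n_items) array, True where the cell is missing."""
        return np.isnan(self.values)

    @property
    def is_complete(self) -> bool:
        return not np.isnan(self.values).any()

    def series(self, item: str) -> np.ndarray:
        """Return the column for ``item`` (view, length T)."""
        try:
            j = self.items.index(item)
        except ValueError:
            raise KeyError(f"unknown item {item!r}") from None
        return self.values[:, j]

    def subset(self, items: Sequence[str]) -> "DiaryDataset":
        """New dataset restricted to ``items`` (in the given order)."""
        idx = [self.items.index(it) for it in items]
        return DiaryDataset(
            self.patient_id, self.group, tuple(items), self.values[:, idx].copy()
        )


@dataclass
class ImputationReport:
    """Provenance record of one :func:`impute_missing` run."""

    imputed_counts: dict[str, int]
    #: True where the cell was imputed (same shape as the dataset values).
    imputed_mask: np.ndarray
    #: per-item regression coefficients: intercept, other items, day term.
    coefficients: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def total_imputed(self) -> int:
        return int(sum(self.imputed_counts.values()))


def read_diary(path: str | Path, schema: Sequence[str] | None = None) -> DiaryDataset:
    """Read a wide-CSV diary file into a :class:`DiaryDataset`.

    The file must have a header ``patient_id,group,day,<item...>``; missing
    cells are empty fields or ``NA``.  Days absent from the file become
    all-missing rows so the returned day index is gap-free from day 1.

    Parameters
    ----------
    path : str or Path
        CSV file to read.
    schema : sequence of str, optional
        Item columns to keep, in order.  Defaults to every non-key column
        in file order.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, na_values=["NA", ""], dtype={"patient_id": str})
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as e:
        raise FormatError(f"{path}: cannot parse CSV: {e}") from e

    for col in _KEY_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")

    items = tuple(schema) if schema is not None else tuple(
        c for c in df.columns if c not in _KEY_COLUMNS
    )
    if len(items) == 0:
        raise FormatError(f"{path}: no item columns found")
    for it in items:
        if it not in df.columns:
            raise FormatError(f"{path}: item column {it!r} not in file")

    if df.empty:
        raise FormatError(f"{path}: no data rows")

    pid = str(df["patient_id"].iloc[0])
    group = str(df["group"].iloc[0])
    days = pd.to_numeric(df["day"], errors="coerce")
    if days.isna().any() or (days != days.astype(int)).any():
        raise ValidationError(f"{path}: non-integer day values")
    days = days.astype(int)
    if (days < 1).any():
        raise ValidationError(f"{path}: day indices must be >= 1")
    dup = days[days.duplicated()]
    if len(dup):
        raise ValidationError(f"{path}: duplicate day {int(dup.iloc[0])}")

    T = int(days.max())
    values = np.full((T, len(items)), np.nan)
    for row_pos, day in enumerate(days):
        for j, it in enumerate(items):
            raw = df[it].iloc[row_pos]
            if pd.isna(raw):
                continue
            try:
                v = float(raw)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"{path}: non-numeric value {raw!r} at day {day}, item {it!r}"
                ) from None
            if not (VAS_MIN <= v <= VAS_MAX):
                raise ValidationError(
                    f"{path}: value {v} out of [0, 100] at day {day}, item {it!r}"
                )
            values[day - 1, j] = v

    return DiaryDataset(pid, group, items, values)


def write_diary(d: DiaryDataset, path: str | Path) -> None:
    """Write ``d`` in the same wide-CSV dialect accepted by :func:`read_diary`."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(list(_KEY_COLUMNS) + list(d.items))
        for t in range(d.T):
            row = [d.patient_id, d.group, t + 1]
            for j in range(d.n_items):
                v = d.values[t, j]
                row.append("" if np.isnan(v) else format(v, "g"))
            w.writerow(row)


def _day_trend_fill(col: np.ndarray, days: np.ndarray) -> np.ndarray:
    """Fill NaNs in one column with a linear day-trend prediction."""
    obs = np.isfinite(col)
    out = col.copy()
    if obs.sum() >= 2 and np.ptp(days[obs]) > 0:
        b = np.polyfit(days[obs], col[obs], 1)
        out[~obs] = np.polyval(b, days[~obs])
    else:  # constant fallback
        out[~obs] = col[obs].mean()
    return out


def impute_missing(
    d: DiaryDataset,
    add_noise: bool = False,
    seed: int | None = None,
    max_missing_frac: float = 0.25,
    min_complete_rows: int = 10,
) -> tuple[DiaryDataset, ImputationReport]:
    """Replace missing cells by regression predictions.

    Each item with missing cells is regressed on all other items (same day)
    plus a linear day-index term, fitted on the complete rows.  Missing
    cells get the least-squares prediction; missing predictor values are
    pre-filled with a per-item day-trend estimate so that all-missing days
    can be completed too.  With ``add_noise`` a seeded resample of the
    fit residuals is added to each imputed cell.

    Returns the completed dataset (observed cells untouched) and an
    :class:`ImputationReport`.  Imputed values are clipped to [0, 100].
    """
    mask = d.missing_mask
    report = ImputationReport(
        imputed_counts={it: int(mask[:, j].sum()) for j, it in enumerate(d.items)},
        imputed_mask=mask.copy(),
    )
    if not mask.any():
        return d, report

    values = d.values
    days = d.days.astype(float)
    complete = ~mask.any(axis=1)
    n_complete = int(complete.sum())

    for j, it in enumerate(d.items):
        n_miss = int(mask[:, j].sum())
        if n_miss == 0:
            continue
        if n_miss == d.T:
            raise ImputationError(f"item {it!r} is entirely missing")
        if n_miss / d.T > max_missing_frac:
            raise ImputationError(
                f"item {it!r}: {n_miss}/{d.T} missing exceeds cap "
                f"{max_missing_frac:.0%}"
            )
        if n_complete < min_complete_rows:
            raise ImputationError(
                f"only {n_complete} complete rows; need >= {min_complete_rows}"
            )

    # Stage 1: day-trend fill gives every predictor a provisional value.
    prefill = np.column_stack(
        [_day_trend_fill(values[:, j], days) for j in range(d.n_items)]
    )

    rng = np.random.default_rng(seed)
    out = values.copy()
    for j, it in enumerate(d.items):
        rows = np.where(mask[:, j])[0]
        if rows.size == 0:
            continue
        others = [m for m in range(d.n_items) if m != j]
        X = np.column_stack(
            [np.ones(n_complete), values[complete][:, others], days[complete]]
        )
        y = values[complete, j]
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        report.coefficients[it] = beta
        Xm = np.column_stack(
            [np.ones(rows.size), prefill[rows][:, others], days[rows]]
        )
        pred = Xm @ beta
        if add_noise:
            pred = pred + rng.choice(resid, size=rows.size, replace=True)
        out[rows, j] = np.clip(pred, VAS_MIN, VAS_MAX)

    return DiaryDataset(d.patient_id, d.group, d.items, out), report
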
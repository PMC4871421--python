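"""Linear time trends and same-day correlations.

The trend of an item is the standardised coefficient of a simple regression
of the (z-scored) series on the (z-scored) day index — algebraically the
Pearson correlation between series and day index — with a two-sided t test
on T - 2 degrees of freedom.  Same-day association is the Pearson
correlation of two items restricted to the analysis window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .errors import DegenerateSeriesError, LengthError
from .stationarity import AnalysisWindow


@dataclass
class TrendResult:
    item: str
    beta: float          # standardised slope, equals corr(series, day index)
    p_value: float
    T: int
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass
class CorrelationResult:
    item_x: str
    item_y: str
    r: float
    p_value: float
    window: AnalysisWindow | None
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def _pearson_with_t_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    n = len(x)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise DegenerateSeriesError("constant series")
    r = float(np.clip((xc @ yc) / denom, -1.0, 1.0))
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1 - r * r))
    return r, float(2 * t_dist.sf(abs(t), n - 2))


def linear_trend(x: np.ndarray, item: str = "", alpha: float = 0.05) -> TrendResult:
    """Standardised linear time-trend coefficient of a daily series."""
    x = np.asarray(x, dtype=float).ravel()
    day = np.arange(1, len(x) + 1, dtype=float)
    finite = np.isfinite(x)
    x, day = x[finite], day[finite]  # pairwise deletion keeps day alignment
    T = len(x)
    if T < 3:
        raise LengthError("need at least 3 observations for a trend")
    beta, p = _pearson_with_t_test(x, day)
    return TrendResult(item=item, beta=beta, p_value=p, T=T, alpha=alpha)


def same_day_correlation(
    x: np.ndarray,
    y: np.ndarray,
    window: AnalysisWindow | None = None,
    items: tuple[str, str] = ("x", "y"),
    alpha: float = 0.05,
) -> CorrelationResult:
    """Pearson correlation of two same-day series on an analysis window."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y):
        raise LengthError("series lengths differ")
    if window is not None:
        x, y = window.slice(x), window.slice(y)
    if len(x) < 3:
        raise LengthError("window must contain at least 3 days")
    r, p = _pearson_with_t_test(x, y)
    return CorrelationResult(
        item_x=items[0], item_y=items[1], r=r, p_value=p, window=window, alpha=alpha
    )


def cohort_trend_summary(
    results: Mapping[str, Mapping[str, TrendResult]],
    groups: Mapping[str, str],
) -> pd.DataFrame:
    """Per-group percentages of significant (and significantly negative) trends.

    Parameters
    ----------
    results : mapping patient -> item -> TrendResult
    groups : mapping patient -> group label

    Returns a DataFrame indexed by (group, item) with columns
    ``pct_significant`` and ``pct_significant_negative`` (percent of
    patients in the group, e.g. 88.9).
    """
    rows = []
    group_order = [g for g in ("HSS", "LSS") if g in set(groups.values())]
    group_order += sorted(set(groups.values()) - set(group_order))
    items: list[str] = []
    for per_item in results.values():
        for it in per_item:
            if it not in items:
                items.append(it)
    for g in group_order:
        patients = [p for p in results if groups.get(p) == g]
        if not patients:
            continue
        for it in items:
            have = [results[p][it] for p in patients if it in results[p]]
            if not have:
                continue
            n = len(have)
            n_sig = sum(r.significant for r in have)
            n_neg = sum(r.significant and r.beta < 0 for r in have)
            rows.append(
                {
                    "group": g,
                    "item": it,
                    "n_patients": n,
                    "pct_significant": 100.0 * n_sig / n,
                    "pct_significant_negative": 100.0 * n_neg / n,
                }
            )
    return pd.DataFrame(rows).set_index(["group", "item"])
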
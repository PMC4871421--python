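"""Augmented Dickey-Fuller testing and stationary-window determination.

The ADF regression is

    dx_t = phi * x_{t-1} + sum_{j=1..q} beta_j * dx_{t-j} + deterministics + e_t

with the augmentation order ``q`` chosen by minimum AIC over ``0..max_lags``
on a common estimation sample.  The test statistic is the t-ratio of ``phi``
and its p-value comes from MacKinnon's response-surface approximation
(coefficients below are MacKinnon's published values for a single series).

Because per-patient treatment phases differ, the analysis window is found
by a deterministic scan: if the focus items are stationary on the full
range, the full range is used; otherwise start/end offsets on a step grid
are searched for the longest window on which both focus items reject the
unit root.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .diary_io import DiaryDataset
from .errors import (
    DegenerateSeriesError,
    LengthError,
    NoStationaryWindowError,
    ParameterError,
)

# MacKinnon response-surface coefficients (single series), small-p /
# large-p polynomial branches in the tau statistic.
_MACKINNON = {
    "c": {
        "tau_star": -1.61,
        "tau_min": -18.83,
        "tau_max": 2.74,
        "smallp": np.array([2.1659, 1.4412, 0.038269]),
        "largep": np.array([1.7339, 0.93202, -0.12745, -0.010368]),
    },
    "ct": {
        "tau_star": -2.89,
        "tau_min": -16.18,
        "tau_max": 0.7,
        "smallp": np.array([3.2512, 1.6047, 0.049588]),
        "largep": np.array([2.5261, 0.61654, -0.37956, -0.060285]),
    },
}

_VARIANTS = {"c": 1, "constant": 1, "ct": 2, "constant+trend": 2}


@dataclass
class ADFResult:
    """Outcome of one augmented Dickey-Fuller test."""

    statistic: float
    lags_used: int
    variant: str  # "c" (constant) or "ct" (constant + trend)
    p_value: float
    alpha: float
    nobs: int

    @property
    def reject_unit_root(self) -> bool:
        return self.p_value < self.alpha


@dataclass
class AnalysisWindow:
    """Inclusive, 1-based day window on the diary index."""

    start_day: int
    end_day: int
    stationary_items: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (1 <= self.start_day <= self.end_day):
            raise ParameterError(
                f"invalid window ({self.start_day}, {self.end_day})"
            )
        self.stationary_items = tuple(self.stationary_items)

    @property
    def length(self) -> int:
        return self.end_day - self.start_day + 1

    def slice(self, x: np.ndarray) -> np.ndarray:
        """Restrict a length-T array (axis 0) to this window."""
        return x[self.start_day - 1 : self.end_day]


def mackinnon_pvalue(tau: float, variant: str = "c") -> float:
    """MacKinnon (1994) approximate asymptotic p-value for an ADF tau."""
    key = "ct" if _VARIANTS.get(variant, 1) == 2 else "c"
    tab = _MACKINNON[key]
    if tau > tab["tau_max"]:
        return 1.0
    if tau < tab["tau_min"]:
        return 0.0
    coef = tab["smallp"] if tau <= tab["tau_star"] else tab["largep"]
    return float(norm.cdf(np.polyval(coef[::-1], tau)))


def default_max_lags(T: int) -> int:
    """Schwert rule: floor(12 * (T/100)^(1/4))."""
    return int(np.floor(12.0 * (T / 100.0) ** 0.25))


def _ols_aic(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    n = len(y)
    ssr = float(resid @ resid)
    llf = -n / 2.0 * (np.log(2 * np.pi) + np.log(ssr / n) + 1)
    return beta, -2 * llf + 2 * X.shape[1]


def adf_test(
    x: np.ndarray,
    variant: str = "c",
    max_lags: int | None = None,
    alpha: float = 0.05,
) -> ADFResult:
    """Augmented Dickey-Fuller unit-root test.

    Parameters
    ----------
    x : array-like, 1-d
        Series to test (no missing values).
    variant : {"c", "ct"}
        Deterministic terms: constant, or constant plus linear trend.
    max_lags : int, optional
        Upper bound for the AIC search over augmentation lags.  Defaults
        to the Schwert rule, capped so the regression stays estimable.
    alpha : float
        Significance level for the rejection flag.

    Rejection (``p < alpha``) indicates stationarity.
    """
    x = np.asarray(x, dtype=float).ravel()
    if np.isnan(x).any():
        raise ParameterError("series contains missing values")
    if _VARIANTS.get(variant) is None:
        raise ParameterError(f"unknown variant {variant!r}")
    ntrend = _VARIANTS[variant]
    T = len(x)
    if np.ptp(x) == 0:
        raise DegenerateSeriesError("series is constant")
    if max_lags is None:
        max_lags = default_max_lags(T)
    max_lags = max(0, min(max_lags, T // 2 - ntrend - 1))
    if T - max_lags - 1 < 15:
        if max_lags > 0 and T - 1 >= 15:
            max_lags = T - 1 - 15
        else:
            raise LengthError(f"series too short for ADF (T={T})")

    dx = np.diff(x)

    def design(q: int, n: int) -> tuple[np.ndarray, np.ndarray]:
        # regression sample: last n observations of dx
        t0 = len(dx) - n
        y = dx[t0:]
        cols = [x[t0 : t0 + n]]  # lagged level x_{t-1}
        for j in range(1, q + 1):
            cols.append(dx[t0 - j : t0 - j + n])
        cols.append(np.ones(n))
        if ntrend == 2:
            cols.append(np.arange(t0 + 1, t0 + n + 1, dtype=float))
        return np.column_stack(cols), y

    # lag choice by AIC on the common sample (max_lags reserved)
    n_common = len(dx) - max_lags
    best_q, best_aic = 0, np.inf
    for q in range(0, max_lags + 1):
        X, y = design(q, n_common)
        _, aic = _ols_aic(X, y)
        if aic < best_aic:
            best_q, best_aic = q, aic

    # final fit on the longest sample the chosen lag allows
    n_fit = len(dx) - best_q
    X, y = design(best_q, n_fit)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n_fit - X.shape[1]
    if dof <= 0:
        raise LengthError("not enough observations after lag truncation")
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(sigma2 * xtx_inv[0, 0])
    tau = float(beta[0] / se)
    p = mackinnon_pvalue(tau, variant)
    return ADFResult(
        statistic=tau,
        lags_used=best_q,
        variant="ct" if ntrend == 2 else "c",
        p_value=p,
        alpha=alpha,
        nobs=n_fit,
    )


def _window_passes(
    d: DiaryDataset,
    items: Sequence[str],
    start: int,
    end: int,
    variant: str,
    max_lags: int | None,
    alpha: float,
) -> bool:
    for it in items:
        seg = d.series(it)[start - 1 : end]
        try:
            if not adf_test(seg, variant=variant, max_lags=max_lags, alpha=alpha).reject_unit_root:
                return False
        except (LengthError, DegenerateSeriesError):
            return False
    return True


def find_stationary_window(
    d: DiaryDataset,
    focus_items: Sequence[str],
    step: int = 7,
    alpha: float = 0.05,
    T_min: int = 30,
    variant: str = "c",
    max_lags: int | None = None,
) -> AnalysisWindow:
    """Find the longest window on which all focus items are stationary.

    If every focus item rejects the unit root on the full range, the full
    range is returned.  Otherwise candidate windows with start offsets
    0, step, 2*step, ... and end offsets likewise are scanned; the longest
    window of length >= ``T_min`` on which all focus items reject is
    returned, ties broken toward the earliest start.

    Raises
    ------
    NoStationaryWindowError
        If no candidate window qualifies (the patient is excluded).
    """
    if step < 1:
        raise ParameterError("step must be >= 1")
    if T_min < 1:
        raise ParameterError("T_min must be >= 1")
    for it in focus_items:
        if np.isnan(d.series(it)).any():
            raise ParameterError(f"focus item {it!r} has missing values; impute first")

    T = d.T
    focus = tuple(focus_items)
    if T >= T_min and _window_passes(d, focus, 1, T, variant, max_lags, alpha):
        return AnalysisWindow(1, T, focus)

    starts = list(range(1, T + 1, step))
    ends = list(range(T, 0, -step))
    candidates = [
        (s, e)
        for s in starts
        for e in ends
        if e - s + 1 >= T_min and not (s == 1 and e == T)
    ]
    # longest first, then earliest start
    candidates.sort(key=lambda se: (-(se[1] - se[0] + 1), se[0]))
    for s, e in candidates:
        if _window_passes(d, focus, s, e, variant, max_lags, alpha):
            return AnalysisWindow(s, e, focus)
    raise NoStationaryWindowError(
        f"no window of length >= {T_min} is stationary for {focus}"
    )


def screen_items(
    d: DiaryDataset,
    window: AnalysisWindow,
    items: Sequence[str],
    alpha: float = 0.05,
    variant: str = "c",
    max_lags: int | None = None,
) -> dict[str, bool]:
    """ADF-screen each item on ``window``; True means stationary (usable)."""
    out: dict[str, bool] = {}
    for it in items:
        seg = window.slice(d.series(it))
        try:
            out[it] = adf_test(
                seg, variant=variant, max_lags=max_lags, alpha=alpha
            ).reject_unit_root
        except (LengthError, DegenerateSeriesError):
            out[it] = False
    return out
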
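"""VAR(k) estimation, lag-order selection and the diagnostic loop.

Estimation is multivariate least squares with an intercept, which is
algebraically identical to equation-by-equation OLS.  Lag order is chosen
by four information criteria (AIC, FPE, HQ, SC) computed on a common
effective sample; a consensus order is the one picked by the majority of
criteria, ties broken toward the most parsimonious order.  Diagnostics are
the companion-matrix eigenvalue stability condition and an adjusted
(small-sample) Portmanteau test for residual autocorrelation; when either
fails the model is re-estimated at the next higher order.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import chi2, t as t_dist

from .errors import (
    LengthError,
    NoValidModelError,
    ParameterError,
    RankError,
)
from .stationarity import AnalysisWindow

CRITERIA = ("aic", "fpe", "hq", "sc")


@dataclass
class VARModel:
    """A fitted VAR(k) with intercept.

    ``coefs[j-1][i, m]`` is the weight of variable ``m`` at lag ``j`` in
    the equation for variable ``i``.
    """

    k: int
    intercept: np.ndarray           # (K,)
    coefs: np.ndarray               # (k, K, K)
    sigma_u: np.ndarray             # (K, K), df-adjusted
    resid: np.ndarray               # (T_eff, K)
    T_eff: int
    items: tuple[str, ...] = ()
    window: AnalysisWindow | None = None
    #: standard errors / t-ratios / p-values aligned with the stacked
    #: parameter matrix [intercept; lag1; ...; lagk], shape (1+K*k, K).
    se_params: np.ndarray | None = None
    tvalues: np.ndarray | None = None
    pvalues: np.ndarray | None = None
    _zz_inv: np.ndarray | None = field(default=None, repr=False)
    _y: np.ndarray | None = field(default=None, repr=False)

    @property
    def K(self) -> int:
        return len(self.intercept)

    @property
    def df_resid(self) -> int:
        return self.T_eff - self.K * self.k - 1

    def companion_matrix(self) -> np.ndarray:
        """(K*k, K*k) companion form of the lag polynomial."""
        K, k = self.K, self.k
        C = np.zeros((K * k, K * k))
        C[:K, :] = np.concatenate(self.coefs, axis=1)
        if k > 1:
            C[K:, :-K] = np.eye(K * (k - 1))
        return C

    def eigenvalue_moduli(self) -> np.ndarray:
        return np.sort(np.abs(np.linalg.eigvals(self.companion_matrix())))[::-1]

    @property
    def is_stable(self) -> bool:
        return bool(self.eigenvalue_moduli().max() < 1.0)

    def significant_coefficients(self, alpha: float = 0.05) -> list[dict]:
        """Lag coefficients with two-sided p < alpha.

        Returns records with equation (response item), lag, regressor item,
        estimate and p-value — the "(t-x)"-tagged entries of a report.
        """
        if self.pvalues is None:
            return []
        out = []
        names = self.items or tuple(f"y{i+1}" for i in range(self.K))
        for i in range(self.K):           # equation
            for j in range(self.k):       # lag
                for m in range(self.K):   # regressor
                    row = 1 + j * self.K + m
                    if self.pvalues[row, i] < alpha:
                        out.append(
                            {
                                "equation": names[i],
                                "lag": j + 1,
                                "regressor": names[m],
                                "estimate": float(self.coefs[j, i, m]),
                                "p_value": float(self.pvalues[row, i]),
                            }
                        )
        return out

    def to_dict(self) -> dict:
        d = {
            "k": self.k,
            "items": list(self.items),
            "intercept": self.intercept.tolist(),
            "coefs": self.coefs.tolist(),
            "sigma_u": self.sigma_u.tolist(),
            "T_eff": self.T_eff,
            "stable": self.is_stable,
        }
        if self.se_params is not None:
            d["se_params"] = self.se_params.tolist()
        return d


@dataclass
class LagSelection:
    """Orders chosen by each criterion over 1..p_max, plus the consensus."""

    by_criterion: dict[str, int]
    consensus: int
    p_max: int
    criterion_values: dict[str, list[float]] = field(default_factory=dict)


@dataclass
class DiagnosticsResult:
    """Stability and residual-whiteness diagnostics of a fitted VAR."""

    eigenvalue_moduli: np.ndarray
    portmanteau_statistic: float
    portmanteau_df: int
    portmanteau_p: float
    residual_acf: np.ndarray  # (h, K, K)

    @property
    def stable(self) -> bool:
        return bool(self.eigenvalue_moduli.max() < 1.0)

    def passes(self, alpha: float = 0.05) -> bool:
        return self.stable and self.portmanteau_p >= alpha


def _design(y: np.ndarray, k: int, offset: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Stack [1, y_{t-1}, ..., y_{t-k}] for t = offset..T-1 (offset >= k)."""
    T, K = y.shape
    start = max(k, offset)
    rows = T - start
    Z = np.ones((rows, 1 + K * k))
    for j in range(1, k + 1):
        Z[:, 1 + (j - 1) * K : 1 + j * K] = y[start - j : T - j]
    return Z, y[start:]


def fit_var(
    y: np.ndarray,
    k: int,
    items: Sequence[str] = (),
    window: AnalysisWindow | None = None,
) -> VARModel:
    """Fit a VAR(k) with intercept by multivariate least squares.

    Parameters
    ----------
    y : ndarray, shape (T, K)
        Complete multivariate series (rows are consecutive days).
    k : int
        Lag order, >= 1.

    The residual covariance uses the degrees-of-freedom adjusted divisor
    ``T_eff - K*k - 1``; standard errors and two-sided p-values are stored
    per parameter for the significance flags of the report.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 2:
        raise ParameterError("y must be 2-d (T, K)")
    if np.isnan(y).any():
        raise ParameterError("y contains missing values")
    if k < 1:
        raise ParameterError("order k must be >= 1")
    T, K = y.shape
    T_eff = T - k
    n_params = K * k + 1
    if T_eff <= n_params:
        raise LengthError(
            f"T_eff={T_eff} too small for K={K}, k={k} ({n_params} params/eq)"
        )

    Z, Y = _design(y, k)
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise RankError("design matrix is rank deficient (constant/collinear series)")
    B, *_ = np.linalg.lstsq(Z, Y, rcond=None)
    E = Y - Z @ B
    df = T_eff - n_params
    sigma_u = (E.T @ E) / df
    zz_inv = np.linalg.inv(Z.T @ Z)

    se = np.sqrt(np.outer(np.diag(zz_inv), np.diag(sigma_u)))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = B / se
    pvals = 2 * t_dist.sf(np.abs(tvals), df)

    coefs = np.stack(
        [B[1 + j * K : 1 + (j + 1) * K].T for j in range(k)], axis=0
    )
    return VARModel(
        k=k,
        intercept=B[0].copy(),
        coefs=coefs,
        sigma_u=sigma_u,
        resid=E,
        T_eff=T_eff,
        items=tuple(items),
        window=window,
        se_params=se,
        tvalues=np.asarray(tvals),
        pvalues=np.asarray(pvals),
        _zz_inv=zz_inv,
        _y=y,
    )


def _criterion_values(y: np.ndarray, p_max: int) -> dict[str, list[float]]:
    """Criterion value per order 1..p_max on the common sample."""
    T, K = y.shape
    Tc = T - p_max
    vals: dict[str, list[float]] = {c: [] for c in CRITERIA}
    for m in range(1, p_max + 1):
        Z, Y = _design(y, m, offset=p_max)
        B, *_ = np.linalg.lstsq(Z, Y, rcond=None)
        E = Y - Z @ B
        sigma_ml = (E.T @ E) / Tc
        sign, logdet = np.linalg.slogdet(sigma_ml)
        if sign <= 0:
            logdet = -np.inf
        n_lag_params = m * K * K
        vals["aic"].append(logdet + 2.0 * n_lag_params / Tc)
        vals["hq"].append(logdet + 2.0 * np.log(np.log(Tc)) * n_lag_params / Tc)
        vals["sc"].append(logdet + np.log(Tc) * n_lag_params / Tc)
        fpe_factor = K * np.log((Tc + K * m + 1) / (Tc - K * m - 1))
        vals["fpe"].append(logdet + fpe_factor)
    return vals


def select_lag_order(y: np.ndarray, p_max: int) -> LagSelection:
    """Choose the VAR order by AIC, FPE, HQ and SC on a common sample.

    All candidates 1..p_max are fitted on the same effective sample (the
    first ``p_max`` observations are reserved as presample).  The consensus
    order is the one named by the most criteria; ties go to the smallest
    order among the tied ones.
    """
    y = np.asarray(y, dtype=float)
    if p_max < 1:
        raise ParameterError("p_max must be >= 1")
    T, K = y.shape
    if T - p_max <= K * p_max + 1:
        raise LengthError(f"T={T} too short to compare orders up to {p_max}")
    vals = _criterion_values(y, p_max)
    by_crit = {c: int(np.argmin(vals[c])) + 1 for c in CRITERIA}
    counts = Counter(by_crit.values())
    top = max(counts.values())
    consensus = min(o for o, c in counts.items() if c == top)
    return LagSelection(
        by_criterion=by_crit,
        consensus=consensus,
        p_max=p_max,
        criterion_values=vals,
    )


def residual_autocorrelations(resid: np.ndarray, h: int) -> np.ndarray:
    """Residual autocorrelation matrices R_1..R_h, shape (h, K, K)."""
    T, K = resid.shape
    u = resid - resid.mean(axis=0)
    C0 = (u.T @ u) / T
    d = np.sqrt(np.diag(C0))
    acf = np.empty((h, K, K))
    for i in range(1, h + 1):
        Ci = (u[i:].T @ u[:-i]) / T
        acf[i - 1] = Ci / np.outer(d, d)
    return acf


def run_diagnostics(m: VARModel, h: int) -> DiagnosticsResult:
    """Eigenvalue stability condition plus adjusted Portmanteau test.

    The adjusted (small-sample) statistic is

        Q_h = T^2 * sum_{i=1..h} tr(C_i' C_0^{-1} C_i C_0^{-1}) / (T - i)

    referred to chi-square with K^2 * (h - k) degrees of freedom.
    """
    if h <= m.k:
        raise ParameterError(f"h={h} must exceed the model order k={m.k}")
    u = m.resid - m.resid.mean(axis=0)
    T, K = u.shape
    if h >= T:
        raise ParameterError(f"h={h} must be < T_eff={T}")
    C0 = (u.T @ u) / T
    C0_inv = np.linalg.inv(C0)
    Q = 0.0
    for i in range(1, h + 1):
        Ci = (u[i:].T @ u[:-i]) / T
        Q += np.trace(Ci.T @ C0_inv @ Ci @ C0_inv) / (T - i)
    Q *= T * T
    df = K * K * (h - m.k)
    p = float(chi2.sf(Q, df))
    return DiagnosticsResult(
        eigenvalue_moduli=m.eigenvalue_moduli(),
        portmanteau_statistic=float(Q),
        portmanteau_df=df,
        portmanteau_p=p,
        residual_acf=residual_autocorrelations(m.resid, h),
    )


def default_p_max(T_w: int) -> int:
    return max(1, min(10, T_w // 10))


def default_portmanteau_h(T_w: int) -> int:
    return min(16, T_w // 4)


def fit_with_adjustment(
    y: np.ndarray,
    selection: LagSelection | None = None,
    p_max: int | None = None,
    h: int | None = None,
    alpha: float = 0.05,
    items: Sequence[str] = (),
    window: AnalysisWindow | None = None,
) -> tuple[VARModel, DiagnosticsResult, list[dict]]:
    """Fit starting at the consensus order, escalating until diagnostics pass.

    Starting from the consensus of ``selection`` (computed here when not
    given), the order is incremented while the Portmanteau test rejects
    whiteness at ``alpha`` or the stability condition fails, up to
    ``p_max``.  Returns the first passing model, its diagnostics and an
    audit trail of the attempts.

    Raises
    ------
    NoValidModelError
        If no order in [consensus, p_max] passes both checks.
    """
    y = np.asarray(y, dtype=float)
    T = y.shape[0]
    if p_max is None:
        p_max = selection.p_max if selection is not None else default_p_max(T)
    if selection is None:
        selection = select_lag_order(y, p_max)
    if h is None:
        h = default_portmanteau_h(T)

    trail: list[dict] = []
    for k in range(selection.consensus, p_max + 1):
        try:
            model = fit_var(y, k, items=items, window=window)
            h_eff = min(max(h, k + 2), model.T_eff - 1)
            if h_eff <= k:
                raise ParameterError("window too short for diagnostics")
            diag = run_diagnostics(model, h_eff)
        except (LengthError, RankError, ParameterError) as e:
            trail.append({"order": k, "error": str(e)})
            continue
        entry = {
            "order": k,
            "stable": diag.stable,
            "portmanteau_p": diag.portmanteau_p,
        }
        trail.append(entry)
        if diag.passes(alpha):
            return model, diag, trail
    raise NoValidModelError(
        f"no order in [{selection.consensus}, {p_max}] passes diagnostics"
    )
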
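"""Granger causality, impulse responses with bootstrap bands, and FEVD.

The Granger test for a bivariate VAR(k) places k zero restrictions on the
cause-variable lags in the effect equation; the Wald statistic divided by
k is referred to an F distribution with df1 = k and

    df2 = 2 * T_eff - 4k - 2

where T_eff is the effective sample size (window length minus k).

Impulse responses use the moving-average recursion
Phi_0 = I, Phi_i = sum_{j<=min(i,k)} Phi_{i-j} A_j; orthogonalised
responses multiply by the lower Cholesky factor of the residual covariance
under a chosen variable ordering (Granger-direction guided).  Confidence
bands come from a residual-based recursive bootstrap with Hall percentile
intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import f as f_dist

from .errors import (
    BootstrapError,
    ParameterError,
    StabilityError,
    UnsupportedDimensionError,
)
from .var_core import VARModel, fit_var

logger = logging.getLogger(__name__)


@dataclass
class GrangerResult:
    """Directed Granger causality test outcome."""

    cause: str
    effect: str
    F: float
    df1: int
    df2: int
    p_value: float
    alpha: float = 0.05
    #: Wald chi-square form of the same restriction set (= F * df1).
    wald: float = 0.0

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass
class IRFBands:
    """Bootstrap confidence bands for an IRF path array."""

    lower: np.ndarray  # (H+1, K, K)
    upper: np.ndarray
    method: str
    level: float
    B_used: int
    n_dropped: int
    seed: int | None = None

    def significant_at(self, h: int, response: int, impulse: int) -> bool:
        """True when the band at horizon h excludes zero."""
        lo = self.lower[h, response, impulse]
        up = self.upper[h, response, impulse]
        return bool(lo > 0.0 or up < 0.0)


@dataclass
class DynamicsResult:
    """IRF paths (plain or orthogonalised) with accumulated sums and bands.

    ``irf[h, i, m]`` is the response of variable ``i`` at horizon ``h`` to
    a one-time unit (or one-standard-deviation, if orthogonalised) shock in
    variable ``m``.
    """

    irf: np.ndarray                   # (H+1, K, K)
    orthogonalized: bool
    ordering: tuple[str, ...]
    items: tuple[str, ...]
    bands: IRFBands | None = None
    accumulated_bands: IRFBands | None = None

    @property
    def horizon(self) -> int:
        return self.irf.shape[0] - 1

    @property
    def accumulated_irf(self) -> np.ndarray:
        return np.cumsum(self.irf, axis=0)

    def path(self, response: str, impulse: str) -> np.ndarray:
        i = self.items.index(response)
        m = self.items.index(impulse)
        return self.irf[:, i, m]


@dataclass
class FEVDResult:
    """Forecast-error variance shares under an orthogonalisation ordering.

    ``proportions[h-1, j, m]`` is the share of the h-step forecast-error
    variance of variable ``j`` attributable to innovations in ``m``.
    """

    proportions: np.ndarray  # (H, K, K)
    ordering: tuple[str, ...]
    items: tuple[str, ...] = ()

    @property
    def horizon(self) -> int:
        return self.proportions.shape[0]

    def share(self, effect: str, cause: str, h: int | None = None) -> float:
        """Variance share of ``effect`` explained by ``cause`` at step h."""
        if h is None:
            h = self.horizon
        j = self.items.index(effect)
        m = self.items.index(cause)
        return float(self.proportions[h - 1, j, m])


def granger_df2(T_eff: int, k: int) -> int:
    """Second F degree of freedom for a bivariate VAR: 2*T_eff - 4k - 2."""
    return 2 * T_eff - 4 * k - 2


def granger_pvalue(F: float, df1: int, df2: int) -> float:
    """Upper-tail F probability P(F_{df1,df2} >= F)."""
    return float(f_dist.sf(F, df1, df2))


def granger_test(
    m: VARModel, cause: str, effect: str, alpha: float = 0.05
) -> GrangerResult:
    """Test whether ``cause`` Granger-causes ``effect`` in a bivariate VAR.

    The k coefficients of the cause lags in the effect equation are tested
    jointly with a Wald statistic; F = Wald / k is referred to
    F(k, 2*T_eff - 4k - 2).
    """
    if m.K != 2:
        raise UnsupportedDimensionError("Granger test implemented for K=2 only")
    if cause == effect:
        raise ParameterError("cause and effect must differ")
    names = list(m.items) if m.items else ["y1", "y2"]
    try:
        ci = names.index(cause)
        ei = names.index(effect)
    except ValueError as e:
        raise ParameterError(f"unknown item: {e}") from None
    if m._zz_inv is None:
        raise ParameterError("model lacks design information; refit with fit_var")

    k = m.k
    rows = np.array([1 + j * m.K + ci for j in range(k)])  # cause-lag params
    b = np.array([m.coefs[j, ei, ci] for j in range(k)])
    V = m.sigma_u[ei, ei] * m._zz_inv[np.ix_(rows, rows)]
    wald = float(b @ np.linalg.solve(V, b))
    F = wald / k
    df2 = granger_df2(m.T_eff, k)
    if df2 <= 0:
        raise ParameterError("nonpositive df2; series too short for this order")
    p = granger_pvalue(F, k, df2)
    return GrangerResult(
        cause=cause, effect=effect, F=F, df1=k, df2=df2,
        p_value=p, alpha=alpha, wald=wald,
    )


def _ma_coefficients(coefs: np.ndarray, H: int) -> np.ndarray:
    """Phi_0..Phi_H from lag matrices, shape (H+1, K, K)."""
    k, K, _ = coefs.shape
    phi = np.zeros((H + 1, K, K))
    phi[0] = np.eye(K)
    for i in range(1, H + 1):
        acc = np.zeros((K, K))
        for j in range(1, min(i, k) + 1):
            acc += phi[i - j] @ coefs[j - 1]
        phi[i] = acc
    return phi


def _ordered_cholesky(sigma: np.ndarray, perm: np.ndarray) -> np.ndarray:
    """Cholesky factor of sigma under a variable ordering, in original index."""
    L = np.linalg.cholesky(sigma[np.ix_(perm, perm)])
    P = np.zeros_like(L)
    P[np.ix_(perm, perm)] = L
    return P


def _resolve_ordering(
    items: tuple[str, ...], ordering: tuple[str, ...] | None
) -> tuple[tuple[str, ...], np.ndarray]:
    if ordering is None:
        ordering = items
    if sorted(ordering) != sorted(items):
        raise ParameterError(f"ordering {ordering} is not a permutation of {items}")
    perm = np.array([items.index(o) for o in ordering])
    return tuple(ordering), perm


def compute_irf(
    m: VARModel,
    H: int = 10,
    orthogonalized: bool = False,
    ordering: tuple[str, ...] | None = None,
) -> DynamicsResult:
    """Impulse response paths over horizons 0..H.

    Plain responses are the moving-average matrices (identity at horizon 0);
    orthogonalised responses post-multiply by the lower Cholesky factor of
    the residual covariance under ``ordering``.
    """
    if H < 1:
        raise ParameterError("H must be >= 1")
    if not m.is_stable:
        raise StabilityError("IRF requires a stable model")
    items = m.items or tuple(f"y{i+1}" for i in range(m.K))
    ordering, perm = _resolve_ordering(items, ordering)
    phi = _ma_coefficients(m.coefs, H)
    if orthogonalized:
        P = _ordered_cholesky(m.sigma_u, perm)
        phi = phi @ P
    return DynamicsResult(
        irf=phi, orthogonalized=orthogonalized, ordering=ordering, items=items
    )


def choose_ordering(
    g_xy: GrangerResult,
    g_yx: GrangerResult,
    default: tuple[str, ...],
) -> tuple[str, ...]:
    """Pick the orthogonalisation ordering from the Granger directions.

    If exactly one direction is significant its cause variable goes first;
    otherwise the default (canonical) ordering is returned and a warning
    logged.
    """
    if {g_xy.cause, g_xy.effect} != {g_yx.cause, g_yx.effect}:
        raise ParameterError("the two tests must concern the same variable pair")
    if g_xy.significant and not g_yx.significant:
        return (g_xy.cause, g_xy.effect)
    if g_yx.significant and not g_xy.significant:
        return (g_yx.cause, g_yx.effect)
    which = "both" if g_xy.significant else "neither"
    logger.warning(
        "%s Granger direction significant for (%s, %s); using default ordering %s",
        which, g_xy.cause, g_xy.effect, default,
    )
    return tuple(default)


def _simulate_bootstrap_paths(
    m: VARModel, y: np.ndarray, idx: np.ndarray, u_centered: np.ndarray
) -> np.ndarray:
    """Rebuild B series from resampled residuals; returns (B, T, K)."""
    B_reps = idx.shape[0]
    T, K = y.shape
    k = m.k
    ystar = np.empty((B_reps, T, K))
    ystar[:, :k] = y[:k]
    A = m.coefs  # (k, K, K)
    nu = m.intercept
    for t in range(k, T):
        acc = np.broadcast_to(nu, (B_reps, K)).copy()
        for j in range(1, k + 1):
            acc += ystar[:, t - j] @ A[j - 1].T
        acc += u_centered[idx[:, t - k]]
        ystar[:, t] = acc
    return ystar


def _batched_var_fit(
    ystar: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares VAR(k) for each replicate.

    Returns (coefs (B,k,K,K), sigma_u (B,K,K), ok mask) where failed
    replicates (singular normal equations) are flagged False.
    """
    B_reps, T, K = ystar.shape
    T_eff = T - k
    P = 1 + K * k
    Z = np.ones((B_reps, T_eff, P))
    for j in range(1, k + 1):
        Z[:, :, 1 + (j - 1) * K : 1 + j * K] = ystar[:, k - j : T - j]
    Y = ystar[:, k:]
    G = np.einsum("btp,btq->bpq", Z, Z)
    ZY = np.einsum("btp,btk->bpk", Z, Y)
    ok = np.ones(B_reps, dtype=bool)
    Bmat = np.zeros((B_reps, P, K))
    try:
        Bmat = np.linalg.solve(G, ZY)
        ok &= np.isfinite(Bmat).all(axis=(1, 2))
    except np.linalg.LinAlgError:
        for b in range(B_reps):
            try:
                Bmat[b] = np.linalg.solve(G[b], ZY[b])
            except np.linalg.LinAlgError:
                ok[b] = False
    E = Y - np.einsum("btp,bpk->btk", Z, Bmat)
    df = max(T_eff - P, 1)
    sigma = np.einsum("bti,btj->bij", E, E) / df
    coefs = np.stack(
        [Bmat[:, 1 + j * K : 1 + (j + 1) * K].transpose(0, 2, 1) for j in range(k)],
        axis=1,
    )
    return coefs, sigma, ok


def _batched_irf(
    coefs: np.ndarray, sigma: np.ndarray, H: int,
    orthogonalized: bool, perm: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """IRFs per replicate, (B, H+1, K, K); ok mask for Cholesky failures."""
    B_reps, k, K, _ = coefs.shape
    phi = np.zeros((B_reps, H + 1, K, K))
    phi[:, 0] = np.eye(K)
    for i in range(1, H + 1):
        acc = np.zeros((B_reps, K, K))
        for j in range(1, min(i, k) + 1):
            acc += phi[:, i - j] @ coefs[:, j - 1]
        phi[:, i] = acc
    ok = np.ones(B_reps, dtype=bool)
    if orthogonalized:
        sig_ord = sigma[:, perm][:, :, perm]
        # guard non-PD covariances replicate-wise
        Pfac = np.zeros_like(sigma)
        for b in range(B_reps):
            try:
                L = np.linalg.cholesky(sig_ord[b])
            except np.linalg.LinAlgError:
                ok[b] = False
                continue
            M = np.zeros((K, K))
            M[np.ix_(perm, perm)] = L
            Pfac[b] = M
        phi = phi @ Pfac[:, None]
    return phi, ok


def bootstrap_irf_bands(
    m: VARModel,
    y: np.ndarray | None = None,
    H: int = 10,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    orthogonalized: bool = False,
    ordering: tuple[str, ...] | None = None,
    method: str = "hall",
    max_dropped_frac: float = 0.10,
) -> tuple[IRFBands, IRFBands]:
    """Residual-based recursive bootstrap bands for IRF and accumulated IRF.

    Centred residuals are resampled with replacement, the series rebuilt
    from the fitted model (original first k values as initial conditions),
    the VAR re-estimated at the same order and the IRF recomputed.  Bands
    are Hall percentile intervals

        [2*theta_hat - q*_{1-a/2},  2*theta_hat - q*_{a/2}]

    (or plain percentile intervals with ``method="percentile"``).

    Returns ``(bands, accumulated_bands)``.  Replicates failing
    re-estimation are dropped; more than ``max_dropped_frac`` dropped is an
    error.
    """
    if B < 100:
        raise ParameterError("B must be >= 100")
    if method not in ("hall", "percentile"):
        raise ParameterError(f"unknown band method {method!r}")
    if y is None:
        y = m._y
    if y is None:
        raise ParameterError("original series required (pass y or refit)")
    y = np.asarray(y, dtype=float)

    items = m.items or tuple(f"y{i+1}" for i in range(m.K))
    ordering, perm = _resolve_ordering(items, ordering)

    point = compute_irf(m, H=H, orthogonalized=orthogonalized, ordering=ordering)
    theta = point.irf
    theta_acc = point.accumulated_irf

    rng = np.random.default_rng(seed)
    u = m.resid - m.resid.mean(axis=0)
    idx = rng.integers(0, u.shape[0], size=(B, y.shape[0] - m.k))
    ystar = _simulate_bootstrap_paths(m, y, idx, u)
    coefs, sigma, ok1 = _batched_var_fit(ystar, m.k)
    phi, ok2 = _batched_irf(coefs, sigma, H, orthogonalized, perm)
    ok = ok1 & ok2 & np.isfinite(phi).all(axis=(1, 2, 3))
    n_dropped = int(B - ok.sum())
    if n_dropped > max_dropped_frac * B:
        raise BootstrapError(
            f"{n_dropped}/{B} bootstrap replicates failed re-estimation"
        )
    phi = phi[ok]
    phi_acc = np.cumsum(phi, axis=1)

    def make(est: np.ndarray, reps: np.ndarray) -> IRFBands:
        qlo = np.quantile(reps, alpha / 2, axis=0)
        qhi = np.quantile(reps, 1 - alpha / 2, axis=0)
        if method == "hall":
            lower, upper = 2 * est - qhi, 2 * est - qlo
        else:
            lower, upper = qlo, qhi
        return IRFBands(
            lower=lower, upper=upper, method=method,
            level=1 - alpha, B_used=int(ok.sum()), n_dropped=n_dropped, seed=seed,
        )

    return make(theta, phi), make(theta_acc, phi_acc)


def compute_dynamics(
    m: VARModel,
    H: int = 10,
    orthogonalized: bool = False,
    ordering: tuple[str, ...] | None = None,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    method: str = "hall",
) -> DynamicsResult:
    """IRF plus bootstrap bands in one call."""
    res = compute_irf(m, H=H, orthogonalized=orthogonalized, ordering=ordering)
    bands, acc_bands = bootstrap_irf_bands(
        m, H=H, B=B, alpha=alpha, seed=seed,
        orthogonalized=orthogonalized, ordering=ordering, method=method,
    )
    res.bands = bands
    res.accumulated_bands = acc_bands
    return res


def fevd(
    m: VARModel, H: int = 10, ordering: tuple[str, ...] | None = None
) -> FEVDResult:
    """Forecast-error variance decomposition over steps 1..H.

    Shares use the orthogonalised moving-average matrices Theta_i under
    ``ordering``:

        prop[h, j, m] = sum_{i<h} Theta_i[j,m]^2 / sum_{i<h} sum_m' Theta_i[j,m']^2
    """
    if H < 1:
        raise ParameterError("H must be >= 1")
    if not m.is_stable:
        raise StabilityError("FEVD requires a stable model")
    items = m.items or tuple(f"y{i+1}" for i in range(m.K))
    ordering, perm = _resolve_ordering(items, ordering)
    phi = _ma_coefficients(m.coefs, H - 1)
    theta = phi @ _ordered_cholesky(m.sigma_u, perm)
    sq = theta**2
    num = np.cumsum(sq, axis=0)           # (H, K, K)
    denom = num.sum(axis=2, keepdims=True)
    return FEVDResult(proportions=num / denom, ordering=ordering, items=items)
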
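"""Synthetic diary generator with known ground truth.

Simulates stationary VAR(k) dynamics with Gaussian innovations, adds
per-item linear trends, maps affinely onto the 0-100 VAS (mean/SD anchor
computed from the model-implied stationary moments, so the mapping is
deterministic in the parameters), clips to the scale bounds and applies
completely-at-random missingness.  An optional random-walk prefix creates
a nonstationary early phase, mimicking an adaptation period before a
stable treatment window.

``make_benchmark_suite`` emits the named scenarios used throughout the
test-suite and acceptance checks (null, contemporaneous-only,
unidirectional, bidirectional, trend+coupling, nonstationary-prefix,
short and long series).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import solve_discrete_lyapunov

from .diary_io import CANONICAL_ITEMS, DiaryDataset
from .errors import ConfigError

DEFAULT_ITEMS = (CANONICAL_ITEMS[0], CANONICAL_ITEMS[2])  # focus pair


@dataclass
class SyntheticConfig:
    """Ground-truth parameters of one synthetic diary scenario."""

    n_items: int = 2
    k: int = 1
    coefs: np.ndarray | None = None        # (k, K, K) lag matrices
    intercepts: np.ndarray | None = None   # (K,) on the latent scale
    sigma: np.ndarray | None = None        # (K, K) innovation covariance
    trend_slopes: np.ndarray | None = None  # VAS units per day, per item
    T: int = 120
    missing_rate: float = 0.0
    nonstationary_prefix: int = 0
    anchor_mean: float = 50.0
    anchor_sd: float = 12.0
    seed: int = 0
    items: tuple[str, ...] = ()
    group: str = "HSS"
    patient_id: str = "SYN"
    burn_in: int = 200
    clip_warn_frac: float = 0.05

    def __post_init__(self) -> None:
        K = self.n_items
        if K < 2:
            raise ConfigError("n_items must be >= 2")
        if self.coefs is None:
            self.coefs = np.zeros((self.k, K, K))
        self.coefs = np.asarray(self.coefs, dtype=float)
        if self.coefs.shape != (self.k, K, K):
            raise ConfigError(f"coefs must be ({self.k}, {K}, {K})")
        if self.intercepts is None:
            self.intercepts = np.zeros(K)
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        if self.sigma is None:
            self.sigma = np.eye(K)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-12):
            raise ConfigError("sigma must be symmetric")
        if np.linalg.eigvalsh(self.sigma).min() <= 0:
            raise ConfigError("sigma must be positive definite")
        if self.trend_slopes is None:
            self.trend_slopes = np.zeros(K)
        self.trend_slopes = np.asarray(self.trend_slopes, dtype=float)
        if not (0.0 <= self.missing_rate <= 0.25):
            raise ConfigError("missing_rate must be in [0, 0.25]")
        if self.spectral_radius() >= 1.0:
            raise ConfigError(
                "unstable coefficient matrices; use nonstationary_prefix for "
                "a nonstationary phase instead"
            )
        if not self.items:
            if K == 2:
                self.items = DEFAULT_ITEMS
            elif K <= len(CANONICAL_ITEMS):
                self.items = CANONICAL_ITEMS[:K]
            else:
                self.items = tuple(f"item_{i+1}" for i in range(K))
        if len(self.items) != K:
            raise ConfigError("items must have n_items entries")

    def companion(self) -> np.ndarray:
        K, k = self.n_items, self.k
        C = np.zeros((K * k, K * k))
        C[:K] = np.concatenate(self.coefs, axis=1)
        if k > 1:
            C[K:, :-K] = np.eye(K * (k - 1))
        return C

    def spectral_radius(self) -> float:
        return float(np.abs(np.linalg.eigvals(self.companion())).max())

    def stationary_moments(self) -> tuple[np.ndarray, np.ndarray]:
        """Model-implied stationary mean and covariance (latent scale)."""
        K, k = self.n_items, self.k
        C = self.companion()
        mean = np.linalg.solve(np.eye(K) - self.coefs.sum(axis=0), self.intercepts)
        Q = np.zeros((K * k, K * k))
        Q[:K, :K] = self.sigma
        gamma_big = solve_discrete_lyapunov(C, Q)
        return mean, gamma_big[:K, :K]


def generate_diary(cfg: SyntheticConfig) -> tuple[DiaryDataset, dict]:
    """Simulate one diary dataset; identical seed gives identical output.

    Returns the dataset and a ground-truth record holding the generating
    parameters and the affine latent-to-VAS mapping actually applied.
    """
    rng = np.random.default_rng(cfg.seed)
    K, k, T = cfg.n_items, cfg.k, cfg.T
    L = np.linalg.cholesky(cfg.sigma)

    n_steps = cfg.burn_in + T
    z = np.zeros((n_steps + k, K))
    eps = rng.standard_normal((n_steps, K)) @ L.T
    for t in range(k, n_steps + k):
        acc = cfg.intercepts + eps[t - k]
        for j in range(1, k + 1):
            acc = acc + cfg.coefs[j - 1] @ z[t - j]
        z[t] = acc
    z = z[k + cfg.burn_in :]  # (T, K) stationary segment

    mean, gamma0 = cfg.stationary_moments()
    sd = np.sqrt(np.diag(gamma0))
    scale = cfg.anchor_sd / sd
    x = cfg.anchor_mean + (z - mean) * scale

    days = np.arange(1, T + 1, dtype=float)[:, None]
    x = x + cfg.trend_slopes * (days - (T + 1) / 2.0)

    if cfg.nonstationary_prefix > 0:
        # level-shifted random walk: an unsettled adaptation phase before
        # the stable treatment window
        n_pre = cfg.nonstationary_prefix
        steps = rng.standard_normal((n_pre, K)) * (cfg.anchor_sd * 0.4)
        walk = cfg.anchor_mean + 2.0 * cfg.anchor_sd + np.cumsum(steps, axis=0)
        x = np.vstack([walk, x])

    n_total = x.shape[0]
    clipped = (x < 0.0) | (x > 100.0)
    clip_frac = clipped.mean()
    if clip_frac > cfg.clip_warn_frac:
        warnings.warn(
            f"{clip_frac:.1%} of cells clipped to [0, 100]; "
            "scale anchor too close to the bounds",
            stacklevel=2,
        )
    x = np.clip(x, 0.0, 100.0)

    if cfg.missing_rate > 0:
        miss = rng.random((n_total, K)) < cfg.missing_rate
        # keep at least the first and last day observed per item
        miss[0] = miss[-1] = False
        x = np.where(miss, np.nan, x)

    data = DiaryDataset(cfg.patient_id, cfg.group, cfg.items, x)
    truth = {
        "config": cfg,
        "latent_mean": mean,
        "latent_sd": sd,
        "scale": scale,
        "offset": cfg.anchor_mean - mean * scale,
        "clip_fraction": float(clip_frac),
        "stationary_start_day": cfg.nonstationary_prefix + 1,
    }
    return data, truth


def _bivariate(
    a11: float, a12: float, a21: float, a22: float, rho: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    A = np.array([[[a11, a12], [a21, a22]]])
    S = np.array([[1.0, rho], [rho, 1.0]])
    return A, S


def make_benchmark_suite(seed: int = 0) -> list[tuple[str, SyntheticConfig]]:
    """Named ground-truth scenarios spanning the behaviours the pipeline
    must distinguish.

    Coupling scenarios place the cross effect in the equation of the second
    item (first item Granger-causes the second); series lengths bracket the
    observed participation range (39-231 days).
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(8)]
    suite: list[tuple[str, SyntheticConfig]] = []

    A_null, S_null = _bivariate(0.3, 0.0, 0.0, 0.3)
    suite.append(("null", SyntheticConfig(
        coefs=A_null, sigma=S_null, T=200, seed=seeds[0])))

    A_c, S_c = _bivariate(0.3, 0.0, 0.0, 0.3, rho=0.5)
    suite.append(("contemporaneous_only", SyntheticConfig(
        coefs=A_c, sigma=S_c, T=200, seed=seeds[1])))

    A_u, S_u = _bivariate(0.5, 0.0, 0.4, 0.4)
    suite.append(("unidirectional", SyntheticConfig(
        coefs=A_u, sigma=S_u, T=200, seed=seeds[2])))

    A_b, S_b = _bivariate(0.4, 0.3, 0.3, 0.4)
    suite.append(("bidirectional", SyntheticConfig(
        coefs=A_b, sigma=S_b, T=200, seed=seeds[3])))

    A_t, S_t = _bivariate(0.5, 0.0, 0.4, 0.4, rho=0.3)
    suite.append(("trend_coupling", SyntheticConfig(
        coefs=A_t, sigma=S_t, T=200, seed=seeds[4],
        trend_slopes=np.array([-0.05, -0.05]))))

    A_n, S_n = _bivariate(0.4, 0.0, 0.3, 0.4)
    suite.append(("nonstationary_prefix", SyntheticConfig(
        coefs=A_n, sigma=S_n, T=120, seed=seeds[5],
        nonstationary_prefix=40)))

    suite.append(("short_series", SyntheticConfig(
        coefs=A_u, sigma=S_u, T=39, seed=seeds[6])))

    suite.append(("long_series", SyntheticConfig(
        coefs=A_u, sigma=S_u, T=231, seed=seeds[7])))

    return suite


def scenario(name: str, seed: int = 0, **overrides) -> SyntheticConfig:
    """Look up one benchmark scenario by name, optionally overriding fields."""
    for n, cfg in make_benchmark_suite(seed):
        if n == name:
            return replace(cfg, **overrides) if overrides else cfg
    raise KeyError(f"unknown scenario {name!r}")
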
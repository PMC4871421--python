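import numpy as np
import pytest

from diarydyn import DiaryDataset


def simulate_var(A, sigma, T, seed, intercept=None, burn=100):
    """Plain VAR simulator used as an independent data source in tests.

    A: (k, K, K) lag matrices; sigma: innovation covariance.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim == 2:
        A = A[None]
    k, K, _ = A.shape
    sigma = np.asarray(sigma, dtype=float)
    nu = np.zeros(K) if intercept is None else np.asarray(intercept, float)
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(sigma)
    y = np.zeros((T + burn + k, K))
    eps = rng.standard_normal((T + burn, K)) @ L.T
    for t in range(k, T + burn + k):
        y[t] = nu + eps[t - k] + sum(A[j] @ y[t - 1 - j] for j in range(k))
    return y[k + burn:]


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_dataset(values, items=("emotional_intolerance", "restraint"),
                 patient_id="P1", group="HSS"):
    return DiaryDataset(patient_id, group, tuple(items), np.asarray(values, float))


def vas_rescale(y, mean=50.0, sd=10.0):
    """Map a simulated series onto the VAS so it fits a DiaryDataset."""
    y = np.asarray(y, float)
    z = (y - y.mean(axis=0)) / y.std(axis=0)
    return np.clip(mean + sd * z, 0.0, 100.0)
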
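import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diarydyn import (
    GrangerResult,
    bootstrap_irf_bands,
    choose_ordering,
    compute_irf,
    fevd,
    fit_var,
    granger_df2,
    granger_pvalue,
    granger_test,
)
from diarydyn.errors import (
    ParameterError,
    StabilityError,
    UnsupportedDimensionError,
)

from conftest import simulate_var
from test_var_core import make_model

# Frozen report fixtures: (window length, VAR order, df2) pairs a bivariate
# analysis must reproduce under df2 = 2*(T_w - k) - 4k - 2.
DF2_FIXTURES = [
    (126, 2, 238),
    (84, 1, 160),
    (45, 1, 82),
    (231, 4, 436),
    (231, 7, 418),
    (113, 1, 218),
    (46, 2, 78),
    (46, 1, 84),
    (75, 1, 142),
]


class TestDegreesOfFreedom:
    @pytest.mark.parametrize("T_w,k,expected", DF2_FIXTURES)
    def test_df2_identity(self, T_w, k, expected):
        assert granger_df2(T_w - k, k) == expected

    def test_df2_from_fitted_model(self):
        # a model fitted on an 84-day window at order 1 must report df2=160
        y = simulate_var(np.array([[0.4, 0.1], [0.2, 0.3]]), np.eye(2), 84, seed=0)
        m = fit_var(y, 1)
        g = granger_test(m, "y1", "y2")
        assert (g.df1, g.df2) == (1, 160)
        # and a 231-day window at order 4 -> df2 = 436
        y = simulate_var(np.array([[0.4, 0.1], [0.2, 0.3]]), np.eye(2), 231, seed=1)
        g = granger_test(fit_var(y, 4), "y1", "y2")
        assert (g.df1, g.df2) == (4, 436)


class TestGrangerTest:
    def test_restricted_regression_oracle(self):
        # F must equal the classic restricted-vs-unrestricted F-change
        # statistic of the effect equation (independent route).
        y = simulate_var(np.array([[0.5, 0.0], [0.4, 0.4]]), np.eye(2), 150, seed=9)
        for k in (1, 2, 3):
            m = fit_var(y, k)
            g = granger_test(m, "y1", "y2")
            Zu = np.ones((150 - k, 1 + 2 * k))
            for j in range(1, k + 1):
                Zu[:, 1 + (j - 1) * 2 : 1 + j * 2] = y[k - j : 150 - j]
            target = y[k:, 1]
            keep = [0] + [1 + (j - 1) * 2 + 1 for j in range(1, k + 1)]  # drop cause lags
            Zr = Zu[:, keep]
            rss_u = np.sum((target - Zu @ np.linalg.lstsq(Zu, target, rcond=None)[0]) ** 2)
            rss_r = np.sum((target - Zr @ np.linalg.lstsq(Zr, target, rcond=None)[0]) ** 2)
            df_u = (150 - k) - (1 + 2 * k)
            F_ref = ((rss_r - rss_u) / k) / (rss_u / df_u)
            assert g.F == pytest.approx(F_ref, abs=1e-8)

    def test_wald_f_consistency(self):
        y = simulate_var(np.array([[0.5, 0.2], [0.3, 0.4]]), np.eye(2), 120, seed=2)
        m = fit_var(y, 2)
        g = granger_test(m, "y1", "y2")
        assert g.wald == pytest.approx(g.F * g.df1, abs=1e-8)

    def test_direction_recovery_power(self):
        # one-way coupling: x->y significant and y->x not, in >=90% of 200 reps
        A = np.array([[0.5, 0.0], [0.4, 0.4]])
        hits = 0
        for s in range(200):
            y = simulate_var(A, np.eye(2), 300, seed=70_000 + s)
            m = fit_var(y, 1)
            fwd = granger_test(m, "y1", "y2")
            rev = granger_test(m, "y2", "y1")
            hits += fwd.significant and not rev.significant
        assert hits / 200 >= 0.90

    def test_cause_equals_effect(self):
        m = fit_var(simulate_var(0.3 * np.eye(2), np.eye(2), 80, 0), 1)
        with pytest.raises(ParameterError):
            granger_test(m, "y1", "y1")

    def test_trivariate_unsupported(self):
        y = np.random.default_rng(0).standard_normal((100, 3))
        with pytest.raises(UnsupportedDimensionError):
            granger_test(fit_var(y, 1), "y1", "y2")

    def test_significant_flag(self):
        g = GrangerResult("a", "b", F=5.0, df1=1, df2=100,
                          p_value=granger_pvalue(5.0, 1, 100))
        assert g.significant == (g.p_value < 0.05)


class TestComputeIRF:
    def test_var1_matrix_powers(self):
        A = np.array([[0.5, 0.2], [0.1, 0.4]])
        m = make_model(A)
        res = compute_irf(m, H=10)
        for i in range(11):
            np.testing.assert_allclose(
                res.irf[i], np.linalg.matrix_power(A, i), atol=1e-12
            )

    def test_horizon_zero_identity(self):
        m = make_model(np.array([[0.3, 0.1], [0.0, 0.2]]))
        res = compute_irf(m, H=5)
        np.testing.assert_array_equal(res.irf[0], np.eye(2))

    def test_oirf_diagonal_closed_form(self):
        d1, d2 = 4.0, 9.0
        m = make_model(np.zeros((2, 2)), sigma=np.diag([d1, d2]))
        res = compute_irf(m, H=5, orthogonalized=True)
        np.testing.assert_allclose(res.irf[0], np.diag([2.0, 3.0]), atol=1e-12)
        np.testing.assert_allclose(res.irf[1:], 0, atol=1e-12)

    def test_accumulated_long_run(self):
        # stable VAR(2): accumulated IRF at large H -> (I - A1 - A2)^{-1}
        A = np.array([[[0.4, 0.1], [0.1, 0.3]], [[0.15, 0.05], [0.0, 0.2]]])
        m = make_model(A)
        res = compute_irf(m, H=200)
        target = np.linalg.inv(np.eye(2) - A[0] - A[1])
        np.testing.assert_allclose(res.accumulated_irf[-1], target, atol=1e-6)

    def test_accumulated_is_cumsum(self):
        m = make_model(np.array([[0.5, 0.2], [0.1, 0.4]]))
        res = compute_irf(m, H=8)
        np.testing.assert_array_equal(
            res.accumulated_irf, np.cumsum(res.irf, axis=0)
        )

    def test_unstable_raises(self):
        with pytest.raises(StabilityError):
            compute_irf(make_model(np.eye(2)), H=5)

    def test_bad_horizon(self):
        with pytest.raises(ParameterError):
            compute_irf(make_model(0.3 * np.eye(2)), H=0)

    def test_ordering_changes_oirf(self):
        sigma = np.array([[1.0, 0.6], [0.6, 1.0]])
        m = make_model(np.array([[0.4, 0.1], [0.2, 0.3]]), sigma=sigma)
        a = compute_irf(m, H=4, orthogonalized=True, ordering=("y1", "y2"))
        b = compute_irf(m, H=4, orthogonalized=True, ordering=("y2", "y1"))
        assert not np.allclose(a.irf, b.irf)

    def test_statsmodels_oracle(self, rng):
        VAR = pytest.importorskip("statsmodels.tsa.api").VAR
        for _ in range(3):
            y = simulate_var(
                rng.normal(0, 0.2, (1, 2, 2)), np.eye(2), 150, seed=int(rng.integers(1e6))
            )
            m = fit_var(y, 1)
            ref = VAR(y).fit(1, trend="c").irf(10)
            mine = compute_irf(m, H=10)
            np.testing.assert_allclose(mine.irf, ref.irfs, atol=1e-8)
            mine_o = compute_irf(m, H=10, orthogonalized=True)
            np.testing.assert_allclose(mine_o.irf, ref.orth_irfs, atol=1e-8)


class TestChooseOrdering:
    def _g(self, cause, effect, p):
        return GrangerResult(cause, effect, F=1.0, df1=1, df2=100, p_value=p)

    def test_single_direction_wins(self):
        assert choose_ordering(
            self._g("x", "y", 0.01), self._g("y", "x", 0.4), default=("y", "x")
        ) == ("x", "y")
        assert choose_ordering(
            self._g("x", "y", 0.4), self._g("y", "x", 0.01), default=("x", "y")
        ) == ("y", "x")

    def test_neither_falls_back(self, caplog):
        with caplog.at_level("WARNING", logger="diarydyn.causality_dynamics"):
            out = choose_ordering(
                self._g("x", "y", 0.4), self._g("y", "x", 0.5), default=("x", "y")
            )
        assert out == ("x", "y")
        assert "neither" in caplog.text

    def test_both_falls_back(self, caplog):
        with caplog.at_level("WARNING", logger="diarydyn.causality_dynamics"):
            out = choose_ordering(
                self._g("x", "y", 0.01), self._g("y", "x", 0.02), default=("x", "y")
            )
        assert out == ("x", "y")
        assert "both" in caplog.text

    def test_mismatched_pair(self):
        with pytest.raises(ParameterError):
            choose_ordering(
                self._g("x", "y", 0.1), self._g("z", "x", 0.1), default=("x", "y")
            )


@pytest.fixture(scope="module")
def fitted_model():
    y = simulate_var(np.array([[0.5, 0.0], [0.4, 0.4]]), np.eye(2), 250, seed=77)
    return fit_var(y, 1), y


class TestBootstrapBands:
    def test_seeded_determinism(self, fitted_model):
        m, _ = fitted_model
        b1, a1 = bootstrap_irf_bands(m, H=5, B=200, seed=4)
        b2, a2 = bootstrap_irf_bands(m, H=5, B=200, seed=4)
        np.testing.assert_array_equal(b1.lower, b2.lower)
        np.testing.assert_array_equal(b1.upper, b2.upper)
        np.testing.assert_array_equal(a1.lower, a2.lower)

    def test_b_too_small(self, fitted_model):
        m, _ = fitted_model
        with pytest.raises(ParameterError):
            bootstrap_irf_bands(m, H=5, B=50, seed=0)

    def test_percentile_contains_point(self, fitted_model):
        # percentile-type intervals must bracket the point estimate
        m, _ = fitted_model
        bands, acc = bootstrap_irf_bands(m, H=6, B=300, seed=1, method="percentile")
        point = compute_irf(m, H=6)
        assert (bands.lower <= point.irf + 1e-12).all()
        assert (bands.upper >= point.irf - 1e-12).all()
        assert (acc.lower <= point.accumulated_irf + 1e-12).all()

    def test_strong_coupling_band_excludes_zero(self, fitted_model):
        m, _ = fitted_model
        bands, _ = bootstrap_irf_bands(m, H=3, B=400, seed=5)
        # response of y2 to y1 at horizon 1: true coefficient 0.4
        assert bands.significant_at(1, 1, 0)

    def test_orthogonalized_bands(self, fitted_model):
        m, _ = fitted_model
        bands, _ = bootstrap_irf_bands(
            m, H=4, B=200, seed=2, orthogonalized=True, ordering=("y1", "y2")
        )
        assert bands.lower.shape == (5, 2, 2)
        assert bands.n_dropped <= 20


class TestFEVD:
    def test_uncoupled_identity_pattern(self):
        m = make_model(np.zeros((2, 2)), sigma=np.diag([2.0, 3.0]))
        res = fevd(m, H=10)
        for h in range(10):
            np.testing.assert_allclose(res.proportions[h], np.eye(2), atol=1e-12)

    def test_rows_sum_to_one(self, rng):
        for _ in range(5):
            A = rng.normal(0, 0.25, (2, 2))
            if np.abs(np.linalg.eigvals(A)).max() >= 1:
                continue
            sig = rng.normal(0, 0.4, (2, 2))
            sig = sig @ sig.T + np.eye(2)
            res = fevd(make_model(A, sigma=sig), H=10)
            np.testing.assert_allclose(
                res.proportions.sum(axis=2), 1.0, atol=1e-10
            )
            assert (res.proportions >= -1e-12).all()
            assert (res.proportions <= 1 + 1e-12).all()

    def test_zero_cross_share_when_uncoupled(self):
        # no cross lags + diagonal innovations -> cause share identically 0
        A = np.array([[0.5, 0.0], [0.0, 0.4]])
        res = fevd(make_model(A, sigma=np.diag([1.0, 2.0])), H=10)
        np.testing.assert_allclose(res.proportions[:, 1, 0], 0.0, atol=1e-14)
        np.testing.assert_allclose(res.proportions[:, 0, 1], 0.0, atol=1e-14)

    def test_share_accessor(self):
        A = np.array([[0.5, 0.0], [0.4, 0.4]])
        m = make_model(A)
        m.items = ("x", "y")
        res = fevd(m, H=10)
        assert res.share("y", "x") == pytest.approx(res.proportions[-1, 1, 0])

    def test_statsmodels_oracle(self, rng):
        VAR = pytest.importorskip("statsmodels.tsa.api").VAR
        for _ in range(3):
            y = simulate_var(
                rng.normal(0, 0.2, (1, 2, 2)), np.eye(2), 180, seed=int(rng.integers(1e6))
            )
            m = fit_var(y, 1)
            ref = VAR(y).fit(1, trend="c").fevd(10).decomp.transpose(1, 0, 2)
            np.testing.assert_allclose(fevd(m, H=10).proportions, ref, atol=1e-8)


@settings(max_examples=20, deadline=None)
@given(st.integers(min_value=0, max_value=99_999))
def test_fevd_normalization_property(seed):
    rng = np.random.default_rng(seed)
    A = rng.normal(0, 0.3, (2, 2))
    if np.abs(np.linalg.eigvals(A)).max() >= 0.98:
        return
    w = rng.normal(0, 0.5, (2, 2))
    sigma = w @ w.T + 0.5 * np.eye(2)
    res = fevd(make_model(A, sigma=sigma), H=8)
    np.testing.assert_allclose(res.proportions.sum(axis=2), 1.0, atol=1e-10)
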
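"""Statistical estimators against hand computations and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from uricmr.models import (
    cox_fit,
    cox_partial_loglik,
    hwe_test,
    linear_fit,
    logistic_fit,
)


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive implementations)
# ---------------------------------------------------------------------------

def efron_loglik_naive(beta, time, event, x):
    """Textbook Efron partial log-likelihood, one covariate, double loop."""
    time, event, x = map(np.asarray, (time, event, x))
    ll = 0.0
    for t in np.unique(time[event == 1]):
        D = np.flatnonzero((time == t) & (event == 1))
        R = np.flatnonzero(time >= t)
        d = len(D)
        s_r = np.exp(beta * x[R]).sum()
        s_d = np.exp(beta * x[D]).sum()
        ll += beta * x[D].sum()
        for ell in range(d):
            ll -= np.log(s_r - (ell / d) * s_d)
    return ll


def breslow_loglik_naive(beta, time, event, x):
    time, event, x = map(np.asarray, (time, event, x))
    ll = 0.0
    for t in np.unique(time[event == 1]):
        D = np.flatnonzero((time == t) & (event == 1))
        R = np.flatnonzero(time >= t)
        ll += beta * x[D].sum() - len(D) * np.log(np.exp(beta * x[R]).sum())
    return ll


def grid_argmax(fun, lo, hi, rounds=6, points=201):
    """Nested grid search for a 1-d maximizer."""
    for _ in range(rounds):
        grid = np.linspace(lo, hi, points)
        vals = np.array([fun(b) for b in grid])
        k = int(vals.argmax())
        lo, hi = grid[max(k - 1, 0)], grid[min(k + 1, points - 1)]
    return (lo + hi) / 2


def logistic_loglik_naive(a, b, y, x):
    p = expit(a + b * x)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))


class TestHWE:
    def test_exact_proportions_give_zero(self):
        res = hwe_test(25, 50, 25)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        res = hwe_test(30, 40, 30)
        assert res.allele_freq == pytest.approx(0.5)
        assert res.expected == pytest.approx((25, 50, 25))
        assert res.chi2 == pytest.approx(4.0)
        assert res.p_value == pytest.approx(0.0455, abs=2e-4)

    def test_allele_relabeling_invariance(self):
        a, b = hwe_test(12, 47, 33), hwe_test(33, 47, 12)
        assert a.chi2 == pytest.approx(b.chi2, rel=1e-12)
        assert a.allele_freq == pytest.approx(1 - b.allele_freq)

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            hwe_test(100, 0, 0)


class TestLinearFit:
    def test_exact_fit_recovers_slope(self):
        x = np.array([0, 1, 2, 0, 1, 2], dtype=float)
        y = 0.23 * x - 0.23
        est = linear_fit(y, x)
        assert est.beta == pytest.approx(0.23, abs=1e-12)
        assert est.se == pytest.approx(0.0, abs=1e-10)

    def test_null_large_n(self):
        rng = np.random.default_rng(0)
        x = rng.binomial(2, 0.4, 20_000).astype(float)
        y = rng.standard_normal(20_000)
        est = linear_fit(y, x)
        assert abs(est.beta) < 0.02
        assert est.ci_low < 0 < est.ci_high

    def test_recovery_with_nominal_se(self):
        """Mean slope near truth; model SE near the empirical SD of the slope."""
        rng = np.random.default_rng(42)
        betas, ses = [], []
        for _ in range(300):
            x = rng.binomial(2, 0.4, 1381).astype(float)
            y = 0.23 * x + rng.standard_normal(1381)
            est = linear_fit(y, x)
            betas.append(est.beta)
            ses.append(est.se)
        assert np.mean(betas) == pytest.approx(0.23, abs=0.02)
        assert np.mean(ses) == pytest.approx(np.std(betas, ddof=1), rel=0.10)

    def test_frisch_waugh_partialling(self):
        rng = np.random.default_rng(7)
        n = 400
        c = rng.standard_normal((n, 2))
        x = rng.standard_normal(n) + c[:, 0]
        y = 0.5 * x + c @ [1.0, -2.0] + rng.standard_normal(n)
        full = linear_fit(y, x, covariates=c)
        import statsmodels.api as sm
        rx = sm.OLS(x, sm.add_constant(c)).fit().resid
        ry = sm.OLS(y, sm.add_constant(c)).fit().resid
        slope = float((rx @ ry) / (rx @ rx))
        assert full.beta == pytest.approx(slope, abs=1e-10)

    def test_rank_deficiency_named(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(50)
        c = pd.DataFrame({"dup": 2 * x})
        with pytest.raises(ValueError, match="dup"):
            linear_fit(rng.standard_normal(50), x, covariates=c)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            linear_fit([1.0, 2.0, 3.0, 4.0], [1.0, 1.0, 1.0, 1.0])


class TestLogisticFit:
    @staticmethod
    def _expand(counts):
        """counts: {dose: (cases, controls)} -> y, x arrays."""
        y, x = [], []
        for dose, (cases, controls) in counts.items():
            y += [1] * cases + [0] * controls
            x += [dose] * (cases + controls)
        return np.array(y, float), np.array(x, float)

    def test_identical_case_fraction_gives_null(self):
        y, x = self._expand({0: (10, 40), 1: (20, 80), 2: (5, 20)})
        est = logistic_fit(y, x)
        assert est.beta == pytest.approx(0.0, abs=1e-8)

    def test_matches_likelihood_grid(self):
        y, x = self._expand({0: (10, 90), 1: (20, 80), 2: (40, 60)})
        est = logistic_fit(y, x)
        # joint nested grid over (intercept, slope)
        lo_a, hi_a, lo_b, hi_b = -4.0, 1.0, -2.0, 2.0
        for _ in range(8):
            A, B = np.linspace(lo_a, hi_a, 81), np.linspace(lo_b, hi_b, 81)
            vals = np.array([[logistic_loglik_naive(a, b, y, x) for b in B] for a in A])
            i, j = np.unravel_index(vals.argmax(), vals.shape)
            lo_a, hi_a = A[max(i - 1, 0)], A[min(i + 1, 80)]
            lo_b, hi_b = B[max(j - 1, 0)], B[min(j + 1, 80)]
        b_hat = (lo_b + hi_b) / 2
        assert est.beta == pytest.approx(b_hat, abs=1e-4)
        assert est.converged

    def test_separation_flagged(self):
        y, x = self._expand({0: (0, 30), 1: (0, 30), 2: (15, 0)})
        est = logistic_fit(y, x)
        assert not est.converged

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            logistic_fit(np.ones(10), np.arange(10.0))


class TestCoxFit:
    def test_swap_symmetry_forces_zero(self):
        time = np.array([1.0, 1.0, 2.0, 2.0])
        event = np.array([1, 1, 1, 1])
        x = np.array([1.0, 0.0, 1.0, 0.0])
        est = cox_fit(time, event, x)
        assert est.beta == pytest.approx(0.0, abs=1e-8)

    def test_relabeled_covariate_flips_sign(self):
        rng = np.random.default_rng(2)
        n = 60
        x = rng.integers(0, 2, n).astype(float)
        time = rng.exponential(1 / np.exp(0.8 * x))
        event = np.ones(n, int)
        a = cox_fit(time, event, x)
        b = cox_fit(time, event, 1.0 - x)
        assert a.beta == pytest.approx(-b.beta, abs=1e-7)
        assert a.se == pytest.approx(b.se, rel=1e-7)

    def test_matches_grid_oracle_distinct_times(self):
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        event = np.array([1, 0, 1, 1, 0, 1, 1, 0])
        x = np.array([0.0, 1.0, 2.0, 0.0, 1.0, 2.0, 1.0, 0.0])
        est = cox_fit(time, event, x)
        oracle = grid_argmax(lambda b: efron_loglik_naive(b, time, event, x), -5, 5)
        assert est.beta == pytest.approx(oracle, abs=1e-4)

    @pytest.mark.parametrize("ties, naive", [
        ("efron", efron_loglik_naive), ("breslow", breslow_loglik_naive),
    ])
    def test_matches_grid_oracle_tied_times(self, ties, naive):
        time = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 3.0, 3.0, 4.0])
        event = np.array([1, 1, 0, 1, 1, 1, 0, 1])
        x = np.array([2.0, 1.0, 0.0, 1.0, 0.0, 2.0, 1.0, 0.0])
        est = cox_fit(time, event, x, ties=ties)
        oracle = grid_argmax(lambda b: naive(b, time, event, x), -5, 5)
        assert est.beta == pytest.approx(oracle, abs=1e-4)

    def test_internal_loglik_agrees_with_naive(self):
        time = np.array([1.0, 1.0, 2.0, 2.0, 2.0, 3.0, 5.0, 6.0])
        event = np.array([1, 1, 1, 1, 0, 1, 1, 0])
        x = np.array([0.3, -1.2, 0.8, 0.0, 1.5, -0.7, 0.2, 1.1])
        for beta in (-1.0, -0.2, 0.0, 0.4, 1.3):
            ll, _, _ = cox_partial_loglik(np.array([beta]), time, event, x)
            assert ll == pytest.approx(efron_loglik_naive(beta, time, event, x), abs=1e-10)

    def test_fit_never_below_null_loglik(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            n = 40
            x = rng.standard_normal(n)
            time = rng.exponential(1 / np.exp(0.3 * x))
            event = rng.integers(0, 2, n)
            if event.sum() == 0:
                event[0] = 1
            est = cox_fit(time, event, x)
            ll_hat, _, _ = cox_partial_loglik(np.array([est.beta]), time, event, x)
            ll_0, _, _ = cox_partial_loglik(np.array([0.0]), time, event, x)
            assert ll_hat >= ll_0 - 1e-12

    def test_agrees_with_lifelines_under_ties(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(3)
        n = 300
        x = rng.binomial(2, 0.4, n).astype(float)
        z = rng.standard_normal(n)
        t = np.round(rng.exponential(1 / np.exp(0.5 * x - 0.3 * z)), 1) + 0.1
        c = rng.uniform(0.5, 3, n)
        time, event = np.minimum(t, c), (t <= c).astype(int)
        est = cox_fit(time, event, x, covariates=z.reshape(-1, 1))
        df = pd.DataFrame({"T": time, "E": event, "x": x, "z": z})
        cph = lifelines.CoxPHFitter().fit(df, "T", "E")
        assert est.beta == pytest.approx(float(cph.params_["x"]), abs=1e-6)
        assert est.se == pytest.approx(float(cph.standard_errors_["x"]), abs=1e-6)

    def test_parameter_recovery_exponential_ph(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(2000)
        t = rng.exponential(1 / (0.5 * np.exp(0.5 * x)))
        c = rng.exponential(2.0, 2000)
        est = cox_fit(np.minimum(t, c), (t <= c).astype(int), x)
        assert est.beta == pytest.approx(0.5, abs=0.07)
        assert est.ci_low < np.exp(0.5) < est.ci_high

    def test_monotone_likelihood_flagged(self):
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.array([1, 1, 1, 0, 0, 0])
        x = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])  # all events at x=1
        est = cox_fit(time, event, x)
        assert not est.converged

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError, match="events"):
            cox_fit([1.0, 2.0], [0, 0], [0.0, 1.0])
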
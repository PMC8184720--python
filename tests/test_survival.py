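import numpy as np
import pandas as pd
import pytest
from scipy import stats

from glycoprog.survival import (
    fit_cox,
    km_estimate,
    logrank_test,
    time_dependent_auc,
)
from tests import oracles


def _random_instance(rng, n_min=4, n_max=8):
    """Small distinct-time instance with an interior partial-likelihood max."""
    while True:
        n = int(rng.integers(n_min, n_max + 1))
        time = rng.choice(np.arange(1, 50), size=n, replace=False).astype(float)
        event = rng.integers(0, 2, n)
        x = rng.integers(0, 2, n).astype(float)
        if event.sum() < 2 or np.ptp(x) == 0:
            continue
        # identifiable only if some event's risk set mixes both covariate values
        informative = any(
            event[i] == 1 and np.ptp(x[time >= time[i]]) > 0 for i in range(n)
        )
        if not informative:
            continue
        b_hat = oracles.grid_max_log_hr(x, time, event)
        if abs(b_hat) < 2.5:
            return x, time, event, b_hat


class TestFitCox:
    def test_matches_grid_oracle_on_small_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            x, time, event, b_oracle = _random_instance(rng)
            fit = fit_cox(x, time, event)
            assert abs(fit.log_hr[0] - b_oracle) < 1e-4

    def test_monotone_likelihood_raises_diagnostic(self):
        # times (1,2,3,4), all events, covariate (1,1,0,0): every x=1 subject
        # dies before every x=0 subject, so the partial likelihood increases
        # monotonically in the coefficient and no finite estimate exists
        from glycoprog.survival import ConvergenceError

        x = np.array([1.0, 1.0, 0.0, 0.0])
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.ones(4)
        with pytest.raises(ConvergenceError, match="monotone"):
            fit_cox(x, time, event)

    def test_flipping_binary_covariate_negates_log_hr(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 2, 40).astype(float)
        time = rng.exponential(10, 40)
        event = rng.integers(0, 2, 40)
        event[:5] = 1
        a = fit_cox(x, time, event)
        b = fit_cox(1 - x, time, event)
        assert a.log_hr[0] == pytest.approx(-b.log_hr[0], abs=1e-7)
        assert a.se_log_hr[0] == pytest.approx(b.se_log_hr[0], abs=1e-7)

    def test_agrees_with_lifelines_with_ties_and_k_covariates(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(7)
        X = rng.normal(size=(120, 2))
        time = np.ceil(rng.exponential(30, 120))  # day resolution -> ties
        event = rng.integers(0, 2, 120)
        fit = fit_cox(X, time, event, names=("a", "b"))
        df = pd.DataFrame(X, columns=["a", "b"]).assign(t=time, e=event)
        cph = lifelines.CoxPHFitter().fit(df, "t", "e")
        np.testing.assert_allclose(fit.log_hr, cph.params_.to_numpy(), atol=1e-4)
        np.testing.assert_allclose(fit.se_log_hr, cph.standard_errors_.to_numpy(), atol=1e-4)

    def test_wald_p_consistent_with_normal_reference(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 2, 60).astype(float)
        fit = fit_cox(x, rng.exponential(10, 60), np.ones(60))
        z = fit.log_hr[0] / fit.se_log_hr[0]
        assert fit.wald_p[0] == pytest.approx(2 * stats.norm.sf(abs(z)), rel=1e-12)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="no variation"):
            fit_cox(np.ones(5), np.arange(1.0, 6.0), np.ones(5))

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError, match="zero events"):
            fit_cox(np.array([0.0, 1, 0, 1]), np.arange(1.0, 5.0), np.zeros(4))


class TestKaplanMeier:
    def test_all_censored_curve_is_one(self):
        curve = km_estimate([5.0, 6.0, 7.0], [0, 0, 0])
        assert len(curve.event_times) == 0
        assert curve.survival_at(100.0) == 1.0

    def test_no_censoring_matches_empirical_survival(self):
        curve = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        np.testing.assert_allclose(curve.survival_prob, [2 / 3, 1 / 3, 0.0])

    def test_censored_product_limit_by_hand(self):
        # times (1,2,3), events (1,0,1): S(1)=2/3, no step at 2, S(3)=0
        curve = km_estimate([1.0, 2.0, 3.0], [1, 0, 1])
        np.testing.assert_allclose(curve.event_times, [1.0, 3.0])
        np.testing.assert_allclose(curve.survival_prob, [2 / 3, 0.0])

    def test_matches_hand_oracle_on_random_data(self):
        rng = np.random.default_rng(5)
        time = np.ceil(rng.exponential(10, 30))
        event = rng.integers(0, 2, 30)
        t_o, s_o = oracles.km_product_limit(time, event)
        curve = km_estimate(time, event)
        np.testing.assert_allclose(curve.event_times, t_o)
        np.testing.assert_allclose(curve.survival_prob, s_o, atol=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            km_estimate([-1.0, 2.0], [1, 1])


class TestLogrank:
    def test_identical_groups_null_identity(self):
        t = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        e = [1, 0, 1, 1, 0, 1]
        g = ["a", "a", "a", "b", "b", "b"]
        chi2, p = logrank_test(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(10, 30)
        e = rng.integers(0, 2, 30)
        g = rng.integers(0, 2, 30)
        a = logrank_test(t, e, g)
        b = logrank_test(t, e, 1 - g)
        assert a == pytest.approx(b)

    def test_six_sample_hand_computation(self):
        t = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        e = [1, 1, 0, 1, 1, 1]
        g = ["x", "y", "x", "y", "x", "y"]
        chi2, _ = logrank_test(t, e, g)
        assert chi2 == pytest.approx(oracles.logrank_chi2_by_risk_sets(t, e, g), abs=1e-10)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1.0, 2.0], [1, 1], ["a", "a"])

    def test_null_p_values_are_uniform(self):
        """Permuting labels under the null gives a uniform p distribution."""
        rng = np.random.default_rng(99)
        t = rng.exponential(10, 40)
        e = rng.integers(0, 2, 40)
        e[:5] = 1
        ps = []
        base = np.array([0] * 20 + [1] * 20)
        for _ in range(2000):
            g = rng.permutation(base)
            ps.append(logrank_test(t, e, g)[1])
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.001


class TestTimeDependentAuc:
    def test_constant_score_is_half(self):
        t = np.array([1.0, 2, 3, 4, 5, 6])
        e = np.array([1, 1, 0, 1, 0, 1])
        assert time_dependent_auc(np.ones(6), t, e, 3.5) == pytest.approx(0.5)

    def test_invariant_to_increasing_transform(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=30)
        t = rng.exponential(10, 30)
        e = rng.integers(0, 2, 30)
        e[np.argmin(t)] = 1
        a = time_dependent_auc(s, t, e, float(np.median(t)))
        b = time_dependent_auc(np.exp(3 * s) + 7, t, e, float(np.median(t)))
        assert a == b

    def test_reduces_to_plain_auc_without_censoring(self):
        rng = np.random.default_rng(4)
        s = rng.normal(size=40)
        t = rng.exponential(10, 40)
        e = np.ones(40, dtype=int)
        horizon = float(np.median(t))
        label = (t <= horizon).astype(int)
        ranks = stats.rankdata(s)
        n1 = label.sum()
        plain = (ranks[label == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * (len(t) - n1))
        assert time_dependent_auc(s, t, e, horizon) == pytest.approx(plain, abs=1e-12)

    def test_matches_weighted_pair_oracle_with_censoring(self):
        s = np.array([0.3, 1.2, -0.5, 2.0, 0.0, -1.1, 0.8, 1.5])
        t = np.array([2.0, 5.0, 3.0, 9.0, 4.0, 8.0, 1.0, 7.0])
        e = np.array([1, 0, 1, 0, 1, 1, 1, 0])
        auc = time_dependent_auc(s, t, e, 4.5)
        assert auc == pytest.approx(oracles.ipcw_auc_pairs(s, t, e, 4.5), abs=1e-10)

    def test_cross_check_scikit_survival(self):
        sksurv_metrics = pytest.importorskip("sksurv.metrics")
        rng = np.random.default_rng(8)
        n = 120
        s = rng.normal(size=n)
        t = rng.exponential(10, n) + 0.01 * rng.random(n)  # continuous, tie-free
        e = rng.integers(0, 2, n)
        horizon = float(np.quantile(t, 0.5))
        y = np.array([(bool(ei), ti) for ei, ti in zip(e, t)], dtype=[("e", bool), ("t", float)])
        expected = float(sksurv_metrics.cumulative_dynamic_auc(y, y, s, [horizon])[0][0])
        assert time_dependent_auc(s, t, e, horizon) == pytest.approx(expected, abs=1e-6)

    def test_errors_state_missing_side(self):
        with pytest.raises(ValueError, match="no cases"):
            time_dependent_auc([1.0, 2.0], [5.0, 6.0], [1, 1], 1.0)
        with pytest.raises(ValueError, match="no controls"):
            time_dependent_auc([1.0, 2.0], [0.5, 0.6], [1, 1], 1.0)
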
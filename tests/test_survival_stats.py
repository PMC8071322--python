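import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from circdiv.survival_stats import (
    SurvivalRecord,
    circ_survival_screen,
    cox_fit,
    km_curve,
    logrank,
    logrank_trend,
)


def recs(times, events, prefix="s"):
    return [SurvivalRecord(f"{prefix}{i}", float(t), int(e)) for i, (t, e) in enumerate(zip(times, events))]


def breslow_neg_loglik(beta, times, events, x):
    """Written-out Breslow partial log-likelihood (negated), for the grid oracle."""
    ll = 0.0
    for t in sorted({t for t, e in zip(times, events) if e == 1}):
        d_idx = [i for i, (ti, ei) in enumerate(zip(times, events)) if ti == t and ei == 1]
        risk = [i for i, ti in enumerate(times) if ti >= t]
        ll += sum(beta * x[i] for i in d_idx)
        ll -= len(d_idx) * np.log(sum(np.exp(beta * x[i]) for i in risk))
    return -ll


class TestKaplanMeier:
    def test_no_events_flat_curve(self):
        curve = km_curve(recs([5, 10, 15], [0, 0, 0]))
        assert (curve["survival"] == 1.0).all()

    def test_hand_product_limit(self):
        curve = km_curve(recs([1, 2, 3], [1, 0, 1]))
        s = curve.set_index("time")["survival"]
        assert s[1.0] == pytest.approx(2 / 3)
        assert s[3.0] == pytest.approx(0.0)

    def test_time_unit_invariance(self):
        a = km_curve(recs([1, 2, 3, 4], [1, 0, 1, 0]))
        b = km_curve(recs([10, 20, 30, 40], [1, 0, 1, 0]))
        assert np.allclose(a["survival"], b["survival"])
        assert np.allclose(b["time"], a["time"] * 10)

    def test_record_order_invariance_and_late_censoring(self):
        base = recs([3, 1, 2, 5], [1, 1, 0, 1])
        a = km_curve(base)
        b = km_curve(base[::-1])
        pd.testing.assert_frame_equal(a, b)
        # a censoring after the last event: its exact time is irrelevant
        ext_a = km_curve(base + [SurvivalRecord("late", 6.0, 0)])
        ext_b = km_curve(base + [SurvivalRecord("late", 99.0, 0)])
        merged = ext_a.merge(ext_b, on="time", suffixes=("_a", "_b"))
        assert np.allclose(merged["survival_a"], merged["survival_b"])

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            SurvivalRecord("x", 0.0, 1)


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        r = recs([1, 2, 3, 1, 2, 3], [1, 0, 1, 1, 0, 1])
        res = logrank(r, ["A", "A", "A", "B", "B", "B"])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)
        assert res.observed.sum() == pytest.approx(res.expected.sum())

    def test_matches_lifelines(self):
        rng = np.random.default_rng(4)
        n = 80
        g = rng.integers(0, 3, size=n)
        t = rng.exponential(10 * (1 + g))
        c = rng.uniform(5, 40, size=n)
        times = np.minimum(t, c)
        events = (t <= c).astype(int)
        res = logrank(recs(times, events), g)
        from lifelines.statistics import multivariate_logrank_test

        ll = multivariate_logrank_test(times, g, events)
        assert res.statistic == pytest.approx(ll.test_statistic, rel=1e-8)
        assert res.p == pytest.approx(ll.p_value, rel=1e-8)
        assert res.df == 2

    def test_two_group_power_on_planted_difference(self):
        """HR 3 with n=200/arm is detected at p < 0.01 nearly always."""
        rng = np.random.default_rng(11)
        hits = 0
        n_rep = 40
        for _ in range(n_rep):
            t0 = rng.exponential(30, size=200)
            t1 = rng.exponential(10, size=200)
            c = rng.uniform(5, 60, size=400)
            t = np.r_[t0, t1]
            times, events = np.minimum(t, c), (t <= c).astype(int)
            res = logrank(recs(times, events), [0] * 200 + [1] * 200)
            hits += res.p < 0.01
        assert hits / n_rep >= 0.95

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(21)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            times = rng.exponential(10, size=60)
            events = (rng.random(60) < 0.7).astype(int)
            g = np.repeat([0, 1, 2], 20)
            rejections += logrank(recs(times, events), g).p < 0.05
        assert 0.02 <= rejections / n_rep <= 0.08

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank(recs([1, 2], [1, 1]), ["A", "A"])


class TestLogrankTrend:
    def test_identical_groups_zero(self):
        r = recs([1, 2, 3] * 3, [1, 0, 1] * 3)
        g = np.repeat([1, 2, 3], 3)
        res = logrank_trend(r, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.df == 1

    def test_two_groups_equals_plain_logrank(self):
        rng = np.random.default_rng(9)
        times = rng.exponential(10, size=50)
        events = (rng.random(50) < 0.6).astype(int)
        g = rng.integers(0, 2, size=50)
        trend = logrank_trend(recs(times, events), g, scores=(0, 1))
        plain = logrank(recs(times, events), g)
        assert trend.statistic == pytest.approx(plain.statistic, rel=1e-10)

    def test_trend_beats_unordered_for_monotone_hazard(self):
        rng = np.random.default_rng(13)
        wins = 0
        n_rep = 100
        for _ in range(n_rep):
            t = np.r_[
                rng.exponential(8, size=40),
                rng.exponential(14, size=40),
                rng.exponential(24, size=40),
            ]
            c = rng.uniform(5, 50, size=120)
            times, events = np.minimum(t, c), (t <= c).astype(int)
            g = np.repeat([1, 2, 3], 40)
            p_trend = logrank_trend(recs(times, events), g).p
            p_plain = logrank(recs(times, events), g).p
            wins += p_trend < p_plain
        assert wins / n_rep > 0.5

    def test_score_validation(self):
        r = recs([1, 2, 3], [1, 1, 1])
        with pytest.raises(ValueError, match="increasing"):
            logrank_trend(r, [1, 2, 3], scores=(3, 2, 1))


class TestCoxFit:
    def test_constant_covariate_rejected(self):
        r = recs([1, 2, 3, 4], [1, 1, 0, 1])
        with pytest.raises(ValueError, match="variation"):
            cox_fit(r, pd.DataFrame({"x": [1.0, 1.0, 1.0, 1.0]}, index=[x.sample_id for x in r]))

    def test_four_subject_grid_oracle(self):
        """Finite-MLE 4-subject design matches golden-section maximization to 1e-6."""
        times, events, x = [1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1], [1.0, 0.0, 1.0, 0.0]
        r = recs(times, events)
        fit = cox_fit(r, pd.DataFrame({"x": x}, index=[s.sample_id for s in r]))
        oracle = minimize_scalar(
            breslow_neg_loglik, bounds=(-10, 10), method="bounded",
            args=(times, events, x), options={"xatol": 1e-10},
        )
        assert fit.converged
        assert fit.coef["x"] == pytest.approx(oracle.x, abs=1e-6)

    def test_monotone_likelihood_flagged(self):
        """All early events in one arm: separation must be flagged, CI suppressed."""
        times, events, x = [1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1], [1.0, 1.0, 0.0, 0.0]
        r = recs(times, events)
        fit = cox_fit(r, pd.DataFrame({"x": x}, index=[s.sample_id for s in r]))
        assert not fit.converged
        assert np.isnan(fit.ci_lower["x"])

    def test_score_identity_with_two_group_logrank(self):
        """Logrank chi-square equals the squared Cox score test under Breslow ties."""
        rng = np.random.default_rng(17)
        n = 60
        x = rng.integers(0, 2, size=n).astype(float)
        t = rng.exponential(10 * np.exp(-0.7 * x))
        c = rng.uniform(3, 25, size=n)
        times, events = np.minimum(t, c), (t <= c).astype(int)
        lr = logrank(recs(times, events), x.astype(int))
        # score test: U(0)^2 / I(0) on the Breslow partial likelihood
        eps = 1e-5
        ll = lambda b: -breslow_neg_loglik(b, times, events, x)
        u0 = (ll(eps) - ll(-eps)) / (2 * eps)
        i0 = -(ll(eps) - 2 * ll(0.0) + ll(-eps)) / eps**2
        assert lr.statistic == pytest.approx(u0**2 / i0, rel=1e-4)

    def test_wald_ci_brackets_hr(self):
        rng = np.random.default_rng(19)
        n = 150
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(0.5 * x) ** -1 * 20)
        c = rng.uniform(5, 50, size=n)
        r = recs(np.minimum(t, c), (t <= c).astype(int))
        fit = cox_fit(r, pd.DataFrame({"x": x}, index=[s.sample_id for s in r]))
        assert fit.ci_lower["x"] < fit.hr["x"] < fit.ci_upper["x"]


class TestCircScreen:
    def _cohort(self, rng, n=181, hr=0.25, prevalence=0.5):
        present = rng.random(n) < prevalence
        t = rng.exponential(1.0 / (0.01 * np.where(present, hr, 1.0)))
        c = rng.uniform(12, 96, size=n)
        times, events = np.minimum(t, c), (t <= c).astype(int)
        r = recs(times, events)
        pres = pd.Series(present, index=[s.sample_id for s in r])
        return r, pres

    def test_protective_circ_recovered(self):
        rng = np.random.default_rng(23)
        r, pres = self._cohort(rng)
        fit, lr = circ_survival_screen(pres, r)
        assert fit.hr["detected"] < 1.0
        assert fit.ci_upper["detected"] < 1.0
        assert lr.p < 0.05

    def test_null_coverage(self):
        rng = np.random.default_rng(29)
        contains = 0
        n_rep = 60
        for _ in range(n_rep):
            r, pres = self._cohort(rng, hr=1.0)
            fit, _ = circ_survival_screen(pres, r)
            contains += fit.ci_lower["detected"] <= 1.0 <= fit.ci_upper["detected"]
        assert contains / n_rep >= 0.85

    def test_empty_stratum_rejected(self):
        r = recs([1, 2, 3], [1, 0, 1])
        pres = pd.Series([True, True, True], index=[s.sample_id for s in r])
        with pytest.raises(ValueError, match="stratum"):
            circ_survival_screen(pres, r)
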
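import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from tiicsig.errors import DegenerateDataError, FitError
from tiicsig.survival_stats import cox_fit, kaplan_meier, logrank_test, ph_check


# ---------------------------------------------------------------- oracles

def km_oracle(times, events):
    """Hand-coded product-limit estimator: list of (t, S(t)) at event times."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    out = []
    s = 1.0
    for t in np.unique(times[events]):
        at_risk = (times >= t).sum()
        deaths = ((times == t) & events).sum()
        s *= 1 - deaths / at_risk
        out.append((t, s))
    return out


def logrank_oracle(ta, ea, tb, eb):
    """Observed-minus-expected Mantel-Cox chi-square, df=1."""
    ta, tb = np.asarray(ta, float), np.asarray(tb, float)
    ea, eb = np.asarray(ea, bool), np.asarray(eb, bool)
    all_t = np.unique(np.concatenate([ta[ea], tb[eb]]))
    o_minus_e, var = 0.0, 0.0
    for t in all_t:
        na = (ta >= t).sum()
        nb = (tb >= t).sum()
        da = ((ta == t) & ea).sum()
        db = ((tb == t) & eb).sum()
        n, d = na + nb, da + db
        e_a = d * na / n
        o_minus_e += da - e_a
        if n > 1:
            var += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    chi2 = o_minus_e**2 / var
    return chi2, stats.chi2.sf(chi2, 1)


def cox_partial_likelihood_oracle(times, events, x):
    """Maximise the (no-ties) Cox partial likelihood directly."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    x = np.asarray(x, float)

    def neg_logpl(beta):
        ll = 0.0
        for i in np.flatnonzero(events):
            risk = times >= times[i]
            ll += beta * x[i] - np.log(np.exp(beta * x[risk]).sum())
        return -ll

    res = optimize.minimize_scalar(neg_logpl, bounds=(-10, 10), method="bounded",
                                   options={"xatol": 1e-10})
    return res.x


class TestKaplanMeier:
    def test_two_subject_by_hand(self):
        km = kaplan_meier([1.0, 2.0], [True, False])
        assert km(1.0) == pytest.approx(0.5)
        assert km(0.5) == 1.0

    def test_no_events_flat_one(self):
        km = kaplan_meier([3.0, 5.0, 7.0], [False, False, False])
        assert km(10.0) == 1.0

    def test_s0_is_one(self):
        km = kaplan_meier([1.0], [True])
        assert km(0.0) == 1.0

    def test_against_product_limit_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 40))
            times = rng.exponential(10, n).round(1) + 0.1
            events = rng.random(n) < 0.7
            km = kaplan_meier(times, events)
            for t, s in km_oracle(times, events):
                assert km(t) == pytest.approx(s, abs=1e-12)

    def test_nonpositive_times_rejected(self):
        with pytest.raises(DegenerateDataError):
            kaplan_meier([0.0, 1.0], [True, True])

    def test_invariant_to_late_censoring(self, rng):
        times = np.array([1.0, 2.0, 3.0, 8.0, 9.0])
        events = np.array([True, True, True, False, False])
        km1 = kaplan_meier(times, events)
        times2 = times.copy()
        times2[3:] = [20.0, 30.0]  # censoring moved past the last event
        km2 = kaplan_meier(times2, events)
        for t in (1.0, 2.0, 3.0):
            assert km1(t) == pytest.approx(km2(t))


class TestLogrank:
    def test_identical_groups(self):
        t = [1.0, 2.0, 3.0]
        e = [True, True, False]
        stat, p = logrank_test(t, e, t, e)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_no_events_warns_p_one(self):
        with pytest.warns(UserWarning):
            stat, p = logrank_test([1, 2], [False, False], [3, 4], [False, False])
        assert p == 1.0

    def test_four_subject_manual_oracle(self):
        ta, ea = [1.0, 3.0], [True, True]
        tb, eb = [2.0, 4.0], [True, True]
        stat, p = logrank_test(ta, ea, tb, eb)
        stat_o, p_o = logrank_oracle(ta, ea, tb, eb)
        assert stat == pytest.approx(stat_o, rel=1e-9)
        assert p == pytest.approx(p_o, rel=1e-9)

    def test_random_oracle_agreement(self, rng):
        for _ in range(10):
            ta = rng.exponential(10, 20).round(0) + 1
            tb = rng.exponential(15, 25).round(0) + 1
            ea = rng.random(20) < 0.8
            eb = rng.random(25) < 0.8
            stat, p = logrank_test(ta, ea, tb, eb)
            stat_o, p_o = logrank_oracle(ta, ea, tb, eb)
            assert stat == pytest.approx(stat_o, rel=1e-6)

    def test_power_under_hazard_ratio_3(self, rng):
        hits = 0
        for _ in range(40):
            ta = rng.exponential(1.0, 100) + 1e-3
            tb = rng.exponential(3.0, 100) + 1e-3
            _, p = logrank_test(ta, np.ones(100, bool), tb, np.ones(100, bool))
            hits += p < 0.01
        assert hits >= 38  # >= 95% power

    def test_permutation_p_uniform(self, rng):
        times = rng.exponential(10, 40) + 1e-3
        events = rng.random(40) < 0.8
        ps = []
        for _ in range(500):
            labels = rng.permutation(np.repeat([0, 1], 20)).astype(bool)
            _, p = logrank_test(times[labels], events[labels],
                                times[~labels], events[~labels])
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestCoxFit:
    def test_zero_variance_covariate_errors(self):
        df = pd.DataFrame({"time": [1.0, 2, 3, 4], "event": [1, 1, 0, 1], "x": [1.0] * 4})
        with pytest.raises(DegenerateDataError):
            cox_fit(df, ["x"])

    def test_manual_partial_likelihood_oracle(self):
        df = pd.DataFrame({
            "time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "event": [True] * 6,
            "x": [1.0, 0.0, 1.0, 0.0, 0.0, 1.0],
        })
        got = cox_fit(df, ["x"])
        beta_oracle = cox_partial_likelihood_oracle(df["time"], df["event"], df["x"])
        assert got.loc["x", "coef"] == pytest.approx(beta_oracle, abs=1e-6)

    def test_parameter_recovery_single_replicate(self, rng):
        n = 400
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1 / (0.05 * np.exp(np.log(2) * x)))
        c = rng.uniform(5, 60, n)
        df = pd.DataFrame({"time": np.minimum(t, c) + 1e-6, "event": t <= c, "x": x})
        got = cox_fit(df, ["x"])
        assert 1.5 < got.loc["x", "hr"] < 2.7

    def test_hr_equivariance_under_rescaling(self, rng):
        n = 200
        x = rng.normal(size=n)
        t = rng.exponential(1 / (0.05 * np.exp(0.5 * x))) + 1e-6
        df = pd.DataFrame({"time": t, "event": np.ones(n, bool), "x": x})
        b1 = cox_fit(df, ["x"]).loc["x", "coef"]
        df["x"] = df["x"] * 10
        b2 = cox_fit(df, ["x"]).loc["x", "coef"]
        assert b2 == pytest.approx(b1 / 10, rel=1e-4)

    def test_multivariable_needs_events(self):
        df = pd.DataFrame({
            "time": [1.0, 2, 3, 4], "event": [True, False, False, False],
            "x": [1.0, 2, 3, 4], "y": [4.0, 3, 2, 1],
        })
        with pytest.raises(DegenerateDataError, match="events"):
            cox_fit(df, ["x", "y"], adjustment="multivariable")

    def test_missing_covariate_rejected(self):
        df = pd.DataFrame({"time": [1.0, 2], "event": [1, 1], "x": [np.nan, 1.0]})
        with pytest.raises(DegenerateDataError):
            cox_fit(df, ["x"])

    def test_univariate_vs_multivariable_columns(self, rng):
        n = 150
        df = pd.DataFrame({
            "time": rng.exponential(20, n) + 1e-3,
            "event": rng.random(n) < 0.7,
            "x": rng.normal(size=n),
            "y": rng.normal(size=n),
        })
        uni = cox_fit(df, ["x", "y"], adjustment="univariate")
        multi = cox_fit(df, ["x", "y"], adjustment="multivariable")
        assert list(uni.index) == ["x", "y"]
        assert list(multi.index) == ["x", "y"]
        assert {"hr", "ci_lo", "ci_hi", "p"} <= set(uni.columns)


class TestPhCheck:
    def test_zero_variance_errors(self):
        df = pd.DataFrame({"time": [1.0, 2, 3], "event": [1, 1, 1], "x": [2.0] * 3})
        with pytest.raises(DegenerateDataError):
            ph_check(df, "x")

    def test_proportional_data_satisfied(self, rng):
        n = 150
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1 / (0.08 * np.exp(0.7 * x)))
        c = rng.uniform(5, 40, n)
        df = pd.DataFrame({"time": np.minimum(t, c) + 1e-6, "event": t <= c, "x": x})
        p, ok = ph_check(df, "x")
        assert 0 < p <= 1

    def test_reversing_effect_flagged(self):
        # effect flips sign at the median follow-up time: PH clearly violated
        rng = np.random.default_rng(7)
        n = 500
        x = rng.integers(0, 2, n).astype(float)
        early = rng.exponential(1 / (0.30 * np.exp(1.5 * x)))
        t = np.where(early < 3.0, early, 3.0 + rng.exponential(1 / (0.30 * np.exp(-1.5 * x))))
        df = pd.DataFrame({"time": t + 1e-6, "event": np.ones(n, bool), "x": x})
        p, ok = ph_check(df, "x")
        assert not ok
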
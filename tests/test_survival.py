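import numpy as np
import pandas as pd
import pytest

from constru import (
    SurvivalError,
    Term,
    compare_distributions,
    fit_cox,
    km_estimate,
    logrank_test,
)
from constru.survival import _efron_ll_grad_hess, _tie_groups

from _oracles import efron_loglik, grid_search_beta, simulate_one_cov


class TestCoxFit:
    def test_matches_grid_search_oracle(self):
        t, e, x = simulate_one_cov(seed=1)
        res = fit_cox(t, e, [Term("x", x)])
        beta_grid = grid_search_beta(t, e, x)
        assert abs(res["x"]["coef"] - beta_grid) < 1e-3

    def test_matches_lifelines_multivariable(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(5)
        n = 120
        x1 = rng.standard_normal(n)
        x2 = (rng.random(n) < 0.4).astype(float)
        t = rng.exponential(np.exp(-(0.5 * x1 - 0.8 * x2)))
        e = (rng.random(n) < 0.7).astype(int)
        mine = fit_cox(t, e, [Term("x1", x1), Term("x2", x2)])
        cph = CoxPHFitter().fit(pd.DataFrame({"t": t, "e": e, "x1": x1, "x2": x2}), "t", "e")
        for term in ("x1", "x2"):
            assert mine[term]["coef"] == pytest.approx(cph.params_[term], abs=1e-4)
            assert mine[term]["p"] == pytest.approx(cph.summary.loc[term, "p"], rel=1e-3)

    def test_matches_breslow_when_no_ties(self):
        # with no tied event times Efron reduces to Breslow; cross-check
        # against scikit-survival, whose fitter uses the Breslow likelihood
        from sksurv.linear_model import CoxPHSurvivalAnalysis

        rng = np.random.default_rng(11)
        n = 100
        x = rng.standard_normal((n, 2))
        t = rng.exponential(np.exp(-x @ [0.6, -0.4]))
        e = rng.random(n) < 0.75
        assert len(np.unique(t[e])) == e.sum()  # tie-free by construction
        mine = fit_cox(t, e.astype(int), [Term("a", x[:, 0]), Term("b", x[:, 1])])
        y = np.array(list(zip(e, t)), dtype=[("e", bool), ("t", float)])
        sk = CoxPHSurvivalAnalysis(tol=1e-12).fit(x, y)
        np.testing.assert_allclose(mine.summary["coef"], sk.coef_, atol=1e-6)

    def test_constant_covariate_error_names_term(self):
        t = np.arange(1.0, 11.0)
        e = np.ones(10, dtype=int)
        with pytest.raises(SurvivalError, match="flat"):
            fit_cox(t, e, [Term("flat", np.ones(10))])

    def test_hazard_ratio_is_exp_coef(self):
        t, e, x = simulate_one_cov(seed=3)
        res = fit_cox(t, e, [Term("x", x)])
        assert res["x"]["hr"] == np.exp(res["x"]["coef"])
        assert res["x"]["ci95_low"] <= res["x"]["hr"] <= res["x"]["ci95_high"]

    def test_shift_and_scale_invariance(self):
        rng = np.random.default_rng(8)
        n = 80
        x = rng.standard_normal(n)
        t = rng.exponential(np.exp(-0.5 * x))
        e = (rng.random(n) < 0.8).astype(int)
        base = fit_cox(t, e, [Term("x", x)])
        shifted = fit_cox(t, e, [Term("x", x + 100.0)])
        scaled = fit_cox(t, e, [Term("x", 4.0 * x)])
        assert shifted["x"]["coef"] == pytest.approx(base["x"]["coef"], abs=1e-8)
        assert shifted["x"]["p"] == pytest.approx(base["x"]["p"], rel=1e-9)
        assert scaled["x"]["coef"] == pytest.approx(base["x"]["coef"] / 4.0, abs=1e-8)
        assert scaled["x"]["p"] == pytest.approx(base["x"]["p"], rel=1e-6)

    def test_categorical_expansion_against_reference(self):
        rng = np.random.default_rng(9)
        n = 90
        g = rng.choice(["low", "high", "NA"], size=n)
        t = rng.exponential(np.exp(np.where(g == "high", -0.8, 0.0)))
        e = np.ones(n, dtype=int)
        res = fit_cox(t, e, [Term("stage", g, kind="categorical", reference="low")])
        assert set(res.summary.index) == {"stage[high]", "stage[NA]"}

    def test_monotone_likelihood_flagged_not_raised(self):
        # perfectly separating covariate: likelihood increases without bound
        t = np.arange(1.0, 21.0)
        e = np.r_[np.ones(10), np.zeros(10)].astype(int)
        x = np.r_[np.ones(10), np.zeros(10)]
        res = fit_cox(t, e, [Term("x", x)])
        assert not res.converged
        assert np.isnan(res["x"]["p"])

    def test_too_few_events_rejected(self):
        with pytest.raises(SurvivalError, match="events"):
            fit_cox([1, 2, 3], [0, 0, 1], [Term("x", [1.0, 2.0, 3.0])])

    def test_tie_groups_structure(self):
        T = np.array([1.0, 1.0, 2.0, 3.0, 3.0, 4.0])
        E = np.array([1, 1, 0, 1, 1, 0])
        ev, starts, d, risk_idx = _tie_groups(T, E)
        assert ev.tolist() == [0, 1, 3, 4]
        assert d.tolist() == [2, 2]
        assert risk_idx.tolist() == [0, 3]

    def test_gradient_matches_numerical_derivative(self):
        t, e, x = simulate_one_cov(seed=4)
        order = np.argsort(t, kind="stable")
        T, E, X = t[order], e[order], x[order][:, None]
        groups = _tie_groups(T, E)
        beta = np.array([0.3])
        _, grad, _ = _efron_ll_grad_hess(beta, X, groups)
        h = 1e-6
        num = (efron_loglik(0.3 + h, T, E, X[:, 0]) - efron_loglik(0.3 - h, T, E, X[:, 0])) / (2 * h)
        assert grad[0] == pytest.approx(num, abs=1e-4)


def hand_logrank_two_groups(times_a, events_a, times_b, events_b):
    """Observed-minus-expected tabulation over the pooled event times."""
    o_minus_e, var = 0.0, 0.0
    all_t = np.r_[times_a, times_b]
    all_e = np.r_[events_a, events_b]
    in_a = np.r_[np.ones(len(times_a), bool), np.zeros(len(times_b), bool)]
    for t in sorted(set(all_t[all_e == 1])):
        at_risk = all_t >= t
        death = (all_t == t) & (all_e == 1)
        n, na = at_risk.sum(), (at_risk & in_a).sum()
        d = death.sum()
        o_minus_e += (death & in_a).sum() - d * na / n
        if n > 1:
            var += d * (na / n) * (1 - na / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestLogrank:
    def test_identical_groups_give_null(self):
        t = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        e = np.array([1, 1, 0, 1, 1, 0])
        g = ["A"] * 3 + ["B"] * 3
        chi2, p = logrank_test(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_tabulation(self):
        ta, ea = np.array([1.0, 2.0, 3.0]), np.array([1, 1, 0])
        tb, eb = np.array([1.5, 2.5, 3.5]), np.array([1, 1, 1])
        chi2, _ = logrank_test(np.r_[ta, tb], np.r_[ea, eb], ["A"] * 3 + ["B"] * 3)
        assert chi2 == pytest.approx(hand_logrank_two_groups(ta, ea, tb, eb), rel=1e-10)

    def test_single_group_error(self):
        with pytest.raises(SurvivalError):
            logrank_test([1, 2, 3], [1, 1, 0], ["A", "A", "A"])

    def test_three_group_chi2_df2(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(1, 90)
        e = np.ones(90, dtype=int)
        g = np.repeat(["A", "B", "C"], 30)
        chi2, p = logrank_test(t, e, g)
        from scipy import stats
        assert p == pytest.approx(stats.chi2.sf(chi2, df=2), rel=1e-9)


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        km = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        assert km.survival_at(1.0) == pytest.approx(2 / 3)
        assert km.survival_at(2.0) == pytest.approx(1 / 3)
        assert km.survival_at(3.0) == pytest.approx(0.0)

    def test_all_censored_stays_at_one(self):
        km = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert km.survival_at(3.0) == 1.0

    def test_mixed_censoring_hand_product(self):
        # events at 1 and 3, censor at 2: S(1)=2/3, S(3)=2/3 * 0/1 = 0
        km = km_estimate([1.0, 2.0, 3.0], [1, 0, 1])
        assert km.survival_at(1.0) == pytest.approx(2 / 3)
        assert km.survival_at(3.0) == pytest.approx(0.0)

    def test_survival_monotone_in_groups(self):
        rng = np.random.default_rng(6)
        t = rng.exponential(1, 60)
        e = (rng.random(60) < 0.8).astype(int)
        g = np.repeat(["A", "B"], 30)
        km = km_estimate(t, e, g)
        for tbl in km.groups.values():
            s = tbl["survival"].to_numpy()
            assert s[0] <= 1.0
            assert (np.diff(s) <= 1e-12).all()


class TestCompareDistributions:
    def test_identical_vectors_p_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        _, _, p = compare_distributions(x, x.copy())
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_skewed_data_routes_to_mann_whitney(self):
        rng = np.random.default_rng(12)
        x = rng.lognormal(0, 2.0, 60)  # heavily skewed: Shapiro-Wilk fails
        y = rng.normal(0, 1, 60)
        name, _, _ = compare_distributions(x, y)
        assert name == "Mann-Whitney"

    def test_normal_data_routes_to_t_test(self):
        rng = np.random.default_rng(13)
        name, _, _ = compare_distributions(rng.normal(0, 1, 50), rng.normal(0.2, 1, 50))
        assert name == "t-test"

    def test_short_vector_error(self):
        with pytest.raises(SurvivalError):
            compare_distributions([1.0, 2.0], [1.0, 2.0, 3.0])
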
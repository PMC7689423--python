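import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as ss
from lifelines import CoxPHFitter

from immunosig import (
    ExpressionMatrix,
    ValidationError,
    cox_fit,
    kaplan_meier,
    logrank_test,
    maxstat_cutpoint,
    miller_siegmund_correct,
    pairwise_logrank,
    per_gene_cox,
)
from immunosig.survival import (
    _efron_neg_loglik_and_derivs,
    _logrank_scores,
    _univariate_cox,
)


def _surv(times, events, index=None):
    index = index if index is not None else [f"s{i}" for i in range(len(times))]
    return pd.DataFrame({"time": times, "event": events}, index=index)


class TestKaplanMeier:
    def test_hand_computed_four_subjects(self):
        # times 5+, 8, 12, 16+: S(8) = 3/4 * ... wait hand compute:
        # at t=8, at risk {8,12,16} (5 censored before) -> 3 at risk, 1 event
        # S(8) = 1 - 1/3 = 2/3; at t=12, at risk {12,16} -> S = 2/3 * 1/2 = 1/3
        km = kaplan_meier(_surv([5, 8, 12, 16], [0, 1, 1, 0]))
        assert km.survival_at(7.9) == pytest.approx(1.0)
        assert km.survival_at(8) == pytest.approx(2.0 / 3.0)
        assert km.survival_at(12) == pytest.approx(1.0 / 3.0)
        assert km.survival_at(100) == pytest.approx(1.0 / 3.0)

    def test_all_events_step_function(self):
        km = kaplan_meier(_surv([1, 2, 3, 4], [1, 1, 1, 1]))
        assert km.survival_at(1) == pytest.approx(0.75)
        assert km.survival_at(4) == pytest.approx(0.0)

    def test_all_censored_flat_one(self):
        km = kaplan_meier(_surv([3, 6, 9], [0, 0, 0]))
        assert km.survival_at(9) == pytest.approx(1.0)

    def test_tied_event_times(self):
        # 2 events among 4 at risk at t=5 -> S(5) = 1/2
        km = kaplan_meier(_surv([5, 5, 7, 9], [1, 1, 0, 1]))
        assert km.survival_at(5) == pytest.approx(0.5)

    def test_invalid_times_rejected(self):
        with pytest.raises(ValidationError):
            kaplan_meier(_surv([0, 5], [1, 1]))


class TestLogrank:
    def test_identical_groups_p_near_one(self):
        g = _surv([3, 5, 8, 12, 20], [1, 0, 1, 1, 0])
        res = logrank_test([g, g.copy()])
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p == pytest.approx(1.0)

    def test_statistic_matches_hand_oe_computation(self):
        a = _surv([2, 4, 6, 8], [1, 1, 0, 1])
        b = _surv([5, 7, 9, 11], [1, 0, 1, 1], index=list("wxyz"))
        res = logrank_test([a, b])
        # independent O-E/V chi-square computed directly
        times = np.r_[a["time"], b["time"]].astype(float)
        events = np.r_[a["event"], b["event"]].astype(int)
        grp = np.r_[np.zeros(4), np.ones(4)]
        o_minus_e = v = 0.0
        for t in np.unique(times[events == 1]):
            at = times >= t
            n, n1 = at.sum(), (at & (grp == 0)).sum()
            d = ((times == t) & (events == 1)).sum()
            d1 = ((times == t) & (events == 1) & (grp == 0)).sum()
            o_minus_e += d1 - d * n1 / n
            if n > 1:
                v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        assert res.statistic == pytest.approx(o_minus_e ** 2 / v)
        assert res.p == pytest.approx(ss.chi2.sf(res.statistic, 1))

    def test_permutation_mode_matches_enumeration_oracle(self):
        a = _surv([1, 4, 7], [1, 1, 0])
        b = _surv([3, 9, 12, 15], [1, 1, 0, 1], index=list("wxyz"))
        res = logrank_test([a, b], method="permutation")
        # test-local oracle: enumerate all C(7,3) label assignments
        times = np.r_[a["time"], b["time"]].astype(float)
        events = np.r_[a["event"], b["event"]].astype(int)
        from lifelines.statistics import multivariate_logrank_test

        obs = res.statistic
        count = total = 0
        for combo in itertools.combinations(range(7), 3):
            lab = np.ones(7, dtype=int)
            lab[list(combo)] = 0
            s = float(multivariate_logrank_test(times, lab, events).test_statistic)
            total += 1
            if s >= obs - 1e-12:
                count += 1
        assert total == 35
        assert res.p == pytest.approx(count / total, abs=1e-12)

    def test_permutation_infeasible_guard(self):
        rng = np.random.default_rng(0)
        a = _surv(rng.uniform(1, 10, 15), np.ones(15, dtype=int))
        b = _surv(rng.uniform(1, 10, 15), np.ones(15, dtype=int),
                  index=[f"t{i}" for i in range(15)])
        with pytest.raises(ValidationError, match="infeasible"):
            logrank_test([a, b], method="permutation")

    def test_three_groups_df(self):
        rng = np.random.default_rng(1)
        gs = [_surv(rng.exponential(10, 20), np.ones(20, dtype=int),
                    index=[f"g{k}_{i}" for i in range(20)]) for k in range(3)]
        res = logrank_test(gs)
        assert res.df == 2

    def test_pairwise_table(self):
        rng = np.random.default_rng(2)
        groups = {
            name: _surv(rng.exponential(scale, 25), np.ones(25, dtype=int),
                        index=[f"{name}{i}" for i in range(25)])
            for name, scale in [("a", 5.0), ("b", 5.0), ("c", 40.0)]
        }
        table = pairwise_logrank(groups).set_index(["group_a", "group_b"])
        assert table.loc[("a", "c"), "p"] < 0.001
        assert table.loc[("a", "b"), "p"] > 0.05


class TestMillerSiegmund:
    def test_closed_form_value_at_b3(self):
        # phi(3)(3 - 1/3) ln(0.81/0.01) + 4 phi(3)/3 = 0.057839...
        phi = ss.norm.pdf(3.0)
        expected = phi * (3 - 1 / 3) * np.log(0.81 / 0.01) + 4 * phi / 3
        assert miller_siegmund_correct(3.0) == pytest.approx(expected)
        assert expected == pytest.approx(0.0578, abs=5e-4)

    @pytest.mark.parametrize("b", [2.0, 2.5, 3.0, 4.0, 5.0, 6.0])
    def test_more_conservative_than_pointwise(self, b):
        assert miller_siegmund_correct(b) >= 2 * ss.norm.sf(b)

    def test_monotone_decreasing_in_b(self):
        bs = np.linspace(1.5, 8.0, 50)
        ps = [miller_siegmund_correct(b) for b in bs]
        assert all(x >= y for x, y in zip(ps, ps[1:]))

    def test_b_below_one_returns_one(self):
        assert miller_siegmund_correct(0.8) == 1.0

    def test_wider_window_larger_correction(self):
        assert (miller_siegmund_correct(3.0, 0.05, 0.05)
                > miller_siegmund_correct(3.0, 0.25, 0.25))

    def test_invalid_eps_rejected(self):
        with pytest.raises(ValidationError):
            miller_siegmund_correct(3.0, 0.0, 0.1)


class TestLogrankScores:
    def test_scores_sum_to_zero(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(10, 40)
        e = rng.integers(0, 2, 40)
        e[0] = 1
        a = _logrank_scores(t, e)
        assert a.sum() == pytest.approx(0.0, abs=1e-10)

    def test_hand_computed_no_ties(self):
        # times 1,2,3 all events: H = 1/3, 1/3+1/2, 1/3+1/2+1
        t = np.array([1.0, 2.0, 3.0])
        e = np.array([1, 1, 1])
        a = _logrank_scores(t, e)
        np.testing.assert_allclose(a, [1 - 1 / 3, 1 - 5 / 6, 1 - 11 / 6])


class TestMaxstat:
    def test_planted_cutpoint_recovered(self):
        rng = np.random.default_rng(10)
        n = 120
        score = pd.Series(rng.uniform(0, 10, n), index=[f"s{i}" for i in range(n)])
        high = score > 6.0
        t = np.where(high, rng.exponential(60, n), rng.exponential(8, n))
        d = _surv(np.clip(t, 0.01, None), np.ones(n, dtype=int),
                  index=score.index)
        res = maxstat_cutpoint(score, d)
        assert abs(res.cutpoint - 6.0) < 1.0
        assert res.p_corrected < 1e-6
        assert res.p_corrected >= res.p_pointwise

    def test_scan_respects_epsilon_window(self):
        rng = np.random.default_rng(12)
        n = 50
        score = pd.Series(np.arange(n, dtype=float),
                          index=[f"s{i}" for i in range(n)])
        d = _surv(rng.exponential(10, n), np.ones(n, dtype=int),
                  index=score.index)
        res = maxstat_cutpoint(score, d, eps=0.2)
        ranks = score.rank()
        low_n = (score <= res.scan["cutpoint"].min()).sum()
        high_n = (score > res.scan["cutpoint"].max()).sum()
        assert low_n >= 10 and high_n >= 10
        assert len(res.scan) <= n - 1

    def test_statistic_matches_direct_logrank_z(self):
        """b at the chosen cut equals the standardized permutation
        two-sample log-rank statistic computed directly from scores."""
        rng = np.random.default_rng(21)
        n = 30
        score = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
        events = rng.integers(0, 2, n)
        events[0] = 1
        d = _surv(rng.exponential(10, n), events, index=score.index)
        res = maxstat_cutpoint(score, d)
        a = _logrank_scores(d["time"].to_numpy(), d["event"].to_numpy(int))
        low = (score <= res.cutpoint).to_numpy()
        k = low.sum()
        abar, ssa = a.mean(), ((a - a.mean()) ** 2).sum()
        num = a[low].sum() - k * abar
        var = k * (n - k) / (n * (n - 1)) * ssa
        assert res.statistic == pytest.approx(abs(num) / np.sqrt(var))

    def test_null_score_rarely_significant(self):
        rng = np.random.default_rng(30)
        hits = 0
        reps = 120
        for _ in range(reps):
            n = 60
            score = pd.Series(rng.normal(size=n),
                              index=[f"s{i}" for i in range(n)])
            d = _surv(rng.exponential(10, n), np.ones(n, dtype=int),
                      index=score.index)
            if maxstat_cutpoint(score, d).p_corrected < 0.05:
                hits += 1
        # corrected rate should be near/below nominal; binomial(120, 0.05)
        # has P(X > 13) < 1e-3
        assert hits <= 13

    def test_constant_score_rejected(self):
        score = pd.Series(np.ones(10), index=[f"s{i}" for i in range(10)])
        d = _surv(np.arange(1, 11, dtype=float), np.ones(10, dtype=int),
                  index=score.index)
        with pytest.raises(ValidationError, match="constant"):
            maxstat_cutpoint(score, d)


class TestCoxFit:
    def test_matches_lifelines_directly(self):
        rng = np.random.default_rng(5)
        n = 80
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.8 * x) * 10)
        e = (rng.uniform(size=n) < 0.7).astype(int)
        idx = [f"s{i}" for i in range(n)]
        cov = pd.DataFrame({"x": x}, index=idx)
        d = _surv(t, e, index=idx)
        res = cox_fit(cov, d)
        ref = CoxPHFitter().fit(
            pd.DataFrame({"x": x, "time": t, "event": e}),
            duration_col="time", event_col="event")
        assert res.table.loc["x", "coef"] == pytest.approx(
            ref.summary.loc["x", "coef"])

    def test_hr_scaling_equivariance(self):
        rng = np.random.default_rng(6)
        n = 60
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-x) * 10)
        idx = [f"s{i}" for i in range(n)]
        d = _surv(t, np.ones(n, dtype=int), index=idx)
        a = cox_fit(pd.DataFrame({"x": x}, index=idx), d)
        b = cox_fit(pd.DataFrame({"x": 2 * x}, index=idx), d)
        assert b.table.loc["x", "coef"] == pytest.approx(
            a.table.loc["x", "coef"] / 2, rel=1e-6)
        assert b.table.loc["x", "p"] == pytest.approx(
            a.table.loc["x", "p"], rel=1e-6)

    def test_stratified_fit_drops_stratum_covariate(self):
        rng = np.random.default_rng(7)
        n = 100
        x = rng.normal(size=n)
        stratum = rng.integers(0, 2, n)
        t = rng.exponential(np.exp(-0.5 * x) * (5 + 10 * stratum))
        idx = [f"s{i}" for i in range(n)]
        cov = pd.DataFrame({"x": x, "grp": stratum}, index=idx)
        res = cox_fit(cov, _surv(t, np.ones(n, dtype=int), index=idx),
                      strata="grp")
        assert "grp" not in res.table.index
        assert res.strata == "grp"

    def test_constant_covariate_within_stratum_rejected(self):
        idx = [f"s{i}" for i in range(6)]
        cov = pd.DataFrame({"x": [1, 1, 1, 0, 1, 0], "grp": [0, 0, 0, 1, 1, 1]},
                           index=idx)
        d = _surv([1, 2, 3, 4, 5, 6], [1, 1, 1, 1, 1, 1], index=idx)
        with pytest.raises(ValidationError, match="constant within"):
            cox_fit(cov, d, strata="grp")


class TestUnivariateCox:
    def test_matches_grid_search_on_partial_likelihood(self):
        # oracle: maximize the Efron log partial likelihood on a beta grid
        x = np.array([0.5, -1.2, 0.3, 2.0, -0.7, 1.1])
        t = np.array([3.0, 9.0, 5.0, 1.5, 12.0, 4.0])
        e = np.array([1, 1, 0, 1, 1, 1])
        beta, se, ll = _univariate_cox(x, t, e)
        grid = np.arange(-5.0, 5.0, 1e-3)
        lls = np.array([_efron_neg_loglik_and_derivs(b, x, t, e)[0]
                        for b in grid])
        assert abs(beta - grid[np.argmax(lls)]) <= 2e-3
        assert ll == pytest.approx(lls.max(), abs=1e-5)

    def test_matches_lifelines_with_ties(self):
        rng = np.random.default_rng(9)
        n = 50
        x = rng.normal(size=n)
        t = np.round(rng.exponential(np.exp(-0.6 * x) * 10), 0) + 1.0
        e = (rng.uniform(size=n) < 0.8).astype(int)
        beta, se, _ = _univariate_cox(x, t, e)
        ref = CoxPHFitter().fit(
            pd.DataFrame({"x": x, "time": t, "event": e}),
            duration_col="time", event_col="event")
        assert beta == pytest.approx(ref.summary.loc["x", "coef"], abs=1e-5)
        assert se == pytest.approx(ref.summary.loc["x", "se(coef)"], rel=1e-4)

    def test_separation_detected(self):
        x = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        t = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        e = np.ones(6, dtype=int)
        with pytest.raises(ValidationError):
            _univariate_cox(x, t, e)


@pytest.fixture(scope="module")
def planted_scan():
    rng = np.random.default_rng(13)
    n = 90
    idx = [f"s{i}" for i in range(n)]
    protective = rng.normal(size=n)
    harmful = rng.normal(size=n)
    lam = 0.05 * np.exp(-1.0 * protective + 1.0 * harmful)
    t = rng.exponential(1.0 / lam)
    d = _surv(t, np.ones(n, dtype=int), index=idx)
    genes = {"PROT": protective, "HARM": harmful, "FLAT": np.zeros(n)}
    for i in range(20):
        genes[f"NULL{i}"] = rng.normal(size=n)
    m = ExpressionMatrix(pd.DataFrame(genes, index=idx).T, state="normalized")
    return per_gene_cox(m, d)


class TestPerGeneCox:
    def test_planted_directions_and_significance(self, planted_scan):
        out = planted_scan
        assert out.loc["PROT", "hr"] < 1 and out.loc["PROT", "q"] < 0.05
        assert out.loc["HARM", "hr"] > 1 and out.loc["HARM", "q"] < 0.05

    def test_constant_gene_flagged_not_fitted(self, planted_scan):
        assert planted_scan.loc["FLAT", "status"] == "constant"
        assert np.isnan(planted_scan.loc["FLAT", "q"])

    def test_q_only_over_fitted_genes(self, planted_scan):
        ok = planted_scan["status"] == "ok"
        assert planted_scan.loc[ok, "q"].notna().all()
        assert ok.sum() == 22

    def test_null_fdr_controlled(self, planted_scan):
        nulls = planted_scan.loc[[f"NULL{i}" for i in range(20)]]
        assert (nulls["q"] < 0.05).sum() <= 1
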
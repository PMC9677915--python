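import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from matreotype import (InputError, cox_ph, encode_stage, fisher_enrichment,
                        group_compare_bh, km_logrank)


def _surv(times, events, prefix="s"):
    idx = [f"{prefix}{i}" for i in range(len(times))]
    return pd.DataFrame({"sample_id": idx, "time_months": times,
                         "event": events}).set_index("sample_id")


class TestKmLogrank:
    def test_identical_groups_give_null_test(self):
        times = [3.0, 5.0, 8.0, 12.0]
        events = [1, 0, 1, 1]
        surv = _surv(times + times, events + events)
        groups = pd.Series(["A"] * 4 + ["B"] * 4, index=surv.index)
        res = km_logrank(surv, groups)
        assert res.logrank_chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.logrank_p == pytest.approx(1.0)

    def test_statistic_matches_hand_enumeration(self):
        """Group A dies at t=1,2; group B at t=3,4: the log-rank O-E/V over
        the four event-time tables gives chi2 = (2 - (4/4+3/3... ))."""
        surv = _surv([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
        groups = pd.Series(["A", "A", "B", "B"], index=surv.index)
        # hand computation: at t=1 nA=2,nB=2,d=1 -> eA=1/2, v=1/4*... per table
        o_minus_e, var = 0.0, 0.0
        at_risk_a, at_risk_b = 2, 2
        for t, is_a in [(1, 1), (2, 1), (3, 0), (4, 0)]:
            n = at_risk_a + at_risk_b
            e_a = at_risk_a / n
            o_minus_e += is_a - e_a
            var += at_risk_a * at_risk_b / n ** 2 if n > 1 else 0.0
            if is_a:
                at_risk_a -= 1
            else:
                at_risk_b -= 1
        chi2 = o_minus_e ** 2 / var
        res = km_logrank(surv, groups)
        assert res.logrank_chi2 == pytest.approx(chi2, abs=1e-9)

    def test_km_starts_at_one_and_equals_empirical_without_censoring(self):
        rng = np.random.default_rng(0)
        times = rng.exponential(10.0, 50).round(3) + 0.01
        surv = _surv(np.r_[times, times * 0.5],
                     np.ones(100, int))
        groups = pd.Series(["A"] * 50 + ["B"] * 50, index=surv.index)
        res = km_logrank(surv, groups)
        km_a = res.km_curves["A"]["survival"]
        assert km_a.iloc[0] == 1.0
        assert (km_a.diff().dropna() <= 1e-12).all()
        t_half = np.quantile(times, 0.5)
        emp = (times > t_half).mean()
        km_at = km_a[km_a.index <= t_half].iloc[-1]
        assert km_at == pytest.approx(emp, abs=0.5 / 50 + 1e-9)

    def test_zero_event_group_warns_but_returns(self, caplog):
        surv = _surv([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], [1, 1, 0, 0, 1, 1])
        groups = pd.Series(["A", "A", "B", "B", "C", "C"], index=surv.index)
        with caplog.at_level("WARNING", logger="matreotype"):
            res = km_logrank(surv, groups)
        assert "zero events" in caplog.text
        assert res.logrank_df == 1  # B dropped from the test
        assert "B" in res.km_curves  # but kept in the KM output

    def test_logrank_p_uniform_under_permutation(self):
        """Permuting labels on null data yields uniform p-values."""
        rng = np.random.default_rng(1)
        n = 60
        times = rng.exponential(20.0, n) + 0.01
        events = (rng.random(n) < 0.8).astype(int)
        surv = _surv(times, events)
        pvals = []
        for _ in range(300):
            labels = pd.Series(rng.permutation(["A"] * 30 + ["B"] * 30),
                               index=surv.index)
            pvals.append(km_logrank(surv, labels).logrank_p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestCox:
    def test_recovers_planted_hazard_ratio(self):
        rng = np.random.default_rng(2)
        n = 300
        lab = np.r_[np.ones(n), np.zeros(n)]
        hz = 0.05 * np.exp(math.log(2.0) * lab)
        t_event = rng.exponential(1.0 / hz)
        t_cens = rng.exponential(1.0 / (hz * 0.25))
        surv = _surv(np.minimum(t_event, t_cens) + 1e-6,
                     (t_event <= t_cens).astype(int))
        groups = pd.Series(np.where(lab == 1, "high", "low"), index=surv.index)
        res = cox_ph(surv, groups, reference="low")
        beta = res.cox_summary["coef"].iloc[0]
        assert 0.51 <= beta <= 0.88
        assert res.cox_summary["hr_ci_low"].iloc[0] < math.exp(beta) \
            < res.cox_summary["hr_ci_high"].iloc[0]

    def test_label_swap_inverts_hazard_ratio(self):
        rng = np.random.default_rng(3)
        n = 80
        times = rng.exponential(10, 2 * n) + 0.01
        events = (rng.random(2 * n) < 0.9).astype(int)
        surv = _surv(times, events)
        groups = pd.Series(["a"] * n + ["b"] * n, index=surv.index)
        hr_ab = cox_ph(surv, groups, reference="a").cox_summary["coef"].iloc[0]
        hr_ba = cox_ph(surv, groups, reference="b").cox_summary["coef"].iloc[0]
        assert hr_ab == pytest.approx(-hr_ba, abs=1e-8)

    def test_efron_matches_breslow_without_ties(self):
        """With unique event times the Efron and Breslow partial likelihoods
        coincide; compare against a hand-rolled Breslow Newton fit."""
        rng = np.random.default_rng(4)
        n = 120
        x = rng.standard_normal(n)
        times = rng.exponential(np.exp(-0.7 * x)) + 1e-9
        assert len(np.unique(times)) == n
        events = np.ones(n, int)
        surv = _surv(times, events)
        scores = pd.Series(x, index=surv.index, name="x")

        def breslow_beta():
            order = np.argsort(times)
            xs = x[order]
            beta = 0.0
            for _ in range(50):
                eta = np.exp(beta * xs)
                s0 = np.cumsum(eta[::-1])[::-1]
                s1 = np.cumsum((xs * eta)[::-1])[::-1]
                s2 = np.cumsum((xs ** 2 * eta)[::-1])[::-1]
                grad = np.sum(xs - s1 / s0)
                hess = -np.sum(s2 / s0 - (s1 / s0) ** 2)
                step = grad / hess
                beta -= step
                if abs(step) < 1e-12:
                    break
            return beta

        res = cox_ph(surv, scores)
        assert res.cox_summary["coef"].iloc[0] == pytest.approx(
            breslow_beta(), abs=1e-8)

    def test_identical_arms_estimate_near_zero(self):
        rng = np.random.default_rng(5)
        n = 500
        times = rng.exponential(10, 2 * n) + 0.01
        events = (rng.random(2 * n) < 0.85).astype(int)
        surv = _surv(times, events)
        groups = pd.Series(["a"] * n + ["b"] * n, index=surv.index)
        beta = cox_ph(surv, groups).cox_summary["coef"].iloc[0]
        assert abs(beta) < 0.1

    def test_covariate_adjustment_accepts_stage_coding(self):
        assert encode_stage(pd.Series(["I", "Stage II", "iv"])).tolist() == \
            [1.0, 2.0, 4.0]
        with pytest.raises(InputError):
            encode_stage(pd.Series(["bogus"]))

    def test_invalid_survival_rejected(self):
        surv = _surv([0.0, 1.0], [1, 1])
        groups = pd.Series(["a", "b"], index=surv.index)
        with pytest.raises(InputError):
            cox_ph(surv, groups)


class TestFisher:
    def test_reproduces_published_subtype_association_table(self):
        """Observed matreotype-by-canonical-subtype contingency counts give
        the printed exact-test p-values for each subtype column."""
        matreotype = pd.Series(["ECM-Low"] * 94 + ["ECM-High"] * 129)
        subtype = pd.Series(["primitive"] * 12 + ["classical"] * 61
                            + ["secretory"] * 7 + ["basal"] * 14
                            + ["primitive"] * 9 + ["classical"] * 33
                            + ["secretory"] * 41 + ["basal"] * 46)
        res = fisher_enrichment(matreotype, subtype)
        assert res.loc["classical", "p_value"] == pytest.approx(5.18e-9, rel=5e-3)
        assert res.loc["basal", "p_value"] == pytest.approx(6.93e-4, rel=5e-3)
        assert res.loc["primitive", "p_value"] == pytest.approx(0.167, rel=5e-3)

    def test_small_table_matches_enumeration(self):
        """[[3,1],[1,3]]: enumerating all hypergeometric outcomes gives a
        two-sided p of 34/70."""
        a = pd.Series(["x"] * 4 + ["y"] * 4)
        b = pd.Series(["in"] * 3 + ["out"] + ["in"] + ["out"] * 3)
        res = fisher_enrichment(a, b)
        assert res.loc["in", "p_value"] == pytest.approx(34.0 / 70.0)

    def test_matches_brute_force_for_all_small_tables(self):
        rng = np.random.default_rng(6)
        for _ in range(25):
            n = int(rng.integers(8, 41))
            a = rng.integers(0, 2, n)
            b = rng.integers(0, 2, n)
            table = np.array([[np.sum((a == 0) & (b == 0)),
                               np.sum((a == 1) & (b == 0))],
                              [np.sum((a == 0) & (b == 1)),
                               np.sum((a == 1) & (b == 1))]])
            # enumerate all tables with the same margins
            r0, c0 = table[0].sum(), table[:, 0].sum()
            lo = max(0, r0 + c0 - n)
            hi = min(r0, c0)
            probs = {k: stats.hypergeom.pmf(k, n, r0, c0)
                     for k in range(lo, hi + 1)}
            obs = probs[table[0, 0]]
            expected = sum(p for p in probs.values() if p <= obs * (1 + 1e-9))
            got = fisher_enrichment(
                pd.Series(np.where(a == 0, "u", "v")),
                pd.Series(np.where(b == 0, "cat", "rest")),
            ).loc["cat", "p_value"]
            assert got == pytest.approx(expected, abs=1e-10)

    def test_requires_binary_first_factor(self):
        a = pd.Series(["x", "y", "z", "x"])
        b = pd.Series(["c", "c", "d", "d"])
        with pytest.raises(InputError):
            fisher_enrichment(a, b)


class TestGroupCompare:
    def test_exact_small_sample_value(self):
        values = pd.DataFrame([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]],
                              index=["v"], columns=[f"s{i}" for i in range(6)])
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=values.columns)
        res = group_compare_bh(values, groups)
        assert res.loc["v", "U"] == 0.0
        assert res.loc["v", "p_value"] == pytest.approx(0.1)

    def test_identical_groups_give_p_one(self):
        values = pd.DataFrame([[5.0] * 8], index=["v"],
                              columns=[f"s{i}" for i in range(8)])
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=values.columns)
        res = group_compare_bh(values, groups)
        assert res.loc["v", "p_value"] == 1.0
        assert bool(res.loc["v", "constant"])

    def test_bh_adjustment_formula(self):
        """BH on p = (0.01, 0.02, 0.03, 0.04) gives 0.04 for every variable;
        construct variables wired to any p and check the adjustment only."""
        from statsmodels.stats.multitest import multipletests
        adj = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        np.testing.assert_allclose(adj, [0.04] * 4)
        rng = np.random.default_rng(7)
        values = pd.DataFrame(rng.standard_normal((6, 30)),
                              index=[f"v{i}" for i in range(6)],
                              columns=[f"s{i}" for i in range(30)])
        groups = pd.Series(["a"] * 15 + ["b"] * 15, index=values.columns)
        res = group_compare_bh(values, groups)
        expected = multipletests(res["p_value"].to_numpy(), method="fdr_bh")[1]
        np.testing.assert_allclose(res["adj_p"].to_numpy(), expected)
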
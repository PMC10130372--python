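"""Cohort statistics: ROC cutoffs, χ², Kaplan–Meier, log-rank, the Cox
Breslow-Newton fit (against a grid oracle and lifelines) and ρ²."""

import numpy as np
import pandas as pd
import pytest

from glycoclust.stats import (
    chi_square_2x2,
    cox_fit,
    cox_loglik,
    heterogeneity_table,
    km_estimate,
    log_rank,
    median_split,
    reproducibility,
    rho2_xoq,
    roc_cutoff,
)


class TestRocCutoff:
    def test_perfect_separation(self):
        r = roc_cutoff([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert r.youden_j == pytest.approx(1.0)
        assert 3 < r.cutoff < 10

    def test_identical_values(self):
        r = roc_cutoff([5, 5, 5, 5], [0, 1, 0, 1])
        assert r.youden_j == 0.0

    def test_exhaustive_scan_example(self):
        r = roc_cutoff([1, 4, 5, 6, 9], [0, 0, 1, 0, 1])
        assert r.cutoff == pytest.approx(4.5)
        assert r.youden_j == pytest.approx(2 / 3)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_cutoff([1, 2, 3], [1, 1, 1])


class TestChiSquare:
    def test_study_table(self):
        r = chi_square_2x2([[11, 2], [2, 6]])
        assert round(r.statistic, 1) == 7.5
        assert round(r.p, 3) == 0.006

    def test_independence_is_zero(self):
        assert chi_square_2x2([[5, 5], [5, 5]]).statistic == 0.0

    def test_closed_form_example(self):
        assert chi_square_2x2([[8, 2], [3, 7]]).statistic == pytest.approx(5.05, abs=0.005)

    def test_matches_scipy_no_correction(self, rng):
        from scipy.stats import chi2_contingency

        for _ in range(10):
            t = rng.integers(1, 30, size=(2, 2))
            mine = chi_square_2x2(t)
            ref = chi2_contingency(t, correction=False)
            assert mine.statistic == pytest.approx(ref.statistic)
            assert mine.p == pytest.approx(ref.pvalue)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[0, 0], [3, 7]])

    def test_heterogeneity_table_construction(self):
        het = [True] * 11 + [True] * 2 + [False] * 2 + [False] * 6
        ev = [1] * 11 + [0] * 2 + [1] * 2 + [0] * 6
        r = heterogeneity_table(het, ev)
        assert np.array_equal(r.table, [[11, 2], [2, 6]])


class TestKaplanMeier:
    def test_all_censored(self):
        km = km_estimate([1, 2, 3], [0, 0, 0])
        assert km.at(10) == 1.0

    def test_all_events_closed_form(self):
        km = km_estimate([1, 2, 3], [1, 1, 1])
        assert [km.at(t) for t in (1, 2, 3)] == [pytest.approx(2 / 3), pytest.approx(1 / 3), 0.0]

    def test_hand_product_limit_with_censoring(self):
        km = km_estimate([1, 2, 3], [1, 0, 1])
        assert km.at(2.5) == pytest.approx(2 / 3)
        assert km.at(3) == 0.0

    def test_matches_lifelines_on_random_data(self, rng):
        from lifelines import KaplanMeierFitter

        t = rng.exponential(2, 40)
        e = (rng.random(40) < 0.7).astype(int)
        km = km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for u in np.linspace(0.1, t.max(), 7):
            assert km.at(u) == pytest.approx(float(kmf.predict(u)), abs=1e-9)


class TestLogRank:
    def test_identical_groups_zero(self):
        g = ([1, 2, 3, 4], [1, 1, 0, 1])
        r = log_rank(g, g)
        assert r.statistic == 0.0

    def test_manual_risk_table_oracle(self):
        # complete separation of event times: A events at 1,2,3; B at 4,5,6
        ta, ea = np.array([1.0, 2, 3]), np.array([1, 1, 1])
        tb, eb = np.array([4.0, 5, 6]), np.array([1, 1, 1])
        o_minus_e = 0.0
        v = 0.0
        for t in [1, 2, 3, 4, 5, 6]:
            na = (ta >= t).sum()
            nb = (tb >= t).sum()
            da = ((ta == t) & (ea == 1)).sum()
            db = ((tb == t) & (eb == 1)).sum()
            n, d = na + nb, da + db
            o_minus_e += da - d * na / n
            if n > 1:
                v += d * (na / n) * (nb / n) * (n - d) / (n - 1)
        expected = o_minus_e**2 / v
        r = log_rank((ta, ea), (tb, eb))
        assert r.statistic == pytest.approx(expected)

    def test_matches_lifelines_with_ties(self, rng):
        from lifelines.statistics import logrank_test

        ta = rng.integers(1, 6, 30).astype(float)
        tb = rng.integers(1, 6, 25).astype(float)
        ea = (rng.random(30) < 0.8).astype(int)
        eb = (rng.random(25) < 0.8).astype(int)
        mine = log_rank((ta, ea), (tb, eb))
        ref = logrank_test(ta, tb, ea, eb)
        assert mine.statistic == pytest.approx(ref.test_statistic)
        assert mine.p == pytest.approx(ref.p_value)


def grid_maximizer(t, e, x, lo=-6.0, hi=6.0):
    """Independent 1-D grid search of the Breslow partial likelihood:
    coarse scan then fine refinement to 1e-6 resolution."""
    coarse = np.linspace(lo, hi, 1201)
    lls = [cox_loglik(t, e, x, b)[0] for b in coarse]
    b0 = coarse[int(np.argmax(lls))]
    fine = np.linspace(b0 - 0.02, b0 + 0.02, 40001)
    lls = [cox_loglik(t, e, x, b)[0] for b in fine]
    return float(fine[int(np.argmax(lls))])


class TestCoxFit:
    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError):
            cox_fit([1, 2, 3], [1, 1, 1], [2, 2, 2])

    def test_newton_matches_grid_oracle(self):
        for r in range(20):
            rng = np.random.default_rng(700 + r)
            n = 20
            x = rng.normal(size=n)
            t = rng.exponential(1 / (0.5 * np.exp(0.7 * x)))
            e = (rng.random(n) < 0.8).astype(int)
            if e.sum() == 0:
                e[0] = 1
            fit = cox_fit(t, e, x)
            if fit.separation:
                continue
            assert abs(fit.beta_hat - grid_maximizer(t, e, x)) <= 1e-4

    def test_matches_lifelines_breslow(self, rng):
        from lifelines import CoxPHFitter

        n = 60
        x = rng.normal(size=n)
        t = rng.exponential(1 / np.exp(0.5 * x))
        e = np.ones(n, int)
        fit = cox_fit(t, e, x)
        cph = CoxPHFitter(baseline_estimation_method="breslow").fit(
            pd.DataFrame({"t": t, "e": e, "x": x}), "t", "e", formula="x"
        )
        assert fit.beta_hat == pytest.approx(float(cph.params_["x"]), abs=1e-5)
        assert fit.se == pytest.approx(float(cph.standard_errors_["x"]), rel=1e-4)

    def test_separation_flagged_not_crashed(self):
        t = np.array([1.0, 2, 3, 10, 11, 12])
        e = np.ones(6, int)
        x = np.array([1.0, 1, 1, 0, 0, 0])
        fit = cox_fit(t, e, x)
        assert fit.separation

    def test_parameter_recovery(self):
        betas = []
        for r in range(50):
            rng = np.random.default_rng(900 + r)
            n = 300
            x = (rng.random(n) < 0.5).astype(float)
            t = rng.exponential(1 / (0.2 * np.exp(np.log(2) * x)))
            betas.append(cox_fit(t, np.ones(n, int), x).beta_hat)
        assert abs(np.mean(betas) - np.log(2)) <= 0.1


class TestRho2:
    def test_zero_iff_zero_lr(self):
        assert rho2_xoq(0.0, 10) == 0.0

    def test_direct_formula(self):
        assert rho2_xoq(2.0, 10) == pytest.approx(1 - np.exp(-0.2))

    def test_monotone_in_lr(self):
        vals = [rho2_xoq(lr, 10) for lr in np.linspace(0, 20, 15)]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert all(0.0 <= v < 1.0 for v in vals)

    def test_n_variant_and_errors(self):
        assert rho2_xoq(2.0, 5, variant="n", n_total=20) == pytest.approx(1 - np.exp(-0.1))
        with pytest.raises(ValueError):
            rho2_xoq(1.0, 0)


class TestMedianSplitAndReproducibility:
    def test_median_split_tie_convention(self):
        high = median_split([1, 2, 3, 4, 5])
        assert list(high) == [False, False, False, True, True]  # ⌈n/2⌉ low

    def test_reproducibility_identity_and_reversal(self):
        df = pd.DataFrame(
            {"specimen_id": list("abcde"), "q": [1.0, 2, 3, 4, 5], "heterogeneous": [0, 1, 0, 1, 1]}
        )
        same = reproducibility(df, df)
        assert same.correlations["q"] == pytest.approx(1.0)
        assert same.concordance == 1.0
        rev = df.copy()
        rev["q"] = rev["q"].values[::-1]
        assert reproducibility(df, rev).correlations["q"] == pytest.approx(-1.0)

    def test_few_specimens_skip_correlation(self):
        df = pd.DataFrame({"specimen_id": ["a", "b"], "q": [1.0, 2], "heterogeneous": [0, 1]})
        r = reproducibility(df, df)
        assert r.correlations == {}
        assert r.concordance == 1.0
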
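"""Survival statistics: Cox recovery, c-index vs exhaustive oracle, LRT,
Kaplan-Meier/log-rank, 1-year ROC, Schoenfeld diagnostics."""

import numpy as np
import pandas as pd
import pytest

from cinempca.survival import (
    concordance_index,
    cox_fit,
    km_logrank,
    likelihood_ratio_test,
    median_risk_grouping,
    model_comparison_table,
    one_year_labels,
    roc_auc_1yr,
    schoenfeld_ph_check,
    standardize_covariates,
)


def brute_force_cindex(risk, t, e):
    """Oracle: enumerate all ordered pairs; the earlier subject must be an
    event and the later strictly later; risk ties count 1/2."""
    conc, comp = 0.0, 0
    n = len(t)
    for i in range(n):
        for j in range(n):
            if i == j or not e[i] or not (t[j] > t[i]):
                continue
            comp += 1
            if risk[i] > risk[j]:
                conc += 1
            elif risk[i] == risk[j]:
                conc += 0.5
    return conc / comp if comp else float("nan")


def exp_cohort(rng, n, beta, x=None, horizon=np.inf, h0=0.2):
    x = rng.standard_normal(n) if x is None else x
    t = rng.exponential(1.0 / (h0 * np.exp(beta * x)))
    e = t <= horizon
    t = np.minimum(t, horizon)
    return pd.DataFrame({"time": t, "event": e.astype(int), "x": x})


class TestStandardize:
    def test_training_columns_standardized(self, rng):
        df = pd.DataFrame({"a": rng.normal(5, 3, 100), "b": rng.normal(-2, 0.5, 100)})
        out, stats_ = standardize_covariates(df)
        for c in ("a", "b"):
            assert abs(out[c].mean()) < 1e-10
            assert abs(out[c].std(ddof=0) - 1) < 1e-10

    def test_frozen_stats_preserve_validation_shift(self, rng):
        train = pd.DataFrame({"a": rng.normal(0, 2, 200)})
        _, stats_ = standardize_covariates(train)
        val = pd.DataFrame({"a": train["a"][:50] + 4.0})
        out, _ = standardize_covariates(val, reference_stats=stats_)
        shift = out["a"].mean() - ((train["a"][:50] - stats_["a"][0]) / stats_["a"][1]).mean()
        assert shift == pytest.approx(4.0 / stats_["a"][1], abs=1e-10)

    def test_idempotent(self, rng):
        df = pd.DataFrame({"a": rng.normal(3, 2, 50)})
        once, _ = standardize_covariates(df)
        twice, _ = standardize_covariates(once)
        assert np.allclose(once["a"], twice["a"])

    def test_zero_sd_column_dropped(self):
        df = pd.DataFrame({"a": [1.0] * 10, "b": np.arange(10.0)})
        out, stats_ = standardize_covariates(df)
        assert "a" not in out.columns and "b" in stats_


class TestCox:
    def test_two_group_hr2_recovery(self):
        rng = np.random.default_rng(0)
        x = np.repeat([0.0, 1.0], 1000)
        df = exp_cohort(rng, 2000, np.log(2), x=x)
        res = cox_fit(df, ["x"])
        assert abs(res.coefficients[0] - np.log(2)) < 0.1
        assert res.hazard_ratios[0] == pytest.approx(np.exp(res.coefficients[0]))

    def test_null_covariate_within_two_se(self):
        ok = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            df = exp_cohort(rng, 300, 0.0)
            res = cox_fit(df, ["x"])
            se = (np.log(res.ci_upper[0]) - np.log(res.ci_lower[0])) / (2 * 1.959964)
            ok += abs(res.coefficients[0]) < 2 * se
        assert ok >= 18  # ~95% coverage, allow slack

    def test_duplicating_records_keeps_coefficient(self):
        rng = np.random.default_rng(3)
        df = exp_cohort(rng, 200, 0.7)
        res1 = cox_fit(df, ["x"])
        res2 = cox_fit(pd.concat([df, df], ignore_index=True), ["x"])
        # duplication creates exact event-time ties, so Efron's tie correction
        # perturbs the estimating equation slightly; invariance is approximate
        assert res2.coefficients[0] == pytest.approx(res1.coefficients[0], abs=0.01)
        # SE shrinks: CI narrows
        w1 = res1.ci_upper[0] / res1.ci_lower[0]
        w2 = res2.ci_upper[0] / res2.ci_lower[0]
        assert w2 < w1

    def test_aic_identity(self):
        rng = np.random.default_rng(1)
        df = exp_cohort(rng, 150, 0.5)
        res = cox_fit(df, ["x"])
        assert res.aic == pytest.approx(2 * res.n_params - 2 * res.log_likelihood)

    def test_no_events_rejected(self):
        df = pd.DataFrame({"time": [1.0, 2.0], "event": [0, 0], "x": [0.0, 1.0]})
        with pytest.raises(ValueError):
            cox_fit(df, ["x"])

    def test_constant_covariate_rejected(self):
        df = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [1, 1, 0], "x": [1.0] * 3})
        with pytest.raises(ValueError):
            cox_fit(df, ["x"])


class TestConcordance:
    def test_worked_example(self):
        # times (1,2,3) all events, risks (3,1,2): pairs 3, concordant 2
        c = concordance_index([3.0, 1.0, 2.0], [1.0, 2.0, 3.0], [True] * 3)
        assert c == pytest.approx(2.0 / 3.0)

    def test_perfect_ordering(self):
        t = np.arange(1.0, 11.0)
        c = concordance_index(-t, t, np.ones(10, bool))
        assert c == 1.0

    def test_all_tied_risks(self):
        t = np.arange(1.0, 11.0)
        assert concordance_index(np.zeros(10), t, np.ones(10, bool)) == 0.5

    def test_no_comparable_pairs_is_nan(self):
        assert np.isnan(concordance_index([1.0, 2.0], [5.0, 5.0], [False, False]))

    def test_matches_exhaustive_oracle_on_random_instances(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            n = int(rng.integers(3, 51))
            t = rng.integers(1, 15, n).astype(float)  # ties exercised
            e = rng.random(n) < 0.7
            risk = rng.integers(0, 6, n).astype(float)  # risk ties exercised
            if not e.any():
                e[0] = True
            expected = brute_force_cindex(risk, t, e)
            got = concordance_index(risk, t, e)
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-12)

    def test_matches_lifelines_on_continuous_times(self):
        from lifelines.utils import concordance_index as ll_cindex
        rng = np.random.default_rng(5)
        t = rng.exponential(1, 80)
        e = rng.random(80) < 0.6
        e[0] = True
        risk = rng.standard_normal(80)
        # lifelines reports concordance of predicted survival (higher = later
        # death), so negate risk
        assert concordance_index(risk, t, e) == pytest.approx(
            ll_cindex(t, -risk, e), abs=1e-12
        )


class TestLRT:
    def test_identical_models_p_one(self):
        rng = np.random.default_rng(2)
        df = exp_cohort(rng, 100, 0.5)
        res = cox_fit(df, ["x"])
        assert likelihood_ratio_test(res, res) == 1.0

    def test_null_p_values_uniform(self):
        # adding a pure-noise covariate: p ~ U(0,1) across simulations
        from scipy import stats
        ps = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            df = exp_cohort(rng, 120, 0.5)
            df["noise"] = rng.standard_normal(len(df))
            nested = cox_fit(df, ["x"])
            full = cox_fit(df, ["x", "noise"])
            ps.append(likelihood_ratio_test(nested, full))
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_strong_covariate_power(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed + 40)
            df = exp_cohort(rng, 500, np.log(3))
            df["null0"] = rng.standard_normal(len(df))
            nested = cox_fit(df, ["null0"])
            full = cox_fit(df, ["null0", "x"])
            hits += likelihood_ratio_test(nested, full) < 0.001
        assert hits >= 19

    def test_non_nested_rejected(self):
        rng = np.random.default_rng(0)
        df = exp_cohort(rng, 80, 0.5)
        df["z"] = rng.standard_normal(len(df))
        a = cox_fit(df, ["x"])
        b = cox_fit(df, ["z"])
        with pytest.raises(ValueError):
            likelihood_ratio_test(a, b)


class TestKMLogrank:
    def test_identical_groups_p_one(self):
        rng = np.random.default_rng(1)
        df = exp_cohort(rng, 60, 0.0)
        both = pd.concat([df, df], ignore_index=True)
        labels = ["a"] * 60 + ["b"] * 60
        _, p = km_logrank(both, labels)
        assert p == pytest.approx(1.0)

    def test_km_equals_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(1, 50)
        df = pd.DataFrame({"time": np.concatenate([t, t + 1]), "event": 1,
                           "g": ["a"] * 50 + ["b"] * 50})
        curves, _ = km_logrank(df, df["g"].to_numpy())
        kmf = curves["a"]
        for q in (0.5, 1.0, 2.0):
            emp = (t > q).mean()
            assert kmf.predict(q) == pytest.approx(emp, abs=1e-10)

    def test_hr3_power(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed + 900)
            x = np.repeat([0.0, 1.0], 200)
            df = exp_cohort(rng, 400, np.log(3), x=x)
            _, p = km_logrank(df, np.where(x > 0, "high", "low"))
            hits += p < 0.001
        assert hits >= 19

    def test_empty_group_rejected(self):
        df = pd.DataFrame({"time": [1.0, 2.0], "event": [1, 1]})
        with pytest.raises(ValueError):
            km_logrank(df, np.array(["a", "a"]))


class TestMedianGrouping:
    def test_worked_example(self):
        p = np.array([0.1, 0.4, 0.6, 0.9])
        g = median_risk_grouping(p, p)
        assert list(g) == ["low", "low", "high", "high"]

    def test_self_reference_balanced(self, rng):
        p = rng.random(101)
        g = median_risk_grouping(p, p)
        assert abs((g == "high").sum() - (g == "low").sum()) <= 1

    def test_monotone_transform_invariance(self, rng):
        p = rng.random(40)
        ref = rng.random(60)
        g1 = median_risk_grouping(p, ref)
        g2 = median_risk_grouping(np.log(p + 1), np.log(ref + 1))
        assert np.array_equal(g1, g2)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            median_risk_grouping(np.full(5, 0.3), np.full(5, 0.3))


class TestOneYearROC:
    def test_perfect_separation(self):
        t = np.array([0.5, 0.7, 2.0, 3.0, 4.0])
        e = np.array([True, True, False, False, False])
        auc, n = roc_auc_1yr([0.9, 0.8, 0.2, 0.1, 0.3], t, e)
        assert auc == 1.0 and n == 5

    def test_null_auc_near_half(self, rng):
        t = rng.exponential(2, 1000) + 0.01
        e = np.ones(1000, bool)
        auc, _ = roc_auc_1yr(rng.random(1000), t, e)
        assert 0.45 <= auc <= 0.55

    def test_matches_pairwise_enumeration(self):
        probs = np.array([0.1, 0.8, 0.5, 0.5, 0.3, 0.9, 0.2, 0.6, 0.4, 0.7])
        t = np.array([0.4, 0.6, 2.0, 1.5, 3.0, 0.2, 2.5, 1.2, 0.9, 4.0])
        e = np.array([1, 1, 0, 0, 0, 1, 0, 0, 1, 0], bool)
        labels, include = one_year_labels(t, e)
        p = probs[include]
        pos, neg = p[labels], p[~labels]
        pairs = sum((a > b) + 0.5 * (a == b) for a in pos for b in neg)
        expected = pairs / (len(pos) * len(neg))
        auc, _ = roc_auc_1yr(probs, t, e)
        assert auc == pytest.approx(expected, abs=1e-12)

    def test_early_censored_excluded(self):
        t = np.array([0.5, 0.5, 2.0])
        e = np.array([False, True, False])
        _, n = roc_auc_1yr([0.1, 0.9, 0.2], t, e)
        assert n == 2  # the early-censored subject drops out


class TestSchoenfeld:
    def test_residuals_sum_to_zero(self):
        rng = np.random.default_rng(4)
        df = exp_cohort(rng, 200, 0.6)
        res = cox_fit(df, ["x"])
        resid = res.fitter.compute_residuals(
            df[["time", "event", "x"]].astype(float), kind="scaled_schoenfeld")
        # unscaled Schoenfeld residuals sum to ~0; the scaled version inherits
        # a near-zero mean relative to its spread
        assert abs(resid["x"].mean()) < 0.5 * resid["x"].std()

    def test_type_one_error_calibrated(self):
        rejections = 0
        n_rep = 100
        for seed in range(n_rep):
            rng = np.random.default_rng(seed + 2000)
            df = exp_cohort(rng, 150, 0.5)
            res = cox_fit(df, ["x"])
            p = schoenfeld_ph_check(res, df)["x"]
            rejections += p < 0.05
        # ~alpha = 0.05: binomial 99% envelope around 5/100
        assert rejections <= 13

    def test_time_varying_effect_detected(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed + 3000)
            n = 500
            x = rng.standard_normal(n)
            # effect flips sign at the median time: strong PH violation
            t1 = rng.exponential(1.0 / (0.8 * np.exp(1.5 * x)))
            t = np.where(t1 < 0.6, t1, 0.6 + rng.exponential(
                1.0 / (0.8 * np.exp(-1.5 * x))))
            df = pd.DataFrame({"time": t, "event": 1, "x": x})
            res = cox_fit(df, ["x"])
            hits += schoenfeld_ph_check(res, df)["x"] < 0.05
        assert hits >= 8


class TestModelComparison:
    def test_baseline_vs_itself_and_added_signal(self):
        rng = np.random.default_rng(8)
        n = 300
        x = rng.standard_normal(n)
        z = rng.standard_normal(n)
        t = rng.exponential(1.0 / (0.3 * np.exp(0.8 * x + 0.8 * z)))
        df = pd.DataFrame({"time": t, "event": 1, "x": x, "z": z})
        base = cox_fit(df, ["x"])
        full = cox_fit(df, ["x", "z"])
        table = model_comparison_table({"base": base, "full": full}, df,
                                       baseline="base", n_bootstrap=200, seed=0)
        assert np.isnan(table.loc["base", "lrt_p_vs_baseline"])
        assert table.loc["full", "c_index"] >= table.loc["base", "c_index"]
        assert table.loc["full", "aic"] < table.loc["base", "aic"]
        assert table.loc["full", "lrt_p_vs_baseline"] < 0.05
        for name in ("base", "full"):
            lo, hi = table.loc[name, "c_index_lo"], table.loc[name, "c_index_hi"]
            assert lo <= table.loc[name, "c_index"] <= hi
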
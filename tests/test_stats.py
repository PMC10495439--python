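"""Unit and property tests for the statistical primitives."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from predscreen.stats import (HazardRatioEstimate, PooledEstimate,
                              ValidationError, Z95, clopper_pearson,
                              fisher_exact, fit_cox, group_compare, km_curve,
                              km_logrank, log_hr_from_ci, pool_random_effects,
                              spearman, subgroup_difference_test)


def make_estimate(log_hr, se):
    return HazardRatioEstimate(hr=math.exp(log_hr),
                               ci_low=math.exp(log_hr - Z95 * se),
                               ci_high=math.exp(log_hr + Z95 * se),
                               log_hr=log_hr, se_log_hr=se)


# ---------------------------------------------------------------------------
# CI back-calculation


class TestLogHrFromCI:
    def test_symmetric_ci_about_one(self):
        est = log_hr_from_ci(1.0, 0.5, 2.0)
        assert est.log_hr == 0.0
        assert est.se_log_hr == pytest.approx((math.log(2) - math.log(0.5))
                                              / (2 * Z95))
        assert est.se_log_hr == pytest.approx(0.3536, abs=1e-4)

    def test_published_interval_roundtrip(self):
        # a published HR 0.59 (0.36-0.98) must reproduce its own CI bounds
        est = log_hr_from_ci(0.59, 0.36, 0.98)
        lo = math.exp(est.log_hr - Z95 * est.se_log_hr)
        hi = math.exp(est.log_hr + Z95 * est.se_log_hr)
        # back-calculated interval is centered on sqrt(lo*hi), not on the
        # published point estimate; bounds agree to publication rounding
        assert lo == pytest.approx(0.36, abs=0.01)
        assert hi == pytest.approx(0.98, abs=0.01)

    @pytest.mark.parametrize("args", [(2.0, 2.0, 2.0), (-1.0, 0.5, 2.0),
                                      (1.0, 2.0, 0.5), (0.4, 0.5, 2.0)])
    def test_invalid_inputs_rejected(self, args):
        with pytest.raises(ValidationError):
            log_hr_from_ci(*args)


# ---------------------------------------------------------------------------
# DerSimonian-Laird pooling


def dl_oracle(ys, ses):
    """Straight transcription of the DL equations (independent of the
    implementation's code path; operates on plain floats)."""
    w = [1 / s**2 for s in ses]
    ybar = sum(wi * yi for wi, yi in zip(w, ys)) / sum(w)
    q = sum(wi * (yi - ybar) ** 2 for wi, yi in zip(w, ys))
    k = len(ys)
    denom = sum(w) - sum(wi**2 for wi in w) / sum(w)
    tau2 = max(0.0, (q - (k - 1)) / denom)
    ws = [1 / (s**2 + tau2) for s in ses]
    pooled = sum(wi * yi for wi, yi in zip(ws, ys)) / sum(ws)
    se = 1 / math.sqrt(sum(ws))
    i2 = max(0.0, (q - (k - 1)) / q) * 100 if q > 0 else 0.0
    return pooled, se, q, tau2, i2


class TestPooling:
    def test_single_estimate_is_identity(self):
        p = pool_random_effects([make_estimate(-0.5, 0.2)])
        assert (p.log_hr, p.se, p.Q, p.tau2, p.I2) == (-0.5, 0.2, 0, 0, 0)
        assert p.k == 1

    def test_zero_heterogeneity_closed_form(self):
        p = pool_random_effects([make_estimate(-0.5, 0.2)] * 2)
        assert p.log_hr == pytest.approx(-0.5)
        assert p.se == pytest.approx(0.2 / math.sqrt(2))
        assert p.Q == pytest.approx(0.0, abs=1e-12)
        assert p.tau2 == 0.0 and p.I2 == 0.0

    def test_matches_hand_executed_formulas(self):
        ys, ses = [-0.2, -0.9], [0.2, 0.25]
        p = pool_random_effects([make_estimate(y, s) for y, s in zip(ys, ses)])
        pooled, se, q, tau2, i2 = dl_oracle(ys, ses)
        assert p.log_hr == pytest.approx(pooled, rel=1e-12)
        assert p.se == pytest.approx(se, rel=1e-12)
        assert p.Q == pytest.approx(q, rel=1e-12)
        assert p.tau2 == pytest.approx(tau2, rel=1e-12)
        assert p.I2 == pytest.approx(i2, rel=1e-12)
        # frozen values from the manual evaluation of the same equations
        assert p.log_hr == pytest.approx(-0.53393, abs=1e-5)
        assert p.se == pytest.approx(0.34963, abs=1e-5)

    def test_matches_statsmodels_backend(self):
        from statsmodels.stats.meta_analysis import combine_effects
        rng = np.random.default_rng(5)
        ys = rng.normal(-0.3, 0.4, 5)
        ses = rng.uniform(0.1, 0.4, 5)
        p = pool_random_effects([make_estimate(y, s) for y, s in zip(ys, ses)])
        res = combine_effects(ys, ses**2, method_re="dl")
        assert p.tau2 == pytest.approx(float(res.tau2), rel=1e-8)
        frame = res.summary_frame()
        assert p.log_hr == pytest.approx(
            float(frame.loc["random effect", "eff"]), rel=1e-8)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            pool_random_effects([])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(-2, 2), st.floats(0.05, 1.0)),
                    min_size=1, max_size=8))
    def test_pooling_invariants(self, pairs):
        ests = [make_estimate(y, s) for y, s in pairs]
        p = pool_random_effects(ests)
        ys = [y for y, _ in pairs]
        assert min(ys) - 1e-9 <= p.log_hr <= max(ys) + 1e-9
        assert 0.0 <= p.I2 <= 100.0
        assert p.tau2 >= 0.0


class TestSubgroupDifference:
    def test_identical_pools_give_null(self):
        p = pool_random_effects([make_estimate(-0.5, 0.2)])
        z, pv = subgroup_difference_test(p, p)
        assert z == 0.0 and pv == 1.0

    def test_against_normal_cdf_oracle(self):
        pos = pool_random_effects([make_estimate(-0.5, 0.2)])
        neg = pool_random_effects([make_estimate(0.0, 0.2)])
        z, pv = subgroup_difference_test(pos, neg)
        assert z == pytest.approx(-0.5 / math.sqrt(0.08), rel=1e-9)
        assert z == pytest.approx(-1.768, abs=1e-3)
        assert pv == pytest.approx(2 * sps.norm.sf(abs(z)), rel=1e-12)
        assert pv == pytest.approx(0.077, abs=1e-3)

    def test_antisymmetry(self):
        pos = pool_random_effects([make_estimate(-0.7, 0.25)])
        neg = pool_random_effects([make_estimate(0.1, 0.15)])
        z1, p1 = subgroup_difference_test(pos, neg)
        z2, p2 = subgroup_difference_test(neg, pos)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)


# ---------------------------------------------------------------------------
# exact tests


def fisher_enumeration_oracle(a, b, c, d):
    """Two-sided Fisher p by full enumeration over fixed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    probs = []
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)
        probs.append((x, p))
    p_obs = dict(probs)[a]
    return sum(p for _, p in probs if p <= p_obs * (1 + 1e-12))


class TestFisher:
    def test_identical_proportions(self):
        assert fisher_exact([[1, 1], [1, 1]]) == 1.0

    def test_crossed_table_enumeration_value(self):
        assert fisher_exact([[2, 0], [0, 2]]) == pytest.approx(1 / 3)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 6)] * 4))
    def test_matches_enumeration(self, cells):
        a, b, c, d = cells
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            return
        assert fisher_exact([[a, b], [c, d]]) == pytest.approx(
            fisher_enumeration_oracle(a, b, c, d), rel=1e-9)

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact([[0, 0], [0, 0]])


class TestClopperPearson:
    @pytest.mark.parametrize("s,n,expect", [
        (0, 1, (0.0, 0.975)),
        (1, 1, (0.025, 1.0)),
    ])
    def test_boundary_closed_forms(self, s, n, expect):
        lo, hi = clopper_pearson(s, n)
        assert (lo, hi) == pytest.approx(expect, abs=1e-9)

    def test_matches_beta_quantiles(self):
        lo, hi = clopper_pearson(3, 10)
        assert lo == pytest.approx(sps.beta.ppf(0.025, 3, 8), rel=1e-12)
        assert hi == pytest.approx(sps.beta.ppf(0.975, 4, 7), rel=1e-12)
        assert lo <= 0.3 <= hi

    def test_invalid_inputs(self):
        for args in [(5, 3), (-1, 10), (0, 0), (1, 10, 1.5)]:
            with pytest.raises(ValidationError):
                clopper_pearson(*args)


# ---------------------------------------------------------------------------
# survival machinery


class TestKaplanMeier:
    def test_all_censored_flat_curve_test_undefined(self):
        t = [1.0, 2.0, 3.0]
        e = [0, 0, 0]
        ca, cb, chi2, p = km_logrank(t, e, t, e)
        assert ca.at(10.0) == 1.0
        assert math.isnan(chi2) and math.isnan(p)

    def test_identical_groups_null(self):
        t = [1, 2, 3, 4, 5.0]
        e = [1, 0, 1, 1, 0]
        _, _, chi2, p = km_logrank(t, e, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_three_subject_product_limit_by_hand(self):
        # times 1 (event), 2 (censored), 3 (event):
        # S(1) = 1 - 1/3 = 2/3 ; S(3) = 2/3 * (1 - 1/1) = 0
        c = km_curve([1.0, 2.0, 3.0], [1, 0, 1])
        assert c.at(1.0) == pytest.approx(2 / 3)
        assert c.at(2.5) == pytest.approx(2 / 3)
        assert c.at(3.0) == 0.0
        assert c.median == 3.0

    def test_curve_monotone_and_starts_at_one(self, rng):
        t = rng.exponential(5, 60)
        e = rng.integers(0, 2, 60)
        c = km_curve(t, e)
        assert c.at(0.0) == 1.0
        assert np.all(np.diff(c.survival) <= 1e-12)

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter
        from lifelines.statistics import logrank_test
        ta, tb = rng.exponential(8, 50), rng.exponential(5, 40)
        ea, eb = rng.integers(0, 2, 50), rng.integers(0, 2, 40)
        ca, cb, chi2, p = km_logrank(ta, ea, tb, eb)
        kmf = KaplanMeierFitter().fit(ta, ea)
        for t in [1.0, 3.0, 7.0]:
            assert ca.at(t) == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0]), rel=1e-9)
        ll = logrank_test(ta, tb, ea, eb)
        assert chi2 == pytest.approx(ll.test_statistic, rel=1e-6)
        assert p == pytest.approx(ll.p_value, rel=1e-6)


class TestCox:
    def test_identical_groups_zero_coefficient(self, rng):
        t = rng.exponential(10, 100)
        e = np.ones(100, int)
        df = pd.DataFrame({"time": np.concatenate([t, t]),
                           "event": np.concatenate([e, e]),
                           "g": np.repeat([0, 1], 100)})
        fit = fit_cox(df, "time", "event", ["g"])
        assert abs(fit.summary.loc["g", "z"]) < 0.01

    def test_planted_log_hr_recovered(self, rng):
        n = 2000
        g = np.tile([0, 1], n // 2)
        t = rng.exponential(1.0, n) / np.exp(0.7 * g)
        df = pd.DataFrame({"time": t, "event": 1, "g": g})
        fit = fit_cox(df, "time", "event", ["g"])
        coef = fit.summary.loc["g", "coef"]
        se = fit.summary.loc["g", "se"]
        assert abs(coef - 0.7) < 3 * se

    def test_flip_coding_negates_coefficient(self, rng):
        g = rng.integers(0, 2, 150)
        t = rng.exponential(10, 150) * np.exp(-0.4 * g)
        df = pd.DataFrame({"time": t, "event": 1, "g": g})
        fit1 = fit_cox(df, "time", "event", ["g"])
        df["g"] = 1 - df["g"]
        fit2 = fit_cox(df, "time", "event", ["g"])
        assert fit1.summary.loc["g", "coef"] == pytest.approx(
            -fit2.summary.loc["g", "coef"], abs=1e-6)

    @pytest.mark.parametrize("ties", [False, True])
    def test_matches_lifelines_efron(self, rng, ties):
        from lifelines import CoxPHFitter
        n = 250
        P = rng.integers(0, 2, n)
        V = rng.integers(0, 2, n)
        t = rng.exponential(12, n) * np.exp(-0.5 * P + 0.3 * V)
        if ties:
            t = np.maximum(np.ceil(t), 1.0)  # month resolution
        e = (rng.uniform(size=n) < 0.8).astype(int)
        df = pd.DataFrame({"time": t, "event": e, "P": P, "V": V,
                           "PV": P * V})
        fit = fit_cox(df, "time", "event", ["P", "V", "PV"])
        cph = CoxPHFitter().fit(df, "time", "event")
        assert np.allclose(fit.summary["coef"], cph.params_, atol=2e-4)
        assert np.allclose(fit.summary["se"], cph.standard_errors_, atol=2e-4)

    def test_constant_covariate_named_in_error(self):
        df = pd.DataFrame({"time": [1.0, 2, 3, 4], "event": [1, 1, 1, 1],
                           "flat": [1, 1, 1, 1]})
        with pytest.raises(ValidationError, match="flat"):
            fit_cox(df, "time", "event", ["flat"])

    def test_separation_flagged_not_estimable(self):
        # perfectly separated groups -> monotone likelihood
        df = pd.DataFrame({"time": [1, 2, 3, 10, 11, 12.0],
                           "event": [1, 1, 1, 1, 1, 1],
                           "g": [1, 1, 1, 0, 0, 0]})
        fit = fit_cox(df, "time", "event", ["g"])
        assert not fit.converged


# ---------------------------------------------------------------------------
# correlation / group comparison


class TestSpearman:
    def test_monotone_extremes(self):
        assert spearman([1, 2, 3], [10, 20, 30])[0] == pytest.approx(1.0)
        assert spearman([1, 2, 3], [30, 20, 10])[0] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self, rng):
        x = rng.normal(size=20)
        y = 0.6 * x + rng.normal(size=20)
        rho, p = spearman(x, y)
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        rho_oracle = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(rho_oracle, rel=1e-12)
        assert p == pytest.approx(sps.spearmanr(x, y).pvalue, rel=1e-6)

    def test_small_n_exact_permutation(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [1.0, 3.0, 2.0, 5.0, 4.0]
        rho, p = spearman(x, y)
        # brute-force oracle: enumerate all orderings of y
        rx = sps.rankdata(x)
        obs = np.corrcoef(rx, sps.rankdata(y))[0, 1]
        count = 0
        total = 0
        for perm in itertools.permutations(y):
            total += 1
            r = np.corrcoef(rx, sps.rankdata(perm))[0, 1]
            if abs(r) >= abs(obs) - 1e-12:
                count += 1
        assert p == pytest.approx(count / total, rel=1e-12)

    def test_constant_vector_undefined(self):
        rho, p = spearman([1, 1, 1], [1, 2, 3])
        assert math.isnan(rho) and math.isnan(p)


class TestGroupCompare:
    def test_identical_groups(self):
        assert group_compare([1.0, 2, 3, 4], [1.0, 2, 3, 4]) == pytest.approx(1.0)

    def test_chi2_balanced_table(self):
        a = ["yes"] * 10 + ["no"] * 10
        b = ["yes"] * 10 + ["no"] * 10
        assert group_compare(np.array(a), np.array(b)) == pytest.approx(1.0)

    def test_wilcoxon_matches_exact_permutation(self):
        a = [1.2, 3.4, 2.2]
        b = [4.5, 5.1, 2.9, 6.0]
        p = group_compare(a, b)
        pooled = np.array(a + b)
        ranks = sps.rankdata(pooled)
        obs = ranks[:3].sum()
        n = len(pooled)
        stats = []
        for idx in itertools.combinations(range(n), 3):
            stats.append(ranks[list(idx)].sum())
        stats = np.array(stats)
        mean = stats.mean()
        p_exact = np.mean(np.abs(stats - mean) >= abs(obs - mean) - 1e-12)
        # normal approximation vs exact enumeration: loose agreement
        assert p == pytest.approx(p_exact, abs=0.12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            group_compare([], [1.0])
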
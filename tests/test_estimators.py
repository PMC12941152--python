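"""Closed-form examples, oracle equivalence and equivariance of the five
MR estimators and the heterogeneity diagnostics."""

import numpy as np
import pytest
from scipy import stats

from mrmediate import (
    MethodError,
    ParameterError,
    TriangleTruth,
    all_methods,
    cochran_q,
    harmonize,
    ivw,
    mode_estimate,
    mr_egger,
    select_instruments,
    simulate_triangle,
    wald_ratio,
    weighted_median,
)

from conftest import make_harmonized, random_harmonized


class TestWaldRatio:
    @pytest.mark.parametrize(
        "bx, by, sy, beta, se",
        [(1.0, 0.5, 0.1, 0.5, 0.1), (2.0, 1.0, 0.2, 0.5, 0.1), (-1.0, 0.5, 0.1, -0.5, 0.1)],
    )
    def test_hand_arithmetic(self, bx, by, sy, beta, se):
        res = wald_ratio(make_harmonized([bx], [sy], [by]))
        assert res.beta == pytest.approx(beta)
        assert res.se == pytest.approx(se)

    def test_zero_exposure_beta_undefined(self):
        with pytest.raises(MethodError, match="zero"):
            wald_ratio(make_harmonized([0.0], [0.1], [0.5]))

    def test_requires_single_variant(self):
        with pytest.raises(MethodError):
            wald_ratio(make_harmonized([1.0, 1.0], [0.1, 0.1], [0.5, 0.5]))


class TestIVW:
    def test_two_snp_hand_computation(self):
        h = make_harmonized([1.0, 2.0], [0.1, 0.2], [0.5, 1.0])
        res = ivw(h, mode="fixed")
        assert res.beta == pytest.approx(0.5)
        assert res.se == pytest.approx(1 / np.sqrt(200))
        assert res.q_stat == pytest.approx(0.0, abs=1e-12)

    def test_identical_ratios_mre_equals_fixed(self):
        h = make_harmonized([1.0, 2.0, 0.5], [0.1, 0.1, 0.1], [0.3, 0.6, 0.15])
        fixed = ivw(h, mode="fixed")
        mre = ivw(h, mode="multiplicative_random")
        assert fixed.q_stat == pytest.approx(0.0, abs=1e-12)
        assert mre.se == pytest.approx(fixed.se)

    def test_matches_weighted_mean_oracle(self, rng):
        """IVW equals the independent ratio-weighted-mean oracle to 1e-10
        on 100 random instances."""
        for _ in range(100):
            h = random_harmonized(rng, n=int(rng.integers(2, 30)))
            r = h.beta_out / h.beta_exp
            w = h.beta_exp**2 / h.se_out**2
            oracle = np.sum(w * r) / np.sum(w)
            assert ivw(h).beta == pytest.approx(oracle, abs=1e-10)

    def test_too_few_variants(self):
        with pytest.raises(MethodError, match="wald_ratio"):
            ivw(make_harmonized([1.0], [0.1], [0.5]))
        with pytest.raises(ParameterError):
            ivw(make_harmonized([1.0, 1.0], [0.1, 0.1], [0.5, 0.5]), mode="bogus")


class TestEgger:
    def test_exact_linear_fit(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        by = 0.1 + 0.6 * bx
        res = mr_egger(make_harmonized(bx, np.full(4, 0.05), by))
        assert res.beta == pytest.approx(0.6, abs=1e-10)
        assert res.egger_intercept == pytest.approx(0.1, abs=1e-10)
        assert res.q_stat == pytest.approx(0.0, abs=1e-10)

    def test_orientation_to_positive_exposure_beta(self):
        """Negating both members of some pairs must not change the fit."""
        bx = np.array([0.1, -0.2, 0.3, -0.4])
        by = np.where(bx > 0, 0.1 + 0.6 * bx, -(0.1 + 0.6 * -bx))
        res = mr_egger(make_harmonized(bx, np.full(4, 0.05), by))
        assert res.beta == pytest.approx(0.6, abs=1e-10)
        assert res.egger_intercept == pytest.approx(0.1, abs=1e-10)

    def test_matches_statsmodels_wls(self, rng):
        """Cross-check slope/intercept and t-tests against a direct WLS fit."""
        import statsmodels.api as sm

        h = random_harmonized(rng, n=15)
        sign = np.where(h.beta_exp < 0, -1.0, 1.0)
        X = sm.add_constant(h.beta_exp * sign)
        fit = sm.WLS(h.beta_out * sign, X, weights=1.0 / h.se_out**2).fit()
        res = mr_egger(h)
        assert res.beta == pytest.approx(fit.params[1], abs=1e-10)
        assert res.egger_intercept == pytest.approx(fit.params[0], abs=1e-10)
        scale = max(1.0, np.sqrt(fit.scale))
        assert res.se == pytest.approx(fit.bse[1] / np.sqrt(fit.scale) * scale, abs=1e-10)

    def test_balanced_pleiotropy_nominal_intercept_rejection(self):
        """Balanced pleiotropy: the intercept test rejects at ~5%."""
        reps, rejections = 200, 0
        for rep in range(reps):
            truth = TriangleTruth(pleio_mean=0.0, pleio_sd=0.01, n_snps_med=0, seed=5000 + rep)
            exp, _, out, _ = simulate_triangle(truth)
            h = harmonize(select_instruments(exp, 1e-6), out)
            if mr_egger(h).egger_intercept_pval < 0.05:
                rejections += 1
        rate = rejections / reps
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_directional_pleiotropy_positive_intercept(self):
        """Strong directional pleiotropy yields a positive intercept
        estimate in nearly every replicate."""
        positive = 0
        reps = 40
        for rep in range(reps):
            truth = TriangleTruth(pleio_mean=0.02, pleio_sd=0.002, n_snps_med=0, seed=7000 + rep)
            exp, _, out, _ = simulate_triangle(truth)
            h = harmonize(select_instruments(exp, 1e-6), out)
            positive += mr_egger(h).egger_intercept > 0
        assert positive / reps > 0.95

    def test_too_few_variants(self):
        with pytest.raises(MethodError):
            mr_egger(make_harmonized([1.0, 1.0], [0.1, 0.1], [0.5, 0.5]))


class TestWeightedMedian:
    def test_equal_weights_middle_ratio(self):
        h = make_harmonized([1.0, 1.0, 1.0], [0.1, 0.1, 0.1], [0.1, 0.5, 0.9])
        assert weighted_median(h, reps=200, seed=0).beta == pytest.approx(0.5)

    def test_dominant_weight_breakdown(self):
        # the middle ratio carries 60% of the weight: the 50% point is it
        se = np.array([0.1, 0.1 / np.sqrt(3), 0.1])  # weights 0.2, 0.6, 0.2
        h = make_harmonized([1.0, 1.0, 1.0], se, [0.1, 0.5, 0.9])
        assert weighted_median(h, reps=200, seed=0).beta == pytest.approx(0.5)

    def test_seeded_bootstrap_deterministic(self):
        h = make_harmonized([1.0, 1.2, 0.8], [0.1, 0.1, 0.1], [0.1, 0.5, 0.9],
                            se_exp=[0.05, 0.05, 0.05])
        a = weighted_median(h, reps=300, seed=7)
        b = weighted_median(h, reps=300, seed=7)
        assert a.se == b.se
        c = weighted_median(h, reps=300, seed=8)
        assert a.se != c.se

    def test_few_reps_warns(self):
        h = make_harmonized([1.0, 1.0, 1.0], [0.1, 0.1, 0.1], [0.1, 0.5, 0.9])
        with pytest.warns(UserWarning, match="bootstrap"):
            weighted_median(h, reps=99, seed=0)


class TestModeEstimators:
    def test_majority_cluster(self):
        h = make_harmonized(np.ones(4), np.full(4, 0.1), [0.5, 0.5, 0.5, 3.0])
        res = mode_estimate(h, weighted=False, reps=200, seed=0)
        assert res.beta == pytest.approx(0.5, abs=0.05)

    def test_all_ratios_equal_degenerate(self):
        h = make_harmonized([1.0, 2.0, 4.0], [1e-8, 1e-8, 1e-8], [0.5, 1.0, 2.0])
        res = mode_estimate(h, reps=200, seed=0)
        assert res.beta == pytest.approx(0.5, abs=1e-6)
        assert res.se < 1e-6  # bootstrap SE -> 0 as sigma -> 0

    def test_weighted_and_simple_recover_truth(self):
        """Invalid-minority scenario: both variants stay within 3 MC-SEs."""
        truth = TriangleTruth(n_snps=60, n_snps_med=0, seed=31)
        exp, _, out, _ = simulate_triangle(truth)
        h = harmonize(select_instruments(exp, 1e-6), out)
        # corrupt a 20% minority with a shifted effect
        k = h.n_snp // 5
        h.beta_out[:k] += 0.3 * h.beta_exp[:k]
        for weighted in (False, True):
            res = mode_estimate(h, weighted=weighted, reps=300, seed=3)
            assert abs(res.beta - truth.total_effect) < 3 * res.se

    def test_bad_bandwidth(self):
        h = make_harmonized(np.ones(3), np.full(3, 0.1), [0.1, 0.5, 0.9])
        with pytest.raises(ParameterError):
            mode_estimate(h, bandwidth_factor=0.0)


class TestCochranQ:
    def test_identical_ratios(self):
        h = make_harmonized([1.0, 2.0], [0.1, 0.2], [0.5, 1.0])
        q, df, p = cochran_q(h)
        assert q == pytest.approx(0.0, abs=1e-12)
        assert df == 1
        assert p == pytest.approx(1.0)

    def test_two_point_hand_formula(self):
        # unit weights: bx=1, sy=1; ratios 0 and 1 -> Q = 0.5
        h = make_harmonized([1.0, 1.0], [1.0, 1.0], [0.0, 1.0])
        q, df, p = cochran_q(h)
        w = np.array([1.0, 1.0])
        r = np.array([0.0, 1.0])
        expected = np.sum(w * (r - r.mean()) ** 2)
        assert q == pytest.approx(expected)
        assert p == pytest.approx(stats.chi2.sf(expected, 1))

    def test_null_simulation_q_over_df_near_one(self):
        vals = []
        for rep in range(60):
            truth = TriangleTruth(n_snps_med=0, seed=9000 + rep)
            exp, _, out, _ = simulate_triangle(truth)
            q, df, _ = cochran_q(harmonize(select_instruments(exp, 1e-6), out))
            vals.append(q / df)
        mc_se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - 1.0) < 3 * mc_se


class TestEquivariance:
    def test_sign_equivariance(self, rng):
        """Negating all outcome betas negates every estimator's beta and
        leaves the analytic SEs unchanged."""
        h = random_harmonized(rng, n=12)
        neg = make_harmonized(h.beta_exp, h.se_out, -h.beta_out, se_exp=h.se_exp)
        for fn in (lambda x: ivw(x), lambda x: mr_egger(x)):
            a, b = fn(h), fn(neg)
            assert b.beta == pytest.approx(-a.beta, abs=1e-12)
            assert b.se == pytest.approx(a.se, abs=1e-12)
        a = weighted_median(h, reps=100, seed=1)
        b = weighted_median(neg, reps=100, seed=1)
        assert b.beta == pytest.approx(-a.beta, abs=1e-12)
        a = mode_estimate(h, reps=100, seed=1)
        b = mode_estimate(neg, reps=100, seed=1)
        assert b.beta == pytest.approx(-a.beta, abs=1e-8)

    def test_scale_equivariance(self, rng):
        """Multiplying all exposure betas by c divides every beta by c."""
        h = random_harmonized(rng, n=12)
        c = 2.5
        scaled = make_harmonized(c * h.beta_exp, h.se_out, h.beta_out, se_exp=h.se_exp)
        assert ivw(scaled).beta == pytest.approx(ivw(h).beta / c, rel=1e-12)
        assert mr_egger(scaled).beta == pytest.approx(mr_egger(h).beta / c, rel=1e-12)
        wm_a = weighted_median(h, reps=100, seed=1).beta
        wm_b = weighted_median(scaled, reps=100, seed=1).beta
        assert wm_b == pytest.approx(wm_a / c, rel=1e-9)
        m_a = mode_estimate(h, reps=100, seed=1).beta
        m_b = mode_estimate(scaled, reps=100, seed=1).beta
        assert m_b == pytest.approx(m_a / c, rel=1e-6)


def test_all_estimators_agree_under_valid_instruments():
    """With zero pleiotropy and a common true ratio the five estimators
    agree within 3 combined SEs."""
    truth = TriangleTruth(n_snps=80, n_snps_med=0, seed=17)
    exp, _, out, _ = simulate_triangle(truth)
    h = harmonize(select_instruments(exp, 1e-6), out)
    res = all_methods(h, reps=300, seed=5)
    betas = {k: r.beta for k, r in res.items()}
    for k1, r1 in res.items():
        for k2, r2 in res.items():
            combined = np.hypot(r1.se, r2.se)
            assert abs(r1.beta - r2.beta) < 3 * combined, (k1, k2, betas)
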
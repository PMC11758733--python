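"""Estimators against independent brute-force oracles and algebraic invariants."""

import math

import numpy as np
import pytest
import statsmodels.api as sm_api

from steromr import (
    InsufficientInstrumentsError,
    PreconditionError,
    ivw,
    mr_egger,
    orient_positive,
    to_odds_ratio,
    wald_ratio,
    weighted_median,
)

from conftest import make_hset, random_hset


def wls_through_origin_oracle(g, G, sy):
    """Brute-force normal equations for y = b*x with weights 1/sy^2."""
    w = 1.0 / np.asarray(sy) ** 2
    g, G = np.asarray(g), np.asarray(G)
    return float(np.sum(w * g * G) / np.sum(w * g * g))


def wls_with_intercept_oracle(g, G, sy):
    """Brute-force weighted normal equations for y = b0 + b1*x."""
    w = 1.0 / np.asarray(sy) ** 2
    X = np.column_stack([np.ones(len(g)), g])
    A = X.T @ (w[:, None] * X)
    b = X.T @ (w * np.asarray(G))
    return np.linalg.solve(A, b)


def weighted_median_oracle(ratios, weights):
    """Brute-force sort-and-interpolate 50th weighted percentile."""
    pairs = sorted(zip(ratios, weights))
    b = [p[0] for p in pairs]
    wn = np.array([p[1] for p in pairs]) / sum(weights)
    p = np.cumsum(wn) - wn / 2
    if 0.5 <= p[0]:
        return b[0]
    for i in range(1, len(b)):
        if p[i] >= 0.5:
            frac = (0.5 - p[i - 1]) / (p[i] - p[i - 1])
            return b[i - 1] + frac * (b[i] - b[i - 1])
    return b[-1]


class TestWaldRatio:
    def test_direct_arithmetic(self):
        rec = make_hset([0.5], [0.10], sigma_y=0.02).records[0]
        assert wald_ratio(rec) == pytest.approx((0.20, 0.04), rel=1e-12)

    def test_null_numerator(self):
        rec = make_hset([0.5], [0.0], sigma_y=0.02).records[0]
        beta, se = wald_ratio(rec)
        assert beta == 0.0
        assert se == pytest.approx(0.04)

    def test_sign_symmetric(self):
        a = make_hset([0.5], [0.1]).records[0]
        b = make_hset([-0.5], [-0.1]).records[0]
        assert wald_ratio(a) == pytest.approx(wald_ratio(b), rel=1e-15)

    def test_zero_gamma_names_snp(self):
        rec = make_hset([0.0], [0.1]).records[0]
        with pytest.raises(PreconditionError, match="rs1"):
            wald_ratio(rec)

    def test_second_order_se_is_larger(self):
        rec = make_hset([0.5], [0.1], sigma_x=0.05, sigma_y=0.02).records[0]
        _, se1 = wald_ratio(rec)
        _, se2 = wald_ratio(rec, second_order=True)
        assert se2 > se1
        expected = math.sqrt(0.02**2 / 0.25 + 0.1**2 * 0.05**2 / 0.5**4)
        assert se2 == pytest.approx(expected, rel=1e-12)


class TestIvw:
    def test_single_snp_equals_wald_ratio(self):
        hset = make_hset([0.5], [0.1], sigma_y=0.02)
        res = ivw(hset, model="fixed")
        assert (res.beta, res.se) == pytest.approx((0.2, 0.04), rel=1e-12)

    def test_homogeneous_ratios_have_no_overdispersion(self):
        # ratios all 0.2 under weights {1, 4, 25} (sy = g/sqrt(w))
        g = np.array([0.1, 0.2, 0.4])
        sy = g / np.sqrt([1.0, 4.0, 25.0])
        hset = make_hset(g, 0.2 * g, sigma_y=sy)
        fixed = ivw(hset, model="fixed")
        random = ivw(hset, model="multiplicative_random")
        assert fixed.beta == pytest.approx(0.2, rel=1e-12)
        assert random.se == pytest.approx(fixed.se, rel=1e-12)

    def test_matches_wls_through_origin_oracle(self):
        g = [0.1, 0.2, 0.4]
        G = [0.03, 0.04, 0.10]
        sy = [0.01, 0.01, 0.02]
        res = ivw(make_hset(g, G, sigma_y=sy), model="fixed")
        assert res.beta == pytest.approx(wls_through_origin_oracle(g, G, sy), abs=1e-12)

    @pytest.mark.parametrize("j", [3, 7, 20])
    def test_oracle_equivalence_random_instances(self, rng, j):
        for _ in range(20):
            hset = random_hset(rng, j)
            g = [r.gamma_hat for r in hset.records]
            G = [r.Gamma_hat for r in hset.records]
            sy = [r.sigma_y for r in hset.records]
            expected = wls_through_origin_oracle(g, G, sy)
            assert ivw(hset, model="fixed").beta == pytest.approx(expected, abs=1e-10)
            # statsmodels WLS as a second, library-independent cross-check
            fit = sm_api.WLS(G, np.asarray(g)[:, None], weights=1 / np.asarray(sy) ** 2).fit()
            assert ivw(hset, model="fixed").beta == pytest.approx(fit.params[0], abs=1e-10)

    def test_invariant_under_orientation(self, rng):
        hset = random_hset(rng, 8)
        flipped = make_hset(
            [-r.gamma_hat for r in hset.records],
            [-r.Gamma_hat for r in hset.records],
            [r.sigma_x for r in hset.records],
            [r.sigma_y for r in hset.records],
        )
        assert ivw(hset).beta == pytest.approx(ivw(flipped).beta, rel=1e-12)
        assert ivw(hset).beta == pytest.approx(ivw(orient_positive(hset)).beta, rel=1e-12)

    def test_se_scales_linearly_with_outcome_noise(self, rng):
        hset = random_hset(rng, 10)
        scaled = make_hset(
            [r.gamma_hat for r in hset.records],
            [r.Gamma_hat for r in hset.records],
            [r.sigma_x for r in hset.records],
            [3.0 * r.sigma_y for r in hset.records],
        )
        a, b = ivw(hset, model="fixed"), ivw(scaled, model="fixed")
        assert b.beta == pytest.approx(a.beta, rel=1e-12)
        assert b.se == pytest.approx(3.0 * a.se, rel=1e-12)

    def test_random_model_needs_two_snps(self):
        with pytest.raises(InsufficientInstrumentsError):
            ivw(make_hset([0.1], [0.02]), model="multiplicative_random")


class TestMrEgger:
    def test_exact_affine_data_recovered(self):
        g = np.array([0.1, 0.2, 0.3, 0.5])
        hset = make_hset(g, 0.05 + 0.3 * g, sigma_y=[0.01, 0.02, 0.01, 0.03])
        res = mr_egger(hset)
        assert res.beta == pytest.approx(0.3, abs=1e-10)
        egger = res.extra["egger"]
        assert egger.intercept == pytest.approx(0.05, abs=1e-10)
        assert res.extra["rss_weighted"] == pytest.approx(0.0, abs=1e-18)

    def test_proportional_data_zero_intercept_ivw_slope(self):
        g = np.array([0.1, 0.25, 0.4])
        hset = make_hset(g, 0.37 * g, sigma_y=0.01)  # equal weights
        res = mr_egger(hset)
        assert res.extra["egger"].intercept == pytest.approx(0.0, abs=1e-12)
        assert res.beta == pytest.approx(ivw(hset, model="fixed").beta, abs=1e-12)

    def test_coefficients_match_weighted_normal_equations_oracle(self, rng):
        for j in (4, 9, 15):
            hset = random_hset(rng, j)
            g = [r.gamma_hat for r in hset.records]
            G = [r.Gamma_hat for r in hset.records]
            sy = np.array([r.sigma_y for r in hset.records])
            b0, b1 = wls_with_intercept_oracle(g, G, sy)
            res = mr_egger(hset)
            assert res.extra["egger"].intercept == pytest.approx(b0, abs=1e-10)
            assert res.beta == pytest.approx(b1, abs=1e-10)
            # statsmodels cross-check of coefficients
            fit = sm_api.WLS(G, sm_api.add_constant(np.asarray(g)), weights=1 / sy**2).fit()
            assert res.beta == pytest.approx(fit.params[1], abs=1e-10)

    def test_requires_three_snps(self):
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(make_hset([0.1, 0.2], [0.02, 0.05]))


class TestWeightedMedian:
    def test_equal_weights_odd_count_is_sample_median(self):
        g = np.array([1.0, 1.0, 1.0])
        hset = make_hset(g, [0.1, 0.2, 0.3], sigma_y=1.0)  # equal weights
        res = weighted_median(hset, n_boot=50, seed=1)
        assert res.beta == pytest.approx(0.2, abs=1e-12)

    def test_dominant_weight_matches_brute_force_interpolation(self):
        # middle SNP carries > 50% of the weight (w = g^2/sy^2)
        g = np.array([0.1, 1.0, 0.1])
        G = np.array([0.01, 0.3, 0.05])
        sy = np.array([0.1, 0.1, 0.1])
        hset = make_hset(g, G, sigma_y=sy)
        ratios = G / g
        weights = g**2 / sy**2
        expected = weighted_median_oracle(list(ratios), list(weights))
        res = weighted_median(hset, n_boot=50, seed=1)
        assert res.beta == pytest.approx(expected, abs=1e-12)
        lo, hi = sorted(ratios)[0], sorted(ratios)[2]
        assert lo <= res.beta <= hi

    def test_matches_oracle_on_random_instances(self, rng):
        for j in (3, 5, 11, 18):
            hset = random_hset(rng, j)
            g = np.array([r.gamma_hat for r in hset.records])
            G = np.array([r.Gamma_hat for r in hset.records])
            sy = np.array([r.sigma_y for r in hset.records])
            expected = weighted_median_oracle(list(G / g), list(g**2 / sy**2))
            res = weighted_median(hset, n_boot=10, seed=0)
            assert res.beta == pytest.approx(expected, abs=1e-12)

    def test_bootstrap_se_deterministic_under_seed(self, rng):
        hset = random_hset(rng, 6)
        a = weighted_median(hset, n_boot=200, seed=42)
        b = weighted_median(hset, n_boot=200, seed=42)
        assert a.se == b.se
        assert a.pval == b.pval

    def test_requires_three_snps(self):
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median(make_hset([0.1, 0.2], [0.02, 0.05]), n_boot=10, seed=0)


class TestToOddsRatio:
    def test_null_beta_gives_unit_or_with_log_symmetric_ci(self):
        or_, lo, hi = to_odds_ratio(0.0, 0.1)
        assert or_ == 1.0
        assert lo * hi == pytest.approx(1.0, rel=1e-12)

    def test_back_transform_of_printed_interval(self):
        # log-odds 0.2070 with SE 0.0806 corresponds to OR 1.23 (1.05-1.44)
        or_, lo, hi = to_odds_ratio(0.2070, 0.0806)
        assert or_ == pytest.approx(math.exp(0.2070), rel=1e-12)
        assert round(or_, 2) == 1.23
        assert round(lo, 2) == 1.05
        assert round(hi, 2) == 1.44

    def test_ci_collapses_as_se_vanishes(self):
        or_, lo, hi = to_odds_ratio(0.3, 1e-12)
        assert lo == pytest.approx(or_, rel=1e-9)
        assert hi == pytest.approx(or_, rel=1e-9)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(PreconditionError):
            to_odds_ratio(0.1, 0.0)

    def test_or_consistent_with_beta_everywhere(self, rng):
        hset = random_hset(rng, 6)
        for res in (ivw(hset), mr_egger(hset), weighted_median(hset, n_boot=20, seed=0)):
            assert res.or_ == pytest.approx(math.exp(res.beta), rel=1e-12)
            assert res.ci_low <= res.or_ <= res.ci_high
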
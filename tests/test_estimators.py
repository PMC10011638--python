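"""Causal-effect estimators against independent oracles and limit cases."""

import numpy as np
import pytest
import statsmodels.api as sm

from tsmr import (
    RatioEstimate,
    egger,
    ivw,
    ivw_penalized,
    ratio_estimates,
    wald_ratio,
    weighted_median,
    with_or_scale,
)
from tsmr.estimators import _weighted_median_point
from tsmr.harmonize import HarmonizedRecord, HarmonizedSet

from conftest import make_harmonized, random_harmonized, random_ratios


class TestWaldRatio:
    def test_arithmetic(self):
        rec = HarmonizedRecord("rs1", beta_x=0.5, se_x=0.02, beta_y=0.25, se_y=0.1)
        r = wald_ratio(rec)
        assert r.ratio == pytest.approx(0.5) and r.se == pytest.approx(0.2)

    def test_zero_numerator(self):
        rec = HarmonizedRecord("rs1", beta_x=0.5, se_x=0.02, beta_y=0.0, se_y=0.1)
        r = wald_ratio(rec)
        assert r.ratio == 0.0 and r.se == pytest.approx(0.2)

    def test_orientation_invariance(self):
        a = HarmonizedRecord("rs1", 0.5, 0.02, 0.25, 0.1)
        b = HarmonizedRecord("rs1", -0.5, 0.02, -0.25, 0.1)
        assert wald_ratio(a) == wald_ratio(b)

    def test_zero_denominator_is_error(self):
        with pytest.raises(ValueError, match="beta_x"):
            wald_ratio(HarmonizedRecord("rs1", 0.0, 0.02, 0.25, 0.1))


class TestIVW:
    def test_equal_weight_mean(self):
        ratios = [RatioEstimate("a", 1.0, 1.0), RatioEstimate("b", 3.0, 1.0)]
        res = ivw(ratios, "fixed")
        assert res.estimate == pytest.approx(2.0)
        assert res.se == pytest.approx(1 / np.sqrt(2))

    def test_homogeneous_limit_random_equals_fixed(self):
        ratios = [RatioEstimate(f"r{i}", 0.4, 0.1 * (i + 1)) for i in range(4)]
        fe, re = ivw(ratios, "fixed"), ivw(ratios, "random")
        assert fe.estimate == pytest.approx(0.4) == pytest.approx(re.estimate)
        assert re.se == pytest.approx(fe.se)

    def test_matches_wls_through_origin_oracle(self, rng):
        for _ in range(20):
            h = random_harmonized(rng, j=20)
            kept = h.kept
            y = np.array([r.beta_y for r in kept])
            x = np.array([r.beta_x for r in kept])
            w = np.array([1 / r.se_y**2 for r in kept])
            fit = sm.WLS(y, x, weights=w).fit()
            res = ivw(ratio_estimates(h), "fixed")
            assert res.estimate == pytest.approx(fit.params[0], abs=1e-8)
            # fixed-effects SE assumes unit dispersion
            assert res.se == pytest.approx(float(fit.bse[0] / np.sqrt(fit.scale)), abs=1e-8)

    def test_random_se_never_below_fixed(self, rng):
        for _ in range(10):
            ratios = random_ratios(rng, j=15)
            fe, re = ivw(ratios, "fixed"), ivw(ratios, "random")
            assert re.estimate == fe.estimate
            assert re.se >= fe.se

    def test_single_ratio_collapses_to_wald_with_warning(self):
        with pytest.warns(UserWarning, match="single instrument"):
            res = ivw([RatioEstimate("a", 0.5, 0.1)], "fixed")
        assert res.estimate == 0.5 and res.se == 0.1

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            ivw([], "fixed")


class TestEgger:
    def test_exact_line_recovered(self):
        x = np.array([0.1, 0.2, 0.3, 0.4])
        y = 0.1 + 0.5 * x
        h = make_harmonized(x, y, se_y=np.full(4, 0.01))
        slope, icpt = egger(h)
        assert slope.estimate == pytest.approx(0.5, abs=1e-10)
        assert icpt.intercept == pytest.approx(0.1, abs=1e-10)

    def test_no_intercept_mode_reproduces_ivw(self, rng):
        h = random_harmonized(rng, j=12)
        constrained, none_icpt = egger(h, intercept=False)
        assert none_icpt is None
        assert constrained.estimate == pytest.approx(
            ivw(ratio_estimates(h), "fixed").estimate, abs=1e-10)

    def test_matches_wls_oracle(self, rng):
        for _ in range(20):
            h = random_harmonized(rng, j=20)
            # orientation first: the regression is not orientation-invariant
            kept = [r if r.beta_x > 0 else
                    HarmonizedRecord(r.rsid, -r.beta_x, r.se_x, -r.beta_y, r.se_y)
                    for r in h.kept]
            x = np.array([r.beta_x for r in kept])
            y = np.array([r.beta_y for r in kept])
            w = np.array([1 / r.se_y**2 for r in kept])
            fit = sm.WLS(y, sm.add_constant(x), weights=w).fit()
            slope, icpt = egger(h)
            assert slope.estimate == pytest.approx(fit.params[1], abs=1e-8)
            assert icpt.intercept == pytest.approx(fit.params[0], abs=1e-8)
            # our dispersion is floored at 1; statsmodels' is not
            adj = np.sqrt(max(1.0, fit.scale) / fit.scale)
            assert slope.se == pytest.approx(float(fit.bse[1] * adj), abs=1e-8)
            assert icpt.se == pytest.approx(float(fit.bse[0] * adj), abs=1e-8)

    def test_too_few_records_is_error(self):
        h = make_harmonized([0.1, 0.2], [0.05, 0.1], [0.01, 0.01])
        with pytest.raises(ValueError, match="at least 3"):
            egger(h)


def brute_force_weighted_median(ratios, weights):
    """Independent cumulative-weight interpolation, plain-python."""
    order = sorted(range(len(ratios)), key=lambda i: ratios[i])
    r = [ratios[i] for i in order]
    w = [weights[i] / sum(weights) for i in order]
    cum = 0.0
    s = []
    for wi in w:
        cum += wi
        s.append(cum - wi / 2.0)
    if s[0] >= 0.5:
        return r[0]
    for k in range(1, len(r)):
        if s[k] >= 0.5:
            return r[k - 1] + (r[k] - r[k - 1]) * (0.5 - s[k - 1]) / (s[k] - s[k - 1])
    return r[-1]


class TestWeightedMedian:
    def test_equal_weights_reduce_to_median(self):
        ratios = [RatioEstimate(c, v, 1.0) for c, v in zip("abc", [1.0, 2.0, 3.0])]
        res = weighted_median(ratios, n_boot=200, seed=1)
        assert res.estimate == pytest.approx(2.0)

    def test_weight_concentration_limit(self):
        ratios = [RatioEstimate("a", 5.0, 0.001),
                  RatioEstimate("b", 1.0, 10.0), RatioEstimate("c", 2.0, 10.0)]
        res = weighted_median(ratios, n_boot=200, seed=1)
        assert res.estimate == pytest.approx(5.0, abs=1e-3)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            ratios = random_ratios(rng, j=15)
            expected = brute_force_weighted_median(
                [r.ratio for r in ratios], [r.weight for r in ratios])
            got = _weighted_median_point(
                np.array([r.ratio for r in ratios]),
                np.array([r.weight for r in ratios]))
            assert got == pytest.approx(expected, abs=1e-10)

    def test_bootstrap_is_seeded(self):
        ratios = random_ratios(np.random.default_rng(0), j=10)
        a = weighted_median(ratios, n_boot=100, seed=5)
        b = weighted_median(ratios, n_boot=100, seed=5)
        assert a == b
        with pytest.raises(ValueError, match="seed"):
            weighted_median(ratios, n_boot=100, seed=None)


class TestPenalizedIVW:
    def test_homogeneous_equals_plain_ivw(self):
        ratios = [RatioEstimate(f"r{i}", 0.3, 0.1) for i in range(5)]
        assert ivw_penalized(ratios).estimate == pytest.approx(ivw(ratios, "fixed").estimate)
        assert ivw_penalized(ratios).se == pytest.approx(ivw(ratios, "fixed").se)

    def test_outlier_downweighted_toward_consensus(self):
        ratios = [RatioEstimate(f"r{i}", 0.3, 0.05) for i in range(10)]
        ratios.append(RatioEstimate("out", 3.0, 0.05))
        plain = ivw(ratios, "fixed").estimate
        pen = ivw_penalized(ratios).estimate
        assert abs(pen - 0.3) < abs(plain - 0.3)

    def test_penalization_never_shrinks_se_below_plain(self, rng):
        # penalized weights never exceed the originals, so the SE cannot shrink
        for _ in range(10):
            ratios = random_ratios(rng, j=12)
            assert ivw_penalized(ratios).se >= ivw(ratios, "fixed").se - 1e-12


class TestInvariances:
    def test_permutation_invariance(self, rng):
        ratios = random_ratios(rng, j=12)
        perm = [ratios[i] for i in rng.permutation(12)]
        for estimator in (lambda r: ivw(r, "fixed"), lambda r: ivw(r, "random"), ivw_penalized):
            assert estimator(ratios).estimate == pytest.approx(estimator(perm).estimate)

    def test_joint_sign_flip_invariance(self, rng):
        h = random_harmonized(rng, j=10)
        flipped = HarmonizedSet([
            HarmonizedRecord(r.rsid, -r.beta_x, r.se_x, -r.beta_y, r.se_y)
            for r in h.kept])
        assert ivw(ratio_estimates(h), "fixed").estimate == pytest.approx(
            ivw(ratio_estimates(flipped), "fixed").estimate)
        s1, i1 = egger(h)
        s2, i2 = egger(flipped)
        assert s1.estimate == pytest.approx(s2.estimate)
        assert i1.intercept == pytest.approx(i2.intercept)

    def test_or_scale_is_exponentiated_linear_scale(self, rng):
        res = with_or_scale(ivw(random_ratios(rng, j=8), "fixed"))
        assert res.or_scale[0] == pytest.approx(np.exp(res.estimate))
        assert res.or_scale[1] == pytest.approx(np.exp(res.ci_low))
        assert res.or_scale[2] == pytest.approx(np.exp(res.ci_high))
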
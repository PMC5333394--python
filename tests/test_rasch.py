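"""Conditional-likelihood machinery of the partial-credit model."""

import itertools

import numpy as np
import pytest
from scipy import stats

from gllrasch.rasch import (
    ConvergenceError,
    DataError,
    ItemParameters,
    conditional_item_given_score,
    conditional_probability_tables,
    elementary_symmetric,
    estimate_person,
    expected_score,
    fit_cml,
    log_esf,
    sample_given_score,
    sample_given_theta,
    score_distribution_given_theta,
)
from gllrasch.rasch import test_information as information_at
from tests.conftest import coded_cohort
from gllrasch.simulate import SyntheticConfig


def random_params(k, m, seed):
    rng = np.random.default_rng(seed)
    return ItemParameters(
        items=[f"I{i}" for i in range(k)],
        levels=[np.arange(m)] * k,
        eta=[np.concatenate([[0.0], rng.normal(scale=1.0, size=m - 1)])
             for _ in range(k)])


def brute_force_gamma(params):
    """Exhaustive pattern enumeration oracle for the gamma table."""
    out = np.zeros(params.max_score + 1)
    for pattern in itertools.product(*[range(len(l)) for l in params.levels]):
        w = np.exp(sum(params.eta[i][c] for i, c in enumerate(pattern)))
        r = sum(params.levels[i][c] for i, c in enumerate(pattern))
        out[r] += w
    return out


class TestElementarySymmetric:
    def test_two_dichotomous_items_at_zero(self):
        p = ItemParameters(items=["a", "b"], levels=[np.arange(2)] * 2,
                           eta=[np.zeros(2)] * 2)
        assert np.allclose(elementary_symmetric(p), [1, 2, 1])

    def test_single_item_conditional_is_degenerate(self):
        p = random_params(1, 5, seed=3)
        for r in range(5):
            d = conditional_item_given_score(p, 0, r)
            assert d[r] == pytest.approx(1.0)

    @pytest.mark.parametrize("k,m,seed", [(2, 2, 0), (3, 3, 1), (4, 5, 2),
                                          (3, 5, 3), (4, 3, 4)])
    def test_recursion_equals_enumeration(self, k, m, seed):
        p = random_params(k, m, seed)
        assert np.allclose(elementary_symmetric(p), brute_force_gamma(p),
                           rtol=1e-12, atol=1e-10)

    def test_no_overflow_for_extreme_etas(self):
        p = ItemParameters(items=list("abcdefg"), levels=[np.arange(5)] * 7,
                           eta=[np.linspace(0, 60, 5)] * 7)
        lg = log_esf(p.levels, p.eta)
        assert np.all(np.isfinite(lg[np.isfinite(lg)]))


class TestConditionalItemGivenScore:
    def test_exchangeable_dichotomous_items(self):
        p = ItemParameters(items=["a", "b"], levels=[np.arange(2)] * 2,
                           eta=[np.zeros(2)] * 2)
        d = conditional_item_given_score(p, 0, 1)
        assert d == pytest.approx([0.5, 0.5])

    def test_boundary_score_is_deterministic(self):
        p = random_params(3, 4, seed=5)
        assert conditional_item_given_score(p, 1, 0)[0] == pytest.approx(1.0)

    def test_matches_enumeration(self):
        p = random_params(3, 3, seed=6)
        r = 3
        num = np.zeros(3)
        den = 0.0
        for pattern in itertools.product(range(3), repeat=3):
            if sum(pattern) == r:
                w = np.exp(sum(p.eta[i][c] for i, c in enumerate(pattern)))
                num[pattern[0]] += w
                den += w
        assert np.allclose(conditional_item_given_score(p, 0, r), num / den,
                           atol=1e-12)

    def test_unachievable_score_raises(self):
        p = random_params(2, 3, seed=7)
        with pytest.raises(ValueError):
            conditional_item_given_score(p, 0, 99)

    def test_distributions_sum_to_one(self):
        p = random_params(4, 5, seed=8)
        tables = conditional_probability_tables(p)
        for tab in tables:
            sums = tab.sum(axis=1)
            achievable = sums > 0
            assert np.allclose(sums[achievable], 1.0, atol=1e-10)


class TestFitCML:
    def test_threshold_recovery(self, rasch_cohort_1000):
        cfg, scores, truth = rasch_cohort_1000
        fit = fit_cml(scores, items=list(cfg.scale.items), m=5)
        rmse = np.sqrt(np.mean(
            (fit.all_thresholds() - truth["params"].all_thresholds()) ** 2))
        assert rmse <= 0.15
        assert fit.grad_norm <= 1e-6
        # identification: thresholds sum to zero
        assert abs(fit.all_thresholds().sum()) < 1e-8

    def test_duplicated_items_get_equal_thresholds(self):
        rng = np.random.default_rng(3)
        base = rng.integers(0, 5, size=(200, 2))
        scores = np.column_stack([base[:, 0], base[:, 0], base[:, 1]])
        fit = fit_cml(scores)
        assert np.allclose(fit.thresholds(0), fit.thresholds(1), atol=1e-6)

    def test_tiny_dichotomous_fit_beats_grid_search(self):
        rng = np.random.default_rng(7)
        theta = rng.normal(size=30)
        cut = np.array([-0.5, 0.0, 0.5])
        data = (rng.random((30, 3)) < 1 / (1 + np.exp(-(theta[:, None] - cut)))
                ).astype(int)
        fit = fit_cml(data, m=2)
        # vectorized 0.05-step grid over [-3, 3]^3 in the free etas
        g = np.arange(-3, 3.0001, 0.05)
        E1, E2, E3 = np.meshgrid(g, g, g, indexing="ij")
        counts = data.sum(axis=0)
        n_r = np.bincount(data.sum(axis=1), minlength=4)
        g1, g2, g3 = np.exp(E1), np.exp(E2), np.exp(E3)
        lg1 = np.log(g1 + g2 + g3)
        lg2 = np.log(g1 * g2 + g1 * g3 + g2 * g3)
        lg3 = E1 + E2 + E3
        ll = (counts[0] * E1 + counts[1] * E2 + counts[2] * E3
              - n_r[1] * lg1 - n_r[2] * lg2 - n_r[3] * lg3)
        assert fit.loglik >= ll.max() - 1e-9

    def test_unobserved_category_dropped_or_strict_error(self):
        rng = np.random.default_rng(9)
        scores = rng.integers(0, 5, size=(80, 3))
        scores[scores[:, 0] == 2, 0] = 1   # category 2 of item 1 never observed
        fit = fit_cml(scores)
        assert list(fit.levels[0]) == [0, 1, 3, 4]
        with pytest.raises(DataError):
            fit_cml(scores, strict=True)

    def test_missing_responses_rejected(self):
        scores = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(DataError):
            fit_cml(scores)


class TestPersonSide:
    def symmetric_params(self):
        return SyntheticConfig(seed=0).true_params  # symmetric by construction

    def test_half_max_score_maps_to_zero(self):
        p = self.symmetric_params()
        assert estimate_person(p, 10, kind="ml").theta == pytest.approx(0.0, abs=1e-8)

    def test_extreme_ml_flagged_infinite(self):
        p = self.symmetric_params()
        est = estimate_person(p, p.max_score, kind="ml")
        assert est.extreme and np.isinf(est.theta)

    def test_wle_finite_and_symmetric_at_extremes(self):
        p = self.symmetric_params()
        lo = estimate_person(p, 0, kind="wle")
        hi = estimate_person(p, p.max_score, kind="wle")
        assert np.isfinite(lo.theta) and np.isfinite(hi.theta)
        assert lo.theta == pytest.approx(-hi.theta, abs=1e-6)

    def test_ml_matches_bisection_oracle(self):
        p = ItemParameters(items=list("abc"), levels=[np.arange(2)] * 3,
                           eta=[np.array([0.0, 0.3]), np.array([0.0, -0.2]),
                                np.array([0.0, 0.6])])
        est = estimate_person(p, 2, kind="ml")
        lo, hi = -10.0, 10.0
        for _ in range(60):
            mid = (lo + hi) / 2
            if expected_score(p, mid) < 2:
                lo = mid
            else:
                hi = mid
        assert est.theta == pytest.approx((lo + hi) / 2, abs=1e-6)

    def test_theta_increasing_in_score_and_positive_se(self):
        p = random_params(4, 4, seed=11)
        thetas = [estimate_person(p, r, kind="wle").theta
                  for r in range(p.max_score + 1)]
        assert np.all(np.diff(thetas) > 0)
        for r in range(1, p.max_score):
            assert estimate_person(p, r).se > 0


class TestInformation:
    def test_dichotomous_at_threshold(self):
        p = ItemParameters(items=["a"], levels=[np.arange(2)],
                           eta=[np.array([0.0, 0.0])])
        info, per_item = information_at(p, 0.0)
        assert info == pytest.approx(0.25)

    def test_vanishes_in_the_tails(self):
        p = random_params(3, 5, seed=12)
        assert information_at(p, 30.0)[0] < 1e-8
        assert information_at(p, -30.0)[0] < 1e-8

    def test_equals_derivative_of_expected_score(self):
        p = random_params(1, 5, seed=13)
        h = 1e-5
        for theta in (-1.0, 0.0, 0.7):
            deriv = (expected_score(p, theta + h) - expected_score(p, theta - h)) / (2 * h)
            assert information_at(p, theta)[0] == pytest.approx(deriv, rel=1e-5)


class TestSufficiencyAndSampling:
    def test_conditional_distribution_free_of_theta(self):
        """Patterns given the total score have the same law at theta=-1 and +1."""
        p = random_params(3, 3, seed=14)
        rng = np.random.default_rng(0)
        pooled_p = []
        lo = sample_given_theta(p, np.full(5000, -1.0), rng)
        hi = sample_given_theta(p, np.full(5000, 1.0), rng)
        pat_lo = lo @ np.array([9, 3, 1])
        pat_hi = hi @ np.array([9, 3, 1])
        for r in range(1, 6):
            a = pat_lo[lo.sum(axis=1) == r]
            b = pat_hi[hi.sum(axis=1) == r]
            cats = np.unique(np.concatenate([a, b]))
            ca = np.array([(a == c).sum() for c in cats])
            cb = np.array([(b == c).sum() for c in cats])
            keep = (ca + cb) >= 10
            if keep.sum() < 2:
                continue
            _, pval, _, _ = stats.chi2_contingency(np.stack([ca[keep], cb[keep]]))
            pooled_p.append(pval)
        assert min(pooled_p) > 1e-4

    def test_score_conditioned_sampler_matches_conditional_law(self):
        p = random_params(3, 3, seed=15)
        rng = np.random.default_rng(1)
        r = 3
        draws = sample_given_score(p, np.full(20000, r), rng)
        assert np.all(draws.sum(axis=1) == r)
        tab = conditional_probability_tables(p)[0]
        emp = np.bincount(draws[:, 0], minlength=3) / 20000
        assert np.allclose(emp, tab[r], atol=0.015)

    def test_monotone_conditional_item_means(self, rasch_cohort_1000):
        cfg, scores, _ = rasch_cohort_1000
        fit = fit_cml(scores, m=5)
        tables = conditional_probability_tables(fit)
        for i, tab in enumerate(tables):
            means = tab @ fit.levels[i]
            achievable = tab.sum(axis=1) > 0
            assert np.all(np.diff(means[achievable]) >= -1e-9)

    def test_score_distribution_sums_to_one(self):
        p = random_params(4, 5, seed=16)
        d = score_distribution_given_theta(p, 0.3)
        assert d.sum() == pytest.approx(1.0, abs=1e-10)
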
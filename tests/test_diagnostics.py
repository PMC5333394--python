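"""Conditional fit tests: CLR, screens, gamma statistics, residuals, BH."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gllrasch import diagnostics as D
from gllrasch.gllrm import GLLRMSpec, fit_gllrm
from gllrasch.rasch import DataError, ItemParameters, fit_cml
from gllrasch.simulate import SyntheticConfig
from tests.conftest import coded_cohort

ITEMS5 = ["Q1", "Q2", "Q3", "Q4", "Q5"]


def brute_gamma(x, y):
    C = Dd = 0
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            s = (x[i] - x[j]) * (y[i] - y[j])
            C += s > 0
            Dd += s < 0
    return (C - Dd) / (C + Dd)


class TestGamma:
    def test_perfect_concordance(self):
        x = np.arange(10)
        assert D.goodman_kruskal_gamma(x, x * 2) == pytest.approx(1.0)

    def test_six_person_toy_table_matches_pair_count(self):
        x = np.array([0, 1, 1, 2, 0, 2])
        y = np.array([3, 1, 2, 2, 0, 3])
        assert D.goodman_kruskal_gamma(x, y) == pytest.approx(brute_gamma(x, y))

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_exhaustive_pairs_and_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 4, size=15)
        y = rng.integers(0, 5, size=15)
        oracle = brute_gamma(x, y)
        if np.isnan(oracle):
            return
        got = D.goodman_kruskal_gamma(x, y)
        assert got == pytest.approx(oracle)
        assert D.goodman_kruskal_gamma(x.max() - x, y) == pytest.approx(-oracle)
        assert -1 <= got <= 1

    def test_item_rest_gamma_requires_variation(self):
        scores = np.column_stack([np.ones(10, dtype=int),
                                  np.arange(10) % 3])
        with pytest.raises(DataError):
            D.item_rest_gamma(scores, 0)

    def test_independent_item_has_small_gamma(self):
        rng = np.random.default_rng(0)
        scores = rng.integers(0, 5, size=(4000, 5))
        assert abs(D.item_rest_gamma(scores, 0)) < 0.1

    def test_partial_gamma_pools_strata(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 3, 60)
        y = rng.integers(0, 2, 60)
        strata = np.repeat([0, 1, 2], 20)
        gam, se = D.partial_gamma(x, y, strata)
        # oracle: pooled concordant/discordant over within-stratum pairs
        C = Dd = 0
        for s in range(3):
            xs, ys = x[strata == s], y[strata == s]
            for i in range(20):
                for j in range(i + 1, 20):
                    v = (xs[i] - xs[j]) * (ys[i] - ys[j])
                    C += v > 0
                    Dd += v < 0
        assert gam == pytest.approx((C - Dd) / (C + Dd))
        assert se > 0


class TestBH:
    def test_step_up_examples(self):
        rej, p_adj = D.bh_adjust([0.01, 0.02, 0.03, 0.04], 0.05)
        assert rej.all()
        rej, _ = D.bh_adjust([1.0, 1.0, 1.0], 0.05)
        assert not rej.any()
        rej, p_adj = D.bh_adjust([0.04], 0.05)
        assert rej[0] and p_adj[0] == pytest.approx(0.04)

    def test_empty_input(self):
        rej, p_adj = D.bh_adjust([], 0.05)
        assert len(rej) == 0 and len(p_adj) == 0

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_matches_hand_rolled_step_up(self, ps):
        q = 0.05
        rej, p_adj = D.bh_adjust(ps, q)
        # oracle: classic step-up rule
        m = len(ps)
        order = np.argsort(ps)
        sorted_p = np.asarray(ps)[order]
        kmax = 0
        for i, p in enumerate(sorted_p, start=1):
            if p <= q * i / m:
                kmax = i
        expect = np.zeros(m, dtype=bool)
        expect[order[:kmax]] = True
        assert np.array_equal(rej, expect)
        assert np.all(np.diff(p_adj[order]) >= -1e-12)   # monotone

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            D.bh_adjust([0.5, 1.5], 0.05)


class TestCLR:
    def test_zero_on_duplicated_groups(self):
        cfg = SyntheticConfig(n=200, seed=21)
        scores, _ = coded_cohort(cfg)
        dup = np.vstack([scores, scores])
        codes = {"half": np.r_[np.zeros(len(scores), int), np.ones(len(scores), int)]}
        fit = fit_cml(dup)
        res = D.clr_test(fit, dup, codes, grouping="half")
        assert res.statistic == pytest.approx(0.0, abs=1e-5)
        assert res.df > 0

    def test_nonnegative_and_chisquare_p(self):
        cfg = SyntheticConfig(n=300, seed=22)
        scores, truth = coded_cohort(cfg)
        fit = fit_cml(scores, items=ITEMS5)
        for grouping, codes in (("score", None),
                                ("age", {"age": truth["group_codes"]["age"]})):
            res = D.clr_test(fit, scores, codes, grouping=grouping)
            assert res.statistic >= 0
            assert 0 <= res.p <= 1
            assert res.df > 0

    def test_detects_strong_age_dif(self):
        cfg = SyntheticConfig(n=500, seed=5003, dif=(("Q5", "age", 0.8),))
        scores, truth = coded_cohort(cfg)
        fit = fit_cml(scores, items=ITEMS5)
        res = D.clr_test(fit, scores, {"age": truth["group_codes"]["age"]},
                         grouping="age")
        assert res.p < 0.05

    def test_evidence_grades(self):
        assert D.TestResult("t", None, 1.0, 1, 0.005).evidence == "strong"
        assert D.TestResult("t", None, 1.0, 1, 0.03).evidence == "weak-to-moderate"
        assert D.TestResult("t", None, 1.0, 1, 0.5).evidence == "none"


class TestScreens:
    def test_two_item_scale_yields_single_pair(self):
        rng = np.random.default_rng(23)
        scores = rng.integers(0, 3, size=(150, 2))
        fit = fit_cml(scores)
        res = D.screen_local_dependence(fit, scores)
        assert len(res) == 1
        assert res[0].df > 0

    def test_injected_pair_attains_smallest_p(self):
        cfg = SyntheticConfig(n=500, seed=13001, ld=(("Q1", "Q3", 0.5),))
        scores, _ = coded_cohort(cfg)
        fit = fit_cml(scores, items=ITEMS5)
        res = D.screen_local_dependence(fit, scores)
        best = min(res, key=lambda t: t.p)
        assert best.term == ("Q1", "Q3")
        assert best.rejected

    def test_dif_screen_flags_injected_combination(self):
        cfg = SyntheticConfig(n=500, seed=5001, dif=(("Q5", "age", 0.9),))
        scores, truth = coded_cohort(cfg)
        fit = fit_cml(scores, items=ITEMS5)
        gc = {k: v for k, v in truth["group_codes"].items()
              if k in ("age", "sex", "hba1c", "treatment")}
        res = D.screen_dif(fit, scores, gc)
        hits = [t for t in res if t.rejected]
        assert any(t.term == ("Q5", "age") for t in hits)

    def test_constant_covariate_skipped(self):
        cfg = SyntheticConfig(n=200, seed=29)
        scores, _ = coded_cohort(cfg)
        fit = fit_cml(scores, items=ITEMS5)
        res = D.screen_dif(fit, scores, {"const": np.zeros(len(scores), int)})
        assert res == []


class TestExpectedGamma:
    def test_two_item_scale_matches_enumeration(self):
        """With two items the rest score is the other item, so the expected
        gamma has a closed enumeration form given the score distribution."""
        rng = np.random.default_rng(31)
        scores = rng.integers(0, 3, size=(500, 2))
        fit = fit_cml(scores)
        rec = D.expected_gamma_and_p(fit, scores, 0, B=2000,
                                     rng=np.random.default_rng(0))
        # enumeration oracle: E over replicate tables of gamma is intractable
        # in closed form, but the *per-pattern* law is exact; build the
        # expected cell table and check the simulated mean against the gamma
        # of a large simulated pool drawn directly from the conditional law
        totals = scores.sum(axis=1)
        from gllrasch.rasch import sample_given_score
        pool = sample_given_score(fit, np.tile(totals, 50),
                                  np.random.default_rng(1))
        oracle = D.goodman_kruskal_gamma(pool[:, 0], pool[:, 1])
        assert rec["expected"] == pytest.approx(oracle, abs=0.05)

    def test_noise_item_flagged_below_expected(self):
        cfg = SyntheticConfig(n=500, seed=27003, off_dimension=(("Q5", 0.3),))
        scores, _ = coded_cohort(cfg)
        fit = fit_cml(scores, items=ITEMS5)
        rec = D.expected_gamma_and_p(fit, scores, 4, B=400,
                                     rng=np.random.default_rng(2))
        assert rec["direction"] == "below"
        assert rec["p"] < 0.05

    def test_simulation_p_reproducible_with_seed(self):
        cfg = SyntheticConfig(n=200, seed=33)
        scores, _ = coded_cohort(cfg)
        fit = fit_cml(scores, items=ITEMS5)
        a = D.expected_gamma_and_p(fit, scores, 1, B=200,
                                   rng=np.random.default_rng(7))
        b = D.expected_gamma_and_p(fit, scores, 1, B=200,
                                   rng=np.random.default_rng(7))
        assert a == b

    def test_small_B_rejected(self):
        cfg = SyntheticConfig(n=100, seed=34)
        scores, _ = coded_cohort(cfg)
        fit = fit_cml(scores, items=ITEMS5)
        with pytest.raises(ValueError):
            D.expected_gamma_and_p(fit, scores, 0, B=50)


class TestResiduals:
    def test_model_data_gives_unit_mean_squares(self):
        cfg = SyntheticConfig(n=1000, seed=35)
        scores, _ = coded_cohort(cfg)
        fit = fit_cml(scores, items=ITEMS5)
        recs = D.conditional_fit_residuals(fit, scores, B=200,
                                           rng=np.random.default_rng(0))
        for rec in recs:
            assert 0.8 <= rec["infit"] <= 1.2
            assert 0.8 <= rec["outfit"] <= 1.2

    def test_noise_item_has_largest_outfit(self):
        rng = np.random.default_rng(36)
        cfg = SyntheticConfig(n=800, seed=36)
        scores, _ = coded_cohort(cfg)
        noise = rng.integers(0, 5, size=(len(scores), 1))
        scores = np.column_stack([scores, noise])
        fit = fit_cml(scores)
        recs = D.conditional_fit_residuals(fit, scores, B=200,
                                           rng=np.random.default_rng(1))
        outfits = [r["outfit"] for r in recs]
        assert np.argmax(outfits) == 5
        assert outfits[5] > 1

    def test_single_person_flagged_unreliable(self):
        scores = np.array([[1, 2, 3]])
        p = ItemParameters(items=["a", "b", "c"], levels=[np.arange(4)] * 3,
                           eta=[np.zeros(4)] * 3)
        recs = D.conditional_fit_residuals(p, scores, B=150,
                                           rng=np.random.default_rng(2))
        assert all(r["p_unreliable"] for r in recs)
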
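"""GLLRM estimation, pattern probabilities and structure search."""

import itertools

import numpy as np
import pytest

from gllrasch.gllrm import (
    GLLRMParameters,
    GLLRMSpec,
    conditional_pattern_prob,
    fit_gllrm,
    model_search,
)
from gllrasch.rasch import ItemParameters, fit_cml
from gllrasch.simulate import SyntheticConfig
from tests.conftest import coded_cohort

ITEMS5 = ["Q1", "Q2", "Q3", "Q4", "Q5"]


def hand_built_gllrm(lam=0.7, delta=0.5, m=3):
    """Three-item GLLRM with an LD pair (0,1) and age DIF on item 2."""
    rng = np.random.default_rng(4)
    eta = [np.concatenate([[0.0], rng.normal(size=m - 1)]) for _ in range(3)]
    base = ItemParameters(items=["A", "B", "C"], levels=[np.arange(m)] * 3, eta=eta)
    spec = GLLRMSpec(ld_pairs=(("A", "B"),), dif_terms=(("C", "age"),))
    return GLLRMParameters(
        spec=spec, base=base, ld={("A", "B"): lam},
        dif={("C", "age"): np.array([0.0, delta])}, group_levels={})


def brute_pattern_probs(gp, group, r):
    """Enumeration oracle for P(pattern | stratum, score)."""
    m = len(gp.base.levels[0])
    lam = gp.ld[("A", "B")]
    delta = gp.dif[("C", "age")][group]
    pats, weights = [], []
    for pat in itertools.product(range(m), repeat=3):
        if sum(pat) != r:
            continue
        w = sum(gp.base.eta[i][pat[i]] for i in range(3))
        w += lam * pat[0] * pat[1]
        w -= delta * pat[2]
        pats.append(pat)
        weights.append(np.exp(w))
    weights = np.array(weights)
    return np.array(pats), weights / weights.sum()


class TestSpec:
    def test_self_pair_rejected(self):
        with pytest.raises(ValueError):
            GLLRMSpec(ld_pairs=(("A", "A"),))

    def test_unknown_references_rejected(self):
        spec = GLLRMSpec(ld_pairs=(("A", "Z"),))
        with pytest.raises(ValueError):
            spec.validate(["A", "B"], [])

    def test_pairs_are_canonicalized(self):
        spec = GLLRMSpec(ld_pairs=(("B", "A"),))
        assert spec.ld_pairs == (("A", "B"),)


class TestPatternProbabilities:
    def test_empty_spec_reduces_to_rasch(self):
        cfg = SyntheticConfig(n=400, seed=5)
        scores, _ = coded_cohort(cfg)
        cml = fit_cml(scores, items=ITEMS5)
        fit = fit_gllrm(scores, GLLRMSpec(), items=ITEMS5)
        for a, b in zip(cml.eta, fit.base.eta):
            assert np.allclose(a, b, atol=1e-6)
        from gllrasch.rasch import log_esf
        lg = log_esf(cml.levels, cml.eta)
        pats, probs = conditional_pattern_prob(fit, {}, 7)
        direct = np.array([
            np.exp(sum(cml.eta[i][list(cml.levels[i]).index(p[i])]
                       for i in range(5)) - lg[7]) for p in pats])
        assert np.allclose(probs, direct, atol=1e-10)

    @pytest.mark.parametrize("r", [2, 3, 4])
    @pytest.mark.parametrize("group", [0, 1])
    def test_matches_enumeration_oracle(self, r, group):
        gp = hand_built_gllrm()
        pats, probs = conditional_pattern_prob(gp, {"age": group}, r)
        opats, oprobs = brute_pattern_probs(gp, group, r)
        order = {tuple(p): q for p, q in zip(opats, oprobs)}
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)
        for p, q in zip(pats, probs):
            assert q == pytest.approx(order[tuple(p)], abs=1e-10)

    def test_positive_ld_raises_conditional_covariance(self):
        def cond_cov(gp, r):
            pats, probs = conditional_pattern_prob(gp, {"age": 0}, r)
            x, y = pats[:, 0].astype(float), pats[:, 1].astype(float)
            return probs @ (x * y) - (probs @ x) * (probs @ y)
        # symmetric instrument: the lift holds at every interior score
        sym = hand_built_gllrm(lam=0.8, delta=0.0)
        sym0 = hand_built_gllrm(lam=0.0, delta=0.0)
        for gp in (sym, sym0):
            for e in gp.base.eta:
                e[:] = 0.0
        for r in (2, 3, 4):
            assert cond_cov(sym, r) > cond_cov(sym0, r)
        # skewed thresholds: the lift holds on average over scores (tight
        # score conditioning can reverse it at individual mid scores)
        dep = hand_built_gllrm(lam=0.8, delta=0.0)
        ind = hand_built_gllrm(lam=0.0, delta=0.0)
        rs = range(1, 6)
        assert (np.mean([cond_cov(dep, r) for r in rs])
                > np.mean([cond_cov(ind, r) for r in rs]))

    def test_positive_dif_offset_lowers_conditional_item_mean(self):
        gp = hand_built_gllrm(lam=0.0, delta=0.5)
        for r in range(1, 6):
            means = []
            for group in (0, 1):
                pats, probs = conditional_pattern_prob(gp, {"age": group}, r)
                means.append(probs @ pats[:, 2].astype(float))
            assert means[1] < means[0]


class TestFitting:
    def test_ld_parameter_recovery(self):
        cfg = SyntheticConfig(n=1000, seed=11, ld=(("Q1", "Q3", 0.5),))
        scores, _ = coded_cohort(cfg)
        fit = fit_gllrm(scores, GLLRMSpec(ld_pairs=(("Q1", "Q3"),)), items=ITEMS5)
        assert abs(fit.ld[("Q1", "Q3")] - 0.5) <= 0.2

    def test_dif_offset_recovery(self):
        cfg = SyntheticConfig(n=1000, seed=13, dif=(("Q5", "age", 0.6),))
        scores, truth = coded_cohort(cfg)
        fit = fit_gllrm(scores, GLLRMSpec(dif_terms=(("Q5", "age"),)),
                        group_codes={"age": truth["group_codes"]["age"]},
                        items=ITEMS5)
        offsets = fit.dif[("Q5", "age")]
        assert offsets[0] == 0.0
        for off in offsets[1:]:
            assert off > 0 and abs(off - 0.6) <= 0.25

    def test_nested_likelihood_monotone(self):
        cfg = SyntheticConfig(n=400, seed=17)
        scores, _ = coded_cohort(cfg)
        base = fit_gllrm(scores, GLLRMSpec(), items=ITEMS5)
        aug = fit_gllrm(scores, GLLRMSpec(ld_pairs=(("Q1", "Q2"),)), items=ITEMS5)
        assert aug.loglik >= base.loglik - 1e-6
        assert aug.df == base.df + 1

    def test_perfectly_dependent_pair_flags_separation(self):
        rng = np.random.default_rng(19)
        col = rng.integers(0, 3, size=400)
        other = rng.integers(0, 3, size=400)
        scores = np.column_stack([col, col, other])
        fit = fit_gllrm(scores, GLLRMSpec(ld_pairs=(("I1", "I2"),)))
        assert any(kind == "ld" for kind, _ in fit.separation_flags)

    def test_full_table_interaction_nests_linear(self):
        cfg = SyntheticConfig(n=600, seed=23, ld=(("Q1", "Q3", 0.4),))
        scores, _ = coded_cohort(cfg)
        lin = fit_gllrm(scores, GLLRMSpec(ld_pairs=(("Q1", "Q3"),),
                                          interaction="linear"), items=ITEMS5)
        full = fit_gllrm(scores, GLLRMSpec(ld_pairs=(("Q1", "Q3"),),
                                           interaction="full"), items=ITEMS5)
        assert full.loglik >= lin.loglik - 1e-6
        assert full.df > lin.df


class TestModelSearch:
    def test_recovers_injected_ld_pair(self):
        cfg = SyntheticConfig(n=500, seed=23000, ld=(("Q1", "Q3", 0.5),))
        scores, truth = coded_cohort(cfg)
        gc = {k: v for k, v in truth["group_codes"].items()
              if k in ("age", "sex", "hba1c", "treatment")}
        spec, fit, trail, weak = model_search(scores, gc, items=ITEMS5,
                                              seed=0, gamma_B=150)
        assert spec.ld_pairs == (("Q1", "Q3"),)
        assert trail[0].action == "add_ld"

    def test_recovers_injected_age_dif(self):
        cfg = SyntheticConfig(n=500, seed=25001, dif=(("Q5", "age", 0.6),))
        scores, truth = coded_cohort(cfg)
        gc = {k: v for k, v in truth["group_codes"].items()
              if k in ("age", "sex", "hba1c", "treatment")}
        spec, fit, trail, weak = model_search(scores, gc, items=ITEMS5,
                                              seed=0, gamma_B=150)
        assert ("Q5", "age") in spec.dif_terms

    def test_flags_off_dimension_item_as_removal_candidate(self):
        cfg = SyntheticConfig(n=500, seed=27002, off_dimension=(("Q5", 0.4),))
        scores, truth = coded_cohort(cfg)
        gc = {k: v for k, v in truth["group_codes"].items()
              if k in ("age", "sex", "hba1c", "treatment")}
        spec, fit, trail, weak = model_search(scores, gc, items=ITEMS5,
                                              seed=0, gamma_B=300)
        assert "Q5" in weak

    def test_pure_rasch_data_keeps_empty_spec(self):
        cfg = SyntheticConfig(n=300, seed=41000)
        scores, truth = coded_cohort(cfg)
        gc = {k: v for k, v in truth["group_codes"].items()
              if k in ("age", "sex", "hba1c", "treatment")}
        spec, fit, trail, weak = model_search(scores, gc, items=ITEMS5,
                                              seed=0, gamma_B=150)
        assert spec.is_empty
        assert trail[-1].action == "stop"
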
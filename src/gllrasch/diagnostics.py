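"""Fit diagnostics by conditional inference.

Everything here conditions on total scores (and covariate strata), so no
assumption about the latent distribution enters any test:

* conditional likelihood ratio (CLR) tests of item-parameter homogeneity
  across score groups or covariate groups — the overall fit / overall DIF
  tests;
* screens for local dependence (one CLR per item pair) and for DIF (partial
  Goodman-Kruskal gamma between item and covariate given rest-score strata,
  with a CLR confirmation for flagged combinations), Benjamini-Hochberg
  adjusted within each screen;
* observed vs model-expected item-rest-score gamma correlations, with
  Monte-Carlo p-values from parametric simulation conditional on the
  observed score distribution;
* conditional infit / outfit (residuals standardized against score-
  conditional moments, never against person-parameter estimates).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import gllrm as _gllrm
from .gllrm import GLLRMParameters, GLLRMSpec, fit_gllrm
from .rasch import (
    DataError,
    ItemParameters,
    conditional_probability_tables,
    fit_cml,
    sample_given_score,
    _prepare_scores,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TestResult", "ItemFitRecord", "clr_test", "screen_local_dependence",
    "screen_dif", "item_rest_gamma", "goodman_kruskal_gamma", "partial_gamma",
    "expected_gamma_and_p", "conditional_fit_residuals", "bh_adjust",
]


def _evidence(p: float) -> str:
    if not np.isfinite(p) or p > 0.05:
        return "none"
    return "strong" if p < 0.01 else "weak-to-moderate"


@dataclass
class TestResult:
    """One conditional test: statistic, df, p and its multiplicity verdict."""

    kind: str                 # "clr-homogeneity", "ld-screen", "dif-screen", ...
    term: object              # grouping variable, item pair, or (item, covariate)
    statistic: float
    df: int
    p: float
    p_adjusted: float = np.nan
    rejected: bool = False
    evidence: str = "none"
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.isfinite(self.p):
            self.p = float(min(max(self.p, 0.0), 1.0))
        self.evidence = _evidence(self.p)


@dataclass
class ItemFitRecord:
    item: str
    observed_gamma: float
    expected_gamma: float
    gamma_p: float
    direction: str
    infit: float = np.nan
    outfit: float = np.nan
    infit_p: float = np.nan
    outfit_p: float = np.nan


# ---------------------------------------------------------------------------
# CLR tests
# ---------------------------------------------------------------------------

def _fit_and_df(scores, spec, group_codes, items, m, gtol=1e-3, base0=None):
    """Fit the given structure and return (loglik, df, fit).

    Test internals use a looser gradient tolerance than the public fitters:
    a gradient of 1e-3 perturbs the maximized log-likelihood (hence a CLR
    statistic) only quadratically, far below any reporting precision.
    """
    if spec is None or spec.is_empty:
        params = fit_cml(scores, items=items, m=m, gtol=gtol)
        return params.loglik, params.n_free_parameters, params
    fit = fit_gllrm(scores, spec, group_codes, items=items, m=m, gtol=gtol,
                    base0=base0)
    return fit.loglik, fit.df, fit


def _model_pieces(model):
    if isinstance(model, GLLRMParameters):
        return model.spec, model.base.items, model.loglik, model.df
    if isinstance(model, ItemParameters):
        return GLLRMSpec(), model.items, model.loglik, model.n_free_parameters
    raise TypeError("model must be ItemParameters or GLLRMParameters")


def score_split_groups(scores: np.ndarray, max_score: int | None = None) -> np.ndarray:
    """Low/high score groups split at the median total among non-extreme
    scorers; ties go to the low group. Extreme scorers join the nearer group
    (they contribute nothing to the conditional likelihood either way)."""
    scores = _prepare_scores(scores)
    total = scores.sum(axis=1)
    if max_score is None:
        max_score = int(scores.max(axis=0).sum())
    interior = (total > 0) & (total < max_score)
    med = np.median(total[interior]) if interior.any() else np.median(total)
    return (total > med).astype(int)


def clr_test(model, scores, group_codes=None, grouping="score",
             items=None, m=None) -> TestResult:
    """Conditional likelihood ratio test of item-parameter homogeneity.

    Compares the pooled conditional likelihood with the sum of group-wise
    maximized conditional likelihoods, groups defined either by the median
    score split (``grouping="score"``) or by a discretized covariate
    (``grouping=<covariate name>``).

    A category unobserved within a group is dropped from that group's
    level set — the exact supremum of the group likelihood as the category
    parameter tends to minus infinity, keeping the likelihoods comparable —
    while the df keeps the full per-group parameter count: the boundary
    category's (bounded) deviance contribution is covered by the
    chi-square degree of freedom it retains.  Dropping both the statistic
    contribution and the df would make the test anti-conservative, because
    score-dependent category sparsity concentrates the dropped categories
    in the group fits.
    """
    scores = _prepare_scores(scores)
    spec, mitems, _, _ = _model_pieces(model)
    if items is None:
        items = mitems
    if m is None:
        m = int(scores.max()) + 1
    group_codes = dict(group_codes or {})
    if grouping == "score":
        g = score_split_groups(scores)
    else:
        if grouping not in group_codes:
            raise DataError(f"no group codes for covariate {grouping!r}")
        g = np.asarray(group_codes[grouping], dtype=int)

    pooled_ll, pooled_df, _ = _fit_and_df(scores, spec, group_codes, items, m)
    ll_sum, n_groups = 0.0, 0
    for gv in np.unique(g):
        sel = g == gv
        sub_codes = {c: np.asarray(v)[sel] for c, v in group_codes.items()}
        ll_g, _, _ = _fit_and_df(scores[sel], spec, sub_codes, items, m)
        ll_sum += ll_g
        n_groups += 1
    statistic = max(2.0 * (ll_sum - pooled_ll), 0.0)
    df = max((n_groups - 1) * pooled_df, 0)
    p = float(stats.chi2.sf(statistic, df)) if df > 0 else 1.0
    return TestResult(kind="clr-homogeneity", term=grouping,
                      statistic=float(statistic), df=int(df), p=p)


# ---------------------------------------------------------------------------
# screens
# ---------------------------------------------------------------------------

def screen_local_dependence(model, scores, group_codes=None, alpha=0.05,
                            items=None, m=None) -> list:
    """CLR screen over all item pairs for residual (local) dependence.

    For each pair the declared model plus that pair's interaction term is
    fitted and compared with the declared model; p-values are BH-adjusted
    over the pairs.
    """
    scores = _prepare_scores(scores)
    spec, mitems, base_ll, base_df = _model_pieces(model)
    if items is None:
        items = mitems
    if m is None:
        m = int(scores.max()) + 1
    base0 = model.base if isinstance(model, GLLRMParameters) else model
    if not np.isfinite(base_ll):
        base_ll, base_df, refit = _fit_and_df(scores, spec, group_codes, items, m)
        base0 = refit.base if isinstance(refit, GLLRMParameters) else refit
    results = []
    k = len(items)
    for a in range(k):
        for b in range(a + 1, k):
            pair = tuple(sorted((items[a], items[b])))
            if pair in spec.ld_pairs:
                continue
            aug = spec.with_ld(pair)
            ll, df, _ = _fit_and_df(scores, aug, group_codes, items, m,
                                    base0=base0)
            statistic = max(2.0 * (ll - base_ll), 0.0)
            ddf = max(df - base_df, 1)
            p = float(stats.chi2.sf(statistic, ddf))
            results.append(TestResult(kind="ld-screen", term=pair,
                                      statistic=float(statistic), df=ddf, p=p))
    _apply_bh(results, alpha)
    return results


def screen_dif(model, scores, group_codes, alpha=0.05, items=None, m=None,
               confirm=True) -> list:
    """Screen all item-covariate combinations for uniform DIF.

    The primary statistic is the partial Goodman-Kruskal gamma between the
    item and the covariate given rest-score strata (the partial association
    given the total score over the other items), with a normal-approximation
    p.  Combinations flagged after BH adjustment get a CLR confirmation test
    (declared model + that DIF term vs declared model); the final verdict
    requires both.
    """
    scores = _prepare_scores(scores)
    spec, mitems, base_ll, base_df = _model_pieces(model)
    if items is None:
        items = mitems
    if m is None:
        m = int(scores.max()) + 1
    results = []
    for cov, codes in group_codes.items():
        codes = np.asarray(codes, dtype=int)
        if len(np.unique(codes)) < 2:
            logger.warning("covariate %s is constant; DIF screen skipped", cov)
            continue
        for i, it in enumerate(items):
            if (it, cov) in spec.dif_terms:
                continue
            rest = scores.sum(axis=1) - scores[:, i]
            gam, se = partial_gamma(scores[:, i], codes, rest)
            if not np.isfinite(se) or se == 0:
                p, z = 1.0, 0.0
            else:
                z = gam / se
                p = float(2 * stats.norm.sf(abs(z)))
            results.append(TestResult(
                kind="dif-screen", term=(it, cov), statistic=float(abs(z)),
                df=1, p=p, extras={"partial_gamma": gam, "se": se}))
    _apply_bh(results, alpha)
    if confirm:
        base_known = np.isfinite(base_ll)
        base0 = model.base if isinstance(model, GLLRMParameters) else model
        for tr in results:
            if not tr.rejected:
                continue
            if not base_known:
                base_ll, base_df, refit = _fit_and_df(scores, spec, group_codes,
                                                      items, m)
                base0 = refit.base if isinstance(refit, GLLRMParameters) else refit
                base_known = True
            aug = spec.with_dif(*tr.term)
            ll, df, _ = _fit_and_df(scores, aug, group_codes, items, m,
                                    base0=base0)
            statistic = max(2.0 * (ll - base_ll), 0.0)
            ddf = max(df - base_df, 1)
            cp = float(stats.chi2.sf(statistic, ddf))
            tr.extras.update(clr=statistic, clr_df=ddf, clr_p=cp)
            if cp >= alpha:
                tr.rejected = False
    return results


def _apply_bh(results, alpha):
    if not results:
        return
    ps = np.array([tr.p for tr in results])
    rej, p_adj = bh_adjust(ps, alpha)
    for tr, r, pa in zip(results, rej, p_adj):
        tr.rejected = bool(r)
        tr.p_adjusted = float(pa)


def bh_adjust(pvalues, q=0.05):
    """Benjamini-Hochberg step-up adjustment.

    Returns ``(rejected, p_adjusted)``; rejections control the false
    discovery rate at level ``q`` within the family supplied.
    """
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((pvalues < 0) | (pvalues > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    rejected, p_adj, _, _ = multipletests(pvalues, alpha=q, method="fdr_bh")
    return rejected, p_adj


# ---------------------------------------------------------------------------
# Goodman-Kruskal gamma
# ---------------------------------------------------------------------------

def _concordance_tables(table: np.ndarray):
    """Per-cell concordant / discordant partner counts for a 2-way table."""
    R, C = table.shape
    cum = np.cumsum(np.cumsum(table, axis=0), axis=1)

    def boxsum(r0, r1, c0, c1):
        # inclusive box sums over [r0..r1] x [c0..c1]; empty -> 0
        if r0 > r1 or c0 > c1:
            return 0.0
        tot = cum[r1, c1]
        if r0 > 0:
            tot -= cum[r0 - 1, c1]
        if c0 > 0:
            tot -= cum[r1, c0 - 1]
        if r0 > 0 and c0 > 0:
            tot += cum[r0 - 1, c0 - 1]
        return tot

    A = np.zeros_like(table, dtype=float)
    D = np.zeros_like(table, dtype=float)
    for r in range(R):
        for c in range(C):
            A[r, c] = boxsum(0, r - 1, 0, c - 1) + boxsum(r + 1, R - 1, c + 1, C - 1)
            D[r, c] = boxsum(0, r - 1, c + 1, C - 1) + boxsum(r + 1, R - 1, 0, c - 1)
    return A, D


def goodman_kruskal_gamma(x, y) -> float:
    """Goodman-Kruskal rank correlation (C - D) / (C + D) for ordinal pairs."""
    table = _crosstab(x, y)
    A, D = _concordance_tables(table)
    C = float((table * A).sum()) / 2.0
    Dd = float((table * D).sum()) / 2.0
    if C + Dd == 0:
        return np.nan
    return (C - Dd) / (C + Dd)


def _crosstab(x, y):
    x = np.asarray(x)
    y = np.asarray(y)
    xv, xi = np.unique(x, return_inverse=True)
    yv, yi = np.unique(y, return_inverse=True)
    table = np.zeros((len(xv), len(yv)))
    np.add.at(table, (xi, yi), 1.0)
    return table


def partial_gamma(x, y, strata):
    """Partial Goodman-Kruskal gamma of (x, y) given strata, with its
    delta-method standard error (concordance pooled over strata)."""
    strata = np.asarray(strata)
    Cs, Ds = 0.0, 0.0
    cells = []  # (counts, A, D) per stratum
    for s in np.unique(strata):
        sel = strata == s
        if sel.sum() < 2:
            continue
        table = _crosstab(np.asarray(x)[sel], np.asarray(y)[sel])
        if table.shape[0] < 2 or table.shape[1] < 2:
            continue
        A, D = _concordance_tables(table)
        Cs += float((table * A).sum()) / 2.0
        Ds += float((table * D).sum()) / 2.0
        cells.append((table, A, D))
    tot = Cs + Ds
    if tot == 0:
        return np.nan, np.nan
    gam = (Cs - Ds) / tot
    # delta method: gamma = (C-D)/(C+D), dgamma/dn_sij = 2(D A_sij - C D_sij)
    # / (C+D)^2; multinomial variance within each stratum (its n fixed)
    # requires centering the per-cell terms stratum by stratum
    var = 0.0
    for table, A, D in cells:
        t = Ds * A - Cs * D
        ns = table.sum()
        s1 = float((table * t ** 2).sum())
        s2 = float((table * t).sum())
        var += s1 - s2 ** 2 / ns
    se = 2.0 * np.sqrt(max(var, 0.0)) / (tot ** 2)
    return gam, se


def item_rest_gamma(scores: np.ndarray, item: int) -> float:
    """Observed gamma between an item's score and the rest score."""
    scores = _prepare_scores(scores)
    rest = scores.sum(axis=1) - scores[:, item]
    if len(np.unique(scores[:, item])) < 2 or len(np.unique(rest)) < 2:
        raise DataError("gamma undefined: item or rest score is constant")
    g = goodman_kruskal_gamma(scores[:, item], rest)
    if np.isnan(g):
        raise DataError("gamma undefined: no concordant or discordant pairs")
    return g


# ---------------------------------------------------------------------------
# model-based simulation helpers
# ---------------------------------------------------------------------------

def _simulate_conditional(model, scores, B, rng, group_codes=None):
    """B replicate response matrices drawn from the fitted model conditional
    on each person's observed total score (and covariate stratum)."""
    totals = scores.sum(axis=1)
    n, k = scores.shape
    if isinstance(model, ItemParameters):
        big = sample_given_score(model, np.tile(totals, B), rng)
        return big.reshape(B, n, k)
    gp = model
    reps = gllrm_sample_given_score(gp, np.tile(totals, B),
                                    _tile_codes(group_codes, gp, n, B), rng)
    return reps.reshape(B, n, k)


def _tile_codes(group_codes, gp, n, B):
    out = {}
    for cov in gp.spec.dif_covariates:
        out[cov] = np.tile(np.asarray(group_codes[cov], dtype=int), B)
    return out


def gllrm_sample_given_score(gp: GLLRMParameters, totals, group_codes, rng):
    """Inverse-CDF sampling over enumerated patterns given (stratum, score)."""
    totals = np.asarray(totals, dtype=int)
    n = len(totals)
    spec = gp.spec
    group_sizes = {cov: len(gp.dif[t]) for t in spec.dif_terms
                   for cov in [t[1]]}
    space = _gllrm._PatternSpace(gp.base.levels, gp.base.items, spec, group_sizes)
    x = _gllrm._pack_parameters(gp, space)
    lp_base = space.base_lp(x)
    dif_codes = {c: np.asarray(v, dtype=int) for c, v in (group_codes or {}).items()
                 if c in spec.dif_covariates}
    stratum_of, strata = _gllrm._strata_from_groups(dif_codes, n)
    out = np.zeros((n, len(gp.base.items)), dtype=int)
    max_score = int(space.scores.max())
    order_by_score = np.argsort(space.scores, kind="stable")
    s_sorted = space.scores[order_by_score]
    bounds = np.searchsorted(s_sorted, np.arange(max_score + 2))
    for s_ix, stratum in enumerate(strata):
        sel = np.nonzero(stratum_of == s_ix)[0]
        if len(sel) == 0:
            continue
        lp = space.stratum_lp(x, lp_base, stratum)
        for r in np.unique(totals[sel]):
            rows = order_by_score[bounds[r]:bounds[r + 1]]
            if len(rows) == 0:
                raise ValueError(f"score {r} not achievable")
            w = lp[rows]
            w = np.exp(w - w.max())
            cum = np.cumsum(w)
            persons = sel[totals[sel] == r]
            u = rng.random(len(persons)) * cum[-1]
            pick = rows[np.searchsorted(cum, u)]
            out[persons] = space.patterns[pick]
    return out


def expected_gamma_and_p(model, scores, item: int, B: int = 1000,
                         rng=None, group_codes=None) -> dict:
    """Model-expected item-rest gamma and a Monte-Carlo p for the observed one.

    Replicate data sets are simulated from the fitted model conditional on
    the observed total-score distribution; the expected gamma is the
    replicate mean and the two-sided p the tail proportion.  The direction
    (observed below expected) is reported because an observed correlation
    much *weaker* than expected is the signature of an item driven by a
    different latent variable — the removal signal.
    """
    if B < 100:
        raise ValueError("B must be at least 100 for a usable Monte-Carlo p")
    if rng is None:
        rng = np.random.default_rng(0)
    scores = _prepare_scores(scores)
    obs = item_rest_gamma(scores, item)
    reps = _simulate_conditional(model, scores, B, rng, group_codes)
    sims = np.full(B, np.nan)
    for b in range(B):
        sb = reps[b]
        rest = sb.sum(axis=1) - sb[:, item]
        if len(np.unique(sb[:, item])) < 2 or len(np.unique(rest)) < 2:
            continue
        sims[b] = goodman_kruskal_gamma(sb[:, item], rest)
    sims = sims[np.isfinite(sims)]
    expected = float(np.mean(sims))
    dev = abs(obs - expected)
    p = float((1 + np.sum(np.abs(sims - expected) >= dev - 1e-12)) / (len(sims) + 1))
    return {
        "observed": float(obs), "expected": expected, "p": p,
        "direction": "below" if obs < expected else "above",
        "n_sims": int(len(sims)),
    }


def _conditional_moments(model, scores, group_codes=None):
    """Per-person conditional mean and variance of each item given the
    person's total score (and stratum)."""
    n, k = scores.shape
    totals = scores.sum(axis=1)
    E = np.zeros((n, k))
    V = np.zeros((n, k))
    if isinstance(model, ItemParameters):
        tables = conditional_probability_tables(model)
        for i in range(k):
            l = model.levels[i]
            probs = tables[i][totals]          # (n, n_levels)
            mu = probs @ l
            E[:, i] = mu
            V[:, i] = probs @ (l.astype(float) ** 2) - mu ** 2
        return E, V
    gp = model
    spec = gp.spec
    group_sizes = {cov: len(gp.dif[t]) for t in spec.dif_terms for cov in [t[1]]}
    space = _gllrm._PatternSpace(gp.base.levels, gp.base.items, spec, group_sizes)
    x = _gllrm._pack_parameters(gp, space)
    lp_base = space.base_lp(x)
    dif_codes = {c: np.asarray(v, dtype=int) for c, v in (group_codes or {}).items()
                 if c in spec.dif_covariates}
    stratum_of, strata = _gllrm._strata_from_groups(dif_codes, n)
    max_score = int(space.scores.max())
    for s_ix, stratum in enumerate(strata):
        sel = np.nonzero(stratum_of == s_ix)[0]
        if len(sel) == 0:
            continue
        lp = space.stratum_lp(x, lp_base, stratum)
        for r in np.unique(totals[sel]):
            rows = space.scores == r
            w = lp[rows]
            w = np.exp(w - w.max())
            w /= w.sum()
            pats = space.patterns[rows].astype(float)
            mu = w @ pats
            mu2 = w @ (pats ** 2)
            persons = sel[totals[sel] == r]
            E[persons] = mu
            V[persons] = mu2 - mu ** 2
    return E, V


def conditional_fit_residuals(model, scores, group_codes=None, B: int = 400,
                              rng=None) -> list:
    """Conditional infit and outfit per item, with simulation p-values.

    Residuals are standardized against the conditional-on-score moments, so
    person parameters never enter.  Outfit is the unweighted mean squared
    standardized residual; infit the information-weighted mean square.
    Null p-values come from parametric simulation under the fitted model
    conditional on the observed score distribution.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    scores = _prepare_scores(scores)
    n, k = scores.shape

    def stats_for(mat, E, V):
        infit = np.full(k, np.nan)
        outfit = np.full(k, np.nan)
        skipped = 0
        for i in range(k):
            v = V[:, i]
            ok = v > 1e-12
            skipped += int((~ok).sum())
            if ok.sum() == 0:
                continue
            e2 = (mat[ok, i] - E[ok, i]) ** 2
            outfit[i] = float(np.mean(e2 / v[ok]))
            infit[i] = float(np.sum(e2) / np.sum(v[ok]))
        return infit, outfit, skipped

    E, V = _conditional_moments(model, scores, group_codes)
    infit, outfit, skipped = stats_for(scores, E, V)
    reps = _simulate_conditional(model, scores, B, rng, group_codes)
    null_in = np.zeros((B, k))
    null_out = np.zeros((B, k))
    for b in range(B):
        ni, no, _ = stats_for(reps[b], E, V)
        null_in[b] = ni
        null_out[b] = no
    records = []
    unreliable = n < 30
    for i in range(k):
        def mc_p(null_col, val):
            col = null_col[np.isfinite(null_col)]
            if len(col) == 0 or not np.isfinite(val):
                return np.nan
            center = np.median(col)
            return float((1 + np.sum(np.abs(col - center) >= abs(val - center)))
                         / (len(col) + 1))
        records.append({
            "item": (model.items[i] if hasattr(model, "items") else f"I{i+1}"),
            "infit": infit[i], "outfit": outfit[i],
            "infit_p": mc_p(null_in[:, i], infit[i]),
            "outfit_p": mc_p(null_out[:, i], outfit[i]),
            "skipped_terms": skipped,
            "p_unreliable": unreliable,
        })
    return records
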
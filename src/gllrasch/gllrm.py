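"""Graphical log-linear Rasch models (GLLRM).

A GLLRM keeps the partial-credit Rasch kernel but adds log-linear
interaction terms for (a) declared pairs of locally dependent items and
(b) uniform DIF: group-specific shifts of an item's thresholds for the
groups of a discretized person covariate.  Within every covariate stratum
the total score remains sufficient, so estimation and testing can still be
carried out conditionally on (stratum, score) without assumptions on the
latent distribution.

Estimation maximizes the conditional likelihood of the observed response
patterns given each person's stratum and total score, over an exhaustive
enumeration of the pattern space (feasible at questionnaire scale,
``m**k <= 5**8``).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .rasch import (
    ConvergenceError,
    DataError,
    ItemParameters,
    fit_cml,
    _prepare_scores,
)

logger = logging.getLogger(__name__)

__all__ = ["GLLRMSpec", "GLLRMParameters", "fit_gllrm", "conditional_pattern_prob",
           "model_search", "SearchStep"]

_PARAM_BOUND = 8.0  # |lambda|, |delta| cap; hitting it flags separation


@dataclass(frozen=True)
class GLLRMSpec:
    """Declared structure of a GLLRM.

    Parameters
    ----------
    ld_pairs : tuple of (item, item)
        Unordered item-name pairs declared locally dependent.
    dif_terms : tuple of (item, covariate)
        Item-name / covariate-name pairs declared to show uniform DIF.
    interaction : {"linear", "full"}
        Local-dependence interaction form: a single linear-by-linear
        parameter ``delta * x_i * x_j`` (default; one df per pair, stable at
        small n) or a full category-by-category table with corner
        constraints.
    """

    ld_pairs: tuple = ()
    dif_terms: tuple = ()
    interaction: str = "linear"

    def __post_init__(self):
        object.__setattr__(self, "ld_pairs",
                           tuple(tuple(sorted(p)) for p in self.ld_pairs))
        object.__setattr__(self, "dif_terms", tuple(tuple(t) for t in self.dif_terms))
        for a, b in self.ld_pairs:
            if a == b:
                raise ValueError(f"item {a!r} paired with itself")
        if self.interaction not in ("linear", "full"):
            raise ValueError("interaction must be 'linear' or 'full'")

    def validate(self, items, covariates):
        items = set(items)
        for a, b in self.ld_pairs:
            if a not in items or b not in items:
                raise ValueError(f"LD pair ({a}, {b}) references unknown items")
        for it, cov in self.dif_terms:
            if it not in items:
                raise ValueError(f"DIF term references unknown item {it!r}")
            if cov not in covariates:
                raise ValueError(f"DIF term references unknown covariate {cov!r}")

    @property
    def dif_covariates(self):
        return tuple(dict.fromkeys(cov for _, cov in self.dif_terms))

    def with_ld(self, pair):
        return dataclasses.replace(self, ld_pairs=self.ld_pairs + (tuple(sorted(pair)),))

    def with_dif(self, item, covariate):
        return dataclasses.replace(self, dif_terms=self.dif_terms + ((item, covariate),))

    @property
    def is_empty(self):
        return not self.ld_pairs and not self.dif_terms


@dataclass
class GLLRMParameters:
    """Fitted GLLRM: base item parameters plus interaction terms.

    ``ld`` maps each declared pair to its interaction parameter (a scalar
    for the linear-by-linear form, a corner-constrained table otherwise).
    ``dif`` maps each (item, covariate) term to the vector of threshold
    shifts per covariate group; group 0 is the reference and fixed at 0.
    A positive shift makes the item harder for that group (lower expected
    item score at equal latent level).
    """

    spec: GLLRMSpec
    base: ItemParameters
    ld: dict
    dif: dict
    group_levels: dict  # covariate -> group labels, index = group code
    loglik: float = np.nan
    df: int = 0
    converged: bool = True
    separation_flags: tuple = ()
    n_persons: int = 0

    @property
    def items(self):
        return self.base.items


# ---------------------------------------------------------------------------
# pattern-space machinery
# ---------------------------------------------------------------------------

class _PatternSpace:
    """Enumerated pattern table with the model's feature columns."""

    def __init__(self, params_levels, items, spec: GLLRMSpec, group_sizes: dict):
        self.items = list(items)
        self.levels = [np.asarray(l) for l in params_levels]
        k = len(self.levels)
        if int(np.prod([len(l) for l in self.levels])) > 400_000:
            raise DataError("pattern space too large to enumerate (k*m limit)")
        grids = np.meshgrid(*self.levels, indexing="ij")
        self.patterns = np.stack([g.ravel() for g in grids], axis=1)  # (npat, k)
        self.scores = self.patterns.sum(axis=1)
        self.spec = spec
        self.group_sizes = group_sizes  # covariate -> number of groups

        # feature bookkeeping: slices into the packed parameter vector
        self.eta_slices = []
        pos = 0
        for l in self.levels:
            self.eta_slices.append(slice(pos, pos + len(l) - 1))
            pos += len(l) - 1
        # position of each pattern's category within its item's level list
        self.level_pos = np.empty_like(self.patterns)
        for i, l in enumerate(self.levels):
            lut = np.zeros(int(l[-1]) + 1, dtype=int)
            for c, v in enumerate(l):
                lut[int(v)] = c
            self.level_pos[:, i] = lut[self.patterns[:, i]]
        self.ld_slices = {}
        self.ld_feats = {}
        item_ix = {name: i for i, name in enumerate(self.items)}
        for pair in spec.ld_pairs:
            i, j = item_ix[pair[0]], item_ix[pair[1]]
            if spec.interaction == "linear":
                self.ld_feats[pair] = (self.patterns[:, i] * self.patterns[:, j]
                                       ).astype(float)[:, None]
                width = 1
            else:
                li, lj = self.levels[i], self.levels[j]
                cols = []
                for a in li[1:]:
                    for b in lj[1:]:
                        cols.append(((self.patterns[:, i] == a)
                                     & (self.patterns[:, j] == b)).astype(float))
                self.ld_feats[pair] = np.stack(cols, axis=1)
                width = (len(li) - 1) * (len(lj) - 1)
            self.ld_slices[pair] = slice(pos, pos + width)
            pos += width
        self.dif_slices = {}
        self.dif_item_col = {}
        for term in spec.dif_terms:
            it, cov = term
            g = group_sizes[cov]
            self.dif_slices[term] = slice(pos, pos + g - 1)
            self.dif_item_col[term] = item_ix[it]
            pos += g - 1
        self.n_params = pos
        self.n_eta = sum(len(l) - 1 for l in self.levels)
        # score-sorted pattern order for fast per-score normalizers
        self.max_score = int(self.scores.max())
        self.score_order = np.argsort(self.scores, kind="stable")
        s_sorted = self.scores[self.score_order]
        self.score_bounds = np.searchsorted(s_sorted, np.arange(self.max_score + 2))

    def base_lp(self, x):
        """Linear predictor from eta and LD terms (stratum independent)."""
        lp = np.zeros(len(self.patterns))
        for i, sl in enumerate(self.eta_slices):
            e = np.concatenate([[0.0], x[sl]])
            lp += e[self.level_pos[:, i]]
        for pair, sl in self.ld_slices.items():
            v = x[sl]
            if v.size == 1:
                lp += v[0] * self.ld_feats[pair][:, 0]
            else:
                lp += self.ld_feats[pair] @ v
        return lp

    def eta_expected(self, w):
        """Per-parameter expected eta sufficient statistics under weights w."""
        out = np.empty(sum(len(l) - 1 for l in self.levels))
        pos = 0
        for i, l in enumerate(self.levels):
            b = np.bincount(self.level_pos[:, i], weights=w, minlength=len(l))
            out[pos:pos + len(l) - 1] = b[1:]
            pos += len(l) - 1
        return out

    def stratum_lp(self, x, lp_base, stratum):
        """Add DIF contributions for a stratum (dict covariate -> group)."""
        lp = lp_base
        for term, sl in self.dif_slices.items():
            it, cov = term
            g = stratum[cov]
            if g > 0:
                delta = x[sl][g - 1]
                lp = lp - delta * self.patterns[:, self.dif_item_col[term]]
        return lp

    def dif_feature(self, term, stratum):
        """Gradient column of a DIF parameter in a stratum (0 if inactive)."""
        it, cov = term
        return -self.patterns[:, self.dif_item_col[term]].astype(float)


def _log_norm_by_score(lp, space: "_PatternSpace"):
    """logsumexp of lp within each score slice; -inf for empty scores."""
    lp_sorted = lp[space.score_order]
    starts = space.score_bounds[:-1]
    nonempty = space.score_bounds[1:] > starts
    out = np.full(space.max_score + 1, -np.inf)
    if not nonempty.all():
        idx = np.minimum(starts, len(lp_sorted) - 1)
        mx = np.maximum.reduceat(lp_sorted, idx)
        sums = np.add.reduceat(np.exp(lp_sorted - np.repeat(
            mx, np.diff(space.score_bounds))), idx)
        out[nonempty] = (mx + np.log(sums))[nonempty]
        return out
    mx = np.maximum.reduceat(lp_sorted, starts)
    seg_max = np.repeat(mx, np.diff(space.score_bounds))
    sums = np.add.reduceat(np.exp(lp_sorted - seg_max), starts)
    out[:] = mx + np.log(sums)
    return out


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _strata_from_groups(group_codes: dict, n: int):
    """Map persons to stratum ids; a stratum is a combination of DIF-covariate
    groups.  Returns (stratum_of_person, list of stratum dicts)."""
    if not group_codes:
        return np.zeros(n, dtype=int), [dict()]
    covs = list(group_codes)
    combos = {}
    stratum_of = np.zeros(n, dtype=int)
    strata = []
    codes = np.stack([np.asarray(group_codes[c]) for c in covs], axis=1)
    for v in range(n):
        key = tuple(int(x) for x in codes[v])
        if key not in combos:
            combos[key] = len(strata)
            strata.append(dict(zip(covs, key)))
        stratum_of[v] = combos[key]
    return stratum_of, strata


def fit_gllrm(
    scores: np.ndarray,
    spec: GLLRMSpec,
    group_codes: dict | None = None,
    items=None,
    m: int | None = None,
    group_levels: dict | None = None,
    gtol: float = 1e-5,
    base0: ItemParameters | None = None,
) -> GLLRMParameters:
    """Fit a GLLRM by maximizing the (stratum, score)-conditional likelihood.

    Parameters
    ----------
    scores : array (n, k)
        Complete-case coded responses.
    spec : GLLRMSpec
        Declared LD pairs and DIF terms.
    group_codes : dict, optional
        Covariate name -> integer group code per person (0 = reference).
        Required when ``spec`` has DIF terms.
    """
    scores = _prepare_scores(scores)
    n, k = scores.shape
    if items is None:
        items = [f"I{i + 1}" for i in range(k)]
    if m is None:
        m = int(scores.max()) + 1
    group_codes = dict(group_codes or {})
    spec.validate(items, group_codes.keys())

    # reuse the CML category bookkeeping: drop unobserved categories
    if base0 is None:
        base0 = fit_cml(scores, items=items, m=m, gtol=max(gtol, 1e-6))
    levels = base0.levels
    # remap raw scores onto level indices (identity for contiguous levels)
    item_ix = {name: i for i, name in enumerate(items)}

    dif_codes = {cov: np.asarray(group_codes[cov], dtype=int)
                 for cov in spec.dif_covariates}
    for cov, codes in dif_codes.items():
        if len(codes) != n:
            raise DataError(f"group codes for {cov!r} have wrong length")
    group_sizes = {cov: int(codes.max()) + 1 for cov, codes in dif_codes.items()}
    for cov, g in group_sizes.items():
        counts = np.bincount(dif_codes[cov], minlength=g)
        if np.any(counts == 0):
            logger.warning("covariate %s: empty groups %s dropped from DIF df",
                           cov, np.nonzero(counts == 0)[0].tolist())

    space = _PatternSpace(levels, items, spec, group_sizes)
    stratum_of, strata = _strata_from_groups(dif_codes, n)
    total = scores.sum(axis=1)
    max_score = int(space.scores.max())

    # observed sufficient statistics per stratum
    pat_index = {}
    # map each person's pattern to its enumeration row for observed stats
    mult = np.ones(k, dtype=int)
    # build a mixed-radix index over level positions
    pos_of_level = [
        {int(v): c for c, v in enumerate(l)} for l in levels
    ]
    radii = [len(l) for l in levels]
    strides = np.ones(k, dtype=np.int64)
    for i in range(k - 2, -1, -1):
        strides[i] = strides[i + 1] * radii[i + 1]
    person_rows = np.zeros(n, dtype=np.int64)
    for i in range(k):
        col = scores[:, i]
        lut = np.full(int(levels[i][-1]) + 1, -1, dtype=np.int64)
        for c, v in enumerate(levels[i]):
            lut[int(v)] = c
        person_rows += lut[col] * strides[i]

    obs_feat = np.zeros(space.n_params)
    neta = space.n_eta
    score_counts = []  # per stratum: counts over scores
    for s_ix, stratum in enumerate(strata):
        sel = stratum_of == s_ix
        rows = person_rows[sel]
        if neta:
            w_rows = np.bincount(rows, minlength=len(space.patterns)).astype(float)
            obs_feat[:neta] += space.eta_expected(w_rows)
        for pair, sl in space.ld_slices.items():
            obs_feat[sl] += space.ld_feats[pair][rows].sum(axis=0)
        for term, sl in space.dif_slices.items():
            it, cov = term
            g = stratum[cov]
            if g > 0:
                obs_feat[sl.start + g - 1] += -scores[sel, space.dif_item_col[term]].sum()
        score_counts.append(np.bincount(total[sel], minlength=max_score + 1).astype(float))

    def negloglik(x):
        lp_base = space.base_lp(x)
        ll = float(np.dot(obs_feat, x))
        grad = obs_feat.copy()
        for s_ix, stratum in enumerate(strata):
            sc = score_counts[s_ix]
            if sc.sum() == 0:
                continue
            lp = space.stratum_lp(x, lp_base, stratum)
            log_norm = _log_norm_by_score(lp, space)
            r_obs = np.nonzero(sc)[0]
            ll -= float(np.dot(sc[r_obs], log_norm[r_obs]))
            # conditional pattern weights: q(pattern) * n_{stratum, score}
            w = np.exp(lp - log_norm[space.scores]) * sc[space.scores]
            if neta:
                grad[:neta] -= space.eta_expected(w)
            for pair, sl in space.ld_slices.items():
                feats = space.ld_feats[pair]
                if feats.shape[1] == 1:
                    grad[sl.start] -= float(feats[:, 0] @ w)
                else:
                    grad[sl] -= feats.T @ w
            for term, sl in space.dif_slices.items():
                it, cov = term
                g = stratum[cov]
                if g > 0:
                    col = -space.patterns[:, space.dif_item_col[term]].astype(float)
                    grad[sl.start + g - 1] -= float(col @ w)
        return -ll, -grad

    x0 = np.zeros(space.n_params)
    # warm start the eta block at the plain CML solution
    pos = 0
    for i, l in enumerate(levels):
        x0[pos:pos + len(l) - 1] = base0.eta[i][1:]
        pos += len(l) - 1

    # remove the flat scale-origin direction from the eta block (adding
    # c*level to every eta adds c*score to each pattern, cancelling in the
    # score-conditional probabilities), keeping the interaction parameters
    # as raw bounded coordinates
    from .rasch import _nullspace_basis
    flat_eta = np.concatenate([(l[1:] - l[0]).astype(float) for l in levels]) \
        if neta else np.zeros(0)
    eta_basis = _nullspace_basis(flat_eta) if neta else np.zeros((0, 0))
    n_int = space.n_params - neta

    def to_full(zx):
        full = np.empty(space.n_params)
        full[:neta] = eta_basis @ zx[:eta_basis.shape[1]]
        full[neta:] = zx[eta_basis.shape[1]:]
        return full

    def obj(zx):
        f, g = negloglik(to_full(zx))
        gz = np.concatenate([eta_basis.T @ g[:neta], g[neta:]])
        return f, gz

    z0 = np.concatenate([eta_basis.T @ x0[:neta], x0[neta:]])
    bounds = ([(None, None)] * eta_basis.shape[1]
              + [(-_PARAM_BOUND, _PARAM_BOUND)] * n_int)
    zres = optimize.minimize(obj, z0, jac=True, method="L-BFGS-B",
                             bounds=bounds,
                             options={"maxiter": 1000, "ftol": 1e-14,
                                      "gtol": gtol * 1e-2})
    z = zres.x
    at_bound = np.abs(z[eta_basis.shape[1]:]) >= _PARAM_BOUND - 1e-6
    if not at_bound.any():
        from .rasch import _newton_polish
        z, _ = _newton_polish(obj, z, gtol * 1e-1)
    res = zres
    res.x = to_full(z)
    res.fun, _ = obj(z)
    _, res.jac = negloglik(res.x)
    gnorm = float(np.max(np.abs(res.jac))) if space.n_params else 0.0
    flags = []
    for pair, sl in space.ld_slices.items():
        if np.any(np.abs(res.x[sl]) >= _PARAM_BOUND - 1e-6):
            flags.append(("ld", pair))
    for term, sl in space.dif_slices.items():
        if np.any(np.abs(res.x[sl]) >= _PARAM_BOUND - 1e-6):
            flags.append(("dif", term))
    if gnorm > gtol and not flags:
        raise ConvergenceError(f"GLLRM gradient norm {gnorm:.2e} above tolerance")

    eta = []
    pos = 0
    for l in levels:
        e = np.zeros(len(l))
        e[1:] = res.x[pos:pos + len(l) - 1]
        pos += len(l) - 1
        eta.append(e)
    base = ItemParameters(items=list(items), levels=levels, eta=eta,
                          loglik=np.nan, n_persons=n).centered()
    ld = {pair: (float(res.x[sl][0]) if spec.interaction == "linear"
                 else res.x[sl].copy())
          for pair, sl in space.ld_slices.items()}
    dif = {}
    for term, sl in space.dif_slices.items():
        it, cov = term
        vec = np.zeros(group_sizes[cov])
        vec[1:] = res.x[sl]
        dif[term] = vec
    # df: structurally estimable parameters (empty groups do not count)
    df = base.n_free_parameters
    for pair in spec.ld_pairs:
        df += 1 if spec.interaction == "linear" else \
            (len(levels[item_ix[pair[0]]]) - 1) * (len(levels[item_ix[pair[1]]]) - 1)
    for term in spec.dif_terms:
        _, cov = term
        occupied = int((np.bincount(dif_codes[cov], minlength=group_sizes[cov]) > 0).sum())
        df += max(occupied - 1, 0)
    glv = dict(group_levels or {})
    params = GLLRMParameters(
        spec=spec, base=base, ld=ld, dif=dif, group_levels=glv,
        loglik=-float(res.fun), df=df, converged=gnorm <= gtol or bool(flags),
        separation_flags=tuple(flags), n_persons=n,
    )
    logger.info("GLLRM fit: loglik=%.4f df=%d |grad|=%.2e flags=%s",
                params.loglik, df, gnorm, flags)
    return params


def conditional_pattern_prob(gp: GLLRMParameters, stratum: dict, r: int):
    """Distribution over response patterns with total score ``r`` in a stratum.

    Returns ``(patterns, probs)``; reduces to the plain Rasch conditional
    distribution when all interaction parameters are zero.
    """
    spec = gp.spec
    group_sizes = {cov: len(vec) for (it, cov), vec in
                   {t: gp.dif[t] for t in spec.dif_terms}.items()}
    space = _PatternSpace(gp.base.levels, gp.base.items, spec, group_sizes)
    x = _pack_parameters(gp, space)
    lp = space.stratum_lp(x, space.base_lp(x), stratum)
    sel = space.scores == r
    if not np.any(sel):
        raise ValueError(f"score {r} not achievable")
    lps = lp[sel]
    lps = lps - lps.max()
    p = np.exp(lps)
    p /= p.sum()
    return space.patterns[sel], p


def _pack_parameters(gp: GLLRMParameters, space: "_PatternSpace") -> np.ndarray:
    x = np.zeros(space.n_params)
    pos = 0
    for i, l in enumerate(gp.base.levels):
        x[pos:pos + len(l) - 1] = gp.base.eta[i][1:]
        pos += len(l) - 1
    for pair, sl in space.ld_slices.items():
        v = gp.ld[pair]
        x[sl] = v if np.ndim(v) else [v]
    for term, sl in space.dif_slices.items():
        x[sl] = gp.dif[term][1:]
    return x


# ---------------------------------------------------------------------------
# model search
# ---------------------------------------------------------------------------

@dataclass
class SearchStep:
    step: int
    action: str            # "add_ld" / "add_dif" / "stop"
    term: object
    p_adjusted: float
    loglik: float


def model_search(scores, group_codes, items=None, m=None, alpha=0.05,
                 max_terms=6, interaction="linear", seed=0,
                 gamma_B=400, flag_weak_items=True):
    """Iterative GLLRM structure search.

    Fits the pure Rasch model, screens all item pairs for local dependence
    and all item-covariate combinations for DIF (Benjamini-Hochberg adjusted
    within each screen), adds the single most significant adjusted-significant
    term, refits, and repeats until nothing is adjusted-significant or the
    term cap is reached.  Items whose observed item-rest correlation is
    significantly *below* its model-expected value are flagged as removal
    candidates but never removed automatically.

    Returns ``(final_spec, final_fit, trail, weak_items)``.
    """
    from . import diagnostics  # local import to avoid a cycle

    scores = _prepare_scores(scores)
    n, k = scores.shape
    if items is None:
        items = [f"I{i + 1}" for i in range(k)]
    spec = GLLRMSpec(interaction=interaction)
    trail = []
    fit = fit_gllrm(scores, spec, group_codes, items=items, m=m)
    base_fit = fit
    for step in range(max_terms):
        # one joint BH family over every candidate term: adding a term is a
        # single selection decision across LD pairs and DIF combinations
        ld_results = diagnostics.screen_local_dependence(
            fit, scores, group_codes, alpha=alpha)
        dif_results = diagnostics.screen_dif(
            fit, scores, group_codes, alpha=alpha, confirm=False)
        pool = ([("add_ld", tr) for tr in ld_results]
                + [("add_dif", tr) for tr in dif_results])
        if not pool:
            trail.append(SearchStep(step, "stop", None, np.nan, fit.loglik))
            break
        rejected, p_adj = diagnostics.bh_adjust([tr.p for _, tr in pool], alpha)
        candidates = []
        for (action, tr), rej, pa in zip(pool, rejected, p_adj):
            if not rej:
                continue
            if action == "add_dif":
                # CLR confirmation before a DIF term may enter the model
                aug = fit.spec.with_dif(*tr.term)
                ll, df, _ = diagnostics._fit_and_df(
                    scores, aug, group_codes, items, m, base0=fit.base)
                from scipy import stats as _st
                clr = max(2.0 * (ll - fit.loglik), 0.0)
                ddf = max(df - fit.df, 1)
                if float(_st.chi2.sf(clr, ddf)) >= alpha:
                    continue
            candidates.append((action, tr, pa))
        if not candidates:
            trail.append(SearchStep(step, "stop", None, np.nan, fit.loglik))
            break
        action, best, pa = min(candidates, key=lambda c: (c[2], c[1].p))
        spec = (fit.spec.with_ld(best.term) if action == "add_ld"
                else fit.spec.with_dif(*best.term))
        fit = fit_gllrm(scores, spec, group_codes, items=items, m=m)
        trail.append(SearchStep(step, action, best.term, pa, fit.loglik))
    # Removal candidates are judged against the *base* Rasch fit: an item
    # driven by a different latent variable shows an item-rest correlation
    # far below its Rasch expectation, a signal the augmented model's
    # interaction terms would otherwise absorb.
    weak = []
    if flag_weak_items:
        rng = np.random.default_rng(seed)
        recs = [diagnostics.expected_gamma_and_p(base_fit.base, scores, i,
                                                 B=gamma_B, rng=rng)
                for i in range(len(items))]
        rejected, _ = diagnostics.bh_adjust([r["p"] for r in recs], alpha)
        weak = [name for name, rec, rej in zip(items, recs, rejected)
                if rej and rec["direction"] == "below"]
    return fit.spec, fit, trail, weak
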
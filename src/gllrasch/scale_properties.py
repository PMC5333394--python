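"""Between-scale dimensionality, reliability and targeting.

Reliability is the ratio of true-score to observed-score variance.  Two
estimates are reported: Cronbach's alpha (a lower bound under local
independence, an *over*-estimate when items are positively locally
dependent) and a Monte-Carlo estimate in the style of Hamon & Mesbah:
assume a normal latent distribution, estimate its mean and variance by
marginal maximum likelihood from the observed total-score distribution,
then simulate a large synthetic cohort with two independent response sets
per person and take the correlation of the two total scores.  Because DIF
and score distributions differ between covariate groups, reliability is
computed separately per group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import logsumexp

from .gllrm import GLLRMParameters, _PatternSpace, _pack_parameters
from .rasch import (
    ItemParameters,
    estimate_person,
    fit_cml,
    log_esf,
    sample_given_score,
    sample_given_theta,
    score_distribution_given_theta,
    test_information,
    _prepare_scores,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DimensionalityResult", "ReliabilityReport", "TargetingReport",
    "test_unidimensionality", "cronbach_alpha", "estimate_latent_normal",
    "mc_reliability", "targeting_report",
]


@dataclass
class DimensionalityResult:
    """Observed vs expected-under-one-latent correlation of two subscales."""

    scales: tuple
    observed: float
    expected: float
    p: float            # one-sided, observed below expected
    n_sims: int

    @property
    def rejected(self) -> bool:
        """True when one latent variable is insufficient to explain the
        correlation between the subscales."""
        return self.p < 0.05


@dataclass
class ReliabilityReport:
    alpha: float
    reliability_by_group: dict      # group label -> reliability
    sem_by_group: dict              # group label -> SEM (score units)
    latent_by_group: dict           # group label -> (mu, sigma2)
    test_retest: float = np.nan
    n_simulated: int = 0

    @property
    def reliability_range(self):
        vals = [v for v in self.reliability_by_group.values() if np.isfinite(v)]
        return (min(vals), max(vals)) if vals else (np.nan, np.nan)


@dataclass
class TargetingReport:
    thresholds: np.ndarray          # all item-threshold locations (logits)
    person_theta: np.ndarray        # latent estimates of the scored persons
    info_fraction_by_group: dict    # mean info at person locations / max info
    mean_bias_by_group: dict
    mean_se_by_group: dict
    max_information: float
    theta_at_max: float


# ---------------------------------------------------------------------------
# unidimensionality
# ---------------------------------------------------------------------------

def test_unidimensionality(scores_a, scores_b, names=("A", "B"),
                           B: int = 400, rng=None) -> DimensionalityResult:
    """Test whether two subscales can share one latent variable.

    A single partial-credit model is fitted to the pooled items; replicate
    subscale-score pairs are then simulated conditional on each person's
    observed pooled total.  The expected correlation is the replicate mean;
    an observed correlation significantly *below* it means one latent
    variable cannot account for the data (the subscales measure different,
    though correlated, constructs).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    a = _prepare_scores(scores_a)
    b = _prepare_scores(scores_b)
    if a.shape[0] != b.shape[0]:
        raise ValueError("subscales must be scored on the same persons")
    joint = np.hstack([a, b])
    params = fit_cml(joint)
    ka = a.shape[1]
    obs = _pearson(a.sum(axis=1), b.sum(axis=1))
    totals = joint.sum(axis=1)
    n = len(totals)
    sims = np.empty(B)
    reps = sample_given_score(params, np.tile(totals, B), rng).reshape(B, n, -1)
    for i in range(B):
        sims[i] = _pearson(reps[i, :, :ka].sum(axis=1), reps[i, :, ka:].sum(axis=1))
    sims = sims[np.isfinite(sims)]
    expected = float(np.mean(sims))
    p = float((1 + np.sum(sims <= obs)) / (len(sims) + 1))
    return DimensionalityResult(scales=tuple(names), observed=float(obs),
                                expected=expected, p=p, n_sims=len(sims))


def _pearson(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 or y.std() == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


# ---------------------------------------------------------------------------
# reliability
# ---------------------------------------------------------------------------

def cronbach_alpha(scores) -> float:
    """Cronbach's alpha, k/(k-1) (1 - sum of item variances / score variance)."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2:
        raise ValueError("scores must be persons x items")
    if np.any(~np.isfinite(scores)):
        raise ValueError("missing responses present; filter to complete cases")
    n, k = scores.shape
    if k < 2:
        raise ValueError("alpha needs at least two items")
    var_total = scores.sum(axis=1).var(ddof=1)
    if var_total == 0:
        raise ValueError("total-score variance is zero; alpha undefined")
    var_items = scores.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1 - var_items / var_total))


def estimate_latent_normal(params: ItemParameters, totals, n_nodes: int = 61,
                           sigma_floor: float = 1e-3):
    """Normal latent mean and variance by marginal ML on the total scores.

    Maximizes ``sum_r n_r log integral P(R=r | theta) phi(theta; mu, sigma^2)``
    with Gauss-Hermite quadrature.
    """
    totals = np.asarray(totals, dtype=int)
    counts = np.bincount(totals, minlength=params.max_score + 1).astype(float)
    lg = log_esf(params.levels, params.eta)
    r_all = np.arange(len(lg))
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    logw = np.log(weights) - 0.5 * np.log(2 * np.pi)
    r_obs = np.nonzero(counts)[0]

    def neg(pars):
        mu, logsig = pars
        sig = np.exp(logsig)
        theta = mu + sig * nodes
        # log P(R=r | theta_q): lg[r] + r*theta - log K(theta)
        logits = lg[None, :] + np.outer(theta, r_all)
        norm = logsumexp(logits, axis=1, b=np.isfinite(lg)[None, :].astype(float))
        ll = 0.0
        for r in r_obs:
            lr = logsumexp(logw + logits[:, r] - norm)
            ll += counts[r] * lr
        return -ll

    best = None
    t0_mu = float(np.mean([estimate_person(params, int(r)).theta
                           for r in np.unique(totals)]))
    for s0 in (0.0, 1.0):
        res = optimize.minimize(neg, np.array([t0_mu, s0]), method="Nelder-Mead",
                                options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    mu = float(best.x[0])
    sigma = max(float(np.exp(best.x[1])), sigma_floor)
    if sigma <= sigma_floor * 1.001:
        logger.warning("latent variance hit the floor; score distribution nearly degenerate")
    return mu, sigma ** 2


def _sample_theta_model(model, thetas, stratum, rng):
    """Responses at latent values under a Rasch or GLLRM (one stratum).

    For a GLLRM the total score is drawn first from P(R | theta) — the
    per-score normalizers absorb the interaction terms — and a pattern is
    then drawn from the theta-free conditional distribution given the score.
    """
    if isinstance(model, ItemParameters):
        return sample_given_theta(model, thetas, rng)
    gp: GLLRMParameters = model
    from .gllrm import _log_norm_by_score
    spec = gp.spec
    group_sizes = {cov: len(gp.dif[t]) for t in spec.dif_terms for cov in [t[1]]}
    space = _PatternSpace(gp.base.levels, gp.base.items, spec, group_sizes)
    x = _pack_parameters(gp, space)
    lp = space.stratum_lp(x, space.base_lp(x), stratum or {})
    logG = _log_norm_by_score(lp, space)
    scores = np.arange(len(logG), dtype=float)
    ok = np.isfinite(logG)
    logits = logG[None, ok] + thetas[:, None] * scores[None, ok]
    logits -= logits.max(axis=1, keepdims=True)
    p = np.exp(logits)
    cum = np.cumsum(p, axis=1)
    u = rng.random(len(thetas)) * cum[:, -1]
    r_ix = (u[:, None] >= cum).sum(axis=1)
    totals = scores[ok][r_ix].astype(int)

    # pattern given score: inverse CDF over the score's pattern slice
    out = np.zeros((len(thetas), len(gp.base.items)), dtype=int)
    order = space.score_order
    bounds = space.score_bounds
    for r in np.unique(totals):
        rows = order[bounds[r]:bounds[r + 1]]
        w = lp[rows]
        w = np.exp(w - w.max())
        cw = np.cumsum(w)
        sel = np.nonzero(totals == r)[0]
        uu = rng.random(len(sel)) * cw[-1]
        out[sel] = space.patterns[rows[np.searchsorted(cw, uu)]]
    return out


def mc_reliability(model, latent_by_group: dict, N: int = 10_000,
                   rng=None) -> ReliabilityReport:
    """Monte-Carlo reliability per covariate group.

    ``latent_by_group`` maps a group label to ``(mu, sigma2)`` or
    ``(mu, sigma2, stratum)`` where ``stratum`` is the covariate-group dict
    selecting the group's DIF offsets (empty for the reference group or for
    plain Rasch models).  For each group, ``N`` latent values are drawn from
    ``N(mu, sigma2)``; each simulated person answers the items twice,
    independently given their latent value (no recollection of the first
    response); reliability is the correlation of the two total scores and
    ``SEM = sd(score) * sqrt(1 - reliability)``.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if N < 1000:
        raise ValueError("N must be at least 1000")
    rel, sem, lat = {}, {}, {}
    for label, entry in latent_by_group.items():
        if len(entry) == 2:
            mu, s2 = entry
            stratum = {}
        else:
            mu, s2, stratum = entry
        thetas = rng.normal(mu, np.sqrt(max(s2, 0.0)), size=N)
        t1 = _sample_theta_model(model, thetas, stratum, rng).sum(axis=1)
        t2 = _sample_theta_model(model, thetas, stratum, rng).sum(axis=1)
        sd = t1.std(ddof=1)
        if sd == 0 or t2.std(ddof=1) == 0:
            r = 0.0
        else:
            r = float(np.corrcoef(t1, t2)[0, 1])
        r = min(max(r, 0.0), 1.0)
        rel[label] = r
        sem[label] = float(sd * np.sqrt(1 - r))
        lat[label] = (float(mu), float(s2))
    return ReliabilityReport(alpha=np.nan, reliability_by_group=rel,
                             sem_by_group=sem, latent_by_group=lat, n_simulated=N)


def observed_test_retest(totals_test, totals_retest) -> float:
    """Correlation of total scores across the two occasions (paired persons)."""
    return _pearson(totals_test, totals_retest)


# ---------------------------------------------------------------------------
# targeting
# ---------------------------------------------------------------------------

def targeting_report(params: ItemParameters, totals, groups=None,
                     grid=None) -> TargetingReport:
    """Item-map data, information fraction, average bias and SE per group.

    The information fraction is the mean test information at the persons'
    latent estimates divided by the maximum of the information function —
    1 means the instrument is perfectly centred on the sample.  Bias is the
    expected difference between the score-based latent estimate and the
    latent value itself, evaluated at each person's estimate.
    """
    totals = np.asarray(totals, dtype=int)
    if groups is None:
        groups = np.zeros(len(totals), dtype=int)
    groups = np.asarray(groups)
    if grid is None:
        grid = np.linspace(-6, 6, 241)
    info_grid = np.array([test_information(params, t)[0] for t in grid])
    imax_ix = int(np.argmax(info_grid))
    info_max = float(info_grid[imax_ix])

    est_by_score = {int(r): estimate_person(params, int(r))
                    for r in range(params.min_score, params.max_score + 1)}
    theta_hat = np.array([est_by_score[int(r)].theta for r in totals])
    se_hat = np.array([est_by_score[int(r)].se for r in totals])
    theta_table = np.array([est_by_score[r].theta
                            for r in range(params.min_score, params.max_score + 1)])

    def bias_at(theta):
        p = score_distribution_given_theta(params, theta)
        p = p[params.min_score:params.max_score + 1]
        return float(np.dot(p, theta_table) - theta)

    info_frac, bias, mean_se = {}, {}, {}
    for gv in np.unique(groups):
        sel = groups == gv
        infos = np.array([test_information(params, t)[0] for t in theta_hat[sel]])
        info_frac[gv] = float(np.mean(infos) / info_max)
        bias[gv] = float(np.mean([bias_at(t) for t in theta_hat[sel]]))
        mean_se[gv] = float(np.mean(se_hat[sel]))
    return TargetingReport(
        thresholds=params.all_thresholds(), person_theta=theta_hat,
        info_fraction_by_group=info_frac, mean_bias_by_group=bias,
        mean_se_by_group=mean_se, max_information=info_max,
        theta_at_max=float(grid[imax_ix]))
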
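"""Polytomous (partial-credit) Rasch model by conditional inference.

The model for item :math:`i` with ordered categories :math:`x` is

.. math:: P(X_i = x \\mid \\theta) \\propto \\exp(x\\theta + \\eta_{ix}),

with :math:`\\eta_{i0} = 0` and thresholds
:math:`\\beta_{ij} = \\eta_{i,j-1} - \\eta_{ij}`.  Because the total score
:math:`R = \\sum_i X_i` is sufficient for :math:`\\theta`, the distribution of
a response pattern given its total score is free of the person parameter:

.. math:: P(x_1,\\dots,x_k \\mid R=r)
          = \\exp\\Big(\\sum_i \\eta_{i,x_i}\\Big) / \\gamma_r ,

where the :math:`\\gamma_r` are elementary-symmetric-function normalizers.
Item parameters are estimated by maximizing this conditional likelihood
(CML), so nothing needs to be assumed about the latent distribution.

Items are allowed per-item category *level sets* (ascending integer score
values).  A category that is never observed in a data set is dropped from
the level set rather than merged with a neighbour; the conditional
likelihood of the reduced model equals the supremum of the full model's
likelihood as that category parameter tends to :math:`-\\infty`, which keeps
log-likelihoods comparable across nested and group-wise fits.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

__all__ = [
    "ItemParameters",
    "PersonEstimate",
    "log_esf",
    "elementary_symmetric",
    "conditional_item_given_score",
    "conditional_probability_tables",
    "fit_cml",
    "estimate_person",
    "test_information",
    "score_distribution_given_theta",
    "sample_given_score",
    "sample_given_theta",
    "ConvergenceError",
    "DataError",
]


class ConvergenceError(RuntimeError):
    """CML optimizer failed to reach the gradient tolerance."""


class DataError(ValueError):
    """Input responses violate a precondition of the estimator."""


@dataclass
class ItemParameters:
    """Fitted partial-credit item parameters.

    Attributes
    ----------
    items : list of str
        Item identifiers, in column order.
    levels : list of ndarray
        Ascending integer score values per item (normally ``0..m-1``).
    eta : list of ndarray
        Category log-weights per item, same shape as ``levels``;
        ``eta[i][0] == 0``. Identified by the sum-to-zero constraint over
        all thresholds (applied through a global slope shift).
    loglik : float
        Maximized conditional log-likelihood (``nan`` for hand-built
        parameter sets).
    """

    items: list
    levels: list
    eta: list
    loglik: float = np.nan
    converged: bool = True
    grad_norm: float = np.nan
    n_iter: int = 0
    n_persons: int = 0

    def __post_init__(self):
        self.levels = [np.asarray(l, dtype=int) for l in self.levels]
        self.eta = [np.asarray(e, dtype=float) for e in self.eta]
        if len(self.items) != len(self.levels) or len(self.items) != len(self.eta):
            raise ValueError("items, levels and eta must have equal length")
        for l, e in zip(self.levels, self.eta):
            if l.shape != e.shape:
                raise ValueError("levels and eta shapes differ for an item")
            if np.any(np.diff(l) <= 0):
                raise ValueError("levels must be strictly ascending")

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def max_score(self) -> int:
        return int(sum(l[-1] for l in self.levels))

    @property
    def min_score(self) -> int:
        return int(sum(l[0] for l in self.levels))

    @property
    def n_free_parameters(self) -> int:
        # one eta per non-baseline level, minus the one flat (scale-origin)
        # direction shared by the whole instrument
        p = sum(len(l) - 1 for l in self.levels)
        return max(p - 1, 0)

    def thresholds(self, item: int) -> np.ndarray:
        """Thresholds beta_{ij} = eta_{i,j-1} - eta_{ij} between successive levels."""
        e = self.eta[item]
        return e[:-1] - e[1:]

    def all_thresholds(self) -> np.ndarray:
        return np.concatenate([self.thresholds(i) for i in range(self.n_items)])

    def subset(self, idx) -> "ItemParameters":
        idx = list(idx)
        return ItemParameters(
            items=[self.items[i] for i in idx],
            levels=[self.levels[i] for i in idx],
            eta=[self.eta[i] for i in idx],
        )

    def centered(self) -> "ItemParameters":
        """Return a copy shifted along the flat direction so that the sum of
        all thresholds is zero (the conventional identification)."""
        tot = sum(float(e[-1]) for e in self.eta)
        span = sum(float(l[-1] - l[0]) for l in self.levels)
        c = -tot / span if span > 0 else 0.0
        new_eta = [e + c * (l - l[0]) for e, l in zip(self.eta, self.levels)]
        return dataclasses.replace(self, eta=new_eta)


@dataclass
class PersonEstimate:
    """Latent-location estimate for one total score."""

    score: int
    theta: float
    se: float
    kind: str  # "ml" or "wle"
    extreme: bool = False


# ---------------------------------------------------------------------------
# elementary symmetric functions
# ---------------------------------------------------------------------------

def log_esf(levels, eta, subset=None) -> np.ndarray:
    """Log elementary-symmetric-function table ``log gamma_r``.

    Returns an array indexed by absolute total score ``0..max``;
    unachievable scores hold ``-inf``.  The forward recursion is carried in
    the log domain, so no rescaling of raw products is ever needed.
    """
    if subset is None:
        subset = range(len(levels))
    subset = list(subset)
    if not subset:
        return np.array([0.0])
    lg = np.array([0.0])
    for i in subset:
        li, ei = np.asarray(levels[i]), np.asarray(eta[i], dtype=float)
        new = np.full(len(lg) + int(li[-1]), -np.inf)
        for x, e in zip(li, ei):
            seg = lg + e
            new[x:x + len(lg)] = np.logaddexp(new[x:x + len(lg)], seg)
        lg = new
    return lg


def elementary_symmetric(params: ItemParameters, subset=None) -> np.ndarray:
    """Gamma table over achievable total scores (linear scale).

    Values are normalized internally in the log domain; the returned table
    satisfies ``gamma_r > 0`` exactly for achievable ``r``.
    """
    if subset is not None and len(list(subset)) == 0:
        raise ValueError("item subset must be non-empty")
    lg = log_esf(params.levels, params.eta, subset)
    with np.errstate(over="ignore"):
        out = np.exp(lg)
    if np.any(np.isinf(out)):
        raise FloatingPointError("gamma overflow; use log_esf directly")
    return out


def conditional_item_given_score(params: ItemParameters, item: int, r: int) -> np.ndarray:
    """P(X_item = x | R = r) over the item's levels, free of theta."""
    lg_all = log_esf(params.levels, params.eta)
    if r < 0 or r >= len(lg_all) or not np.isfinite(lg_all[r]):
        raise ValueError(f"total score {r} is not achievable")
    rest = [j for j in range(params.n_items) if j != item]
    lg_rest = log_esf(params.levels, params.eta, rest)
    li, ei = params.levels[item], params.eta[item]
    logp = np.full(len(li), -np.inf)
    for c, (x, e) in enumerate(zip(li, ei)):
        s = r - x
        if 0 <= s < len(lg_rest) and np.isfinite(lg_rest[s]):
            logp[c] = e + lg_rest[s] - lg_all[r]
    return np.exp(logp)


def conditional_probability_tables(params: ItemParameters) -> list:
    """For each item, the table ``P(X_i = x | R = r)`` for all scores.

    Returns a list of arrays of shape ``(max_score + 1, n_levels_i)``; rows
    for unachievable scores are zero.
    """
    lg_all = log_esf(params.levels, params.eta)
    tables = []
    for i in range(params.n_items):
        rest = [j for j in range(params.n_items) if j != i]
        lg_rest = log_esf(params.levels, params.eta, rest)
        li, ei = params.levels[i], params.eta[i]
        tab = np.zeros((len(lg_all), len(li)))
        for c, (x, e) in enumerate(zip(li, ei)):
            lo, hi = x, x + len(lg_rest)
            rows = np.arange(lo, min(hi, len(lg_all)))
            with np.errstate(invalid="ignore"):
                vals = np.exp(e + lg_rest[rows - x] - lg_all[rows])
            vals[~np.isfinite(vals)] = 0.0
            tab[rows, c] = vals
        tables.append(tab)
    return tables


# ---------------------------------------------------------------------------
# CML estimation
# ---------------------------------------------------------------------------

def _newton_polish(obj, z, gtol, max_iter=8):
    """Drive the gradient of a strictly concave reduced objective to zero.

    L-BFGS-B stalls once relative changes in f reach machine precision; a
    few Newton steps on the gradient (finite-difference Hessian) reach the
    gradient tolerance directly.
    """
    _, g = obj(z)
    for _ in range(max_iter):
        if np.max(np.abs(g)) <= gtol:
            break
        P = len(z)
        H = np.empty((P, P))
        h = 1e-6
        for j in range(P):
            zp = z.copy()
            zp[j] += h
            H[:, j] = (obj(zp)[1] - g) / h
        H = 0.5 * (H + H.T)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        z = z - step
        _, g = obj(z)
    return z, g


def _nullspace_basis(v: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the hyperplane orthogonal to v (P x P-1)."""
    P = len(v)
    if P == 1:
        return np.zeros((1, 0))
    A = np.concatenate([v[:, None] / np.linalg.norm(v), np.eye(P)], axis=1)
    Q, _ = np.linalg.qr(A)
    return Q[:, 1:P]


def _prepare_scores(scores: np.ndarray) -> np.ndarray:
    scores = np.asarray(scores)
    if scores.ndim != 2:
        raise DataError("response matrix must be 2-d (persons x items)")
    if np.any(~np.isfinite(scores)):
        raise DataError("missing responses present; apply complete_case_filter first")
    return scores.astype(int)


def _cml_negloglik_and_grad(free, levels, counts, score_counts):
    """Negative conditional log-likelihood and gradient in the free etas."""
    eta = []
    pos = 0
    for l in levels:
        e = np.zeros(len(l))
        e[1:] = free[pos:pos + len(l) - 1]
        pos += len(l) - 1
        eta.append(e)

    lg_all = log_esf(levels, eta)
    ll = 0.0
    grad = np.zeros_like(free)
    # observed sufficient statistics
    pos = 0
    for i, l in enumerate(levels):
        ll += float(np.dot(counts[i][1:], eta[i][1:]))
        grad[pos:pos + len(l) - 1] += counts[i][1:]
        pos += len(l) - 1
    # normalizers and expected statistics
    r_obs = np.nonzero(score_counts)[0]
    ll -= float(np.dot(score_counts[r_obs], lg_all[r_obs]))
    pos = 0
    for i, l in enumerate(levels):
        rest = [j for j in range(len(levels)) if j != i]
        lg_rest = log_esf(levels, eta, rest)
        for c in range(1, len(l)):
            x, e = l[c], eta[i][c]
            s = r_obs - x
            ok = (s >= 0) & (s < len(lg_rest))
            sv = s[ok]
            with np.errstate(invalid="ignore"):
                p = np.exp(e + lg_rest[sv] - lg_all[r_obs[ok]])
            p[~np.isfinite(p)] = 0.0
            grad[pos + c - 1] -= float(np.dot(score_counts[r_obs[ok]], p))
        pos += len(l) - 1
    return -ll, -grad


def fit_cml(
    scores: np.ndarray,
    items=None,
    m: int | None = None,
    strict: bool = False,
    gtol: float = 1e-6,
) -> ItemParameters:
    """Conditional maximum likelihood fit of the partial-credit model.

    Parameters
    ----------
    scores : array (n_persons, n_items)
        Integer coded responses, no missing values.
    items : sequence of str, optional
        Item names; defaults to ``I1..Ik``.
    m : int, optional
        Number of categories (scores assumed in ``0..m-1``); inferred from
        the data maximum when omitted.
    strict : bool
        If True, an interior category observed zero times raises
        :class:`DataError` instead of being dropped from the level set.
    """
    scores = _prepare_scores(scores)
    n, k = scores.shape
    if k < 2:
        raise DataError("at least two items are required for CML")
    if items is None:
        items = [f"I{i + 1}" for i in range(k)]
    if m is None:
        m = int(scores.max()) + 1
    if scores.min() < 0 or scores.max() > m - 1:
        raise DataError(f"scores outside 0..{m - 1}")

    levels, counts = [], []
    for i in range(k):
        cnt = np.bincount(scores[:, i], minlength=m).astype(float)
        observed = np.nonzero(cnt)[0]
        if len(observed) < m:
            missing = sorted(set(range(m)) - set(observed))
            if strict:
                raise DataError(
                    f"item {items[i]}: categories {missing} unobserved (strict mode)")
            logger.warning(
                "item %s: dropping unobserved categories %s from the level set",
                items[i], missing)
        if len(observed) == 0:  # cannot happen with n >= 1
            observed = np.array([0])
        levels.append(observed.astype(int))
        counts.append(cnt[observed])

    total = scores.sum(axis=1)
    score_counts = np.bincount(total, minlength=sum(int(l[-1]) for l in levels) + 1).astype(float)

    nfree = sum(len(l) - 1 for l in levels)
    x0 = np.zeros(nfree)
    if nfree == 0:
        params = ItemParameters(items=list(items), levels=levels,
                                eta=[np.zeros(len(l)) for l in levels],
                                loglik=0.0, n_persons=n)
        return params

    # The conditional likelihood is invariant along one direction (adding
    # c*level to every eta shifts all pattern weights by c*score, which
    # cancels against the normalizer).  Optimizing in the orthogonal
    # complement of that direction makes the problem strictly concave.
    flat = np.concatenate([(l[1:] - l[0]).astype(float) for l in levels])
    basis = _nullspace_basis(flat)

    def obj(z):
        f, g = _cml_negloglik_and_grad(basis @ z, levels, counts, score_counts)
        return f, basis.T @ g

    res = optimize.minimize(
        obj, np.zeros(basis.shape[1]),
        jac=True, method="L-BFGS-B",
        options={"maxiter": 1000, "ftol": 1e-14, "gtol": gtol * 1e-2},
    )
    z, _ = _newton_polish(obj, res.x, gtol * 1e-1)
    xfull = basis @ z
    res.fun, gred = obj(z)
    _, gfull = _cml_negloglik_and_grad(xfull, levels, counts, score_counts)
    gnorm = float(np.max(np.abs(gfull)))
    if gnorm > gtol:
        raise ConvergenceError(f"CML gradient norm {gnorm:.2e} above tolerance {gtol:.0e}")

    eta = []
    pos = 0
    for l in levels:
        e = np.zeros(len(l))
        e[1:] = xfull[pos:pos + len(l) - 1]
        pos += len(l) - 1
        eta.append(e)
    params = ItemParameters(
        items=list(items), levels=levels, eta=eta,
        loglik=-float(res.fun), converged=True, grad_norm=gnorm,
        n_iter=int(res.nit), n_persons=n,
    ).centered()
    params.loglik = -float(res.fun)
    logger.info("CML fit: loglik=%.4f iter=%d |grad|=%.2e", params.loglik,
                params.n_iter, gnorm)
    return params


# ---------------------------------------------------------------------------
# person side
# ---------------------------------------------------------------------------

def _item_moments(params: ItemParameters, theta: float):
    """Per-item mean, variance and third central moment of X_i at theta."""
    means, vars_, mu3 = [], [], []
    for l, e in zip(params.levels, params.eta):
        logits = l * theta + e
        logits = logits - logits.max()
        p = np.exp(logits)
        p /= p.sum()
        mu = float(np.dot(p, l))
        d = l - mu
        means.append(mu)
        vars_.append(float(np.dot(p, d ** 2)))
        mu3.append(float(np.dot(p, d ** 3)))
    return np.array(means), np.array(vars_), np.array(mu3)


def test_information(params: ItemParameters, theta: float):
    """Test information Var(R | theta) and its per-item decomposition."""
    if not np.isfinite(theta):
        raise ValueError("theta must be finite")
    _, v, _ = _item_moments(params, theta)
    return float(v.sum()), v


def expected_score(params: ItemParameters, theta: float) -> float:
    mu, _, _ = _item_moments(params, theta)
    return float(mu.sum())


def estimate_person(params: ItemParameters, r: int, kind: str = "wle") -> PersonEstimate:
    """Latent estimate for a total score.

    ``kind="ml"`` solves ``E[R | theta] = r``; the estimate is infinite at
    the extreme scores and is flagged as such.  ``kind="wle"`` applies the
    Warm-type bias correction ``E[R|theta] + J/(2I) = r`` (with ``J`` the
    derivative of the information), which stays finite at the extremes and
    is the default display value because raw ML estimates are biased
    outward near the ends of the score range.
    """
    rmin, rmax = params.min_score, params.max_score
    if r < rmin or r > rmax:
        raise ValueError(f"score {r} outside [{rmin}, {rmax}]")

    def ml_eq(t):
        return expected_score(params, t) - r

    def wle_eq(t):
        # Warm's correction: solve E[R|theta] - I'(theta)/(2 I(theta)) = r,
        # with I' the third central moment of R; finite at extreme scores
        mu, v, m3 = _item_moments(params, t)
        info = v.sum()
        return mu.sum() - m3.sum() / (2 * info) - r

    extreme = r in (rmin, rmax)
    if kind == "ml":
        if extreme:
            theta = np.inf if r == rmax else -np.inf
            return PersonEstimate(score=r, theta=theta, se=np.inf, kind="ml", extreme=True)
        theta = _solve_increasing(ml_eq)
    elif kind == "wle":
        theta = _solve_increasing(wle_eq)
    else:
        raise ValueError("kind must be 'ml' or 'wle'")
    info, _ = test_information(params, theta)
    se = 1.0 / np.sqrt(info) if info > 0 else np.inf
    return PersonEstimate(score=r, theta=float(theta), se=float(se), kind=kind,
                          extreme=extreme)


def _solve_increasing(f, lo=-10.0, hi=10.0):
    """Root of an increasing function with bracket expansion."""
    flo, fhi = f(lo), f(hi)
    tries = 0
    while flo > 0 and tries < 10:
        lo -= 10
        flo = f(lo)
        tries += 1
    while fhi < 0 and tries < 20:
        hi += 10
        fhi = f(hi)
        tries += 1
    if flo > 0 or fhi < 0:
        return -np.inf if flo > 0 else np.inf
    return optimize.brentq(f, lo, hi, xtol=1e-10)


def score_distribution_given_theta(params: ItemParameters, theta: float) -> np.ndarray:
    """P(R = r | theta) over absolute scores ``0..max_score``."""
    lg = log_esf(params.levels, params.eta)
    r = np.arange(len(lg))
    logp = lg + r * theta
    logp -= logsumexp(logp[np.isfinite(logp)])
    p = np.zeros(len(lg))
    ok = np.isfinite(logp)
    p[ok] = np.exp(logp[ok])
    return p


# ---------------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------------

def _suffix_tables(params: ItemParameters):
    """Per-item conditional tables for sequential score-conditioned sampling.

    ``tab[i][s, c]`` is ``P(X_i = level_c | remaining score s over items
    i..k-1)``.
    """
    k = params.n_items
    suffix = [None] * (k + 1)
    suffix[k] = np.array([0.0])
    for i in range(k - 1, -1, -1):
        suffix[i] = log_esf(params.levels, params.eta, range(i, k))
    tabs = []
    for i in range(k):
        li, ei = params.levels[i], params.eta[i]
        S = len(suffix[i])
        tab = np.zeros((S, len(li)))
        for c, (x, e) in enumerate(zip(li, ei)):
            s = np.arange(S)
            rem = s - x
            ok = (rem >= 0) & (rem < len(suffix[i + 1]))
            with np.errstate(invalid="ignore"):
                vals = np.exp(e + suffix[i + 1][rem[ok]] - suffix[i][s[ok]])
            vals[~np.isfinite(vals)] = 0.0
            tab[s[ok], c] = vals
        tabs.append(tab)
    return tabs


def sample_given_score(params: ItemParameters, totals: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    """Draw response patterns from P(pattern | R = r) under the model.

    Vectorized over persons: items are sampled sequentially, conditioning on
    the score still to be distributed over the remaining items.
    """
    totals = np.asarray(totals, dtype=int)
    tabs = _suffix_tables(params)
    n = len(totals)
    out = np.zeros((n, params.n_items), dtype=int)
    rem = totals.copy()
    for i in range(params.n_items):
        probs = tabs[i][rem]  # (n, n_levels)
        cum = np.cumsum(probs, axis=1)
        u = rng.random(n) * cum[:, -1]
        idx = (u[:, None] >= cum).sum(axis=1)
        out[:, i] = params.levels[i][idx]
        rem = rem - out[:, i]
    return out


def sample_given_theta(params: ItemParameters, thetas: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    """Draw locally independent response patterns at given latent values."""
    thetas = np.asarray(thetas, dtype=float)
    n = len(thetas)
    out = np.zeros((n, params.n_items), dtype=int)
    for i in range(params.n_items):
        l, e = params.levels[i], params.eta[i]
        logits = thetas[:, None] * l[None, :] + e[None, :]
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        cum = np.cumsum(p, axis=1)
        u = rng.random(n) * cum[:, -1]
        idx = (u[:, None] >= cum).sum(axis=1)
        out[:, i] = l[idx]
    return out
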
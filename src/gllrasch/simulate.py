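"""Synthetic questionnaire cohorts with the structure the analysis assumes.

The generator emulates a paediatric-diabetes questionnaire study: ~100
children aged 8-18 answering 5-category ordinal items on several subscales,
with partial follow-up a week later, covariates (age, sex, HbA1c,
insulin-administration mode, occasion), reverse-coded item orientations,
and optional injections of local dependence, covariate-linked DIF, an
off-dimension item driven by a second latent variable, and missing
responses.  Every generating parameter is returned in a truth record so
recovery tests can compare estimates against it.

Sampling is exact: response patterns are drawn by inverse-CDF either
item-by-item (locally independent models) or over the enumerated pattern
space (models with interactions), never by MCMC.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import (
    LABELS,
    AnalysisConfig,
    CovariateTable,
    RawResponseTable,
    ScaleDefinition,
    discretize_covariates,
)
from .gllrm import GLLRMSpec
from .rasch import ItemParameters

__all__ = ["SyntheticConfig", "generate_cohort", "generate_retest",
           "default_scale", "default_thresholds", "generate_study_cohort"]


def default_scale(k: int = 5, m: int = 5, name: str = "synthetic",
                  orientation: str = "positive") -> ScaleDefinition:
    items = tuple(f"Q{i + 1}" for i in range(k))
    return ScaleDefinition(name=name, items=items,
                           orientation={it: orientation for it in items}, m=m)


def default_thresholds(k: int, m: int = 5, spread: float = 1.0,
                       location_span: float = 1.2) -> np.ndarray:
    """Evenly spaced thresholds: item locations spanning ``location_span``
    logits, category steps ``spread`` logits apart, summing to zero."""
    locs = np.linspace(-location_span / 2, location_span / 2, k)
    steps = (np.arange(m - 1) - (m - 2) / 2) * spread
    return locs[:, None] + steps[None, :]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generating conditions for one synthetic subscale cohort.

    Covariate defaults mirror the study frame this generator emulates:
    99 children aged 8-18, 49% male, HbA1c ~ N(60.3, 10) mmol/mol, 46.4%
    on pen injections, ~59% completing the one-week retest.
    """

    n: int = 99
    scale: ScaleDefinition = field(default_factory=default_scale)
    thresholds: tuple | None = None      # (k, m-1) array-like; default evenly spaced
    latent_mu: float = 0.0
    latent_sigma2: float = 1.0
    latent_group_cov: str | None = None  # covariate whose groups get own (mu, s2)
    latent_group_params: tuple = ()      # ((mu, sigma2), ...) per group code
    age_range: tuple = (8.0, 18.0)
    male_fraction: float = 0.49
    hba1c_mean: float = 60.3
    hba1c_sd: float = 10.0
    pen_fraction: float = 0.464
    follow_up_fraction: float = 0.59
    ld: tuple = ()                # ((item_a, item_b, lam), ...) linear-by-linear
    dif: tuple = ()               # ((item, covariate, offset), ...) threshold shifts
    off_dimension: tuple = ()     # ((item, rho), ...): item driven by a 2nd latent
    missing_rate: float = 0.0
    retest: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for frac in (self.male_fraction, self.pen_fraction,
                     self.follow_up_fraction, self.missing_rate):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        items = set(self.scale.items)
        for a, b, _ in self.ld:
            if a not in items or b not in items:
                raise ValueError(f"LD injection references unknown items ({a}, {b})")
        for it, cov, _ in self.dif:
            if it not in items:
                raise ValueError(f"DIF injection references unknown item {it}")
            if cov not in ("age", "sex", "hba1c", "treatment", "occasion"):
                raise ValueError(f"DIF injection references unknown covariate {cov}")
        for it, _ in self.off_dimension:
            if it not in items:
                raise ValueError(f"off-dimension injection references unknown item {it}")

    @property
    def true_params(self) -> ItemParameters:
        k, m = self.scale.n_items, self.scale.m
        beta = (np.asarray(self.thresholds, dtype=float)
                if self.thresholds is not None else default_thresholds(k, m))
        if beta.shape != (k, m - 1):
            raise ValueError(f"thresholds must have shape ({k}, {m - 1})")
        eta = np.concatenate([np.zeros((k, 1)), -np.cumsum(beta, axis=1)], axis=1)
        return ItemParameters(items=list(self.scale.items),
                              levels=[np.arange(m)] * k,
                              eta=[eta[i] for i in range(k)])

    @property
    def spec(self) -> GLLRMSpec:
        return GLLRMSpec(
            ld_pairs=tuple((a, b) for a, b, _ in self.ld),
            dif_terms=tuple((it, cov) for it, cov, _ in self.dif),
            interaction="linear")


def _draw_covariates(cfg: SyntheticConfig, rng) -> pd.DataFrame:
    n = cfg.n
    return pd.DataFrame({
        "person_id": [f"P{i + 1:04d}" for i in range(n)],
        "occasion": "inclusion",
        "age": np.round(rng.uniform(*cfg.age_range, size=n), 1),
        "sex": np.where(rng.random(n) < cfg.male_fraction, "male", "female"),
        "hba1c": np.round(rng.normal(cfg.hba1c_mean, cfg.hba1c_sd, size=n), 1),
        "treatment": np.where(rng.random(n) < cfg.pen_fraction, "pen", "pump"),
    })


def _sample_responses(cfg: SyntheticConfig, theta, theta2, group_codes, rng):
    """Coded scores from the implied GLLRM at the given latent values."""
    params = cfg.true_params
    k, m = cfg.scale.n_items, cfg.scale.m
    n = len(theta)
    item_ix = {it: i for i, it in enumerate(cfg.scale.items)}
    dif_shift = np.zeros((n, k))         # per person-item threshold shift
    for it, cov, off in cfg.dif:
        codes = group_codes[cov]
        dif_shift[:, item_ix[it]] += off * (codes > 0)  # non-reference groups shifted
    off_items = {item_ix[it] for it, _ in cfg.off_dimension}
    theta_of_item = np.array([
        (theta2 if i in off_items else theta) for i in range(k)
    ])  # (k, n)

    if not cfg.ld:
        out = np.zeros((n, k), dtype=int)
        lev = np.arange(m)
        for i in range(k):
            logits = (theta_of_item[i][:, None] * lev[None, :]
                      + params.eta[i][None, :]
                      - dif_shift[:, i][:, None] * lev[None, :])
            logits -= logits.max(axis=1, keepdims=True)
            p = np.exp(logits)
            cum = np.cumsum(p, axis=1)
            u = rng.random(n) * cum[:, -1]
            out[:, i] = (u[:, None] >= cum).sum(axis=1)
        return out

    # enumeration path: pattern-space inverse CDF, chunked over persons
    patterns = np.array(list(itertools.product(range(m), repeat=k)), dtype=int)
    eta_lp = sum(params.eta[i][patterns[:, i]] for i in range(k))
    for a, b, lam in cfg.ld:
        eta_lp = eta_lp + lam * patterns[:, item_ix[a]] * patterns[:, item_ix[b]]
    main_sum = patterns.sum(axis=1).astype(float)
    off_sum = (patterns[:, sorted(off_items)].sum(axis=1).astype(float)
               if off_items else np.zeros(len(patterns)))
    out = np.zeros((n, k), dtype=int)
    chunk = max(1, int(2_000_000 // len(patterns)))
    for lo in range(0, n, chunk):
        sl = slice(lo, min(lo + chunk, n))
        th1 = theta[sl][:, None]
        th2 = theta2[sl][:, None] if off_items else 0.0
        lp = (eta_lp[None, :] + th1 * (main_sum - off_sum)[None, :]
              + (th2 * off_sum[None, :] if off_items else 0.0)
              - dif_shift[sl] @ patterns.T)
        lp -= lp.max(axis=1, keepdims=True)
        p = np.exp(lp)
        cum = np.cumsum(p, axis=1)
        u = rng.random(cum.shape[0]) * cum[:, -1]
        idx = np.array([np.searchsorted(cum[i], u[i]) for i in range(cum.shape[0])])
        out[sl] = patterns[idx]
    return out


def _encode_labels(coded: np.ndarray, scale: ScaleDefinition,
                   missing_mask: np.ndarray) -> pd.DataFrame:
    """Invert the orientation coding so that apply_scoring recovers ``coded``."""
    cols = {}
    top = scale.m - 1
    for j, it in enumerate(scale.items):
        neg = scale.orientation[it] == "negative"
        label_idx = (top - coded[:, j]) if neg else coded[:, j]
        col = np.array([LABELS[i] for i in label_idx], dtype=object)
        col[missing_mask[:, j]] = None  # writes as an empty CSV cell
        cols[it] = col
    return pd.DataFrame(cols)


def generate_cohort(cfg: SyntheticConfig):
    """Generate one synthetic cohort.

    Returns ``(RawResponseTable, CovariateTable, truth)``; ``truth`` carries
    the generating item parameters, latent values, injected structure and
    the internally coded score matrix, for parameter-recovery tests.
    Identical configs (same seed) produce identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    cov = _draw_covariates(cfg, rng)
    group_codes = discretize_covariates(cov, AnalysisConfig())

    if cfg.latent_group_cov:
        codes = group_codes[cfg.latent_group_cov]
        if len(cfg.latent_group_params) <= codes.max():
            raise ValueError("latent_group_params shorter than the group count")
        mus = np.array([cfg.latent_group_params[c][0] for c in codes])
        s2s = np.array([cfg.latent_group_params[c][1] for c in codes])
    else:
        mus = np.full(cfg.n, cfg.latent_mu)
        s2s = np.full(cfg.n, cfg.latent_sigma2)
    theta = rng.normal(mus, np.sqrt(s2s))

    theta2 = theta
    if cfg.off_dimension:
        rho = cfg.off_dimension[0][1]
        z = rng.normal(size=cfg.n)
        theta2 = mus + np.sqrt(s2s) * (
            rho * (theta - mus) / np.sqrt(s2s) + np.sqrt(max(1 - rho ** 2, 0.0)) * z)

    coded = _sample_responses(cfg, theta, theta2, group_codes, rng)
    missing_mask = rng.random(coded.shape) < cfg.missing_rate
    labels = _encode_labels(coded, cfg.scale, missing_mask)
    frame = pd.concat([cov[["person_id", "occasion"]], labels], axis=1)
    raw = RawResponseTable(frame=frame, items=cfg.scale.items)
    truth = {
        "params": cfg.true_params,
        "spec": cfg.spec,
        "theta": theta,
        "theta2": theta2,
        "group_codes": group_codes,
        "coded": np.where(missing_mask, -1, coded),
        "coded_full": coded,
        "missing_mask": missing_mask,
        "ld": dict(((a, b), lam) for a, b, lam in cfg.ld),
        "dif": dict(((it, c), off) for it, c, off in cfg.dif),
    }
    return raw, CovariateTable(frame=cov), truth


def generate_retest(truth: dict, cfg: SyntheticConfig, seed_offset: int = 1):
    """A second, conditionally independent response set at follow-up.

    The latent values are carried over unchanged (the construct is assumed
    stable over the one-week interval); responses are redrawn independently
    given each person's latent value, and only a ``follow_up_fraction``
    subsample returns the retest.
    """
    if not cfg.retest:
        raise ValueError("config has retest disabled")
    rng = np.random.default_rng(cfg.seed + seed_offset)
    theta, theta2 = truth["theta"], truth["theta2"]
    group_codes = truth["group_codes"]
    coded = _sample_responses(cfg, theta, theta2, group_codes, rng)
    missing_mask = rng.random(coded.shape) < cfg.missing_rate
    keep = rng.random(cfg.n) < cfg.follow_up_fraction
    labels = _encode_labels(coded, cfg.scale, missing_mask)
    frame = pd.DataFrame({
        "person_id": [f"P{i + 1:04d}" for i in range(cfg.n)],
        "occasion": "follow-up",
    })
    frame = pd.concat([frame, labels], axis=1)[keep].reset_index(drop=True)
    raw = RawResponseTable(frame=frame, items=cfg.scale.items)
    retest_truth = {"coded_full": coded, "kept": keep, "missing_mask": missing_mask}
    return raw, retest_truth


# ---------------------------------------------------------------------------
# full study-shaped fixture
# ---------------------------------------------------------------------------

def generate_study_cohort(scales, seed: int = 0, n: int = 99,
                          follow_up_fraction: float = 0.59,
                          latent_correlation: float = 0.5,
                          missing_rate: float = 0.01):
    """A full multi-subscale cohort shaped like the validation study.

    Each subscale is driven by its own latent variable; the latent variables
    are equicorrelated at ``latent_correlation`` (the subscales measure
    different but related constructs).  Roughly ``follow_up_fraction`` of
    the persons answer again at follow-up.  Returns ``(responses_frame,
    covariates_frame, truth_by_scale)`` with responses for inclusion and
    follow-up stacked.
    """
    rng = np.random.default_rng(seed)
    base_cfg = SyntheticConfig(n=n, seed=seed)
    cov = _draw_covariates(base_cfg, rng)
    group_codes = discretize_covariates(cov, AnalysisConfig())
    S = len(scales)
    corr = np.full((S, S), latent_correlation)
    np.fill_diagonal(corr, 1.0)
    thetas = rng.multivariate_normal(np.zeros(S), corr, size=n)
    keep = rng.random(n) < follow_up_fraction

    frames_inc, frames_fup = [cov[["person_id", "occasion"]].copy()], None
    fup_ids = pd.DataFrame({
        "person_id": cov["person_id"][keep].to_numpy(),
        "occasion": "follow-up"})
    frames_fup = [fup_ids.reset_index(drop=True)]
    truth = {}
    for s_ix, scale in enumerate(scales):
        cfg = replace(base_cfg, scale=scale,
                      thresholds=tuple(map(tuple, default_thresholds(scale.n_items, scale.m))))
        th = thetas[:, s_ix]
        coded_inc = _sample_responses(cfg, th, th, group_codes, rng)
        coded_fup = _sample_responses(cfg, th, th, group_codes, rng)
        miss_inc = rng.random(coded_inc.shape) < missing_rate
        miss_fup = rng.random(coded_fup.shape) < missing_rate
        frames_inc.append(_encode_labels(coded_inc, scale, miss_inc))
        frames_fup.append(_encode_labels(coded_fup, scale, miss_fup)[keep].reset_index(drop=True))
        truth[scale.name] = {"theta": th, "params": cfg.true_params}
    inc = pd.concat(frames_inc, axis=1)
    fup = pd.concat(frames_fup, axis=1)
    responses = pd.concat([inc, fup], ignore_index=True)
    cov_fup = cov[keep].copy()
    cov_fup["occasion"] = "follow-up"
    covariates = pd.concat([cov, cov_fup], ignore_index=True)
    truth["follow_up_mask"] = keep
    return responses, covariates, truth
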
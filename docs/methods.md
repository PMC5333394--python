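# Methods

`gllrasch` implements item analysis of ordinal questionnaire subscales by
polytomous Rasch models and their graphical log-linear extensions
(GLLRMs), in the conditional-inference tradition: every estimate and every
fit test conditions on total scores, so nothing has to be assumed about
the distribution of the latent trait during validation.

## The measurement model

Each subscale consists of `k` items with `m` ordered categories
(default `m = 5`, labelled "never" … "always").  Items phrased as negative
experiences are coded 4 ("never") down to 0 ("always"); positive items the
other way, so a high coded score always means few problems.  The
partial-credit Rasch kernel is

    P(X_i = x | θ) ∝ exp(xθ + η_ix),       η_i0 = 0,

with thresholds `β_ij = η_{i,j−1} − η_ij` identified by the sum-to-zero
constraint over all thresholds.  The total score `R = Σ X_i` is sufficient
for `θ`; pattern probabilities given `R = r` are

    P(x | R = r) = exp(Σ_i η_{i,x_i}) / γ_r,

with `γ_r` the elementary symmetric functions, computed by the forward
recursion in the log domain (stable up to at least `k = 8`, `m = 5`; no
rescaling of raw products is ever needed).

A GLLRM adds log-linear terms while keeping score sufficiency within
covariate strata:

* **Local dependence (LD).** A declared item pair gets an interaction.
  The default form is linear-by-linear, a single parameter `λ·x_i·x_j`.
  We chose this over a full category-by-category table as the default
  because the one-degree-of-freedom term keeps screening power and
  numerical stability at the sample sizes these validation studies have
  (n ≈ 100–500); the full table (corner-constrained, `(m−1)²` parameters
  per pair) remains available via `interaction="full"` for larger samples.
* **Uniform DIF.** A declared (item, covariate) term shifts all of that
  item's thresholds by a group-specific constant `δ_g` (reference group
  fixed at 0; positive shift = item harder for the group).  Non-uniform
  DIF (category-specific) is out of scope.

Estimation maximizes the conditional likelihood of response patterns given
each person's covariate stratum and total score over the exhaustively
enumerated pattern space (`m^k ≤ 5^8` cells).  The conditional likelihood
has exactly one flat direction (adding `c·x` to every `η` rescales all
patterns by `exp(c·r)`, which cancels); we optimize in the orthogonal
complement of that direction, where the objective is strictly concave,
with L-BFGS plus a finite-difference Newton polish, and declare
convergence at gradient max-norm ≤ 1e−6 for reported fits (1e−3 inside
test statistics, where the likelihood error is quadratic in the gradient
and far below reporting precision).  Interaction parameters are bounded at
|8|; an estimate at the bound is flagged as separation rather than allowed
to diverge.

**Degenerate categories.**  A category that is never observed drives its
parameter to −∞.  We drop such categories from the item's level set (the
remaining categories keep their original score values), which equals the
supremum of the full model's likelihood, so log-likelihoods of nested and
group-wise fits remain directly comparable.  Degrees of freedom count only
the structurally estimable parameters.  `strict` mode errors instead.

## Fit assessment

* **CLR homogeneity / DIF tests.**  `2(Σ_g max ℓ_g − max ℓ_pooled)`
  against χ² with df = (G−1)·(p−1), `p` the pooled parameter count.
  Groups are the median split of the total score among non-extreme
  scorers (ties to the low group) or the groups of a discretized
  covariate.  A category unobserved inside a group is dropped from that
  group's level set — the exact supremum of the group likelihood, keeping
  all log-likelihoods comparable — while the df deliberately keeps the
  full per-group parameter count: the boundary category still contributes
  a bounded deviance term (≈ twice its expected count given that it was
  not observed), and the χ² degree of freedom it retains covers that
  contribution.  Crediting only estimable parameters is anti-conservative
  for the score split, because score-defined groups systematically lack
  extreme categories (~15% type-I at nominal 5% in our calibration runs);
  with the full-df accounting we measure 5–6% at n = 300 and a mean
  statistic/df ratio of about 1.04.
* **LD screen.**  One CLR per item pair (declared model + that pair's
  interaction vs declared model), Benjamini–Hochberg adjusted over pairs.
* **DIF screen.**  The partial Goodman–Kruskal gamma between item and
  covariate given rest-score strata, with a delta-method standard error
  whose per-cell terms are centered stratum by stratum (the textbook
  single-table formula roughly doubles the SE when applied stratified).
  BH-adjusted over item × covariate combinations; flagged combinations get
  a CLR confirmation, and the final verdict requires both.
* **Item-rest gamma.**  Observed Goodman–Kruskal gamma between an item and
  the rest score, compared with its model expectation obtained by
  parametric simulation conditional on the observed score distribution
  (default B = 1000 replicates; two-sided Monte-Carlo p with the +1
  correction).  Asymptotics are deliberately avoided: at n ≈ 100–160 the
  simulation null is the defensible reference.  An observed gamma far
  *below* expectation is the signature of an item driven by a different
  latent variable and marks it as a removal candidate.
* **Conditional infit/outfit.**  Residuals standardized against the
  conditional-on-score moments (never against person-parameter
  estimates); outfit = unweighted mean square, infit =
  information-weighted mean square; null p by the same conditional
  simulation.

**Model search** iterates: fit → screen LD and DIF → add the single most
significant term → refit, until no term survives adjustment or a cap
(default 6 terms) is reached.  The two screens form **one joint BH family
per iteration** for the add decision, because adding a term is a single
selection across all candidates; the per-screen families are kept for the
reported tables.  Removal candidates are evaluated against the *base*
Rasch fit, not the final GLLRM — interaction terms added during the search
would otherwise absorb exactly the misfit the flag is meant to expose.
Items are flagged, never removed automatically.

## Unidimensionality, reliability, targeting

* **Between-subscale unidimensionality.**  A single partial-credit model
  is fitted to the pooled items of two subscales; subscale-score pairs are
  simulated conditional on each person's observed pooled total; the
  expected correlation is the replicate mean and the one-sided p is the
  proportion of replicates at or below the observed correlation.  An
  observed correlation significantly below expectation means one latent
  variable cannot account for both subscales.  The pooled model is pure
  Rasch: with up to 13 pooled items the enumerated GLLRM is out of reach,
  so within-subscale LD terms are ignored here (a limitation; their
  first-order effect is shared by observed and simulated correlations
  through the score conditioning).
* **Reliability.**  Cronbach's alpha as the classical summary — a lower
  bound to reliability only under local independence, and an
  *over*-estimate under positive LD.  The Monte-Carlo estimate assumes a
  normal latent distribution, estimates its mean and variance by marginal
  maximum likelihood on the observed total-score distribution
  (Gauss–Hermite quadrature, 61 nodes; variance floored at 1e−3 with a
  flag for degenerate score distributions), then simulates N = 10,000
  persons with two conditionally independent response sets each (no
  carry-over between administrations) and takes the correlation of the
  two total scores.  Because DIF and the score distribution differ across
  covariate groups, the estimate is computed per group defined by the
  final model's DIF covariates; `SEM = sd(score)·√(1 − reliability)` per
  group.
* **Targeting.**  Item-map data (thresholds and person estimates on the
  common logit scale), the information fraction (mean test information at
  person locations ÷ the maximum of the information function), and the
  average bias and SE of person estimates per age group.  Person estimates
  are Warm-type weighted-likelihood by default (finite at extreme scores,
  less biased near the ends of the range); plain ML is available and is
  flagged infinite at the extremes.

## Synthetic cohorts

The generator emulates the study frame this kind of validation uses: by
default 99 children aged 8–18 (uniform), 49% male, HbA1c ~ N(60.3, 10²)
mmol/mol, 46.4% on pen injections, and ~59% completing a retest a week
later with the latent trait unchanged.  Thresholds default to evenly
spaced steps (1 logit apart) around item locations spanning 1.2 logits,
summing to zero; the latent is standard normal unless configured per
covariate group.  Injections: linear-by-linear LD, uniform DIF threshold
shifts, an off-dimension item driven by a second latent with chosen
correlation, and missing responses at a configurable rate.  Sampling is
exact (item-wise inverse CDF when locally independent, pattern-space
inverse CDF otherwise — never MCMC), and the orientation encoding is
inverted so that `apply_scoring` recovers the generating score matrix
bit-for-bit.  The covariate distributions are fixtures chosen to make the
pipeline's covariate handling realistic; they are not claims about any
real cohort, and passing tests on these cohorts shows correctness of the
machinery under the stated model, not robustness to real-data features
such as informative missingness, response styles, or latent
non-normality.

## Problem sizes and numerical choices

Simulation-based checks in the test suite and `scripts/acceptance.py` use
deliberately moderate problem sizes — 200 replicates for type-I
calibration at n = 300, 120 for screen FDR, 30 seeded runs for search
power at n = 500, 100 replicates for unidimensionality calibration,
B = 150–400 simulation replicates inside searches — sized so the whole
suite runs in minutes while leaving Monte-Carlo error small against every
asserted margin (e.g. a rejection-rate band of [2%, 9%] is checked with a
standard error of ~1.5%).  Ties in the median score split go to the low
group; simulation p-values carry the +1 numerator/denominator correction;
all random draws flow from explicitly passed `numpy` generators, so every
simulated quantity is reproducible bit-for-bit from the seed.

## Known limitations

* Uniform DIF only; no category-specific DIF.
* The unidimensionality test's pooled model ignores within-subscale LD.
* Available-case CML (persons with partially missing subscales) is not in
  the default path; the complete-case filter mirrors how such studies
  account for complete vs incomplete questionnaires.
* χ² reference distributions for CLR tests are asymptotic; at n ≈ 100 the
  screens are used with BH adjustment and simulation-based item
  diagnostics precisely because single asymptotic p-values at that size
  deserve caution.
* The enumerated pattern space caps the GLLRM at roughly `m^k ≤ 4·10^5`
  cells (e.g. 7 five-category items); larger instruments would need a
  super-item or decomposable-graph formulation.
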
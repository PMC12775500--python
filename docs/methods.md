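# Methods

This note documents the models implemented in `allocurve`, the
assumptions behind them, the synthetic-data mechanism used to exercise
them, the numerical choices that matter, and the limits of what the
package's tests demonstrate.

## The scientific question

Across animals, log brain mass regressed on log body mass looks curved:
a quadratic term fitted across species is reliably negative, so large
animals gain less brain per unit body than small ones. The question the
package addresses is whether that macroevolutionary curvature needs its
own explanation, or whether it can emerge as a *metaphenomenon* of a
lower-level regularity: within-species brain-body slopes that decline
with body size. `allocurve` implements both levels — across-species
phylogenetic regression and individual-level hierarchical models — plus
a generative simulator that couples them, so the emergence claim can be
tested end to end against known truth.

## Across-species models

### PGLS

The core model is Gaussian regression with phylogenetically structured
residuals: y ~ Normal(X beta, sigma^2 V), where V is the Brownian tip
covariance of an ultrametric time tree (entries = shared root-to-tip
branch length, in My). Designs cover a global slope, a global quadratic
("curve"), and per-class / per-subclade variants in which group effects
are sum-to-zero deviation contrasts from the grand mean, so each group's
slope or curvature is read directly as a departure from the shared
curve. The quadratic enters on uncentred log10 body mass; coefficients
are therefore on the same scale as published brain-body curves.

Maximum-likelihood fitting profiles beta and sigma^2 analytically and
optimizes Pagel's lambda (off-diagonal shrinkage of V) by bounded 1-D
search; inference uses t statistics on residual degrees of freedom.
Bayesian fitting uses Normal(0, 2.5^2) priors on all regression
parameters — wide relative to any plausible allometric coefficient — a
half-Cauchy(0, 5) prior on the residual scale (the likelihood
overwhelms it at every n used here; a Jeffreys-like alternative made no
visible difference in pilot runs and is not exposed), conjugate blocked
Gibbs draws for beta, and Metropolis steps on log sigma^2. Parameter
"significance" is summarized by p_x, the fraction of the posterior on
the opposite side of zero from the median (two-sided; capped at 0.5).

### Variable rates

The variable-rates model places multiplicative scalars r on individual
branches, rescaling branch lengths to r * t inside V, and explores the
set of placed scalars by reversible-jump MCMC. Model choices, made here
because the approach is usually described operationally rather than as
an explicit prior:

- geometric prior on the number of placed scalars (success 0.5 per
  increment), uniform prior over branch subsets of a given size;
- log-normal(0, 1) prior on each scalar value;
- add/delete moves propose from the scalar prior (independence
  reversible jump, unit Jacobian); value updates are multiplicative
  log-normal random walks (step 0.7);
- branch-local scalars only — no whole-clade scalars.

Per-branch summaries average the *effective* rate, counting unplaced
samples as r = 1. Detailed balance of the jump moves is verified by
running the sampler with the likelihood disabled and checking the
sampled scalar count against its geometric prior (chi-square
goodness-of-fit). The likelihood for arbitrary rate configurations is
computed by a peeling (pruning) pass that returns U' V^-1 U and
log det V in O(n) without forming V (numba-compiled, with a NumPy
fallback; both are exercised against dense linear algebra in tests).

### Evidence

Marginal likelihoods use stepping-stone sampling along a power ladder
b_k = (k/K)^(1/0.4) (Beta(0.4, 1) quantiles, the standard spacing that
concentrates stones near the prior). Desk-scale default: 32 stones x
5000 samples, validated against the closed-form evidence of a conjugate
Normal-Normal model to within 0.1 nats. Bayes factors are reported as
BF = 2 (log m1 - log m0), so BF > 2 is positive support for m1. The
literature this follows prints the formula with a minus sign while
interpreting BF > 2 as support *for* the richer model; the two are
inconsistent, and we treat the printed sign as an erratum — reports
emit both conventions, with the positive-favours-m1 one flagged as the
default.

## Individual-level models

Individual measurements (species, log10 brain, log10 body, sex,
measurement method) are prepared by (i) shifting each species' (sex x
method) group means onto the species grand mean — the simplest
mean-preserving reading of sex/method centring — (ii) dropping species
with fewer than 10 individuals, and (iii) within-group centring: body
size is split into the species mean ("across") and the deviation from
it ("within"), plus a species-centred squared term.

Three Gaussian mixed models are provided, all with a phylogenetic
random effect (covariance = depth-normalized Brownian tip covariance)
and a species-identity random effect:

1. **Global curve with species variation** — fixed quadratic in raw
   individual body size; establishes whether curvature is present once
   individual variation is modelled.
2. **Hierarchical (within-group-centred)** — fixed across-species body
   size and its square plus a fixed average within-species slope;
   random species-specific slopes on the *within* deviation capture
   slope heterogeneity. Slope effects are independent of species
   intercepts (no covariance term is estimated; none is identified at
   these sample sizes).
3. **Within-quadratic variant** — no random slopes; instead the
   species-centred squared term estimates curvature in the within
   component. Because the centred square expands to 2 * mean_i * w_ij
   (plus a pure within term), its coefficient is exactly half the
   gradient of within-species slopes on species size — the two
   parameterizations coincide when slopes are homogeneous, and tests
   verify both this equivalence and the recovery of s1/2.

Sampling is blocked Gibbs with parameter expansion for every variance
component: effect = lambda * eta with eta ~ N(0, s2 K),
s2 ~ IG(1/2, 1/2) (i.e. V = 1, nu = 1) and lambda ~ N(0, 1000). The
implied prior on each effective standard deviation is a heavy-tailed
half-t, weakly informative near zero, which keeps near-zero variance
components honest (no boundary sticking). The residual variance has a
weak IG(0.001, 0.001) prior. Phylogenetic signal is summarized as
heritability h = s2_phylo / (s2_phylo + s2_species + s2_residual); the
slope-variance contribution is excluded from the denominator because it
is covariate-scale dependent, and an option includes it.

## The synthetic-data generator

Body mass evolves as Brownian motion (variance sigma2_body per My) on a
birth-death tree rescaled to a fixed crown depth. Along every branch,
brain mass follows the lineage-local allometric slope
s(x) = s0 + s1 x: the brain increment is the exact path integral
s0 dx + (s1/2) d(x^2) plus an independent Brownian residual. Because
the integral depends only on endpoints, noiseless species means lie
exactly on brain = const + s0 x + (s1/2) x^2 — the implied macro
quadratic is s1/2 by construction, which the tests assert at three
values of s1. No Euler discretization is needed; each branch is a
single exact draw.

Species-level slope heterogeneity adds Gaussian noise (independent of
size, so any recovered slope-size gradient is attributable to s1) to
s(x_species); individuals are drawn around species means with the
species' slope, and both body and brain draws are recentred so sample
means reproduce the species table exactly. An optional
`species_resid_sd` adds iid species-level scatter (non-phylogenetic
idiosyncrasy / compilation error); it defaults to 0 — the plain
mechanism above — and is switched on explicitly by studies that need
genuine species-identity variance.

Default study conditions: 300 species (200 x 20 individuals for
hierarchical studies), crown depth 100 My, root at 30 g body / 0.4 g
brain, body SD 1.5 log10 units at the tips, brain residual SD 0.25,
s0 = 0.6, s1 = -0.08, within-species body SD 0.15, within residual SD
0.05, slope noise SD 0.15. These magnitudes emulate comparative
brain-size compilations (species spanning several orders of magnitude
of body mass; widely scattered within-species slopes); the generator
makes no attempt to mimic real taxonomic composition, body-size
distributions, or sampling bias, so passing tests demonstrate
correctness of the machinery under the stated mechanism, not fidelity
to any particular empirical dataset.

## What the validation battery shows — and one structural finding

The replicated studies (see `scripts/acceptance.py`) verify: the
closed-form curvature identity; emergence (Bayesian PGLS detects the
negative quadratic in >= 90% of full-noise replicates at n = 300);
oracle agreement for likelihood, evidence, and prior sampling;
variable-rates calibration (null branch rates hug 1; a 25x-variance
clade is flagged); and meta-regression recovery of a slope-size
gradient of -0.031 across 51 groups.

One documented expectation is *not* met, for a structural reason worth
recording. Under this generator the species means are genuinely curved
(exactly s1/2 in the noiseless limit), so a correctly specified
hierarchical model *finds* that curvature: the across-species quadratic
remains credibly negative rather than being absorbed by the random
slopes. Random slopes on the within-species deviation are orthogonal to
species means by construction and cannot soak up across-species
curvature; they absorb slope heterogeneity, and the within-quadratic
variant correctly isolates the slope-size gradient (s1/2) in the within
component. An empirical analysis in which hierarchical modelling
removes across-species curvature is therefore informative: it indicates
that the real species-mean curvature signal is weak relative to
species-level noise — not that slope heterogeneity mechanically
explains it away. The absorption study reports all component rates so
this behaviour is visible rather than hidden.

## Numerical choices and limitations

- Ultrametricity tolerance defaults to 1e-6 x tree depth; short
  terminal clades (< 0.25 My terminal branches, the usual numerical
  hazard) can be collapsed to a single seeded-random representative,
  applied to a fixed point so the operation is idempotent. The rule
  tests terminal branches; a flag switches to the stem-branch reading.
- Polytomies are kept as hard multifurcations everywhere (the peeling
  combines children pairwise, which is exact).
- Chain-length defaults are desk-scale (2 x 10^5 iterations for
  species-level PGLS; a few thousand blocked-Gibbs sweeps for mixed
  models, which mix quickly in these conjugate blocks); production
  analyses of real data should scale these up and check the reported
  split R-hat. Replicate counts (20 seeds) and tree sizes (60-300
  tips) in the studies are likewise desk-scale choices.
- The stepping-stone MC standard error treats within-stone samples as
  independent and is optimistic for MCMC-based models.
- Zero-length cherries make the Brownian covariance singular; the
  simulator avoids them by construction and the likelihood reports them
  as errors rather than regularizing silently.
- Not implemented (out of scope): measurement-error PGLS variants,
  clade-wide rate scalars, non-Gaussian responses, tree inference, and
  any literature-curation logic.
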
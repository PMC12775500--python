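"""Phylogenetic generalized linear mixed models on individual-level data.

Gaussian mixed models in which each individual's log10 brain mass is
modelled from fixed allometric effects plus random effects at the
species level:

- a *phylogenetic* effect with covariance proportional to the Brownian
  tip covariance of the tree (the "animal model" term),
- a *species identity* effect (independent across species; captures
  non-phylogenetic species idiosyncrasy and compilation error),
- optionally a *species slope* effect multiplying the within-species
  body-size deviation, so every species carries its own allometric slope
  around the average within-species slope.

With within-group centring the fixed part separates across-species body
size (species mean and its square) from within-species deviations, so
across- and within-species allometry are estimated in one model.

Sampling is blocked Gibbs with parameter expansion for every variance
component: each random-effect vector is written as lambda * eta with
eta ~ N(0, s2 K), s2 ~ IG(nu/2, nu V/2) (V = 1, nu = 1) and the working
scale lambda ~ N(alpha.mu = 0, alpha.V = 1000). The implied prior on the
effective standard deviation |lambda| sqrt(s2) is a heavy-tailed
half-t, non-informative for variance components near zero. The residual
variance carries a weak IG(0.001, 0.001) prior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .mcmc import McmcSettings, px, summarize
from .treeio import Tree, vcv

__all__ = [
    "HierarchicalSpec",
    "HierarchicalFit",
    "fit_pglmm",
    "fit_global_curve_with_species_variation",
    "fit_hierarchical",
    "fit_hierarchical_within_quadratic",
    "heritability",
]

FIXED_ROLES = (
    "intercept",
    "body",
    "body2",
    "across_body",
    "across_body2",
    "within_body",
    "within_body_sq_centred",
)
RANDOM_ROLES = ("phylogenetic", "species_identity", "species_slope")


@dataclass(frozen=True)
class HierarchicalSpec:
    """Fixed-effect and random-effect roles of one mixed model."""

    fixed: tuple
    random: tuple
    alpha_v: float = 1000.0   # working-parameter prior variance
    px_nu: float = 1.0        # IG shape/rate base: IG(nu/2, nu*V/2), V = 1
    fixed_prior_v: float = 1e8

    def __post_init__(self):
        for f in self.fixed:
            if f not in FIXED_ROLES:
                raise ValueError(f"unknown fixed role '{f}'")
        for r in self.random:
            if r not in RANDOM_ROLES:
                raise ValueError(f"unknown random role '{r}'")
        if "species_slope" in self.random and "within_body_sq_centred" in self.fixed:
            raise ValueError(
                "species_slope random effect and the within-species "
                "quadratic are alternative parameterizations; use one"
            )


GLOBAL_CURVE_SPEC = HierarchicalSpec(
    fixed=("intercept", "body", "body2"),
    random=("phylogenetic", "species_identity"),
)
HIERARCHICAL_SPEC = HierarchicalSpec(
    fixed=("intercept", "across_body", "across_body2", "within_body"),
    random=("phylogenetic", "species_identity", "species_slope"),
)
WITHIN_QUADRATIC_SPEC = HierarchicalSpec(
    fixed=(
        "intercept", "across_body", "across_body2",
        "within_body", "within_body_sq_centred",
    ),
    random=("phylogenetic", "species_identity"),
)


@dataclass
class HierarchicalFit:
    """Posterior summaries and raw chains from one PGLMM fit."""

    spec: HierarchicalSpec
    fixed_names: list
    fixed_samples: np.ndarray          # (S, p)
    variance_samples: pd.DataFrame     # columns sigma2_phylo, ... sigma2_residual
    heritability_samples: np.ndarray
    species: list
    species_slope_deviation: pd.Series | None
    settings: McmcSettings

    def samples(self) -> dict:
        out = {n: self.fixed_samples[:, j] for j, n in enumerate(self.fixed_names)}
        for c in self.variance_samples.columns:
            out[c] = self.variance_samples[c].to_numpy()
        out["heritability"] = self.heritability_samples
        return out

    def summary(self) -> pd.DataFrame:
        return summarize(self.samples())

    def fixed_px(self, name: str) -> float:
        return px(self.fixed_samples[:, self.fixed_names.index(name)])


def heritability(
    sigma2_phylo, sigma2_species, sigma2_residual, sigma2_slope=None
):
    """Phylogenetic signal as the phylogenetic fraction of model variance.

    h = s2_phylo / (s2_phylo + s2_species + s2_residual); the slope
    variance (if any) is excluded from the denominator because its
    contribution depends on the within-species covariate scale. Passing
    ``sigma2_slope`` includes it instead (alternative definition).
    """
    num = np.asarray(sigma2_phylo, dtype=float)
    den = num + np.asarray(sigma2_species, float) + np.asarray(sigma2_residual, float)
    if sigma2_slope is not None:
        den = den + np.asarray(sigma2_slope, dtype=float)
    if np.any(den == 0):
        raise ValueError("all variance components are zero")
    return num / den


def _build_fixed(centred: pd.DataFrame, roles) -> np.ndarray:
    cols = []
    for r in roles:
        if r == "intercept":
            cols.append(np.ones(len(centred)))
        elif r == "body":
            cols.append(centred["log10_body_g"].to_numpy(float))
        elif r == "body2":
            cols.append(centred["log10_body_g"].to_numpy(float) ** 2)
        elif r == "across_body":
            cols.append(centred["across_body"].to_numpy(float))
        elif r == "across_body2":
            cols.append(centred["across_body"].to_numpy(float) ** 2)
        elif r == "within_body":
            cols.append(centred["within_body"].to_numpy(float))
        elif r == "within_body_sq_centred":
            cols.append(centred["within_body_sq_centred"].to_numpy(float))
    return np.column_stack(cols)


def fit_pglmm(
    spec: HierarchicalSpec,
    centred: pd.DataFrame,
    tree: Tree,
    settings: McmcSettings | None = None,
) -> HierarchicalFit:
    """Fit a hierarchical phylogenetic mixed model by blocked Gibbs.

    ``centred`` must carry the columns produced by
    :func:`allocurve.dataprep.within_group_center` whenever ``spec``
    includes centred roles. Every species must be a tip of ``tree``; the
    phylogenetic covariance is depth-normalized so variance components
    are on the trait scale.
    """
    settings = settings or McmcSettings(iterations=4000, burnin=1000, thin=3)
    rng = np.random.default_rng(settings.seed)

    species = sorted(centred["species"].unique())
    q = len(species)
    if q < 2 and any(r in spec.fixed for r in ("across_body", "across_body2")):
        raise ValueError(
            "across-species terms are inestimable with a single species"
        )
    tipset = set(tree.tip_labels)
    missing = [s for s in species if s not in tipset]
    if missing:
        raise ValueError(f"species not found in tree: {missing[:10]}")
    if "within_body" in spec.fixed:
        counts = centred.groupby("species").size()
        if (counts < 2).any():
            raise ValueError(
                "within-species effects need >= 2 individuals per species"
            )

    y = centred["log10_brain_g"].to_numpy(float)
    n = y.size
    X = _build_fixed(centred, spec.fixed)
    p = X.shape[1]
    sp_index = {s: i for i, s in enumerate(species)}
    zi = centred["species"].map(sp_index).to_numpy()
    w = (
        centred["within_body"].to_numpy(float)
        if "within_body" in centred.columns
        else np.zeros(n)
    )

    # phylogenetic covariance among the modelled species, depth-normalized
    use_phylo = "phylogenetic" in spec.random
    if use_phylo:
        from .treeio import keep_tips

        sub = keep_tips(tree, species)
        order = [sub.tip_labels.index(s) for s in species]
        A = vcv(sub)[np.ix_(order, order)]
        A = A / np.diag(A).max()
        Ainv = np.linalg.inv(A + 1e-10 * np.eye(q))

    use_species = "species_identity" in spec.random
    use_slope = "species_slope" in spec.random

    # sufficient statistics
    XtX = X.T @ X
    n_i = np.bincount(zi, minlength=q).astype(float)
    sw2_i = np.bincount(zi, weights=w * w, minlength=q)

    def group_sum(v):
        return np.bincount(zi, weights=v, minlength=q)

    # state
    beta = np.zeros(p)
    eta_u = np.zeros(q)
    eta_s = np.zeros(q)
    eta_d = np.zeros(q)
    lam_u = lam_s = lam_d = 1.0
    s2_u = s2_s = s2_d = 1.0
    sigma2_e = max(np.var(y) / 2.0, 1e-4)

    S = settings.n_samples
    keep_fix = np.empty((S, p))
    vc_cols = (
        (["sigma2_phylo"] if use_phylo else [])
        + (["sigma2_species"] if use_species else [])
        + (["sigma2_slope"] if use_slope else [])
        + ["sigma2_residual"]
    )
    keep_vc = np.empty((S, len(vc_cols)))
    keep_her = np.empty(S)
    slope_dev_sum = np.zeros(q)
    k_out = 0

    prior_fix = np.eye(p) / spec.fixed_prior_v
    nu = spec.px_nu

    def effects():
        out = np.zeros(n)
        if use_phylo:
            out += lam_u * eta_u[zi]
        if use_species:
            out += lam_s * eta_s[zi]
        if use_slope:
            out += lam_d * eta_d[zi] * w
        return out

    for it in range(settings.iterations):
        # --- fixed effects
        r = y - effects()
        Af = XtX / sigma2_e + prior_fix
        cf = linalg.cho_factor(Af, lower=True)
        mean = linalg.cho_solve(cf, X.T @ r / sigma2_e)
        beta = mean + linalg.solve_triangular(
            np.tril(cf[0]), rng.standard_normal(p), lower=True, trans="T"
        )
        xb = X @ beta

        # --- phylogenetic effect (q-dimensional MVN)
        if use_phylo:
            resid = y - xb
            if use_species:
                resid = resid - lam_s * eta_s[zi]
            if use_slope:
                resid = resid - lam_d * eta_d[zi] * w
            P = (lam_u**2 / sigma2_e) * np.diag(n_i) + Ainv / s2_u
            cP = linalg.cho_factor(P, lower=True)
            m = linalg.cho_solve(cP, lam_u * group_sum(resid) / sigma2_e)
            eta_u = m + linalg.solve_triangular(
                np.tril(cP[0]), rng.standard_normal(q), lower=True, trans="T"
            )
            c = eta_u[zi]
            prec = c @ c / sigma2_e + 1.0 / spec.alpha_v
            lam_u = rng.normal((c @ resid / sigma2_e) / prec, 1.0 / np.sqrt(prec))
            quad = eta_u @ Ainv @ eta_u
            s2_u = 1.0 / rng.gamma((nu + q) / 2.0, 2.0 / (nu + quad))

        # --- species identity effect (diagonal)
        if use_species:
            resid = y - xb
            if use_phylo:
                resid = resid - lam_u * eta_u[zi]
            if use_slope:
                resid = resid - lam_d * eta_d[zi] * w
            prec_i = lam_s**2 * n_i / sigma2_e + 1.0 / s2_s
            m_i = lam_s * group_sum(resid) / sigma2_e / prec_i
            eta_s = m_i + rng.standard_normal(q) / np.sqrt(prec_i)
            c = eta_s[zi]
            prec = c @ c / sigma2_e + 1.0 / spec.alpha_v
            lam_s = rng.normal((c @ resid / sigma2_e) / prec, 1.0 / np.sqrt(prec))
            s2_s = 1.0 / rng.gamma((nu + q) / 2.0, 2.0 / (nu + eta_s @ eta_s))

        # --- species slopes on the within-species deviation
        if use_slope:
            resid = y - xb
            if use_phylo:
                resid = resid - lam_u * eta_u[zi]
            if use_species:
                resid = resid - lam_s * eta_s[zi]
            prec_i = lam_d**2 * sw2_i / sigma2_e + 1.0 / s2_d
            m_i = lam_d * group_sum(resid * w) / sigma2_e / prec_i
            eta_d = m_i + rng.standard_normal(q) / np.sqrt(prec_i)
            c = eta_d[zi] * w
            prec = c @ c / sigma2_e + 1.0 / spec.alpha_v
            lam_d = rng.normal((c @ resid / sigma2_e) / prec, 1.0 / np.sqrt(prec))
            s2_d = 1.0 / rng.gamma((nu + q) / 2.0, 2.0 / (nu + eta_d @ eta_d))

        # --- residual variance
        e = y - xb - effects()
        sigma2_e = 1.0 / rng.gamma(
            0.001 + n / 2.0, 1.0 / (0.001 + e @ e / 2.0)
        )

        if it >= settings.burnin and (it - settings.burnin) % settings.thin == 0:
            keep_fix[k_out] = beta
            vc = []
            s2_phylo = lam_u**2 * s2_u if use_phylo else 0.0
            s2_spec = lam_s**2 * s2_s if use_species else 0.0
            s2_slope = lam_d**2 * s2_d if use_slope else 0.0
            if use_phylo:
                vc.append(s2_phylo)
            if use_species:
                vc.append(s2_spec)
            if use_slope:
                vc.append(s2_slope)
            vc.append(sigma2_e)
            keep_vc[k_out] = vc
            keep_her[k_out] = s2_phylo / (s2_phylo + s2_spec + sigma2_e)
            if use_slope:
                slope_dev_sum += lam_d * eta_d
            k_out += 1

    slope_dev = (
        pd.Series(slope_dev_sum / max(k_out, 1), index=species)
        if use_slope
        else None
    )
    return HierarchicalFit(
        spec=spec,
        fixed_names=list(spec.fixed),
        fixed_samples=keep_fix[:k_out],
        variance_samples=pd.DataFrame(keep_vc[:k_out], columns=vc_cols),
        heritability_samples=keep_her[:k_out],
        species=species,
        species_slope_deviation=slope_dev,
        settings=settings,
    )


def fit_global_curve_with_species_variation(
    centred: pd.DataFrame, tree: Tree, settings: McmcSettings | None = None
) -> HierarchicalFit:
    """Global curve PGLMM: quadratic in raw individual body size, with
    phylogenetic and species-identity random effects. Establishes whether
    across-species curvature is present once individual-level variation
    is accounted for."""
    return fit_pglmm(GLOBAL_CURVE_SPEC, centred, tree, settings)


def fit_hierarchical(
    centred: pd.DataFrame, tree: Tree, settings: McmcSettings | None = None
) -> HierarchicalFit:
    """Within-group-centred hierarchical model: across-species curve
    (species-mean body size and its square) plus an average within-species
    slope, with species-level random slopes capturing heterogeneity in
    within-species allometry."""
    return fit_pglmm(HIERARCHICAL_SPEC, centred, tree, settings)


def fit_hierarchical_within_quadratic(
    centred: pd.DataFrame, tree: Tree, settings: McmcSettings | None = None
) -> HierarchicalFit:
    """Alternative parameterization: instead of random species slopes,
    curvature is estimated in the within-species component through the
    species-centred squared body size term."""
    return fit_pglmm(WITHIN_QUADRATIC_SPEC, centred, tree, settings)
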
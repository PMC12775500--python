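"""Replicated validation studies of the whole pipeline on synthetic data.

Each study regenerates data with known ground truth and measures how the
fitting machinery behaves: exactness of the closed-form micro-to-macro
identity, detection of emergent curvature, the behaviour of the
hierarchical within-group-centred model, agreement of the likelihood and
evidence machinery with independent oracles, variable-rates calibration
and clade detection, and recovery of the slope-versus-size
meta-regression. The study sizes are desk-scale defaults chosen so that
the full battery runs in minutes; every study takes a single master seed
and derives all replicate seeds from it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import dataprep, derive, pglmm, pgls, synth, treeio, varrates
from .evidence import ConjugateNormalModel, StoneSchedule, stepping_stone
from .mcmc import McmcSettings, px

__all__ = [
    "noiseless_macro_quadratic",
    "emergence_study",
    "absorption_study",
    "oracle_study",
    "varrates_null_study",
    "varrates_detection_study",
    "metaregression_study",
]


def _spawn(seed: int, k: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(2**31 - 1, size=k)


# ---------------------------------------------------------------------------
# 1. closed-form metaphenomenon
# ---------------------------------------------------------------------------

def noiseless_macro_quadratic(
    seed: int, n_species: int = 300, s0: float = 0.6, s1: float = -0.08
) -> dict:
    """Quadratic coefficient fitted through noiseless species means.

    With all noise sources off, species means satisfy
    brain = const + s0 x + (s1/2) x^2 exactly, so the fitted quadratic
    must equal s1 / 2 to numerical precision.
    """
    cfg = synth.MicroMacroConfig(
        n_species=n_species, s0=s0, s1=s1,
        sigma2_resid=0.0, species_resid_sd=0.0, slope_noise_sd=0.0,
        seed=int(seed),
    )
    ds = synth.simulate_micro_macro(cfg)
    x = ds.species["log10_body_g"].to_numpy()
    y = ds.species["log10_brain_g"].to_numpy()
    quad = float(np.polyfit(x, y, 2)[0])
    return {"quadratic": quad, "expected": s1 / 2.0, "n": n_species}


# ---------------------------------------------------------------------------
# 2. emergence of curvature under full noise
# ---------------------------------------------------------------------------

def emergence_study(
    seed: int,
    n_seeds: int = 20,
    n_species: int = 300,
    settings: McmcSettings | None = None,
) -> dict:
    """Fraction of replicates where Bayesian PGLS finds the emergent
    negative quadratic (posterior median < 0 and p_x < 0.05)."""
    seeds = _spawn(seed, n_seeds)
    hits = 0
    medians = []
    for s in seeds:
        cfg = synth.MicroMacroConfig(n_species=n_species, seed=int(s))
        ds = synth.simulate_micro_macro(cfg)
        design = pgls.build_design(ds.species, "global_curve")
        V = treeio.vcv(ds.tree)
        st = settings or McmcSettings(
            iterations=60_000, burnin=10_000, thin=25, seed=int(s) % (2**31 - 1)
        )
        chain = pgls.fit_pgls_bayes(design, V, settings=st)
        b2 = chain.beta[:, design.names.index("body2")]
        medians.append(float(np.median(b2)))
        if np.median(b2) < 0 and px(b2) < 0.05:
            hits += 1
    return {
        "detection_rate_pct": 100.0 * hits / n_seeds,
        "median_quadratic": float(np.median(medians)),
        "n_seeds": n_seeds,
        "n_species": n_species,
    }


# ---------------------------------------------------------------------------
# 3. hierarchical within-group-centred behaviour
# ---------------------------------------------------------------------------

def absorption_study(
    seed: int,
    n_seeds: int = 20,
    n_species: int = 200,
    n_individuals: int = 20,
    settings: McmcSettings | None = None,
) -> dict:
    """Across-species quadratic under the pooled global-curve PGLMM versus
    the hierarchical within-group-centred model, per replicate.

    Reports the rate at which (a) the pooled model finds a credibly
    negative quadratic, (b) the hierarchical model's across-species
    quadratic overlaps zero (p_x >= 0.05), and (c) both hold jointly.
    Also records the within-species quadratic of the alternative
    parameterization, which isolates the slope-size gradient.
    """
    seeds = _spawn(seed, n_seeds)
    global_sig = hier_ns = joint = withinq_sig = 0
    hier_b2 = []
    for s in seeds:
        cfg = synth.MicroMacroConfig(
            n_species=n_species, n_individuals=n_individuals, seed=int(s)
        )
        ds = synth.simulate_micro_macro(cfg)
        centred = dataprep.within_group_center(ds.individuals)
        st = settings or McmcSettings(
            iterations=4000, burnin=1000, thin=3, seed=int(s) % (2**31 - 1)
        )
        fg = pglmm.fit_global_curve_with_species_variation(centred, ds.tree, st)
        fh = pglmm.fit_hierarchical(centred, ds.tree, st)
        fq = pglmm.fit_hierarchical_within_quadratic(centred, ds.tree, st)
        g_b2 = fg.fixed_samples[:, fg.fixed_names.index("body2")]
        h_b2 = fh.fixed_samples[:, fh.fixed_names.index("across_body2")]
        q_w2 = fq.fixed_samples[:, fq.fixed_names.index("within_body_sq_centred")]
        hier_b2.append(float(np.median(h_b2)))
        g_ok = np.median(g_b2) < 0 and px(g_b2) < 0.05
        h_ok = px(h_b2) >= 0.05
        if g_ok:
            global_sig += 1
        if h_ok:
            hier_ns += 1
        if g_ok and h_ok:
            joint += 1
        if np.median(q_w2) < 0 and px(q_w2) < 0.05:
            withinq_sig += 1
    return {
        "global_curve_significant_rate_pct": 100.0 * global_sig / n_seeds,
        "hierarchical_nonsignificant_rate_pct": 100.0 * hier_ns / n_seeds,
        "joint_rate_pct": 100.0 * joint / n_seeds,
        "within_quadratic_significant_rate_pct": 100.0 * withinq_sig / n_seeds,
        "hierarchical_median_across_quadratic": float(np.median(hier_b2)),
        "n_seeds": n_seeds,
        "n_species": n_species,
        "n_individuals": n_individuals,
    }


# ---------------------------------------------------------------------------
# 4. oracles
# ---------------------------------------------------------------------------

def oracle_study(seed: int) -> dict:
    """Agreement of core numerics with independent oracles.

    - GLS log-likelihood versus a dense multivariate-normal density on
      random trees of 3..12 tips;
    - stepping-stone evidence versus the closed-form conjugate
      Normal-Normal marginal likelihood at 32 stones x 5000 samples;
    - prior-only MCMC recovery of the Normal(0, 2.5^2) regression prior.
    """
    rng = np.random.default_rng(seed)
    # (a) dense MVN comparison
    max_err = 0.0
    for n_tips in range(3, 13):
        tree = synth.simulate_tree(n_tips, seed=int(rng.integers(2**31 - 1)))
        V = treeio.vcv(tree)
        y = rng.normal(size=n_tips)
        X = np.column_stack([np.ones(n_tips), rng.normal(size=n_tips)])
        design = pgls.RegressionDesign(
            y=y, X=X, names=["a", "b"], labels=tree.tip_labels
        )
        beta = rng.normal(size=2)
        sigma2 = float(rng.uniform(0.5, 2.0))
        ours = pgls.gls_loglik(design, V, beta, sigma2)
        ref = stats.multivariate_normal(mean=X @ beta, cov=sigma2 * V).logpdf(y)
        max_err = max(max_err, abs(ours - ref))
    # (b) stepping-stone vs closed form
    y = rng.normal(1.0, 1.0, size=25)
    model = ConjugateNormalModel(y, sigma2=1.0, mu0=0.0, tau2=4.0)
    sched = StoneSchedule.default(
        n_stones=32, n_samples=5000, seed=int(rng.integers(2**31 - 1))
    )
    est = stepping_stone(model, sched)
    ss_err = abs(est.log_marginal - model.log_marginal())
    # (c) prior recovery
    design = pgls.RegressionDesign(
        y=np.zeros(4),
        X=np.column_stack([np.ones(4), np.arange(4.0)]),
        names=["a", "b"],
        labels=list("ABCD"),
    )
    chain = pgls.fit_pgls_bayes(
        design,
        np.eye(4),
        settings=McmcSettings(
            iterations=60_000, burnin=5_000, thin=5,
            seed=int(rng.integers(2**31 - 1)),
        ),
        likelihood_off=True,
    )
    sd_err = float(np.max(np.abs(chain.beta.std(axis=0) - 2.5) / 2.5))
    return {
        "gls_loglik_max_abs_error": float(max_err),
        "stepping_stone_abs_error_nats": float(ss_err),
        "prior_sd_max_rel_error": sd_err,
    }


# ---------------------------------------------------------------------------
# 5. variable rates
# ---------------------------------------------------------------------------

def _clade_nodes(tree: treeio.Tree, min_tips: int, max_tips: int):
    sizes = {}
    for v in tree.postorder():
        sizes[v] = 1 if tree.is_tip(v) else sum(sizes[c] for c in tree.children(v))
    cands = [
        v
        for v in range(tree.n_nodes)
        if not tree.is_tip(v)
        and tree.parent[v] >= 0
        and min_tips <= sizes[v] <= max_tips
    ]
    return cands, sizes


def _simulate_clade_shift(cfg: synth.MicroMacroConfig, var_factor: float):
    """Micro-macro data on a tree where one clade's brain residual
    Brownian variance is multiplied by ``var_factor``."""
    rng = np.random.default_rng(cfg.seed)
    tree = synth.simulate_tree(
        cfg.n_species, cfg.birth_rate, cfg.death_rate, cfg.tree_depth,
        seed=int(rng.integers(2**31 - 1)),
    )
    cands, sizes = _clade_nodes(
        tree, max(4, cfg.n_species // 8), max(6, cfg.n_species // 3)
    )
    node = sorted(cands, key=lambda v: -sizes[v])[0]
    scale = np.ones(tree.n_nodes)
    stack, clade = [node], []
    while stack:
        v = stack.pop()
        clade.append(v)
        stack.extend(tree.children(v))
    scale[clade] = var_factor
    x = synth.simulate_body_bm(tree, cfg.sigma2_body, cfg.root_body, rng, True)
    b = np.zeros(tree.n_nodes)
    b[tree.root] = cfg.root_brain
    for v in tree.preorder():
        p = tree.parent[v]
        if p < 0:
            continue
        dx = x[v] - x[p]
        b[v] = (
            b[p]
            + cfg.s0 * dx
            + 0.5 * cfg.s1 * (x[v] ** 2 - x[p] ** 2)
            + rng.normal(0, np.sqrt(cfg.sigma2_resid * scale[v] * tree.lengths[v]))
        )
    species = pd.DataFrame(
        {
            "species": tree.tip_labels,
            "log10_body_g": x[tree.tips],
            "log10_brain_g": b[tree.tips]
            + rng.normal(0, cfg.species_resid_sd, tree.n_tips),
            "class": "synthetic",
        }
    )
    return tree, species, clade


def varrates_null_study(
    seed: int, n_species: int = 80, settings: McmcSettings | None = None
) -> dict:
    """Calibration on homogeneous-rate data: posterior mean branch rates
    should hug 1 and the modal number of placed scalars should be 0."""
    ds = synth.simulate_micro_macro(
        synth.MicroMacroConfig(n_species=n_species, seed=int(seed))
    )
    design = pgls.build_design(ds.species, "global_curve")
    st = settings or McmcSettings(
        iterations=40_000, burnin=8_000, thin=16, seed=int(seed)
    )
    chain = varrates.rjmcmc_variable_rates(design, ds.tree, settings=st)
    mr = chain.extras["mean_rates"]
    br = ds.tree.parent >= 0
    in_band = float(np.mean((mr[br] >= 0.8) & (mr[br] <= 1.25)))
    return {
        "branches_in_band_pct": 100.0 * in_band,
        "treewide_mean_rate": float(mr[br].mean()),
        "modal_n_scalars": int(np.bincount(chain.extras["n_scalars"]).argmax()),
        "n_species": n_species,
    }


def varrates_detection_study(
    seed: int,
    n_seeds: int = 20,
    n_species: int = 60,
    var_factor: float = 25.0,
    settings: McmcSettings | None = None,
) -> dict:
    """Fraction of replicates in which a clade evolving with var_factor
    times the residual variance shows elevated posterior mean rates
    (clade mean r above the tree-wide median)."""
    seeds = _spawn(seed, n_seeds)
    hits = 0
    for s in seeds:
        cfg = synth.MicroMacroConfig(n_species=n_species, seed=int(s))
        tree, species, clade = _simulate_clade_shift(cfg, var_factor)
        design = pgls.build_design(species, "global_curve")
        st = settings or McmcSettings(
            iterations=40_000, burnin=8_000, thin=16, seed=int(s) % (2**31 - 1)
        )
        chain = varrates.rjmcmc_variable_rates(design, tree, settings=st)
        mr = chain.extras["mean_rates"]
        br = [v for v in range(tree.n_nodes) if tree.parent[v] >= 0]
        if np.mean(mr[clade]) > np.median(mr[br]):
            hits += 1
    return {
        "detection_rate_pct": 100.0 * hits / n_seeds,
        "n_seeds": n_seeds,
        "n_species": n_species,
        "var_factor": var_factor,
    }


# ---------------------------------------------------------------------------
# 6. subclade slope meta-regression
# ---------------------------------------------------------------------------

def metaregression_study(
    seed: int,
    n_seeds: int = 20,
    n_groups: int = 51,
    alpha: float = 0.59,
    beta: float = -0.031,
    noise_sd: float = 0.02,
) -> dict:
    """Recovery of the slope-versus-size gradient across simulated groups.

    Group median body sizes evolve by Brownian motion on a group-level
    tree; group slopes are alpha + beta * body + Normal(0, noise_sd).
    Reports the fraction of replicates with the fitted coefficient in
    [-0.04, -0.02] and the median fitted coefficient.
    """
    seeds = _spawn(seed, n_seeds)
    hits = 0
    betas = []
    for s in seeds:
        rng = np.random.default_rng(int(s))
        tree = synth.simulate_tree(n_groups, seed=int(s))
        body = synth.simulate_body_bm(tree, sigma2=0.0225, root=1.5, rng=rng)
        slopes = alpha + beta * body + rng.normal(0, noise_sd, n_groups)
        groups = pd.DataFrame(
            {"group": tree.tip_labels, "slope": slopes, "median_body": body}
        )
        fit = derive.slope_size_metaregression(groups, tree)
        b = float(fit.coef.loc["median_body", "estimate"])
        betas.append(b)
        if -0.04 <= b <= -0.02:
            hits += 1
    return {
        "recovery_rate_pct": 100.0 * hits / n_seeds,
        "median_coefficient": float(np.median(betas)),
        "n_seeds": n_seeds,
        "n_groups": n_groups,
    }
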
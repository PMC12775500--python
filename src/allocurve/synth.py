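"""Synthetic phylogenies and brain-body datasets with known ground truth.

The generator formalises a micro-to-macro mechanism: body mass evolves as
Brownian motion on the tree, and along every branch log brain mass tracks
log body mass through a lineage-local allometric slope that declines
linearly with size,

    s(x) = s0 + s1 * x,          x = log10 body mass (g), s1 < 0.

Because ds = s(x) dx integrates to s0*x + (s1/2)*x**2 independently of the
path, the species means implied by a noiseless run lie exactly on a
quadratic with curvature s1/2: within-lineage slope decline is converted
into across-species curvature. Evolutionary residual noise (an independent
Brownian motion on brain), species-level slope heterogeneity, and
individual-level sampling noise are layered on top, so every downstream
model in this package can be exercised against known truth.

Default parameter values emulate the magnitudes seen in comparative
brain-size data: species means spanning a few log10 units of body mass,
species scatter around the allometry of ~0.25 log10 units, within-species
body ranges of ~0.15 log10 units, and widely scattered within-species
slopes.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from . import treeio
from .treeio import Tree

__all__ = [
    "MicroMacroConfig",
    "SyntheticDataset",
    "simulate_tree",
    "simulate_body_bm",
    "simulate_micro_macro",
    "simulate_individuals",
    "assign_subclades",
]


@dataclass
class MicroMacroConfig:
    """Ground-truth parameters of the micro-to-macro generative mechanism.

    Rates and variances are per million years on a tree rescaled to
    ``tree_depth`` My. ``sigma2_body`` and ``sigma2_resid`` are Brownian
    variances of log10 body mass and of the brain residual; the slope law
    is ``s(x) = s0 + s1 * x``.
    """

    n_species: int = 300
    birth_rate: float = 1.0
    death_rate: float = 0.0
    tree_depth: float = 100.0
    sigma2_body: float = 0.0225       # tip SD 1.5 log10 units at depth 100
    root_body: float = 1.5            # ~30 g
    root_brain: float = -0.4          # ~0.4 g at the root body mass
    s0: float = 0.6
    s1: float = -0.08
    sigma2_resid: float = 0.000625    # tip residual SD 0.25 log10 units
    species_resid_sd: float = 0.0     # non-phylogenetic species-level scatter
    n_individuals: int = 20
    within_body_sd: float = 0.15
    within_resid_sd: float = 0.05
    slope_noise_sd: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        for name in ("birth_rate", "death_rate", "sigma2_body", "sigma2_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def true_quadratic(self) -> float:
        """Macro curvature implied by the slope law (exactly s1 / 2)."""
        return self.s1 / 2.0


@dataclass
class SyntheticDataset:
    tree: Tree
    species: pd.DataFrame       # species, log10_body_g, log10_brain_g, class, subclade, true_slope
    individuals: pd.DataFrame   # species, log10_body_g, log10_brain_g, sex, method
    config: MicroMacroConfig

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "tree.nwk").write_text(treeio.write_newick(self.tree) + "\n")
        self.species.to_csv(out / "species.tsv", sep="\t", index=False)
        self.individuals.to_csv(out / "individuals.tsv", sep="\t", index=False)
        import json

        (out / "config.json").write_text(
            json.dumps(asdict(self.config), indent=2) + "\n"
        )


# ---------------------------------------------------------------------------
# Tree simulation
# ---------------------------------------------------------------------------

def simulate_tree(
    n_species: int,
    birth_rate: float = 1.0,
    death_rate: float = 0.0,
    depth: float = 100.0,
    seed: int = 0,
) -> Tree:
    """Birth-death tree with exactly ``n_species`` extant tips, rescaled to
    the requested crown depth.

    The birth-death process (dendropy) is stopped at the n-th extant tip;
    tip branches are then extended by the exponential waiting time to the
    next event so that no zero-length cherries remain, and the whole tree
    is rescaled so that the root-to-tip distance equals ``depth``.
    """
    if n_species < 2:
        raise ValueError("need at least two species")
    rng = _random.Random(seed)
    dtree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=death_rate,
        num_extant_tips=n_species,
        rng=rng,
    )
    extend = rng.expovariate(max(n_species * birth_rate, 1e-12))
    for leaf in dtree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extend
    tree = treeio.read_newick(dtree.as_string(schema="newick"))
    d = tree.depth()
    lengths = tree.lengths * (depth / d)
    tree = tree.with_lengths(lengths)
    # canonical tip names T001.. in the order dendropy assigned
    relabel = {
        lab: f"sp{k + 1:04d}" for k, lab in enumerate(sorted(tree.tip_labels))
    }
    labels = tuple(
        relabel[lab] if lab in relabel else lab for lab in tree.labels
    )
    return Tree(tree.parent, tree.lengths, labels)


def simulate_body_bm(
    tree: Tree, sigma2: float, root: float, rng=None, return_nodes: bool = False
):
    """Brownian motion of log10 body mass: tip values (tree.tip_labels
    order) with covariance ``sigma2 * vcv(tree)`` around ``root``."""
    rng = np.random.default_rng(rng)
    x = np.zeros(tree.n_nodes)
    x[tree.root] = root
    for v in tree.preorder():
        p = tree.parent[v]
        if p >= 0:
            x[v] = x[p] + rng.normal(0.0, np.sqrt(sigma2 * tree.lengths[v]))
    return x if return_nodes else x[tree.tips]


# ---------------------------------------------------------------------------
# Micro-to-macro simulation
# ---------------------------------------------------------------------------

def simulate_micro_macro(
    config: MicroMacroConfig,
    resid_var_scale=None,
    subclades: int | None = None,
) -> SyntheticDataset:
    """Simulate tree, species means, and individuals under the slope law.

    Along each branch the brain increment is the exact integral of
    ``s(x) dx`` between the parent and child body values plus a Brownian
    residual; with all noise off the species means therefore satisfy
    ``brain = const + s0*x + (s1/2)*x**2`` exactly.

    ``resid_var_scale`` optionally multiplies the residual Brownian
    variance per node's branch (indexed by child node), emulating lineages
    whose relative brain size evolves at elevated or depressed rates.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    tree = simulate_tree(
        cfg.n_species, cfg.birth_rate, cfg.death_rate, cfg.tree_depth,
        seed=int(rng.integers(2**31 - 1)),
    )
    if resid_var_scale is None:
        scale = np.ones(tree.n_nodes)
    else:
        scale = np.asarray(resid_var_scale, dtype=float)
        if scale.shape != (tree.n_nodes,):
            raise ValueError("resid_var_scale must have one entry per node")

    x = np.zeros(tree.n_nodes)  # log10 body
    b = np.zeros(tree.n_nodes)  # log10 brain
    x[tree.root] = cfg.root_body
    b[tree.root] = cfg.root_brain
    for v in tree.preorder():
        p = tree.parent[v]
        if p < 0:
            continue
        t = tree.lengths[v]
        dx = rng.normal(0.0, np.sqrt(cfg.sigma2_body * t))
        x[v] = x[p] + dx
        drift = cfg.s0 * dx + 0.5 * cfg.s1 * (x[v] ** 2 - x[p] ** 2)
        resid = rng.normal(0.0, np.sqrt(cfg.sigma2_resid * scale[v] * t))
        b[v] = b[p] + drift + resid

    tips = tree.tips
    xbar = x[tips]
    # non-phylogenetic species-level scatter (biological idiosyncrasy plus
    # compilation/measurement error); zero under a pure-Brownian run
    bbar = b[tips] + rng.normal(0.0, cfg.species_resid_sd, size=tips.size)
    true_slope = cfg.s0 + cfg.s1 * xbar + rng.normal(
        0.0, cfg.slope_noise_sd, size=xbar.size
    )
    labels = tree.tip_labels
    if subclades:
        sub = assign_subclades(tree, subclades)
        sub_col = [sub[l] for l in labels]
    else:
        sub_col = ["cladeA"] * len(labels)
    species = pd.DataFrame(
        {
            "species": labels,
            "log10_body_g": xbar,
            "log10_brain_g": bbar,
            "class": "synthetic",
            "subclade": sub_col,
            "true_slope": true_slope,
        }
    )
    individuals = simulate_individuals(species, cfg, rng=rng)
    return SyntheticDataset(tree, species, individuals, cfg)


def simulate_individuals(
    species: pd.DataFrame, config: MicroMacroConfig, rng=None
) -> pd.DataFrame:
    """Individual-level observations around each species mean.

    Bodies are Gaussian with the configured within-species SD and brains
    follow the species' true slope plus Gaussian residuals; both draws are
    recentred so that the sample means reproduce the species table
    exactly, matching the convention that the across-species component of
    a centred dataset is the observed species mean.
    """
    rng = np.random.default_rng(rng)
    cfg = config
    n = cfg.n_individuals
    rows = []
    sexes = np.array(["male", "female"])
    for rec in species.itertuples(index=False):
        w = rng.normal(0.0, cfg.within_body_sd, size=n)
        w -= w.mean()
        eps = rng.normal(0.0, cfg.within_resid_sd, size=n)
        eps -= eps.mean()
        body = rec.log10_body_g + w
        brain = rec.log10_brain_g + rec.true_slope * w + eps
        sex = sexes[rng.integers(0, 2, size=n)]
        method = "mass" if rng.random() < 0.5 else "volume"
        for j in range(n):
            rows.append(
                (rec.species, body[j], brain[j], sex[j], method)
            )
    return pd.DataFrame(
        rows,
        columns=["species", "log10_body_g", "log10_brain_g", "sex", "method"],
    )


def assign_subclades(tree: Tree, n_groups: int, min_size: int = 1) -> dict:
    """Partition the tips into up to ``n_groups`` groups of >= ``min_size``.

    The largest group is repeatedly split into its children clades; child
    clades smaller than ``min_size`` are merged into their smallest large
    sibling, so groups are clades except for occasional small leftover
    lineages attached to a neighbouring group. Stops early if nothing can
    be split further; groups are labelled g01, g02, ... largest first.
    """
    if n_groups < 1 or n_groups > tree.n_tips:
        raise ValueError("n_groups must be in [1, n_tips]")
    sizes = {}
    for v in tree.postorder():
        sizes[v] = 1 if tree.is_tip(v) else sum(sizes[c] for c in tree.children(v))
    # each group is a list of node ids whose union of tips forms the group
    groups: list = [[tree.root]]

    def gsize(g):
        return sum(sizes[v] for v in g)

    frozen: list = []
    while len(groups) < n_groups:
        cands = [
            i for i, g in enumerate(groups)
            if g not in frozen and any(not tree.is_tip(v) for v in g)
        ]
        if not cands:
            break
        i = max(cands, key=lambda i: gsize(groups[i]))
        g = groups[i]
        # descend through the group's largest clade; single-large-child
        # nodes are traversed so pectinate backbones do not deadlock
        v = max((u for u in g if not tree.is_tip(u)), key=lambda u: sizes[u])
        rest = [u for u in g if u != v]
        kids = tree.children(v)
        large = [c for c in kids if sizes[c] >= min_size]
        small = [c for c in kids if sizes[c] < min_size]
        if not large:
            frozen.append(g)
            continue
        new = [[c] for c in large]
        leftovers = small + rest
        if leftovers:
            smallest = min(range(len(new)), key=lambda j: gsize(new[j]))
            new[smallest].extend(leftovers)
        groups.pop(i)
        groups.extend(new)
    out = {}
    ordered = sorted(groups, key=gsize, reverse=True)
    for k, g in enumerate(ordered):
        stack = list(g)
        while stack:
            v = stack.pop()
            if tree.is_tip(v):
                out[tree.labels[v]] = f"g{k + 1:02d}"
            else:
                stack.extend(tree.children(v))
    return out
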
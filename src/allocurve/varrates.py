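"""Variable-rates phylogenetic regression by reversible-jump MCMC.

The Brownian residual covariance of the PGLS model is rescaled branch by
branch: each branch may carry a rate scalar r (r > 1 faster, 0 <= r < 1
slower than the background rate), so effective branch lengths are r * t.
A reversible-jump sampler explores which branches carry scalars and their
values jointly with the regression parameters.

Model choices (configurable): a log-normal(0, 1) prior on each placed
scalar, a geometric prior (success 0.5 per increment) on the number of
placed scalars, branch-local scalars only. Add/delete moves propose from
the scalar prior (independence reversible jump), so the Jacobian is
unity; value updates are multiplicative log-normal random walks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .mcmc import McmcSettings
from .pgls import RegressionDesign, PosteriorChain, _log_prior_sigma2
from .treeio import Tree, phylo_crossproducts

__all__ = [
    "RateConfiguration",
    "VariableRatesPrior",
    "scale_tree",
    "rjmcmc_variable_rates",
    "rate_summary",
    "VariableRatesEvidenceModel",
]


@dataclass
class RateConfiguration:
    """A set of placed branch scalars; branches are indexed by child node.

    Unplaced branches have implicit rate 1; the empty configuration is
    the homogeneous-rate model.
    """

    scalars: dict = field(default_factory=dict)

    def __post_init__(self):
        for b, r in self.scalars.items():
            if r <= 0:
                raise ValueError(f"rate scalar for branch {b} must be positive")

    @property
    def n_placed(self) -> int:
        return len(self.scalars)

    def as_vector(self, tree: Tree) -> np.ndarray:
        r = np.ones(tree.n_nodes)
        for b, v in self.scalars.items():
            if not 0 <= b < tree.n_nodes:
                raise ValueError(f"unknown branch id {b}")
            r[b] = v
        return r


def scale_tree(tree: Tree, config: RateConfiguration) -> Tree:
    """Multiply each branch length by its effective rate scalar."""
    return tree.with_lengths(tree.lengths * config.as_vector(tree))


@dataclass(frozen=True)
class VariableRatesPrior:
    geom_p: float = 0.5        # P(k+1)/P(k) for the number of scalars
    lognorm_sd: float = 1.0    # log-normal(0, sd) prior on each scalar
    regression_sd: float = 2.5

    def log_r_prior(self, r: float) -> float:
        z = np.log(r) / self.lognorm_sd
        return -0.5 * z * z - np.log(r * self.lognorm_sd * np.sqrt(2 * np.pi))


def _move_weights(k: int, n_unplaced: int):
    w = np.array(
        [
            0.3 if n_unplaced > 0 else 0.0,  # add
            0.3 if k > 0 else 0.0,           # delete
            0.4 if k > 0 else 0.0,           # update value
        ]
    )
    return w / w.sum()


class _RatesState:
    """Likelihood bookkeeping: Gaussian cross-products via tree peeling."""

    def __init__(self, design: RegressionDesign, tree: Tree, power: float):
        self.design = design
        self.tree = tree
        self.U = np.column_stack([design.X, design.y])
        self.power = power
        self.const = -0.5 * design.n * np.log(2 * np.pi)

    def crossproducts(self, rates):
        M, logdet = phylo_crossproducts(self.tree, self.U, rates)
        p = self.design.p
        return M[:p, :p], M[:p, p], M[p, p], logdet

    def loglik(self, XtX, Xty, yty, logdet, beta, sigma2):
        q = yty - 2.0 * beta @ Xty + beta @ XtX @ beta
        return self.const - 0.5 * (
            self.design.n * np.log(sigma2) + logdet + q / sigma2
        )


def rjmcmc_variable_rates(
    design: RegressionDesign,
    tree: Tree,
    prior: VariableRatesPrior | None = None,
    settings: McmcSettings | None = None,
    power: float = 1.0,
    likelihood_off: bool = False,
    update_step: float = 0.7,
) -> PosteriorChain:
    """Joint posterior over regression parameters, scale, and branch-rate
    configuration.

    Per iteration: a conjugate Gibbs draw of beta, two Metropolis steps
    on log sigma2, and one reversible-jump move (add / delete / update a
    scalar). ``power`` tempers the likelihood (used by stepping-stone
    evidence); ``likelihood_off`` samples the prior, which is used to
    validate detailed balance of the jump moves.

    Returns a :class:`PosteriorChain` whose ``extras`` hold per-sample
    configurations, per-branch posterior mean effective rates (unplaced
    branches count as r = 1), placement probabilities, and the RJ
    acceptance rate.
    """
    prior = prior or VariableRatesPrior()
    settings = settings or McmcSettings(iterations=20_000, burnin=4_000, thin=8)
    rng = np.random.default_rng(settings.seed)
    n, p = design.n, design.p
    branches = [v for v in range(tree.n_nodes) if tree.parent[v] >= 0]
    state = _RatesState(design, tree, power)

    rates = np.ones(tree.n_nodes)
    placed: dict = {}
    XtX, Xty, yty, logdet = state.crossproducts(rates)
    if likelihood_off:
        power = 0.0
    eff = power

    beta = np.zeros(p)
    sigma2 = 1.0
    prior_prec = np.eye(p) / prior.regression_sd**2

    n_keep = settings.n_samples
    keep_beta = np.empty((n_keep, p))
    keep_s2 = np.empty(n_keep)
    keep_k = np.empty(n_keep, dtype=int)
    configs: list = []
    rate_sum = np.zeros(tree.n_nodes)
    place_count = np.zeros(tree.n_nodes)
    k_out = 0
    rj_prop = 0
    rj_acc = 0

    def log_target(XtX_, Xty_, yty_, logdet_, b_, s2_):
        if eff == 0.0:
            return 0.0
        return eff * state.loglik(XtX_, Xty_, yty_, logdet_, b_, s2_)

    for it in range(settings.iterations):
        # ---- beta | rest (conjugate under the tempered likelihood)
        if eff == 0.0:
            beta = prior.regression_sd * rng.standard_normal(p)
        else:
            A = eff * XtX / sigma2 + prior_prec
            cf = np.linalg.cholesky(A)
            mean = np.linalg.solve(A, eff * Xty / sigma2)
            beta = mean + linalg.solve_triangular(
                cf, rng.standard_normal(p), lower=True, trans="T"
            )
        # ---- sigma2 | rest (Metropolis on log sigma2)
        q = yty - 2.0 * beta @ Xty + beta @ XtX @ beta
        for _ in range(2):
            prop = sigma2 * np.exp(0.6 * rng.normal())
            cur = (
                -0.5 * eff * (n * np.log(sigma2) + q / sigma2)
                + _log_prior_sigma2(sigma2) + np.log(sigma2)
            )
            new = (
                -0.5 * eff * (n * np.log(prop) + q / prop)
                + _log_prior_sigma2(prop) + np.log(prop)
            )
            if np.log(rng.random()) < new - cur:
                sigma2 = prop
        # ---- reversible-jump move on the configuration
        k = len(placed)
        n_un = len(branches) - k
        w = _move_weights(k, n_un)
        move = rng.choice(3, p=w)
        rj_prop += 1
        ll_cur = 0.0 if eff == 0.0 else log_target(XtX, Xty, yty, logdet, beta, sigma2)
        if move == 0:  # add
            unplaced = [b for b in branches if b not in placed]
            b = unplaced[rng.integers(len(unplaced))]
            r_new = float(np.exp(prior.lognorm_sd * rng.normal()))
            rates_new = rates.copy()
            rates_new[b] = r_new
            if eff == 0.0:
                Xn, xn, yn, ldn = XtX, Xty, yty, logdet
                ll_new = 0.0
            else:
                Xn, xn, yn, ldn = state.crossproducts(rates_new)
                ll_new = log_target(Xn, xn, yn, ldn, beta, sigma2)
            # prior over configurations: Geometric(k) x uniform over the
            # C(B, k) branch subsets x iid scalar values; the subset and
            # branch-pick factors cancel, leaving only the move weights
            w_rev = _move_weights(k + 1, n_un - 1)
            log_alpha = (
                ll_new - ll_cur
                + np.log(prior.geom_p)
                + np.log(w_rev[1])
                - np.log(w[0])
            )
            if np.log(rng.random()) < log_alpha:
                placed[b] = r_new
                rates, XtX, Xty, yty, logdet = rates_new, Xn, xn, yn, ldn
                rj_acc += 1
        elif move == 1:  # delete
            keys = list(placed)
            b = keys[rng.integers(len(keys))]
            rates_new = rates.copy()
            rates_new[b] = 1.0
            if eff == 0.0:
                Xn, xn, yn, ldn = XtX, Xty, yty, logdet
                ll_new = 0.0
            else:
                Xn, xn, yn, ldn = state.crossproducts(rates_new)
                ll_new = log_target(Xn, xn, yn, ldn, beta, sigma2)
            w_rev = _move_weights(k - 1, n_un + 1)
            log_alpha = (
                ll_new - ll_cur
                - np.log(prior.geom_p)
                + np.log(w_rev[0])
                - np.log(w[1])
            )
            if np.log(rng.random()) < log_alpha:
                del placed[b]
                rates, XtX, Xty, yty, logdet = rates_new, Xn, xn, yn, ldn
                rj_acc += 1
        else:  # update a scalar value
            keys = list(placed)
            b = keys[rng.integers(len(keys))]
            r_old = placed[b]
            r_new = r_old * np.exp(update_step * rng.normal())
            rates_new = rates.copy()
            rates_new[b] = r_new
            if eff == 0.0:
                Xn, xn, yn, ldn = XtX, Xty, yty, logdet
                ll_new = 0.0
            else:
                Xn, xn, yn, ldn = state.crossproducts(rates_new)
                ll_new = log_target(Xn, xn, yn, ldn, beta, sigma2)
            log_alpha = (
                ll_new - ll_cur
                + prior.log_r_prior(r_new) - prior.log_r_prior(r_old)
                + np.log(r_new / r_old)  # Hastings ratio of the log-scale walk
            )
            if np.log(rng.random()) < log_alpha:
                placed[b] = r_new
                rates, XtX, Xty, yty, logdet = rates_new, Xn, xn, yn, ldn
                rj_acc += 1
        # ---- retain
        if it >= settings.burnin and (it - settings.burnin) % settings.thin == 0:
            keep_beta[k_out] = beta
            keep_s2[k_out] = sigma2
            keep_k[k_out] = len(placed)
            configs.append(dict(placed))
            rate_sum += rates
            for b in placed:
                place_count[b] += 1
            k_out += 1

    accept_rate = rj_acc / max(rj_prop, 1)
    extras = {
        "configs": configs,
        "n_scalars": keep_k[:k_out],
        "mean_rates": rate_sum / max(k_out, 1),
        "placement_prob": place_count / max(k_out, 1),
        "rj_accept_rate": accept_rate,
        "acceptance_collapse": accept_rate < 0.01,
        "tree": tree,
    }
    return PosteriorChain(
        names=list(design.names),
        beta=keep_beta[:k_out],
        sigma2=keep_s2[:k_out],
        settings=settings,
        extras=extras,
    )


def rate_summary(chain: PosteriorChain) -> pd.DataFrame:
    """Per-branch summary of effective rates over the retained samples.

    The mean includes samples in which the branch carries no scalar
    (effective r = 1), giving the posterior mean evolutionary rate of
    each branch relative to background.
    """
    tree: Tree = chain.extras["tree"]
    configs = chain.extras["configs"]
    n_s = len(configs)
    branches = [v for v in range(tree.n_nodes) if tree.parent[v] >= 0]
    draws = np.ones((n_s, len(branches)))
    col = {b: j for j, b in enumerate(branches)}
    for i, cfg in enumerate(configs):
        for b, r in cfg.items():
            draws[i, col[b]] = r
    lo, hi = np.quantile(draws, [0.025, 0.975], axis=0)
    # tips below each branch, as a stable identifier
    below = {}
    for v in tree.postorder():
        below[v] = (
            [tree.labels[v]]
            if tree.is_tip(v)
            else sorted(sum((below[c] for c in tree.children(v)), []))
        )
    return pd.DataFrame(
        {
            "branch": branches,
            "is_tip": [tree.is_tip(b) for b in branches],
            "n_tips_below": [len(below[b]) for b in branches],
            "first_tip_below": [below[b][0] for b in branches],
            "mean_r": draws.mean(axis=0),
            "r_l95": lo,
            "r_u95": hi,
            "placement_prob": chain.extras["placement_prob"][branches],
        }
    ).set_index("branch")


class VariableRatesEvidenceModel:
    """Stepping-stone adapter: runs a tempered RJ chain per stone.

    Expensive relative to the fixed-rate evidence model (a full peeling
    per iteration); intended for modest trees and short per-stone chains.
    """

    def __init__(
        self,
        design: RegressionDesign,
        tree: Tree,
        prior: VariableRatesPrior | None = None,
        base_seed: int = 0,
    ):
        self.design = design
        self.tree = tree
        self.prior = prior or VariableRatesPrior()
        self.base_seed = base_seed
        self._stone = 0
        self._state = _RatesState(design, tree, 1.0)

    def sample_power(self, power, n_samples, n_burn, rng) -> np.ndarray:
        self._stone += 1
        settings = McmcSettings(
            iterations=n_burn + n_samples,
            burnin=n_burn,
            thin=1,
            seed=int(rng.integers(2**31 - 1)),
        )
        chain = rjmcmc_variable_rates(
            self.design, self.tree, self.prior, settings, power=power
        )
        out = np.empty(len(chain.beta))
        for i, cfg in enumerate(chain.extras["configs"]):
            rates = RateConfiguration(cfg).as_vector(self.tree)
            XtX, Xty, yty, logdet = self._state.crossproducts(rates)
            out[i] = self._state.loglik(
                XtX, Xty, yty, logdet, chain.beta[i], chain.sigma2[i]
            )
        return out
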
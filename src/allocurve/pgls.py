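"""Phylogenetic generalized least squares (PGLS).

Regression of log10 brain mass on log10 body mass (and its square, and
deviation-coded group terms) with residual covariance proportional to the
Brownian tip covariance of a phylogeny. Provides the exact Gaussian
log-likelihood, Pagel's lambda transform, profile-ML fitting, and a
Bayesian Gibbs/Metropolis sampler under wide Normal(0, 2.5^2) priors on
all regression parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .mcmc import McmcSettings, px, split_rhat, summarize

__all__ = [
    "RegressionDesign",
    "PosteriorChain",
    "MlFit",
    "MODELS",
    "deviation_code",
    "build_design",
    "lambda_transform",
    "gls_loglik",
    "fit_pgls_ml",
    "fit_pgls_bayes",
]

MODELS = (
    "global_slope",
    "global_curve",
    "class_slope",
    "class_curve",
    "subclade_slope",
    "subclade_curve",
)


@dataclass
class RegressionDesign:
    """Response, design matrix, and column metadata for one model.

    Rows are species, in the order of ``labels``; this order must match
    the tip order of any covariance matrix used with the design.
    """

    y: np.ndarray
    X: np.ndarray
    names: list
    labels: list
    groups: list = field(default_factory=list)  # deviation-coding group order

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y row counts differ")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("design matrix is rank deficient")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def deviation_code(group_labels) -> tuple:
    """Sum-contrast (deviation) coding.

    Returns an (n, K-1) matrix and the ordered group list. Rows of group
    k < K get an indicator 1 in column k; rows of the last group get -1
    everywhere, so fitted group effects are deviations from the grand
    mean and sum to zero across the K groups (the last group's effect is
    minus the sum of the coded ones).
    """
    labels = pd.Series(group_labels).astype(str)
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("deviation coding needs at least two groups")
    K = len(groups)
    cols = np.zeros((len(labels), K - 1))
    for k, g in enumerate(groups[:-1]):
        cols[labels.values == g, k] = 1.0
    cols[labels.values == groups[-1], :] = -1.0
    return cols, groups


def deviation_effects(coefs, groups) -> pd.Series:
    """Recover all K group deviations (summing to zero) from the K-1
    deviation-coded coefficients."""
    coefs = np.asarray(coefs, dtype=float)
    full = np.append(coefs, -coefs.sum())
    return pd.Series(full, index=list(groups))


def build_design(
    species: pd.DataFrame, model: str, group_col: str | None = None
) -> RegressionDesign:
    """Assemble the design matrix for one of the named BBM models.

    ``global_slope``/``global_curve`` fit a single line/quadratic;
    ``class_*`` and ``subclade_*`` add deviation-coded group intercepts
    and interactions so every group effect is a contrast with the grand
    mean. The quadratic term is the square of uncentred log10 body mass.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model '{model}'; choose from {MODELS}")
    x = species["log10_body_g"].to_numpy(dtype=float)
    y = species["log10_brain_g"].to_numpy(dtype=float)
    cols = [np.ones_like(x), x]
    names = ["intercept", "body"]
    curve = model.endswith("curve")
    if curve:
        cols.append(x**2)
        names.append("body2")
    groups: list = []
    if model.startswith(("class", "subclade")):
        gc = group_col or ("class" if model.startswith("class") else "subclade")
        dev, groups = deviation_code(species[gc])
        for k, g in enumerate(groups[:-1]):
            cols.append(dev[:, k])
            names.append(f"dev_int[{g}]")
        for k, g in enumerate(groups[:-1]):
            cols.append(dev[:, k] * x)
            names.append(f"dev_body[{g}]")
        if curve:
            for k, g in enumerate(groups[:-1]):
                cols.append(dev[:, k] * x**2)
                names.append(f"dev_body2[{g}]")
    return RegressionDesign(
        y=y, X=np.column_stack(cols), names=names,
        labels=species["species"].tolist(), groups=groups,
    )


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def _chol(V: np.ndarray):
    try:
        return linalg.cho_factor(V, lower=True)
    except linalg.LinAlgError as exc:
        raise ValueError(
            "phylogenetic covariance matrix is singular or not positive "
            "definite (check for duplicated tips / zero-length cherries)"
        ) from exc


def gls_loglik(design: RegressionDesign, V: np.ndarray, beta, sigma2: float) -> float:
    """Exact log density of y under Normal(X beta, sigma2 * V).

    Evaluated through a Cholesky factorization of V; no explicit inverse
    is ever formed.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    c = _chol(V)
    r = design.y - design.X @ np.asarray(beta, dtype=float)
    w = linalg.cho_solve(c, r)
    n = design.n
    logdet = 2.0 * np.sum(np.log(np.diag(c[0])))
    quad = float(r @ w)
    return -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + quad / sigma2)


def lambda_transform(V: np.ndarray, lam: float) -> np.ndarray:
    """Pagel's lambda: multiply off-diagonal covariance by ``lam``.

    lambda = 1 leaves the Brownian covariance unchanged; lambda = 0 is a
    star phylogeny (no phylogenetic signal).
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    out = lam * np.asarray(V, dtype=float)
    np.fill_diagonal(out, np.diag(V))
    return out


# ---------------------------------------------------------------------------
# Maximum likelihood
# ---------------------------------------------------------------------------

@dataclass
class MlFit:
    """Profile-ML PGLS fit: coefficient table with two-tailed t tests,
    the ML lambda (if estimated), and the profiled variance scale."""

    coef: pd.DataFrame
    lambda_hat: float
    sigma2: float
    loglik: float
    converged: bool
    design: RegressionDesign


def _profile_ml(design: RegressionDesign, V: np.ndarray):
    c = _chol(V)
    L = np.tril(c[0])
    Xw = linalg.solve_triangular(L, design.X, lower=True)
    yw = linalg.solve_triangular(L, design.y, lower=True)
    beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    n = design.n
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    sigma2 = rss / n
    ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    return beta, sigma2, ll, Xw, rss


def fit_pgls_ml(
    design: RegressionDesign,
    V: np.ndarray,
    estimate_lambda: bool = True,
    lam: float | None = None,
) -> MlFit:
    """PGLS by profile maximum likelihood.

    beta and sigma2 are profiled analytically; lambda (phylogenetic
    signal) is optimized over [0, 1] by bounded 1-D search unless fixed
    via ``lam``. Standard errors use the residual-df variance estimate
    and two-tailed t tests, as in standard comparative-methods software.
    """
    if design.n < design.p + 2:
        raise ValueError("need at least p + 2 observations")
    converged = True
    if lam is not None:
        lam_hat = float(lam)
    elif estimate_lambda:
        def neg(l):
            return -_profile_ml(design, lambda_transform(V, l))[2]

        res = optimize.minimize_scalar(
            neg, bounds=(0.0, 1.0), method="bounded",
            options={"xatol": 1e-6},
        )
        # bounded search can miss a boundary optimum on flat profiles
        cands = [(res.x, -neg(res.x)), (0.0, -neg(0.0)), (1.0, -neg(1.0))]
        lam_hat = max(cands, key=lambda t: t[1])[0]
        converged = bool(res.success)
    else:
        lam_hat = 1.0
    Vl = lambda_transform(V, lam_hat)
    beta, sigma2, ll, Xw, rss = _profile_ml(design, Vl)
    n, p = design.n, design.p
    s2_unbiased = rss / (n - p)
    cov = s2_unbiased * np.linalg.inv(Xw.T @ Xw)
    se = np.sqrt(np.diag(cov))
    tval = beta / se
    pval = 2.0 * stats.t.sf(np.abs(tval), df=n - p)
    coef = pd.DataFrame(
        {"estimate": beta, "se": se, "t": tval, "p": pval}, index=design.names
    )
    return MlFit(coef, float(lam_hat), float(sigma2), float(ll), converged, design)


# ---------------------------------------------------------------------------
# Bayesian sampler
# ---------------------------------------------------------------------------

@dataclass
class PosteriorChain:
    """Thinned posterior samples of regression parameters and the scale.

    ``beta`` is (n_samples, p) in ``names`` order; ``extras`` may hold
    per-sample rate configurations or other model-specific state.
    """

    names: list
    beta: np.ndarray
    sigma2: np.ndarray
    settings: McmcSettings
    extras: dict = field(default_factory=dict)

    def samples(self) -> dict:
        out = {n: self.beta[:, j] for j, n in enumerate(self.names)}
        out["sigma2"] = self.sigma2
        return out

    def summary(self) -> pd.DataFrame:
        tab = summarize(self.samples())
        tab.attrs["divergent"] = bool((tab["rhat"] > 1.1).any())
        return tab

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.beta, columns=self.names)
        df["sigma2"] = self.sigma2
        df.insert(0, "sample", np.arange(len(df)))
        return df


_HALF_CAUCHY_SCALE = 5.0


def _log_prior_sigma2(s2: float, scale: float = _HALF_CAUCHY_SCALE) -> float:
    # half-Cauchy(0, scale) on sigma, transformed to sigma^2
    sig = np.sqrt(s2)
    return -np.log1p((sig / scale) ** 2) - np.log(2.0 * sig)


def fit_pgls_bayes(
    design: RegressionDesign,
    V: np.ndarray,
    prior_sd: float = 2.5,
    settings: McmcSettings | None = None,
    likelihood_off: bool = False,
) -> PosteriorChain:
    """Bayesian PGLS under Normal(0, prior_sd^2) priors on all regression
    parameters and a half-Cauchy(0, 5) prior on the residual scale.

    beta is updated by conjugate blocked Gibbs draws given sigma2; sigma2
    by a random-walk Metropolis step on log sigma2. ``likelihood_off``
    disables the data term so the chain samples the prior (a standard
    sampler validation).
    """
    settings = settings or McmcSettings()
    rng = np.random.default_rng(settings.seed)
    n, p = design.n, design.p
    c = _chol(V)
    L = np.tril(c[0])
    Xw = linalg.solve_triangular(L, design.X, lower=True)
    yw = linalg.solve_triangular(L, design.y, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    XtX = Xw.T @ Xw
    Xty = Xw.T @ yw
    yty = float(yw @ yw)
    if likelihood_off:
        XtX = np.zeros_like(XtX)
        Xty = np.zeros_like(Xty)
        yty = 0.0
        n_eff = 0
    else:
        n_eff = n

    # one-time eigendecomposition: the conditional precision of beta is
    # XtX / sigma2 + I / prior_sd^2 = Q (D / sigma2 + I / prior_sd^2) Q',
    # so every Gibbs draw is O(p^2)
    D, Q = np.linalg.eigh(XtX)
    D = np.clip(D, 0.0, None)
    Qt_Xty = Q.T @ Xty
    beta = np.zeros(p)
    sigma2 = 1.0
    keep_beta = np.empty((settings.n_samples, p))
    keep_s2 = np.empty(settings.n_samples)
    k = 0
    step = 0.6

    def quad(b):
        return yty - 2.0 * b @ Xty + b @ XtX @ b

    for it in range(settings.iterations):
        # beta | sigma2: conjugate normal
        d = D / sigma2 + 1.0 / prior_sd**2
        mean = Qt_Xty / sigma2 / d
        z = rng.standard_normal(p)
        beta = Q @ (mean + z / np.sqrt(d))
        # sigma2: Metropolis on log sigma2
        q = quad(beta)
        for _ in range(2):
            prop = sigma2 * np.exp(step * rng.normal())
            cur = (
                -0.5 * (n_eff * np.log(sigma2) + q / sigma2)
                + _log_prior_sigma2(sigma2)
                + np.log(sigma2)
            )
            new = (
                -0.5 * (n_eff * np.log(prop) + q / prop)
                + _log_prior_sigma2(prop)
                + np.log(prop)
            )
            if np.log(rng.random()) < new - cur:
                sigma2 = prop
        if it >= settings.burnin and (it - settings.burnin) % settings.thin == 0:
            keep_beta[k] = beta
            keep_s2[k] = sigma2
            k += 1
    return PosteriorChain(
        names=list(design.names),
        beta=keep_beta[:k],
        sigma2=keep_s2[:k],
        settings=settings,
    )
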
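"""Shared MCMC plumbing: settings, posterior summaries, p_x, and R-hat."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["McmcSettings", "px", "split_rhat", "summarize"]


@dataclass(frozen=True)
class McmcSettings:
    """Chain length settings; a seed is always required.

    Defaults are desk-scale: long enough for stable p_x estimates of
    strongly identified regression parameters while keeping a full
    multi-model analysis in minutes.
    """

    iterations: int = 200_000
    burnin: int = 20_000
    thin: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.burnin >= self.iterations:
            raise ValueError("burnin must be smaller than iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_samples(self) -> int:
        return -((self.iterations - self.burnin) // -self.thin)


def px(samples) -> float:
    """Proportion of the posterior on the opposite side of zero from the
    posterior median (two-sided tail mass at zero; at most 0.5).

    Values below 0.05 indicate a parameter credibly different from zero.
    """
    s = np.asarray(samples, dtype=float)
    if s.size == 0:
        raise ValueError("need at least one sample")
    med = np.median(s)
    if med >= 0:
        p = float(np.mean(s < 0))
    else:
        p = float(np.mean(s > 0))
    return min(p, 0.5)


def split_rhat(samples) -> float:
    """Split-chain potential scale reduction factor for a single chain."""
    s = np.asarray(samples, dtype=float)
    n = s.size // 2
    if n < 2:
        return np.nan
    halves = np.stack([s[:n], s[s.size - n:]])
    within = halves.var(axis=1, ddof=1).mean()
    between = n * halves.mean(axis=1).var(ddof=1)
    if within == 0:
        return 1.0 if between == 0 else np.inf
    var_plus = (n - 1) / n * within + between / n
    return float(np.sqrt(var_plus / within))


def summarize(samples: dict) -> pd.DataFrame:
    """Posterior summary table: median, mean, central 95% interval, p_x,
    and split R-hat, one row per named parameter."""
    rows = []
    for name, s in samples.items():
        s = np.asarray(s, dtype=float)
        lo, hi = np.quantile(s, [0.025, 0.975])
        rows.append(
            {
                "parameter": name,
                "median": float(np.median(s)),
                "mean": float(np.mean(s)),
                "l95": float(lo),
                "u95": float(hi),
                "px": px(s),
                "rhat": split_rhat(s),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")
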
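"""Derived allometric quantities from fitted brain-body curves.

Expected change in relative brain size along the body-size axis, brain
mass predictions (with back-transformation to grams), the percentage by
which a curved fit shrinks a linear extrapolation, and the subclade
slope-versus-size meta-regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import treeio
from .pgls import MlFit, RegressionDesign, fit_pgls_ml
from .treeio import Tree

__all__ = [
    "CurveCoefficients",
    "expected_change",
    "predict_brain",
    "percent_reduction",
    "slope_size_metaregression",
    "representative_group_tree",
]


@dataclass(frozen=True)
class CurveCoefficients:
    """Quadratic log-log allometry: log10 brain = alpha + b1 x + b2 x^2,
    with x = log10 body mass (g). b2 = 0 encodes a pure slope model."""

    alpha: float
    beta1: float
    beta2: float = 0.0

    def __post_init__(self):
        for v in (self.alpha, self.beta1, self.beta2):
            if not np.isfinite(v):
                raise ValueError("coefficients must be finite")


def expected_change(c: CurveCoefficients, x, window: float | None = None):
    """Expected change in brain per unit body (d log10 brain / d log10 body).

    The analytic derivative b1 + 2 b2 x of the quadratic; under a pure
    slope model this is constant. With ``window`` given, returns the
    symmetric finite-difference version over ``x +/- window/2`` instead
    (identical for a quadratic up to rounding; provided for comparison
    with windowed empirical estimates).
    """
    x = np.asarray(x, dtype=float)
    if window is None:
        out = c.beta1 + 2.0 * c.beta2 * x
    else:
        h = window / 2.0
        out = (predict_brain(c, x + h)[0] - predict_brain(c, x - h)[0]) / window
    return out if out.shape else float(out)


def predict_brain(c: CurveCoefficients, x):
    """Predicted log10 brain mass and its back-transform in grams."""
    x = np.asarray(x, dtype=float)
    log10_brain = c.alpha + c.beta1 * x + c.beta2 * x**2
    grams = np.power(10.0, log10_brain)
    if log10_brain.shape:
        return log10_brain, grams
    return float(log10_brain), float(grams)


def percent_reduction(linear_pred_g, curve_pred_g) -> float:
    """Percent by which the curved prediction undercuts the linear one.

    100 * (linear - curve) / linear, on the gram scale. E.g. a linear
    extrapolation of 12 kg reduced to 7 kg is a 41.7% reduction.
    """
    lin = float(linear_pred_g)
    cur = float(curve_pred_g)
    if lin <= 0 or cur < 0:
        raise ValueError("predictions must be positive masses")
    return 100.0 * (lin - cur) / lin


def representative_group_tree(
    tree: Tree, species: pd.DataFrame, group_col: str = "subclade", seed: int = 0
) -> Tree:
    """Group-level tree: prune to one randomly chosen (seeded)
    representative species per group and relabel tips by group."""
    rng = np.random.default_rng(seed)
    reps = {}
    for g, block in species.groupby(group_col):
        sp = sorted(block["species"])
        reps[sp[rng.integers(len(sp))]] = str(g)
    sub = treeio.keep_tips(tree, list(reps))
    labels = tuple(
        reps.get(lab, lab) if lab is not None else None for lab in sub.labels
    )
    return Tree(sub.parent, sub.lengths, labels)


def slope_size_metaregression(
    groups: pd.DataFrame, group_tree: Tree
) -> MlFit:
    """Lambda-ML PGLS of group-level allometric slope on median body size.

    ``groups`` needs columns ``group``, ``slope`` and ``median_body``
    (log10 g); every group must be a tip label of ``group_tree``. A
    negative fitted coefficient means larger-bodied groups have shallower
    brain-body slopes.
    """
    required = {"group", "slope", "median_body"}
    if not required.issubset(groups.columns):
        raise ValueError(f"groups table needs columns {sorted(required)}")
    if len(groups) < 5:
        raise ValueError("need at least five groups")
    tips = set(group_tree.tip_labels)
    missing = sorted(set(groups["group"].astype(str)) - tips)
    if missing:
        raise ValueError(f"groups missing from tree: {missing[:5]}")
    order = groups.set_index("group")
    labels = [l for l in group_tree.tip_labels if l in order.index]
    sub = treeio.keep_tips(group_tree, labels)
    order = order.loc[sub.tip_labels]
    design = RegressionDesign(
        y=order["slope"].to_numpy(float),
        X=np.column_stack(
            [np.ones(len(order)), order["median_body"].to_numpy(float)]
        ),
        names=["intercept", "median_body"],
        labels=list(order.index),
    )
    V = treeio.vcv(sub)
    return fit_pgls_ml(design, V, estimate_lambda=True)
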
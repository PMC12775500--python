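"""Phylogeny input/output and Brownian-motion covariance construction.

Trees are rooted, with branch lengths in units of time (millions of years
for empirical trees). Branches are indexed by their *child* node id, so a
tree with ``n_nodes`` nodes has ``n_nodes - 1`` branches (the root carries
a zero-length pseudo-branch that is ignored everywhere).

The module provides the standard Brownian variance-covariance matrix of
tip values, optionally under per-branch rate scalars, plus an O(n) peeling
(pruning) algorithm for Gaussian quadratic forms that never builds the
dense covariance.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Tree",
    "TreeError",
    "NewickParseError",
    "read_newick",
    "write_newick",
    "is_ultrametric",
    "ensure_ultrametric",
    "prune_short_terminal_clades",
    "keep_tips",
    "vcv",
    "phylo_crossproducts",
]


class TreeError(ValueError):
    pass


class NewickParseError(TreeError):
    pass


@dataclass(frozen=True)
class Tree:
    """Rooted phylogeny stored as parent pointers.

    Attributes
    ----------
    parent : (n_nodes,) int array, -1 for the root.
    lengths : (n_nodes,) float array; ``lengths[i]`` is the branch above
        node ``i`` (0.0 for the root).
    labels : tuple of str or None per node; every tip must be labelled.
    """

    parent: np.ndarray
    lengths: np.ndarray
    labels: tuple

    def __post_init__(self):
        parent = np.asarray(self.parent, dtype=np.int64)
        lengths = np.asarray(self.lengths, dtype=float)
        object.__setattr__(self, "parent", parent)
        object.__setattr__(self, "lengths", lengths)
        n = parent.shape[0]
        if lengths.shape != (n,) or len(self.labels) != n:
            raise TreeError("parent, lengths and labels must have equal length")
        roots = np.flatnonzero(parent < 0)
        if roots.size != 1:
            raise TreeError(f"tree must have exactly one root, found {roots.size}")
        if np.any(lengths < 0):
            raise TreeError("negative branch length")
        # children lists and a postorder traversal, cached once
        children = [[] for _ in range(n)]
        for i in range(n):
            if parent[i] >= 0:
                children[parent[i]].append(i)
        tips = [i for i in range(n) if not children[i]]
        tip_labels = [self.labels[i] for i in tips]
        if any(lab is None for lab in tip_labels):
            raise TreeError("every tip must carry a label")
        if len(set(tip_labels)) != len(tip_labels):
            raise TreeError("tip labels must be unique")
        order = []
        stack = [int(roots[0])]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(children[v])
        object.__setattr__(self, "_children", children)
        object.__setattr__(self, "_preorder", np.array(order, dtype=np.int64))
        object.__setattr__(self, "_tips", np.array(tips, dtype=np.int64))
        # flat child arrays for the compiled peeling kernel
        ptr = np.zeros(n + 1, dtype=np.int64)
        flat = np.empty(max(n - 1, 0), dtype=np.int64)
        pos = 0
        for i in range(n):
            ptr[i] = pos
            for c in children[i]:
                flat[pos] = c
                pos += 1
        ptr[n] = pos
        tip_row = np.full(n, -1, dtype=np.int64)
        for k, t in enumerate(tips):
            tip_row[t] = k
        object.__setattr__(self, "_child_ptr", ptr)
        object.__setattr__(self, "_child_flat", flat)
        object.__setattr__(self, "_tip_row", tip_row)

    # -- basic accessors ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.parent.shape[0]

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    @property
    def tips(self) -> np.ndarray:
        return self._tips

    @property
    def n_tips(self) -> int:
        return self._tips.size

    @property
    def tip_labels(self) -> list:
        return [self.labels[i] for i in self._tips]

    def children(self, node: int) -> list:
        return self._children[node]

    def preorder(self) -> np.ndarray:
        return self._preorder

    def postorder(self) -> np.ndarray:
        return self._preorder[::-1]

    def is_tip(self, node: int) -> bool:
        return not self._children[node]

    def with_lengths(self, lengths) -> "Tree":
        return Tree(self.parent.copy(), np.asarray(lengths, float), self.labels)

    # -- derived quantities ------------------------------------------------
    def node_depths(self, rates=None) -> np.ndarray:
        """Root-to-node path lengths, optionally with branch-rate scaling."""
        lens = self.lengths if rates is None else self.lengths * _as_rates(self, rates)
        depth = np.zeros(self.n_nodes)
        for v in self._preorder:
            p = self.parent[v]
            if p >= 0:
                depth[v] = depth[p] + lens[v]
        return depth

    def tip_depths(self, rates=None) -> np.ndarray:
        return self.node_depths(rates)[self._tips]

    def depth(self) -> float:
        return float(self.tip_depths().max())


def _as_rates(tree: Tree, rates) -> np.ndarray:
    r = np.asarray(rates, dtype=float)
    if r.shape != (tree.n_nodes,):
        raise TreeError(
            f"rate vector length {r.shape} does not match node count {tree.n_nodes}"
        )
    if np.any(r < 0):
        raise TreeError("rate scalars must be nonnegative")
    return r


# ---------------------------------------------------------------------------
# Newick I/O (parsing delegated to dendropy)
# ---------------------------------------------------------------------------

def read_newick(text: str) -> Tree:
    """Parse a Newick string into a :class:`Tree`.

    Branch lengths are required on every non-root branch; a root edge
    length, if present, is discarded (it is shared by all tips and carries
    no information for the Brownian covariance).
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"could not parse Newick: {exc}") from exc
    nodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    parent = np.full(len(nodes), -1, dtype=np.int64)
    lengths = np.zeros(len(nodes))
    labels: list = [None] * len(nodes)
    for i, nd in enumerate(nodes):
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            if nd.edge.length is None:
                raise NewickParseError(
                    f"missing branch length on edge above node {i}"
                )
            lengths[i] = float(nd.edge.length)
        if nd.is_leaf():
            if nd.taxon is None or nd.taxon.label is None:
                raise NewickParseError("unlabelled tip")
            labels[i] = nd.taxon.label
        elif nd.label:
            labels[i] = nd.label
    return Tree(parent, lengths, tuple(labels))


def write_newick(tree: Tree) -> str:
    """Serialise to Newick with branch lengths (root edge omitted)."""
    out = io.StringIO()

    def rec(node: int):
        kids = tree.children(node)
        if kids:
            out.write("(")
            for j, k in enumerate(kids):
                if j:
                    out.write(",")
                rec(k)
            out.write(")")
            if tree.labels[node]:
                out.write(_quote(tree.labels[node]))
        else:
            out.write(_quote(tree.labels[node]))
        if tree.parent[node] >= 0:
            out.write(f":{tree.lengths[node]:.10g}")

    rec(tree.root)
    out.write(";")
    return out.getvalue()


_NEWICK_UNSAFE = set(" ()[]{}:;,'\"")


def _quote(label: str) -> str:
    if any(c in _NEWICK_UNSAFE for c in label):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# Validation and transforms
# ---------------------------------------------------------------------------

def is_ultrametric(tree: Tree, tol: float | None = None) -> bool:
    """True iff all root-to-tip path lengths agree within ``tol``.

    The default tolerance is 1e-6 times the tree depth.
    """
    d = tree.tip_depths()
    if tol is None:
        tol = 1e-6 * float(d.max())
    if tol < 0:
        raise TreeError("tolerance must be nonnegative")
    return bool(d.max() - d.min() <= tol)


def ensure_ultrametric(
    tree: Tree, tol: float | None = None, repair: bool = False
) -> Tree:
    """Return the tree if ultrametric within ``tol``, else raise.

    With ``repair=True`` every terminal branch is instead extended so all
    tips terminate at the maximum root-to-tip depth (a crude repair for
    rounding-induced depth jitter; off by default).
    """
    if is_ultrametric(tree, tol):
        return tree
    if not repair:
        d = tree.tip_depths()
        raise TreeError(
            f"tree is not ultrametric: tip depths span "
            f"[{d.min():.6g}, {d.max():.6g}]"
        )
    depth = tree.node_depths()
    target = tree.tip_depths().max()
    lengths = tree.lengths.copy()
    for t in tree.tips:
        lengths[t] += target - depth[t]
    return tree.with_lengths(lengths)


def keep_tips(tree: Tree, labels) -> Tree:
    """Restrict the tree to the given tip labels.

    Internal nodes left with a single child are suppressed, merging the
    two incident branches; path lengths between retained tips are
    preserved exactly.
    """
    keep = set(labels)
    missing = keep - set(tree.tip_labels)
    if missing:
        raise TreeError(f"tips not in tree: {sorted(missing)}")
    retain = np.zeros(tree.n_nodes, dtype=bool)
    for v in tree.postorder():
        if tree.is_tip(v):
            retain[v] = tree.labels[v] in keep
        else:
            retain[v] = any(retain[c] for c in tree.children(v))
    # rebuild, suppressing unary nodes
    new_parent: list = []
    new_lengths: list = []
    new_labels: list = []

    def build(node: int, parent_new: int, carry: float) -> None:
        kids = [c for c in tree.children(node) if retain[c]]
        length = float(tree.lengths[node]) + carry
        if len(kids) == 1 and not tree.is_tip(node):
            build(kids[0], parent_new, length)
            return
        idx = len(new_parent)
        new_parent.append(parent_new)
        new_lengths.append(length if parent_new >= 0 else 0.0)
        new_labels.append(tree.labels[node])
        for c in kids:
            build(c, idx, 0.0)

    root = tree.root
    # if the root itself becomes unary, descend before anchoring
    node = root
    while True:
        kids = [c for c in tree.children(node) if retain[c]]
        if len(kids) == 1 and not tree.is_tip(node):
            node = kids[0]
        else:
            break
    build(node, -1, 0.0)
    return Tree(np.array(new_parent), np.array(new_lengths), tuple(new_labels))


def prune_short_terminal_clades(
    tree: Tree,
    threshold: float = 0.25,
    seed: int = 0,
    use_stem: bool = False,
) -> Tree:
    """Collapse terminal clades of very short branches to a single tip.

    Wherever an internal node's descendants are all tips and every one of
    those terminal branches is shorter than ``threshold``, exactly one tip
    (chosen uniformly with the given seed) is retained. With
    ``use_stem=True`` the rule instead tests the subtending (stem) branch
    of the terminal clade. Applied repeatedly until no such clade remains,
    so the operation is idempotent.
    """
    if threshold <= 0:
        raise TreeError("threshold must be positive")
    rng = np.random.default_rng(seed)
    current = tree
    while True:
        drop: set = set()
        for v in current.preorder():
            kids = current.children(v)
            if not kids or not all(current.is_tip(c) for c in kids):
                continue
            if use_stem:
                short = current.parent[v] >= 0 and current.lengths[v] < threshold
            else:
                short = all(current.lengths[c] < threshold for c in kids)
            if short and len(kids) > 1:
                labs = sorted(current.labels[c] for c in kids)
                keep_lab = labs[rng.integers(len(labs))]
                drop.update(l for l in labs if l != keep_lab)
        if not drop:
            return current
        current = keep_tips(current, [l for l in current.tip_labels if l not in drop])


# ---------------------------------------------------------------------------
# Brownian covariance
# ---------------------------------------------------------------------------

def vcv(tree: Tree, rates=None) -> np.ndarray:
    """Brownian tip covariance: entry (i, j) is the summed (rate-scaled)
    length of branches shared by the root-to-tip paths of tips i and j.

    Rows/columns follow ``tree.tip_labels`` order. With ``rates`` given,
    each branch contributes ``r * length`` ("branch lengths = r x t").
    """
    lens = tree.lengths if rates is None else tree.lengths * _as_rates(tree, rates)
    n = tree.n_tips
    tip_index = {int(t): k for k, t in enumerate(tree.tips)}
    below: dict = {}
    C = np.zeros((n, n))
    for v in tree.postorder():
        if tree.is_tip(v):
            below[v] = [tip_index[v]]
        else:
            merged = []
            for c in tree.children(v):
                merged.extend(below.pop(c))
            below[v] = merged
        if tree.parent[v] >= 0 and lens[v] != 0.0:
            idx = np.array(below[v])
            C[np.ix_(idx, idx)] += lens[v]
    return C


def phylo_crossproducts(tree: Tree, U: np.ndarray, rates=None):
    """Gaussian peeling: returns ``(U' V^-1 U, log det V)`` in O(n m^2).

    ``U`` is an (n_tips, m) matrix whose rows follow ``tree.tip_labels``
    order and ``V`` is the (rate-scaled) Brownian covariance. Equivalent
    to dense linear algebra but never forms ``V``; used by the
    variable-rates sampler where ``V`` changes every iteration. A
    numba-compiled kernel is used when available.
    """
    U = np.atleast_2d(np.asarray(U, dtype=float))
    if U.shape[0] != tree.n_tips:
        raise TreeError("row count of U must equal the number of tips")
    m = U.shape[1]
    lens = tree.lengths if rates is None else tree.lengths * _as_rates(tree, rates)
    if _peel_kernel is not None:
        M = np.zeros((m, m))
        root_is = np.zeros(tree.n_nodes, dtype=np.int64)
        root_is[tree.root] = 1
        logdet = _peel_kernel(
            tree.postorder().copy(), tree._child_ptr, tree._child_flat,
            tree._tip_row, root_is, np.ascontiguousarray(lens),
            np.ascontiguousarray(U), M,
        )
        if np.isnan(logdet):
            raise TreeError("zero-variance contrast (zero-length cherry or root)")
        return M, float(logdet)
    mu = np.zeros((tree.n_nodes, m))
    extra = np.zeros(tree.n_nodes)  # accumulated uncertainty above each node
    M = np.zeros((m, m))
    logdet = 0.0
    tip_index = {int(t): k for k, t in enumerate(tree.tips)}
    for v in tree.postorder():
        kids = tree.children(v)
        if not kids:
            mu[v] = U[tip_index[v]]
            extra[v] = lens[v]
            continue
        # combine children pairwise (handles multifurcations)
        cur_mu = mu[kids[0]]
        cur_v = extra[kids[0]]
        for c in kids[1:]:
            d = mu[c] - cur_mu
            vsum = cur_v + extra[c]
            if vsum <= 0:
                raise TreeError("zero-length cherry: contrast variance is zero")
            M += np.outer(d, d) / vsum
            logdet += np.log(vsum)
            w = extra[c] / vsum
            cur_mu = w * cur_mu + (1.0 - w) * mu[c]
            cur_v = cur_v * extra[c] / vsum
        mu[v] = cur_mu
        extra[v] = cur_v + (lens[v] if tree.parent[v] >= 0 else 0.0)
    r = tree.root
    if extra[r] <= 0:
        raise TreeError("degenerate tree: zero root variance")
    M += np.outer(mu[r], mu[r]) / extra[r]
    logdet += np.log(extra[r])
    return M, logdet


def _make_peel_kernel():
    try:
        from numba import njit
    except ImportError:  # pragma: no cover - numba is an optional speedup
        return None

    @njit(cache=True)
    def kernel(postorder, child_ptr, child_flat, tip_row, root_is, lens, U, M):
        n_nodes = child_ptr.shape[0] - 1
        m = U.shape[1]
        mu = np.zeros((n_nodes, m))
        extra = np.zeros(n_nodes)
        logdet = 0.0
        for idx in range(postorder.shape[0]):
            v = postorder[idx]
            lo = child_ptr[v]
            hi = child_ptr[v + 1]
            if hi == lo:  # tip
                row = tip_row[v]
                for j in range(m):
                    mu[v, j] = U[row, j]
                extra[v] = lens[v]
                continue
            c0 = child_flat[lo]
            cur_v = extra[c0]
            for j in range(m):
                mu[v, j] = mu[c0, j]
            for ci in range(lo + 1, hi):
                c = child_flat[ci]
                vsum = cur_v + extra[c]
                if vsum <= 0.0:
                    return np.nan
                for a in range(m):
                    da = mu[v, a] - mu[c, a]
                    for b in range(m):
                        M[a, b] += da * (mu[v, b] - mu[c, b]) / vsum
                logdet += np.log(vsum)
                w = extra[c] / vsum
                for j in range(m):
                    mu[v, j] = w * mu[v, j] + (1.0 - w) * mu[c, j]
                cur_v = cur_v * extra[c] / vsum
            if root_is[v] == 1:
                extra[v] = cur_v
            else:
                extra[v] = cur_v + lens[v]
        root = postorder[postorder.shape[0] - 1]
        if extra[root] <= 0.0:
            return np.nan
        for a in range(m):
            for b in range(m):
                M[a, b] += mu[root, a] * mu[root, b] / extra[root]
        logdet += np.log(extra[root])
        return logdet

    return kernel


_peel_kernel = _make_peel_kernel()
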
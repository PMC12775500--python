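"""Tree I/O, validation, pruning, and Brownian covariance."""

import numpy as np
import pytest

from allocurve import synth, treeio
from allocurve.treeio import (
    NewickParseError,
    Tree,
    TreeError,
    ensure_ultrametric,
    is_ultrametric,
    keep_tips,
    phylo_crossproducts,
    prune_short_terminal_clades,
    read_newick,
    vcv,
    write_newick,
)


class TestReadNewick:
    def test_two_tip_identity(self):
        t = read_newick("(A:1,B:1);")
        assert sorted(t.tip_labels) == ["A", "B"]
        assert np.allclose(t.tip_depths(), 1.0)

    def test_three_tip_depths(self, three_tip_tree):
        assert np.allclose(three_tip_tree.tip_depths(), 2.0)

    def test_non_ultrametric_parses(self):
        t = read_newick("((A:1,B:2):1,C:2);")
        assert t.n_tips == 3
        assert not is_ultrametric(t)

    def test_missing_branch_length_is_error(self):
        with pytest.raises(NewickParseError):
            read_newick("((A:1,B),C:2);")

    def test_syntax_error_reported(self):
        with pytest.raises(NewickParseError):
            read_newick("((A:1,B:1:1,C;")

    def test_duplicate_tip_labels_rejected(self):
        with pytest.raises(TreeError, match="(?i)duplicate|unique"):
            read_newick("((A:1,A:1):1,C:2);")

    def test_negative_branch_length_rejected(self):
        with pytest.raises(TreeError, match="negative"):
            Tree(np.array([-1, 0, 0]), np.array([0.0, -1.0, 1.0]),
                 (None, "A", "B"))


class TestRoundTrip:
    def test_path_length_matrix_preserved(self, random_trees):
        for tree in random_trees:
            back = read_newick(write_newick(tree))
            assert sorted(back.tip_labels) == sorted(tree.tip_labels)
            # pairwise path lengths d_ij = V_ii + V_jj - 2 V_ij
            def paths(t):
                order = np.argsort(t.tip_labels)
                V = vcv(t)[np.ix_(order, order)]
                d = np.diag(V)
                return d[:, None] + d[None, :] - 2 * V

            assert np.allclose(paths(back), paths(tree), atol=1e-9)

    def test_quoted_labels(self):
        t = read_newick("('sp one':1,'sp (two)':1);")
        back = read_newick(write_newick(t))
        assert sorted(back.tip_labels) == ["sp (two)", "sp one"]


class TestUltrametric:
    def test_balanced_true(self):
        assert is_ultrametric(read_newick("(A:1,B:1);"))

    def test_unbalanced_false(self):
        assert not is_ultrametric(read_newick("((A:1,B:2):1,C:2);"))

    def test_exact_with_zero_tol(self, three_tip_tree):
        assert is_ultrametric(three_tip_tree, tol=0.0)

    def test_negative_tol_rejected(self, three_tip_tree):
        with pytest.raises(TreeError):
            is_ultrametric(three_tip_tree, tol=-1.0)

    def test_ensure_passes_through_or_raises(self, three_tip_tree):
        assert ensure_ultrametric(three_tip_tree) is three_tip_tree
        ragged = read_newick("((A:1,B:2):1,C:2);")
        with pytest.raises(TreeError, match="not ultrametric"):
            ensure_ultrametric(ragged)

    def test_ensure_repair_extends_tips(self):
        ragged = read_newick("((A:1,B:2):1,C:2);")
        fixed = ensure_ultrametric(ragged, repair=True)
        assert is_ultrametric(fixed, tol=0.0)
        assert np.allclose(fixed.tip_depths(), 3.0)


class TestPruneShortTerminalClades:
    def test_cherry_collapsed(self):
        t = prune_short_terminal_clades(
            read_newick("((A:0.1,B:0.1):1.9,C:2);"), seed=1
        )
        assert t.n_tips == 2
        assert "C" in t.tip_labels
        assert len(set(t.tip_labels) & {"A", "B"}) == 1
        assert is_ultrametric(t)

    def test_threshold_not_met_unchanged(self):
        t = prune_short_terminal_clades(
            read_newick("((A:0.3,B:0.3):1.7,C:2);"), seed=1
        )
        assert t.n_tips == 3

    def test_hard_polytomy(self):
        t = prune_short_terminal_clades(
            read_newick("((A:0.1,B:0.1,D:0.1):1.9,C:2);"), seed=1
        )
        assert t.n_tips == 2
        assert len(set(t.tip_labels) & {"A", "B", "D"}) == 1

    def test_idempotent(self, random_trees):
        for tree in random_trees:
            scaled = tree.with_lengths(tree.lengths / tree.depth())
            once = prune_short_terminal_clades(scaled, threshold=0.25, seed=3)
            twice = prune_short_terminal_clades(once, threshold=0.25, seed=3)
            assert once.tip_labels == twice.tip_labels

    def test_stem_reading_flag(self):
        # terminal branches are long but the subtending stem is short
        tree = read_newick("((A:1.5,B:1.5):0.1,C:1.6);")
        assert prune_short_terminal_clades(tree, seed=0).n_tips == 3
        assert prune_short_terminal_clades(tree, seed=0, use_stem=True).n_tips == 2

    def test_bad_threshold(self, three_tip_tree):
        with pytest.raises(TreeError):
            prune_short_terminal_clades(three_tip_tree, threshold=0.0, seed=0)

    def test_seeded_choice_reproducible(self):
        nwk = "((A:0.1,B:0.1,D:0.1):1.9,C:2);"
        kept = {
            prune_short_terminal_clades(read_newick(nwk), seed=s).tip_labels[0]
            for s in range(20)
        }
        assert len(kept) > 1  # different seeds can keep different tips
        a = prune_short_terminal_clades(read_newick(nwk), seed=7).tip_labels
        b = prune_short_terminal_clades(read_newick(nwk), seed=7).tip_labels
        assert a == b


class TestVcv:
    def test_star_identity(self):
        assert np.allclose(vcv(read_newick("(A:1,B:1);")), np.eye(2))

    def test_three_tip_entries(self, three_tip_tree):
        V = vcv(three_tip_tree)
        labels = three_tip_tree.tip_labels
        a, b, c = (labels.index(x) for x in "ABC")
        assert np.allclose(np.diag(V), 2.0)
        assert V[a, b] == pytest.approx(1.0)
        assert V[a, c] == V[b, c] == 0.0

    def test_rate_scaled_branch(self, three_tip_tree):
        t = three_tip_tree
        rates = np.ones(t.n_nodes)
        a_node = next(i for i in range(t.n_nodes) if t.labels[i] == "A")
        rates[a_node] = 2.0
        V = vcv(t, rates)
        a = t.tip_labels.index("A")
        b = t.tip_labels.index("B")
        assert V[a, a] == pytest.approx(3.0)  # 1 shared + 2 * 1 private
        assert V[a, b] == pytest.approx(1.0)  # shared path unchanged

    def test_rate_vector_length_checked(self, three_tip_tree):
        with pytest.raises(TreeError):
            vcv(three_tip_tree, np.ones(3))

    def test_symmetric_psd_equal_diagonal(self, random_trees):
        big = synth.simulate_tree(300, seed=9)
        for tree in [*random_trees, big]:
            V = vcv(tree)
            assert np.allclose(V, V.T)
            assert np.linalg.eigvalsh(V).min() >= -1e-10
            assert np.allclose(np.diag(V), V[0, 0])  # ultrametric


class TestKeepTips:
    def test_path_lengths_preserved(self):
        t = read_newick("(((A:1,B:1):1,C:2):1,D:3);")
        sub = keep_tips(t, ["A", "D"])
        assert sorted(sub.tip_labels) == ["A", "D"]
        V = vcv(sub)
        assert np.allclose(np.diag(V), 3.0)
        assert V[0, 1] == pytest.approx(0.0)

    def test_missing_tip_error(self, three_tip_tree):
        with pytest.raises(TreeError):
            keep_tips(three_tip_tree, ["A", "Z"])


class TestPhyloCrossproducts:
    def test_matches_dense_with_rates(self, random_trees):
        rng = np.random.default_rng(0)
        for tree in random_trees:
            U = rng.normal(size=(tree.n_tips, 3))
            rates = np.ones(tree.n_nodes)
            picks = rng.integers(0, tree.n_nodes, size=4)
            rates[picks] = rng.lognormal(0, 1, size=4)
            rates[tree.root] = 1.0
            M, ld = phylo_crossproducts(tree, U, rates)
            V = vcv(tree, rates)
            assert np.allclose(M, U.T @ np.linalg.solve(V, U), atol=1e-8)
            assert np.isclose(ld, np.linalg.slogdet(V)[1], atol=1e-8)

    def test_row_count_checked(self, three_tip_tree):
        with pytest.raises(TreeError):
            phylo_crossproducts(three_tip_tree, np.ones((2, 1)))
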
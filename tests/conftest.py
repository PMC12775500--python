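import numpy as np
import pytest

from allocurve import synth, treeio


@pytest.fixture
def three_tip_tree():
    return treeio.read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def small_dataset():
    """A 100-species micro-to-macro dataset shared across read-only tests."""
    cfg = synth.MicroMacroConfig(n_species=100, seed=11)
    return synth.simulate_micro_macro(cfg)


@pytest.fixture(scope="session")
def random_trees():
    """A bag of seeded random trees of assorted sizes."""
    return [synth.simulate_tree(n, seed=n) for n in (3, 5, 8, 12, 20, 40)]
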
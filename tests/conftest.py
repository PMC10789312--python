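import numpy as np
import pandas as pd
import pytest

from mkbmc import branch_profiles, read_newick, to_relative_abundance
from mkbmc.simulate import SimConfig, default_parameters, dm_counts, simulate_study


@pytest.fixture
def toy_tree():
    """Three leaves, four branches: ((A:1,B:1):1,C:2);"""
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)


def random_dataset(q, n, seed):
    """A small synthetic (tree, counts, rel, branch profiles) bundle."""
    tree, pi, theta = default_parameters(q, seed)
    counts = dm_counts(n, pi, theta, seed + 1)
    rel = to_relative_abundance(counts)
    return tree, counts, rel, branch_profiles(tree, rel)


@pytest.fixture(scope="session")
def small_sim():
    """One simulated train/test pair reused by read-only tests."""
    cfg = SimConfig(n=100, q=40, scenario="I", model="A", beta=2.0, seed=42)
    return simulate_study(cfg)


@pytest.fixture
def tiny_table():
    return pd.DataFrame(
        [[2.0, 2.0, 0.0], [1.0, 0.0, 3.0]],
        index=["s1", "s2"],
        columns=["A", "B", "C"],
    )
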
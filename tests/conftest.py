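import numpy as np
import pytest

from rediploid import LossModelSpec, LossParams, ModelFlavor, Phylogeny, simulate_pillar_table


@pytest.fixture
def two_leaf_tree():
    return Phylogeny(["A", "B"], [(), (), (0, 1)], [0.4, 0.5, 0.3])


@pytest.fixture
def three_leaf_tree():
    # ((A,B),C) with a root branch
    return Phylogeny(["A", "B", "C"], [(), (), (), (0, 1), (3, 2)], [0.3, 0.4, 0.5, 0.2, 0.25])


@pytest.fixture
def four_leaf_tree():
    labels = ["A", "B", "C", "D"]
    children = [(), (), (), (), (0, 1), (2, 3), (4, 5)]
    lengths = [0.3, 0.35, 0.25, 0.4, 0.15, 0.2, 0.3]
    return Phylogeny(labels, children, lengths)


@pytest.fixture
def small_table(two_leaf_tree):
    spec = LossModelSpec(ModelFlavor.WGD_n)
    params = LossParams(
        epsilon=1.0, gamma=0.0, branch_lengths=two_leaf_tree.lengths, switch_prob=0.05
    )
    table, truth = simulate_pillar_table(two_leaf_tree, spec, params, 50, seed=11)
    return table, truth, spec, params
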
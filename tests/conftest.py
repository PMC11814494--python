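import io as _io

import numpy as np
import pytest
from skbio import TreeNode

from mdsclust.io import OtuTable


@pytest.fixture
def toy_counts():
    """3 samples x 4 OTUs count table."""
    return OtuTable(
        sample_ids=["s1", "s2", "s3"],
        otu_ids=["o1", "o2", "o3", "o4"],
        values=np.array([[2.0, 3.0, 5.0, 0.0], [1.0, 1.0, 1.0, 1.0], [0.0, 0.0, 4.0, 6.0]]),
    )


@pytest.fixture
def star3():
    """Star tree with unit branches to leaves A, B, C."""
    return TreeNode.read(_io.StringIO("(A:1,B:1,C:1);"))


@pytest.fixture
def cherry3():
    """((A,B),C) with unit branch lengths."""
    return TreeNode.read(_io.StringIO("((A:1,B:1):1,C:1);"))


@pytest.fixture
def two_leaf():
    return TreeNode.read(_io.StringIO("(A:1,B:2);"))


def random_composition(rng, P, zeros=False):
    x = rng.gamma(0.5, size=P)
    if zeros:
        x[rng.random(P) < 0.3] = 0.0
        if x.sum() == 0:
            x[0] = 1.0
    return x / x.sum()


def random_binary_tree(rng, leaf_names):
    """Random topology with uniform(0.1, 1) branch lengths (test oracle helper)."""
    nodes = [TreeNode(name=n, length=float(rng.uniform(0.1, 1.0))) for n in leaf_names]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        p = TreeNode(length=float(rng.uniform(0.1, 1.0)))
        p.append(a)
        p.append(b)
        nodes.append(p)
    root = nodes[0]
    root.length = None
    return root
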
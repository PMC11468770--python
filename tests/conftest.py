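import numpy as np
import pytest

from arborkit.swc import AXON, SOMA, NeuronNode, NeuronTree
from arborkit.synthetic import PhantomSpec, make_tree


def chain_tree(n: int, step: float = 1.0, radius: float = 1.0) -> NeuronTree:
    """Soma followed by a straight chain of n-1 axon nodes along +x."""
    nodes = [NeuronNode(1, SOMA, 0.0, 0.0, 0.0, radius, -1)]
    for i in range(2, n + 1):
        nodes.append(
            NeuronNode(i, AXON, (i - 1) * step, 0.0, 0.0, radius, i - 1)
        )
    return NeuronTree(nodes)


def y_tree(stem: float = 10.0, arm: float = 10.0) -> NeuronTree:
    """Soma, a stem along +z, then two arms; the classic Y."""
    nodes = [
        NeuronNode(1, SOMA, 0, 0, 0, 1, -1),
        NeuronNode(2, AXON, 0, 0, stem, 1, 1),
        NeuronNode(3, AXON, arm * 0.6, 0, stem + arm * 0.8, 1, 2),
        NeuronNode(4, AXON, -arm * 0.6, 0, stem + arm * 0.8, 1, 2),
    ]
    return NeuronTree(nodes)


def full_binary_tree(depth: int, seg: float = 5.0) -> NeuronTree:
    """Full binary tree of the given bifurcation depth below a 1-child soma."""
    nodes = [NeuronNode(1, SOMA, 0, 0, 0, 1, -1)]
    next_id = [2]

    def grow(parent, level, x, z):
        nid = next_id[0]
        next_id[0] += 1
        nodes.append(NeuronNode(nid, AXON, x, 0, z, 1, parent))
        if level < depth:
            dx = seg / (2**level)
            grow(nid, level + 1, x - dx, z + seg)
            grow(nid, level + 1, x + dx, z + seg)

    grow(1, 0, 0.0, seg)
    return NeuronTree(nodes)


def random_tree(seed: int, n_branches: int = 8) -> NeuronTree:
    spec = PhantomSpec(seed=seed, n_branches=n_branches)
    return make_tree(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
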
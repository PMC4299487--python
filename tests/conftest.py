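import itertools

import dendropy
import numpy as np
import pytest

from epleio import Alignment


@pytest.fixture
def quartet_tree():
    """Balanced 4-leaf tree ((s1,s2),(s3,s4)) with unit branch lengths."""
    return dendropy.Tree.get(
        data="((s1:1,s2:1):1,(s3:1,s4:1):1);", schema="newick"
    )


@pytest.fixture
def identity_alignment():
    """4 identical 10-residue sequences."""
    return Alignment(
        taxa=["s1", "s2", "s3", "s4"],
        data=np.array([list("ACDEFGHIKL")] * 4),
    )


def make_alignment(seqs: dict[str, str]) -> Alignment:
    return Alignment(
        taxa=list(seqs), data=np.array([list(s) for s in seqs.values()])
    )


def random_binary_tree(
    rng: np.random.Generator, n_leaves: int, bl_low=0.05, bl_high=1.0
) -> dendropy.Tree:
    """Random rooted binary tree with uniform random branch lengths."""
    frags = [f"t{i}" for i in range(n_leaves)]
    while len(frags) > 1:
        i, j = sorted(rng.choice(len(frags), size=2, replace=False))
        b = frags.pop(j)
        a = frags.pop(i)
        la, lb = (float(x) for x in rng.uniform(bl_low, bl_high, size=2))
        frags.append(f"({a}:{la!r},{b}:{lb!r})")
    return dendropy.Tree.get(data=frags[0] + ";", schema="newick")


def brute_force_min_changes(tree: dendropy.Tree, states: dict) -> int:
    """Exhaustive minimum change count over all internal-state assignments.

    Independent oracle for the Fitch/Hartigan dynamic program: leaves with
    missing states are free variables like internal nodes; the alphabet is
    restricted to observed states (sufficient for an optimum).
    """
    alphabet = sorted({s for s in states.values() if s is not None})
    assert alphabet
    free = [
        n
        for n in tree.preorder_node_iter()
        if not n.is_leaf() or states[n.taxon.label] is None
    ]
    fixed = {
        n: states[n.taxon.label]
        for n in tree.leaf_node_iter()
        if states[n.taxon.label] is not None
    }
    edges = [
        (n.parent_node, n)
        for n in tree.preorder_node_iter()
        if n.parent_node is not None
    ]
    best = len(edges) + 1
    for combo in itertools.product(alphabet, repeat=len(free)):
        assign = dict(zip(free, combo)) | fixed
        cost = sum(assign[u] != assign[v] for u, v in edges)
        best = min(best, cost)
    return best
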
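"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from olfrep.phylo import SupportTree


def random_newick(rng: np.random.Generator, n_leaves: int,
                  with_supports: bool = True) -> str:
    """A random bifurcating tree by successive random joins.

    Branch lengths ~ U(0.01, 2); supports ~ U{0..100} on internal nodes.
    Independent of any library tree-simulation routine.
    """
    subtrees = [(f"t{i}", None) for i in range(n_leaves)]
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        (sj, _), (si, _) = subtrees.pop(j), subtrees.pop(i)
        bi, bj = rng.uniform(0.01, 2.0, size=2).round(4)
        sup = str(int(rng.integers(0, 101))) if with_supports else ""
        subtrees.append((f"({si}:{bi},{sj}:{bj}){sup}", None))
    return subtrees[0][0] + ";"


def brute_force_path_length(tree: SupportTree, a: str, b: str) -> float:
    """Leaf-to-leaf path length by explicit ancestor-chain enumeration.

    Walks each leaf's parent chain to the root, finds the deepest shared
    ancestor, and sums edge lengths on both sides — no depth bookkeeping,
    no matrix algorithm, so it is an independent check on the cophenetic
    matrix.
    """
    t = tree.dendropy_tree
    nodes = {lf.taxon.label: lf for lf in t.leaf_node_iter()}
    na, nb = nodes[a], nodes[b]

    def chain(n):
        out = [n]
        while n.parent_node is not None:
            n = n.parent_node
            out.append(n)
        return out

    chain_a = chain(na)
    set_a = set(id(x) for x in chain_a)
    lca = None
    n = nb
    while n is not None:
        if id(n) in set_a:
            lca = n
            break
        n = n.parent_node
    dist = 0.0
    n = na
    while n is not lca:
        dist += n.edge.length or 0.0
        n = n.parent_node
    n = nb
    while n is not lca:
        dist += n.edge.length or 0.0
        n = n.parent_node
    return dist


def exhaustive_maximal_clades(tree: SupportTree, focal: set[str],
                              min_size: int, min_support: float) -> set[frozenset[str]]:
    """Oracle for clade extraction: scan every internal node, keep the
    qualifying leaf sets with no qualifying strict superset."""
    qualifying = [
        leaves
        for leaves, support in tree.clade_leafsets()
        if leaves <= focal and len(leaves) >= min_size
        and support is not None and support >= min_support
    ]
    return {
        s for s in qualifying
        if not any(s < other for other in qualifying)
    }


@pytest.fixture(scope="session")
def default_sim():
    """One default simulated repertoire, shared across tests."""
    from olfrep.simulate import SimConfig, simulate_repertoire

    return simulate_repertoire(SimConfig(seed=7))
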
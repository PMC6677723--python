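"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from retronest import synthetic_data as sd


@pytest.fixture(scope="session")
def replica():
    """One synthetic nested-insertion locus shared across the session."""
    return sd.nonagouti_replica(seed=11)


@pytest.fixture(scope="session")
def splice_locus(replica):
    return sd.replica_splice_locus(replica)


# --------------------------------------------------------------------------
# independent oracle: exhaustive least-squares topology search
# (deliberately separate from retronest.phylo.nj_tree)
# --------------------------------------------------------------------------

def enumerate_unrooted_topologies(taxa):
    """All unrooted binary topologies over the taxa (15 for five taxa).

    A topology is an edge list over nodes; leaves are the taxon labels,
    internal nodes are integers.  Trees are grown by attaching each new leaf
    to every existing edge.
    """
    assert len(taxa) >= 3
    base_center = 0
    trees = [[(base_center, taxa[0]), (base_center, taxa[1]), (base_center, taxa[2])]]
    next_internal = 1
    for leaf in taxa[3:]:
        grown = []
        for edges in trees:
            for k in range(len(edges)):
                u, v = edges[k]
                mid = next_internal
                new_edges = edges[:k] + edges[k + 1:]
                new_edges += [(u, mid), (mid, v), (mid, leaf)]
                grown.append(new_edges)
        trees = grown
        next_internal += 1
    return trees


def _leaf_paths(edges, taxa):
    """Map each leaf pair to the set of edge indices on its path."""
    adj = {}
    for idx, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, idx))
        adj.setdefault(v, []).append((u, idx))

    def path(a, b):
        stack = [(a, None, [])]
        seen = {a}
        while stack:
            node, _parent, used = stack.pop()
            if node == b:
                return used
            for nxt, eidx in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append((nxt, node, used + [eidx]))
        raise AssertionError("disconnected topology")

    return {(a, b): path(a, b) for a, b in itertools.combinations(taxa, 2)}


def least_squares_best_topology(D):
    """Fit branch lengths to every topology by ordinary least squares and
    return (edge list, SSE) of the best-fitting one."""
    taxa = list(D.taxa)
    best = None
    for edges in enumerate_unrooted_topologies(taxa):
        paths = _leaf_paths(edges, taxa)
        pairs = list(paths)
        A = np.zeros((len(pairs), len(edges)))
        y = np.zeros(len(pairs))
        for r, (a, b) in enumerate(pairs):
            for eidx in paths[(a, b)]:
                A[r, eidx] = 1.0
            y[r] = D.get(a, b)
        x, *_ = np.linalg.lstsq(A, y, rcond=None)
        sse = float(((A @ x - y) ** 2).sum())
        if best is None or sse < best[1]:
            best = (edges, sse)
    return best


def topology_splits(edges, taxa):
    """Nontrivial bipartitions of an edge-list topology, as frozensets of
    frozensets (orientation-free)."""
    taxa = set(taxa)
    adj = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)

    def side(u, v):
        # leaves reachable from v without crossing u
        stack, seen = [v], {u, v}
        leaves = set()
        while stack:
            node = stack.pop()
            if node in taxa:
                leaves.add(node)
            for nxt in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return frozenset(leaves)

    splits = set()
    for u, v in edges:
        s = side(u, v)
        if 1 < len(s) < len(taxa) - 1:
            splits.add(frozenset({s, frozenset(taxa - s)}))
    return splits


def dendropy_splits(tree):
    """Nontrivial bipartitions of a dendropy tree in the same orientation-free
    encoding as :func:`topology_splits`."""
    leaves = {l.taxon.label for l in tree.leaf_node_iter()}
    splits = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = {l.taxon.label for l in node.leaf_iter()}
        if 1 < len(below) < len(leaves) - 1:
            splits.add(frozenset({frozenset(below), frozenset(leaves - below)}))
    return splits
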
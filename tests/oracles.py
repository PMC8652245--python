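"""Independent brute-force oracles used by the test suite.

Everything here works on frozensets of tip labels and exhaustive
enumeration — deliberately sharing no code with the package's bitmask
and assignment-based implementations.
"""

from __future__ import annotations

import itertools
import math
from typing import Iterable


# ---------------------------------------------------------------------------
# Split extraction from nested-tuple tree encodings
# ---------------------------------------------------------------------------

def newick_of(struct) -> str:
    """Nested tuples of labels -> Newick."""
    if isinstance(struct, str):
        return struct
    return "(" + ",".join(newick_of(c) for c in struct) + ")"


def tips_of(struct) -> frozenset:
    if isinstance(struct, str):
        return frozenset([struct])
    return frozenset().union(*(tips_of(c) for c in struct))


def splits_of(struct, universe: frozenset | None = None) -> set[frozenset]:
    """Nontrivial splits of an unrooted nested-tuple tree.

    Each split is represented canonically as the side not containing the
    alphabetically smallest label.
    """
    universe = universe or tips_of(struct)
    anchor = min(universe)
    out: set[frozenset] = set()

    def walk(node):
        if isinstance(node, str):
            return frozenset([node])
        below = frozenset()
        for c in node:
            sub = walk(c)
            below |= sub
            side = sub if anchor not in sub else universe - sub
            if 2 <= len(side) <= len(universe) - 2:
                out.add(side)
        return below

    walk(struct)
    return out


def all_unrooted_binary_trees(labels: list[str]):
    """Every unrooted binary topology, as nested-tuple structures.

    Built by inserting each new tip on every edge of each smaller tree;
    gives (2n-5)!! distinct topologies.
    """
    assert len(labels) >= 3
    base = (labels[0], labels[1], labels[2])  # the unique 3-tip tree

    def insert_everywhere(tree, tip):
        # tree is a tuple of 3 children around the central node
        results = []

        def rebuild(node, path, replacement):
            if not path:
                return replacement
            i, rest = path[0], path[1:]
            return tuple(rebuild(c, rest, replacement) if j == i else c
                         for j, c in enumerate(node))

        def edges(node, path):
            # yields (path-to-child) for every edge below node
            if isinstance(node, str):
                return
            for i, c in enumerate(node):
                yield path + (i,)
                yield from edges(c, path + (i,))

        for path in edges(tree, ()):
            # attach the tip in the middle of this edge
            def get(node, p):
                for i in p:
                    node = node[i]
                return node
            child = get(tree, path)
            results.append(rebuild(tree, path, (child, tip)))
        return results

    trees = [base]
    for tip in labels[3:]:
        trees = [t2 for t in trees for t2 in insert_everywhere(t, tip)]
    return trees


# ---------------------------------------------------------------------------
# Set-based split scores
# ---------------------------------------------------------------------------

def entropy_of(side: frozenset, universe: frozenset) -> float:
    a = len(side)
    b = len(universe) - a
    n = len(universe)
    return -(a / n) * math.log2(a / n) - (b / n) * math.log2(b / n)


def mci_of(s1: frozenset, s2: frozenset, universe: frozenset) -> float:
    n = len(universe)
    total = 0.0
    for x in (s1, universe - s1):
        for y in (s2, universe - s2):
            c = len(x & y)
            if c:
                total += (c / n) * math.log2(n * c / (len(x) * len(y)))
    return max(total, 0.0)


def nye_of(s1: frozenset, s2: frozenset, universe: frozenset) -> float:
    c1, c2 = universe - s1, universe - s2

    def jac(x, y):
        return len(x & y) / len(x | y)

    return max(min(jac(s1, s2), jac(c1, c2)), min(jac(s1, c2), jac(c1, s2)))


# ---------------------------------------------------------------------------
# Brute-force distances (exhaustive injective split matchings)
# ---------------------------------------------------------------------------

def _best_matching(splits1, splits2, universe, score) -> float:
    """Maximum total score over every injective pairing, by enumeration."""
    s1, s2 = list(splits1), list(splits2)
    if len(s1) > len(s2):
        s1, s2 = s2, s1
    best = 0.0
    k = len(s1)
    for subset in itertools.permutations(s2, k):
        tot = sum(score(a, b, universe) for a, b in zip(s1, subset))
        best = max(best, tot)
    return best


def brute_rf(t1, t2) -> float | None:
    universe = tips_of(t1)
    s1, s2 = splits_of(t1), splits_of(t2)
    total = len(s1) + len(s2)
    if total == 0:
        return None
    return (total - 2 * len(s1 & s2)) / total


def brute_nye(t1, t2) -> float | None:
    universe = tips_of(t1)
    s1, s2 = splits_of(t1), splits_of(t2)
    total = len(s1) + len(s2)
    if total == 0:
        return None
    s = _best_matching(s1, s2, universe, nye_of)
    return 1.0 - 2.0 * s / total


def brute_ci(t1, t2) -> float | None:
    universe = tips_of(t1)
    s1, s2 = splits_of(t1), splits_of(t2)
    h = sum(entropy_of(s, universe) for s in s1) \
        + sum(entropy_of(s, universe) for s in s2)
    if h == 0:
        return None
    m = _best_matching(s1, s2, universe, mci_of)
    return (h - 2.0 * m) / h
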
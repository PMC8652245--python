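"""Canonical bipartitions and per-split-pair scores.

A :class:`Split` is one side of the bipartition induced by removing an
internal edge of an unrooted tree, stored as a bitmask over a fixed, sorted
taxon restriction.  The side *not* containing the lowest-indexed taxon is
stored, so a split and its complement compare and hash equal.  These are
the atoms of the Robinson–Foulds distance and of its generalized variants:
the Jaccard-based split similarity of Nye and the mutual clustering
information of Smith, both computed here in bits (the base cancels after
normalization).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateTreeError, TreeValidationError
from .treeio import PhyloTree

__all__ = [
    "Split",
    "nontrivial_splits",
    "split_masks",
    "split_matrix",
    "split_entropy",
    "mutual_clustering_information",
    "nye_split_score",
]


@dataclass(frozen=True)
class Split:
    """A nontrivial bipartition over a fixed taxon restriction.

    ``mask`` has bit *i* set when ``taxa[i]`` lies on the stored side; the
    stored side never contains ``taxa[0]`` (canonical form).
    """

    mask: int
    taxa: tuple[str, ...]

    def __post_init__(self):
        n = len(self.taxa)
        if self.mask & 1:
            object.__setattr__(self, "mask", self.mask ^ ((1 << n) - 1))
        size = self.mask.bit_count()
        if size < 2 or n - size < 2:
            raise TreeValidationError(
                f"trivial split: sides {size}|{n - size}")

    @property
    def n(self) -> int:
        return len(self.taxa)

    @property
    def sizes(self) -> tuple[int, int]:
        s = self.mask.bit_count()
        return s, self.n - s

    def side_labels(self) -> tuple[frozenset[str], frozenset[str]]:
        a = frozenset(t for i, t in enumerate(self.taxa) if self.mask >> i & 1)
        return a, frozenset(self.taxa) - a


def split_masks(tree: PhyloTree, index: dict[str, int]) -> set[int]:
    """Canonical nontrivial split bitmasks of a tree over ``index``.

    The tree's tips must be exactly the keys of ``index``.  Computed on the
    unrooted topology: the two edges meeting at the root of a rooted tree
    induce the same split and are merged.
    """
    n = len(index)
    full = (1 << n) - 1
    masks: set[int] = set()
    below: dict[int, int] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = 1 << index[node.label]
        else:
            m = 0
            for c in node.children:
                m |= below[id(c)]
            below[id(node)] = m
            if node.parent is not None:
                if m & 1:
                    m ^= full
                s = m.bit_count()
                if 2 <= s <= n - 2:
                    masks.add(m)
    return masks


def nontrivial_splits(tree: PhyloTree) -> frozenset[Split]:
    """All nontrivial splits of the unrooted topology."""
    labels = tuple(sorted(tree.tip_labels()))
    if len(labels) < 4:
        raise DegenerateTreeError("splits require >= 4 tips")
    index = {lab: i for i, lab in enumerate(labels)}
    return frozenset(Split(m, labels) for m in split_masks(tree, index))


def split_entropy(s: Split) -> float:
    """Entropy of the two-block partition, in bits."""
    a, b = s.sizes
    n = s.n
    return -(a / n) * math.log2(a / n) - (b / n) * math.log2(b / n)


def _check_same_restriction(s1: Split, s2: Split) -> None:
    if s1.taxa != s2.taxa:
        raise TreeValidationError("splits defined on different taxon restrictions")


def mutual_clustering_information(s1: Split, s2: Split) -> float:
    """Mutual information (bits) between two bipartitions of the same tips.

    Sums ``(|X∩Y|/n)·log2(n·|X∩Y|/(|X|·|Y|))`` over the four side
    intersections; empty cells contribute nothing.  Bounded above by the
    smaller split entropy.
    """
    _check_same_restriction(s1, s2)
    n = s1.n
    full = (1 << n) - 1
    a, c = s1.mask, s2.mask
    b, d = a ^ full, c ^ full
    total = 0.0
    for x in (a, b):
        nx = x.bit_count()
        for y in (c, d):
            cell = (x & y).bit_count()
            if cell:
                total += (cell / n) * math.log2(n * cell / (nx * y.bit_count()))
    return max(total, 0.0)  # clip -0.0 / rounding noise at independence


def nye_split_score(s1: Split, s2: Split) -> float:
    """Nye's split similarity: the better side-alignment's worse Jaccard.

    Equals 1 iff the splits are identical.
    """
    _check_same_restriction(s1, s2)
    n = s1.n
    full = (1 << n) - 1
    a, c = s1.mask, s2.mask
    b, d = a ^ full, c ^ full

    def jac(x: int, y: int) -> float:
        inter = (x & y).bit_count()
        union = (x | y).bit_count()
        return inter / union

    return max(min(jac(a, c), jac(b, d)), min(jac(a, d), jac(b, c)))


# ---------------------------------------------------------------------------
# Vectorized all-pairs scores (used by the tree distances)
# ---------------------------------------------------------------------------

def split_matrix(masks: list[int], n: int) -> np.ndarray:
    """Stack split bitmasks into a (k, n) boolean membership matrix."""
    if not masks:
        return np.zeros((0, n), dtype=bool)
    nbytes = (n + 7) // 8
    raw = np.frombuffer(
        b"".join(m.to_bytes(nbytes, "little") for m in masks), dtype=np.uint8
    ).reshape(len(masks), nbytes)
    bits = np.unpackbits(raw, axis=1, bitorder="little")[:, :n]
    return bits.astype(bool)


def _cells(m1: np.ndarray, m2: np.ndarray):
    """2x2 intersection cell counts for every split pair."""
    n = m1.shape[1]
    a1 = m1.astype(np.float64)
    a2 = m2.astype(np.float64)
    nA = a1.sum(axis=1).astype(np.int64)  # |A| per split of tree 1
    nC = a2.sum(axis=1).astype(np.int64)
    ac = np.rint(a1 @ a2.T).astype(np.int64)  # |A∩C| via BLAS matmul
    ad = nA[:, None] - ac
    bc = nC[None, :] - ac
    bd = n - nA[:, None] - nC[None, :] + ac
    return n, nA, nC, ac, ad, bc, bd


def mutual_information_matrix(m1: np.ndarray, m2: np.ndarray,
                              cells=None) -> np.ndarray:
    """Pairwise mutual clustering information (bits) between split sets."""
    n, nA, nC, ac, ad, bc, bd = cells if cells is not None else _cells(m1, m2)
    nB = n - nA
    nD = n - nC
    out = np.zeros(ac.shape, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        for cell, rx, cy in ((ac, nA, nC), (ad, nA, nD),
                             (bc, nB, nC), (bd, nB, nD)):
            term = (cell / n) * np.log2(n * cell / (rx[:, None] * cy[None, :]))
            out += np.where(cell > 0, term, 0.0)
    return np.maximum(out, 0.0)


def nye_score_matrix(m1: np.ndarray, m2: np.ndarray,
                     cells=None) -> np.ndarray:
    """Pairwise Nye split similarities between split sets."""
    n, nA, nC, ac, ad, bc, bd = cells if cells is not None else _cells(m1, m2)
    nB = n - nA
    nD = n - nC
    j_ac = ac / (nA[:, None] + nC[None, :] - ac)
    j_bd = bd / (nB[:, None] + nD[None, :] - bd)
    j_ad = ad / (nA[:, None] + nD[None, :] - ad)
    j_bc = bc / (nB[:, None] + nC[None, :] - bc)
    return np.maximum(np.minimum(j_ac, j_bd), np.minimum(j_ad, j_bc))
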
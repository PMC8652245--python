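"""Per-clade concordance/conflict tallies and the normalized quartet score.

For every internal clade of a rooted species tree, each rooted gene tree
is classified (after collapsing poorly supported edges) as concordant,
conflicting, or uninformative, in the style of Phyparts pie charts:

* concordant — the clade's tips present in the gene tree form a clade;
* conflicting — some gene-tree clade positively conflicts (intersects the
  restricted clade but neither contains nor is contained in it) and the
  restricted clade is non-monophyletic;
* uninformative — fewer than two clade tips present, or the signal was
  lost to polytomies (non-monophyly without a positively conflicting
  clade).

The most frequent conflicting alternative across gene trees is reported
as the "main conflict".  The normalized quartet score is the proportion
of resolved gene-tree quartets whose topology the species tree satisfies.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import TreeValidationError
from .treeio import PhyloTree, collapse_low_support

__all__ = [
    "NodeTally",
    "ConcordanceTally",
    "phyparts_tally",
    "normalized_quartet_score",
]


@dataclass
class NodeTally:
    node_id: int
    clade_tips: frozenset[str]
    n_concordant: int = 0
    n_main_conflict: int = 0
    n_other_conflict: int = 0
    n_uninformative: int = 0
    main_conflict_clade: frozenset[str] | None = None

    @property
    def n_analyzed(self) -> int:
        return (self.n_concordant + self.n_main_conflict
                + self.n_other_conflict + self.n_uninformative)


@dataclass
class ConcordanceTally:
    nodes: dict[int, NodeTally] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for nid in sorted(self.nodes):
            t = self.nodes[nid]
            rows.append((nid, ",".join(sorted(t.clade_tips)),
                         t.n_concordant, t.n_main_conflict,
                         t.n_other_conflict, t.n_uninformative,
                         ",".join(sorted(t.main_conflict_clade))
                         if t.main_conflict_clade else ""))
        return pd.DataFrame(rows, columns=[
            "node_id", "clade_tips", "n_concordant", "n_main_conflict",
            "n_other_conflict", "n_uninformative", "main_conflict_tips"])


def _mask_clades(tree: PhyloTree, index: dict[str, int]) -> tuple[int, list[int]]:
    """Tip mask and proper rooted clade masks over a shared tip index."""
    below: dict[int, int] = {}
    clades: list[int] = []
    tipmask = 0
    for n in tree.postorder():
        if n.is_leaf:
            below[id(n)] = 1 << index[n.label]
            tipmask |= below[id(n)]
        else:
            m = 0
            for c in n.children:
                m |= below[id(c)]
            below[id(n)] = m
            if n.parent is not None:
                clades.append(m)
    clades = [m for m in clades if 2 <= m.bit_count() and m != tipmask]
    return tipmask, sorted(set(clades))


def phyparts_tally(species_tree: PhyloTree,
                   gene_trees: Sequence[PhyloTree | tuple[str, PhyloTree]],
                   collapse_threshold: float = 0.33) -> ConcordanceTally:
    """Four-way concordance tally at every internal species-tree clade.

    Gene trees must already be rooted (unrootable trees are excluded by
    the caller).  Gene trees with no tip inside, or none outside, a clade
    are not analyzed at that clade, so the four counts always sum to the
    number of gene trees analyzed there.
    """
    if not species_tree.rooted:
        raise TreeValidationError("species tree must be rooted")
    trees = [g[1] if isinstance(g, tuple) else g for g in gene_trees]
    for g in trees:
        if not g.rooted:
            raise TreeValidationError(
                "phyparts_tally requires rooted gene trees")
    labels = sorted(set(species_tree.tip_labels()).union(
        *(set(g.tip_labels()) for g in trees)))
    index = {lab: i for i, lab in enumerate(labels)}
    prepared = []
    for g in trees:
        g = collapse_low_support(g, collapse_threshold) \
            if collapse_threshold > 0 else g
        prepared.append(_mask_clades(g, index))

    # species clades: internal, non-root nodes with >= 2 tips below
    sp_tipmask, _ = _mask_clades(species_tree, index)
    below: dict[int, int] = {}
    sp_clades: list[tuple[int, int]] = []
    order = {id(n): i for i, n in enumerate(species_tree.preorder())}
    for n in species_tree.postorder():
        if n.is_leaf:
            below[id(n)] = 1 << index[n.label]
        else:
            m = 0
            for c in n.children:
                m |= below[id(c)]
            below[id(n)] = m
            if n.parent is not None and m.bit_count() >= 2 and m != sp_tipmask:
                sp_clades.append((order[id(n)], m))

    def to_tips(mask: int) -> frozenset[str]:
        return frozenset(labels[i] for i in range(len(labels)) if mask >> i & 1)

    tally = ConcordanceTally()
    for nid, clade in sorted(sp_clades):
        nt = NodeTally(node_id=nid, clade_tips=to_tips(clade))
        conflict_counts: dict[int, int] = {}
        conflicting_trees = 0
        for gtips, gclades in prepared:
            inside = clade & gtips
            if inside == 0 or gtips & ~clade == 0:
                continue  # tree not analyzed at this node
            if inside.bit_count() < 2:
                nt.n_uninformative += 1
                continue
            if inside in gclades:
                nt.n_concordant += 1
                continue
            conflicts = [x for x in gclades
                         if (x & inside) and (x & ~inside) and (inside & ~x)]
            if conflicts:
                conflicting_trees += 1
                for x in set(conflicts):
                    conflict_counts[x] = conflict_counts.get(x, 0) + 1
            else:
                nt.n_uninformative += 1
        if conflict_counts:
            main = min(conflict_counts,
                       key=lambda x: (-conflict_counts[x],
                                      tuple(sorted(to_tips(x)))))
            nt.main_conflict_clade = to_tips(main)
            nt.n_main_conflict = conflict_counts[main]
            nt.n_other_conflict = conflicting_trees - nt.n_main_conflict
        tally.nodes[nid] = nt
    return tally


# ---------------------------------------------------------------------------
# Quartet score
# ---------------------------------------------------------------------------

def _quartet_pattern(split_mat: np.ndarray, idx: np.ndarray) -> int | None:
    """Pairing of a 4-tip subset induced by a tree's splits.

    Returns 0 for {0,1}|{2,3}, 1 for {0,2}|{1,3}, 2 for {0,3}|{1,2}, or
    None when no split separates the quartet 2-2 (unresolved).
    """
    sub = split_mat[:, idx]
    sums = sub.sum(axis=1)
    rows = np.flatnonzero(sums == 2)
    for r in rows:
        a, b, c, d = sub[r]
        if a == b:
            return 0
        if a == c:
            return 1
        return 2
    return None


def _split_mat(tree: PhyloTree, index: dict[str, int]) -> np.ndarray:
    from .splits import split_masks, split_matrix
    masks = sorted(split_masks(tree, index))
    return split_matrix(masks, len(index))


def normalized_quartet_score(species_tree: PhyloTree,
                             gene_trees: Iterable[PhyloTree | tuple[str, PhyloTree]],
                             mode: str = "auto",
                             n_quartets: int = 1000,
                             seed: int | None = None,
                             max_exact_tips: int = 25) -> float:
    """Proportion of resolved gene-tree quartets satisfied by the species tree.

    ``mode='exact'`` enumerates every shared 4-tip subset (permitted only
    up to ``max_exact_tips`` shared tips); ``'sampled'`` draws
    ``n_quartets`` quartets in total, spread over gene trees in proportion
    to their quartet counts (an unbiased estimate of the exact score);
    ``'auto'`` picks exact when permitted.  Counts are pooled over gene
    trees; the denominator is the number of gene-tree-resolved quartets.
    """
    from .treeio import prune_to_taxa

    if mode not in ("auto", "exact", "sampled"):
        raise TreeValidationError(f"unknown mode {mode!r}")
    sp_tips = set(species_tree.tip_labels())
    rng = np.random.default_rng(seed)

    prepared = []  # (gene splits, species splits, n shared, n quartets)
    for g in gene_trees:
        g = g[1] if isinstance(g, tuple) else g
        shared = sorted(sp_tips & set(g.tip_labels()))
        if len(shared) < 4:
            continue
        if mode == "exact" and len(shared) > max_exact_tips:
            raise TreeValidationError(
                f"exact mode limited to {max_exact_tips} shared tips; "
                "use sampled mode")
        index = {lab: i for i, lab in enumerate(shared)}
        gp = prune_to_taxa(g, shared) if len(shared) < g.n_tips() else g
        sp = prune_to_taxa(species_tree, shared) \
            if len(shared) < len(sp_tips) else species_tree
        k = len(shared)
        n_q = k * (k - 1) * (k - 2) * (k - 3) // 24
        prepared.append((_split_mat(gp, index), _split_mat(sp, index), k, n_q))
    if not prepared:
        raise TreeValidationError("no resolved shared quartets")

    use_exact = mode == "exact" or (
        mode == "auto" and max(k for _, _, k, _ in prepared) <= max_exact_tips)
    matches = 0
    resolved = 0
    if use_exact:
        per_tree = [None] * len(prepared)
    else:
        # allocate the sample in proportion to each tree's quartet count so
        # sampling is unbiased for the exact pooled score
        weights = np.array([nq for _, _, _, nq in prepared], dtype=float)
        per_tree = rng.multinomial(n_quartets, weights / weights.sum())
    for (gmat, smat, k, _), n_draw in zip(prepared, per_tree):
        if use_exact:
            quartets = itertools.combinations(range(k), 4)
        else:
            quartets = (np.sort(rng.choice(k, 4, replace=False))
                        for _ in range(int(n_draw)))
        for q in quartets:
            qi = np.asarray(q)
            gpat = _quartet_pattern(gmat, qi)
            if gpat is None:
                continue
            resolved += 1
            if _quartet_pattern(smat, qi) == gpat:
                matches += 1
    if resolved == 0:
        raise TreeValidationError("no resolved shared quartets")
    return matches / resolved
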
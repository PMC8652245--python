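"""Contained-coalescent simulation of gene trees inside a species tree.

The species tree carries branch lengths in coalescent units: within a
branch, ``k`` gene lineages coalesce at rate ``k(k-1)/2`` per unit.  One
haploid gene copy is sampled per species tip; lineages surviving to a
speciation node merge into the ancestral branch, and coalescence continues
above the root until a single lineage remains.  This is the null model for
how much gene-tree/species-tree discordance incomplete lineage sorting
alone produces.

Optional level-1 reticulation events model introgression: each event sits
at a fixed time on a recipient edge and, independently for every simulated
gene, reroutes all lineages present there to a donor edge with inheritance
probability γ — the fraction of the genome expected to take the minor
parental path (no within-locus recombination).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import TreeValidationError
from .treeio import Node, PhyloTree

__all__ = [
    "ReticulationEvent",
    "SpeciesTreeModel",
    "simulate_contained_gene_tree",
    "simulate_gene_trees",
    "three_taxon_concordance_probability",
]


@dataclass(frozen=True)
class ReticulationEvent:
    """A gene-flow event from a donor edge into a recipient edge.

    Edges are named by the set of tip labels descending from their child
    node.  ``time`` is an age (coalescent units above the tips) strictly
    inside the spans of both edges.
    """

    donor_edge: frozenset[str]
    recipient_edge: frozenset[str]
    gamma: float
    time: float

    def __post_init__(self):
        if not (0.0 < self.gamma <= 0.5):
            raise TreeValidationError("gamma must lie in (0, 0.5]")
        if self.donor_edge == self.recipient_edge:
            raise TreeValidationError("donor and recipient edges coincide")


class SpeciesTreeModel:
    """A rooted species tree in coalescent units, plus reticulations."""

    def __init__(self, tree: PhyloTree,
                 reticulations: Sequence[ReticulationEvent] = ()):
        if not tree.rooted:
            raise TreeValidationError("species tree must be rooted")
        for n in tree.preorder():
            if n.parent is not None and n.length is None:
                raise TreeValidationError(
                    "all species-tree branches need coalescent-unit lengths")
        self.tree = tree
        self.reticulations = tuple(reticulations)
        self.ages = self._node_ages()
        self._edge_by_tips = {
            frozenset(self._tips_below(n)): n
            for n in tree.preorder() if n.parent is not None
        }
        recipients = [ev.recipient_edge for ev in self.reticulations]
        if len(set(recipients)) != len(recipients):
            raise TreeValidationError(
                "level-1 constraint: at most one event per recipient edge")
        for ev in self.reticulations:
            for name, edge in (("donor", ev.donor_edge),
                               ("recipient", ev.recipient_edge)):
                node = self._edge_by_tips.get(edge)
                if node is None:
                    raise TreeValidationError(
                        f"{name} edge {sorted(edge)} not found in species tree")
                lo, hi = self.edge_span(node)
                if not (lo < ev.time < hi):
                    raise TreeValidationError(
                        f"event time {ev.time} outside {name} edge span "
                        f"({lo:.4g}, {hi:.4g})")

    def _tips_below(self, node: Node) -> list[str]:
        out = []
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n.label)
            stack.extend(n.children)
        return out

    def _node_ages(self) -> dict[int, float]:
        """Ages above the tips; tips are contemporaneous at age 0."""
        ages: dict[int, float] = {}
        for n in self.tree.postorder():
            if n.is_leaf:
                ages[id(n)] = 0.0
            else:
                ages[id(n)] = max(ages[id(c)] + (c.length or 0.0)
                                  for c in n.children)
        return ages

    def edge_node(self, tips: Iterable[str]) -> Node:
        """The child node of the edge whose descendant tip set is ``tips``."""
        node = self._edge_by_tips.get(frozenset(tips))
        if node is None:
            raise TreeValidationError(f"no edge with tip set {sorted(tips)}")
        return node

    def edge_span(self, node: Node) -> tuple[float, float]:
        lo = self.ages[id(node)]
        return lo, lo + (node.length or 0.0)

    @property
    def depth(self) -> float:
        return self.ages[id(self.tree.root)]


def _coerce_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    if isinstance(rng, (int, np.integer, np.random.SeedSequence)):
        return np.random.default_rng(rng)
    raise TreeValidationError(
        "simulate_contained_gene_tree requires an explicit seeded generator "
        "or seed; implicit global randomness is refused")


class _Pool:
    """Gene lineages inside one species-tree edge, advanced lazily."""

    __slots__ = ("lineages", "tops", "time")

    def __init__(self, time: float):
        self.lineages: list[Node] = []
        self.tops: list[float] = []
        self.time = time

    def advance(self, to_time: float, rng: np.random.Generator) -> None:
        """Run the Kingman coalescent among the pooled lineages."""
        t = self.time
        k = len(self.lineages)
        while k > 1:
            rate = k * (k - 1) / 2.0
            t_next = t + rng.exponential(1.0 / rate)
            if t_next > to_time:
                break
            i, j = rng.choice(k, size=2, replace=False)
            i, j = (int(i), int(j)) if i < j else (int(j), int(i))
            parent = Node()
            for idx in (i, j):
                child = self.lineages[idx]
                child.length = t_next - self.tops[idx]
                parent.add_child(child)
            self.lineages[i] = parent
            self.tops[i] = t_next
            del self.lineages[j], self.tops[j]
            t = t_next
            k -= 1
        self.time = to_time


def simulate_contained_gene_tree(model: SpeciesTreeModel,
                                 rng,
                                 force_reticulations: bool = False) -> PhyloTree:
    """Simulate one gene tree contained in the species tree.

    Returns a rooted binary tree on the species tips with coalescent-time
    branch lengths.  Reticulation events are each taken with probability
    γ, independently per gene; a taken event moves every lineage present
    on the recipient edge at the event time onto the donor edge.  With
    ``force_reticulations`` every event is taken deterministically (used
    to model organellar capture).
    """
    rng = _coerce_rng(rng)
    tree = model.tree
    if force_reticulations:
        taken = list(model.reticulations)
    else:
        taken = [ev for ev in model.reticulations if rng.random() < ev.gamma]

    pools: dict[int, _Pool] = {}
    for leaf in tree.leaves():
        pool = _Pool(0.0)
        tip = Node(label=leaf.label)
        pool.lineages.append(tip)
        pool.tops.append(0.0)
        pools[id(leaf)] = pool

    # event queue: speciation nodes at their ages, plus taken reticulations.
    # Reticulation times are strictly inside edge spans; among speciation
    # nodes of equal age (zero-length branches) children must merge before
    # their parent, so ties break on postorder rank.
    events: list[tuple[float, int, int, object]] = []
    post_rank = {id(n): i for i, n in enumerate(tree.postorder())}
    for n in tree.preorder():
        if not n.is_leaf:
            events.append((model.ages[id(n)], 1, post_rank[id(n)], n))
    for i, ev in enumerate(taken):
        events.append((ev.time, 0, i, ev))
    events.sort(key=lambda e: (e[0], e[1], e[2]))

    for time, kind, _, payload in events:
        if kind == 0:  # reticulation transfer
            ev = payload
            rec = model.edge_node(ev.recipient_edge)
            don = model.edge_node(ev.donor_edge)
            rpool = pools[id(rec)]
            dpool = pools[id(don)]
            rpool.advance(time, rng)
            dpool.advance(time, rng)
            dpool.lineages.extend(rpool.lineages)
            dpool.tops.extend(rpool.tops)
            rpool.lineages, rpool.tops = [], []
        else:  # speciation: merge child pools into the ancestral branch
            node = payload
            pool = _Pool(time)
            for c in node.children:
                cp = pools.pop(id(c))
                cp.advance(time, rng)
                pool.lineages.extend(cp.lineages)
                pool.tops.extend(cp.tops)
            pools[id(node)] = pool

    root_pool = pools[id(tree.root)]
    root_pool.advance(math.inf, rng)  # ancestral population: coalesce to one
    assert len(root_pool.lineages) == 1
    gene_root = root_pool.lineages[0]
    gene_root.length = None
    return PhyloTree(gene_root, rooted=True)


def simulate_gene_trees(model: SpeciesTreeModel, n: int,
                        seed) -> list[PhyloTree]:
    """Simulate ``n`` independent gene trees with per-gene derived seeds.

    Sub-seeds are spawned deterministically from ``seed``, so gene *i* is
    reproducible regardless of evaluation order.
    """
    if n < 1:
        raise TreeValidationError("n must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    return [simulate_contained_gene_tree(model, np.random.default_rng(child))
            for child in ss.spawn(n)]


def three_taxon_concordance_probability(t: float) -> float:
    """P(gene-tree triplet matches the species triplet), internal branch t.

    The classic closed form ``1 − (2/3)·exp(−t)``: with probability
    ``exp(−t)`` the two lineages fail to coalesce within the internal
    branch, after which the three orderings are equiprobable.
    """
    if t < 0:
        raise TreeValidationError("t must be non-negative")
    return 1.0 - (2.0 / 3.0) * math.exp(-t)
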
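"""Synthetic study generator.

Builds complete synthetic datasets with the statistical structure of an
anchored-enrichment phylogenomic study of a large plant radiation: a deep
species tree whose tips fall into named subgenus-like clade blocks, ~114
locus trees simulated under the multispecies coalescent (optionally with
introgression), gene-tree estimation error with bootstrap-like supports,
per-locus taxon dropout concentrated in the outgroups, and a plastome tree
simulated as a single locus with a faster coalescent (haploid, uniparental
inheritance) that can be routed through a reticulation to emulate
chloroplast capture.

Everything is a pure function of the configuration, so equal seeds give
byte-identical serialized studies.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import TreeValidationError
from .msc_sim import (
    ReticulationEvent,
    SpeciesTreeModel,
    simulate_contained_gene_tree,
)
from .splits import split_masks
from .treeio import (
    Node,
    PhyloTree,
    prune_to_taxa,
    write_clade_table,
    write_newick,
    write_tree_file,
)

__all__ = [
    "SupportModel",
    "ReticulationSpec",
    "SimulationConfig",
    "SyntheticStudy",
    "generate_species_tree",
    "perturb_gene_tree",
    "assign_conflict_aware_supports",
    "apply_missingness",
    "generate_study",
]

# clade blocks echoing the subgenus sizes of the emulated study
DEFAULT_CLADE_BLOCKS = {
    "cladeA": 93,   # large recent radiation
    "cladeB": 10,
    "cladeC": 10,
    "cladeD": 37,
    "cladeE": 20,
    "outgroup": 20,
}


@dataclass(frozen=True)
class SupportModel:
    """Beta parameters for bootstrap-like supports on gene-tree edges.

    ``low`` governs edges near estimation errors (mass well below 0.33);
    ``high`` governs confidently estimated edges.
    """

    low: tuple[float, float] = (2.0, 12.0)
    high: tuple[float, float] = (14.0, 2.0)


@dataclass(frozen=True)
class ReticulationSpec:
    """A gene-flow event named by clades (or explicit tip lists).

    Resolved against the generated species tree: each side's edge is the
    stem edge of the most recent common ancestor of the named tips; the
    event time is the midpoint of the two edges' temporal overlap.
    """

    donor: str | tuple[str, ...]
    recipient: str | tuple[str, ...]
    gamma: float


@dataclass(frozen=True)
class SimulationConfig:
    n_tips: int = 190
    clade_blocks: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLADE_BLOCKS))
    birth_rate: float = 1.0
    depth_cu: float = 8.0
    clade_crown_cu: float = 2.0
    n_loci: int = 114
    mean_locus_recovery: float = 96.25 / 114
    outgroup_recovery_multiplier: float = 0.5
    error_nni_rate: float = 1.0
    support_model: SupportModel = SupportModel()
    support_mode: str = "neighborhood"  # or "conflict_aware"
    reticulations: tuple[ReticulationSpec, ...] = ()
    plastome_rate_scale: float = 2.0
    plastome_capture: bool = False
    seed: int = 0

    def __post_init__(self):
        if sum(self.clade_blocks.values()) != self.n_tips:
            raise TreeValidationError("clade block sizes must sum to n_tips")
        if not (0.0 < self.mean_locus_recovery <= 1.0):
            raise TreeValidationError("mean_locus_recovery must lie in (0, 1]")
        if self.birth_rate < 0 or self.error_nni_rate < 0:
            raise TreeValidationError("rates must be non-negative")
        if not (0.0 < self.clade_crown_cu < self.depth_cu):
            raise TreeValidationError("need 0 < clade_crown_cu < depth_cu")
        if self.support_mode not in ("neighborhood", "conflict_aware"):
            raise TreeValidationError("unknown support_mode")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["support_model"] = {"low": list(self.support_model.low),
                              "high": list(self.support_model.high)}
        d["reticulations"] = [dataclasses.asdict(r) for r in self.reticulations]
        return d


@dataclass
class SyntheticStudy:
    model: SpeciesTreeModel
    clade_map: dict[str, str]
    gene_trees: list[tuple[str, PhyloTree]]
    plastome_tree: PhyloTree
    truth: dict
    config: SimulationConfig

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "species.nwk").write_text(
            write_newick(self.model.tree) + "\n")
        write_tree_file(outdir / "genetrees.nwk", self.gene_trees)
        (outdir / "plastome.nwk").write_text(
            write_newick(self.plastome_tree) + "\n")
        write_clade_table(outdir / "clades.tsv", self.clade_map)
        (outdir / "truth.json").write_text(
            json.dumps(self.truth, indent=2, sort_keys=True) + "\n")
        (outdir / "config.yaml").write_text(
            yaml.safe_dump(self.config.to_dict(), sort_keys=True))


# ---------------------------------------------------------------------------
# Species tree
# ---------------------------------------------------------------------------

def _yule_ultrametric(labels: list[str], rate: float, depth: float,
                      rng: np.random.Generator) -> Node:
    """A pure-birth tree on ``labels``, rescaled to crown depth ``depth``."""
    n = len(labels)
    if n == 1:
        return Node(label=labels[0], length=depth)
    rate = rate if rate > 0 else 1.0
    # forward simulation: record each split time
    tips: list[Node] = [Node(), Node()]
    root = Node()
    for t_node in tips:
        root.add_child(t_node)
    birth: dict[int, float] = {id(root): 0.0}
    t = 0.0
    while len(tips) < n:
        k = len(tips)
        t += rng.exponential(1.0 / (k * rate))
        idx = int(rng.integers(k))
        split = tips[idx]
        birth[id(split)] = t
        c1, c2 = Node(), Node()
        split.add_child(c1)
        split.add_child(c2)
        tips[idx] = c1
        tips.append(c2)
    present = t + rng.exponential(1.0 / (n * rate))
    scale = depth / present
    # convert birth times to ages, then to branch lengths
    order = rng.permutation(n)
    for i, tip in enumerate(tips):
        tip.label = labels[int(order[i])]

    def set_lengths(node: Node, node_age: float) -> None:
        for c in node.children:
            age = 0.0 if c.is_leaf else (present - birth[id(c)]) * scale
            c.length = node_age - age
            set_lengths(c, age)

    set_lengths(root, depth)
    return root


def generate_species_tree(config: SimulationConfig,
                          rng: np.random.Generator | None = None
                          ) -> tuple[SpeciesTreeModel, dict[str, str]]:
    """A clade-structured ultrametric species tree in coalescent units.

    A pure-birth backbone joins the clade blocks, with every block grafted
    as its own pure-birth subtree of crown depth ``clade_crown_cu`` — so
    each block is monophyletic by construction.  Returns the model (with
    reticulation specs resolved) and the tip → clade map.
    """
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed).spawn(1)[0])
    blocks = list(config.clade_blocks.items())
    crown = config.clade_crown_cu
    backbone = _yule_ultrametric([name for name, _ in blocks],
                                 config.birth_rate, config.depth_cu - crown,
                                 rng)
    # backbone tips currently sit at age 0 of a (depth - crown)-deep tree;
    # graft clade subtrees and push the backbone up by the crown depth
    clade_map: dict[str, str] = {}
    backbone_leaves = [n for n in _iter_nodes(backbone) if n.is_leaf]
    for leaf in backbone_leaves:
        name = leaf.label
        size = config.clade_blocks[name]
        labels = [f"{name}_{i + 1:03d}" for i in range(size)]
        for lab in labels:
            clade_map[lab] = name
        if size == 1:
            leaf.label = labels[0]
            leaf.length = (leaf.length or 0.0) + crown
        else:
            sub = _yule_ultrametric(labels, config.birth_rate, crown, rng)
            leaf.label = None
            leaf.length = leaf.length or 0.0  # stem keeps its backbone length
            for c in sub.children:
                leaf.add_child(c)
    tree = PhyloTree(backbone, rooted=True)
    model = SpeciesTreeModel(tree)
    if config.reticulations:
        events = [resolve_reticulation(model, clade_map, spec)
                  for spec in config.reticulations]
        model = SpeciesTreeModel(tree, events)
    return model, clade_map


def _iter_nodes(root: Node):
    stack = [root]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(n.children)


def resolve_reticulation(model: SpeciesTreeModel, clade_map: dict[str, str],
                         spec: ReticulationSpec) -> ReticulationEvent:
    """Resolve clade-named donor/recipient to edges and pick an event time."""

    def edge_of(side: str | tuple[str, ...]) -> Node:
        if isinstance(side, str):
            tips = [t for t, c in clade_map.items() if c == side]
            if not tips:
                raise TreeValidationError(f"unknown clade {side!r}")
        else:
            tips = list(side)
        node = model.tree.mrca(tips) if len(tips) > 1 \
            else next(l for l in model.tree.leaves() if l.label == tips[0])
        if node is model.tree.root:
            raise TreeValidationError("cannot use the root edge")
        return node

    donor = edge_of(spec.donor)
    recipient = edge_of(spec.recipient)
    d_lo, d_hi = model.edge_span(donor)
    r_lo, r_hi = model.edge_span(recipient)
    lo, hi = max(d_lo, r_lo), min(d_hi, r_hi)
    if not lo < hi:
        raise TreeValidationError(
            "donor and recipient edges do not overlap in time")
    return ReticulationEvent(
        donor_edge=frozenset(model._tips_below(donor)),
        recipient_edge=frozenset(model._tips_below(recipient)),
        gamma=spec.gamma,
        time=(lo + hi) / 2.0,
    )


# ---------------------------------------------------------------------------
# Gene-tree estimation error and supports
# ---------------------------------------------------------------------------

def _internal_edges(tree: PhyloTree) -> list[Node]:
    return [n for n in tree.preorder()
            if n.children and n.parent is not None]


def perturb_gene_tree(tree: PhyloTree, rng: np.random.Generator,
                      error_nni_rate: float = 1.0,
                      support_model: SupportModel = SupportModel()
                      ) -> tuple[PhyloTree, dict]:
    """Inject estimation error: random NNIs plus bootstrap-like supports.

    Applies ``Poisson(error_nni_rate)`` nearest-neighbour interchanges to
    the (binary) input.  Internal edges within graph distance 1 of a
    perturbed edge draw support from the low-support distribution, all
    others from the high-support distribution.  Returns the perturbed tree
    and a truth record of the perturbed edges' supports.
    """
    out = tree.copy()
    k = int(rng.poisson(error_nni_rate))
    touched: set[int] = set()
    n_applied = 0
    for _ in range(k):
        candidates = [v for v in _internal_edges(out)
                      if v.parent is not None and len(v.parent.children) >= 2
                      and len(v.children) >= 2]
        candidates = [v for v in candidates
                      if any(s is not v for s in v.parent.children)]
        if not candidates:
            break
        v = candidates[int(rng.integers(len(candidates)))]
        u = v.parent
        siblings = [s for s in u.children if s is not v]
        s = siblings[int(rng.integers(len(siblings)))]
        c = v.children[int(rng.integers(len(v.children)))]
        # swap subtree c (below v) with sibling s (below u)
        vi, ui = v.children.index(c), u.children.index(s)
        v.children[vi], u.children[ui] = s, c
        s.parent, c.parent = v, u
        n_applied += 1
        touched.add(id(v))
        touched.add(id(u))
        for nb in (*v.children, *u.children, u.parent):
            if nb is not None:
                touched.add(id(nb))
    low_sups, high_sups = [], []
    for node in _internal_edges(out):
        if id(node) in touched:
            node.support = float(rng.beta(*support_model.low))
            low_sups.append(node.support)
        else:
            node.support = float(rng.beta(*support_model.high))
            high_sups.append(node.support)
    record = {"n_nni": n_applied,
              "perturbed_supports": low_sups,
              "clean_supports": high_sups}
    return out, record


def assign_conflict_aware_supports(gene_tree: PhyloTree,
                                   reference_tree: PhyloTree,
                                   rng: np.random.Generator,
                                   support_model: SupportModel = SupportModel()
                                   ) -> PhyloTree:
    """Supports that track agreement with a reference topology.

    Edges whose induced split (on the tips shared with the reference) is
    present in the reference tree draw from the high-support distribution;
    conflicting edges draw from the low-support distribution.  This mimics
    the empirical tendency of bootstrap support to be weak exactly where a
    gene tree departs from the dominant signal.
    """
    out = gene_tree.copy()
    shared = set(out.tip_labels()) & set(reference_tree.tip_labels())
    labels = sorted(shared)
    index = {lab: i for i, lab in enumerate(labels)}
    ref = prune_to_taxa(reference_tree, shared) \
        if shared != set(reference_tree.tip_labels()) else reference_tree
    ref_masks = split_masks(ref, index)
    n = len(labels)
    full = (1 << n) - 1
    below: dict[int, int] = {}
    for node in out.postorder():
        if node.is_leaf:
            below[id(node)] = 1 << index[node.label] if node.label in index else 0
        else:
            m = 0
            for c in node.children:
                m |= below[id(c)]
            below[id(node)] = m
            if node.parent is None:
                continue
            mm = m ^ full if m & 1 else m
            s = mm.bit_count()
            if 2 <= s <= n - 2 and mm not in ref_masks:
                node.support = float(rng.beta(*support_model.low))
            else:
                node.support = float(rng.beta(*support_model.high))
    return out


# ---------------------------------------------------------------------------
# Missingness
# ---------------------------------------------------------------------------

def apply_missingness(gene_trees: list[tuple[str, PhyloTree]],
                      config: SimulationConfig,
                      rng: np.random.Generator,
                      clade_map: dict[str, str]
                      ) -> tuple[list[tuple[str, PhyloTree]], list[str]]:
    """Independent per-(tip, locus) dropout; outgroups drop out more.

    Each tip is retained in each locus with probability
    ``mean_locus_recovery`` (times the outgroup multiplier for outgroup
    tips).  Loci left with fewer than four tips are dropped and reported.
    """
    kept: list[tuple[str, PhyloTree]] = []
    dropped: list[str] = []
    for locus_id, tree in gene_trees:
        keep = []
        for tip in tree.tip_labels():
            p = config.mean_locus_recovery
            if clade_map.get(tip) == "outgroup":
                p *= config.outgroup_recovery_multiplier
            if rng.random() < p:
                keep.append(tip)
        if len(keep) < 4:
            dropped.append(locus_id)
            continue
        if len(keep) == len(tree.tip_labels()):
            kept.append((locus_id, tree))
        else:
            kept.append((locus_id, prune_to_taxa(tree, keep)))
    if not kept:
        raise TreeValidationError(
            "missingness removed every locus; retention too low")
    return kept, dropped


# ---------------------------------------------------------------------------
# Full study
# ---------------------------------------------------------------------------

def generate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate a complete synthetic study (pure function of the config)."""
    ss = np.random.SeedSequence(config.seed)
    s_species, s_genes, s_perturb, s_missing, s_plastome = ss.spawn(5)

    model, clade_map = generate_species_tree(
        config, np.random.default_rng(s_species))

    gene_seeds = s_genes.spawn(config.n_loci)
    perturb_seeds = s_perturb.spawn(config.n_loci)
    gene_trees: list[tuple[str, PhyloTree]] = []
    truth_perturb: dict[str, int] = {}
    for i in range(config.n_loci):
        locus = f"locus_{i + 1:03d}"
        g = simulate_contained_gene_tree(
            model, np.random.default_rng(gene_seeds[i]))
        prng = np.random.default_rng(perturb_seeds[i])
        g, rec = perturb_gene_tree(g, prng, config.error_nni_rate,
                                   config.support_model)
        if config.support_mode == "conflict_aware":
            g = assign_conflict_aware_supports(
                g, model.tree, prng, config.support_model)
        truth_perturb[locus] = rec["n_nni"]
        gene_trees.append((locus, g))

    gene_trees, dropped = apply_missingness(
        gene_trees, config, np.random.default_rng(s_missing), clade_map)

    # plastome: one haploid uniparental locus; coalescent-unit lengths
    # scale with 1/Ne, so multiply by the plastome rate factor
    ptree_template = model.tree.copy()
    for nd in ptree_template.preorder():
        if nd.length is not None:
            nd.length *= config.plastome_rate_scale
    p_events = [
        ReticulationEvent(
            donor_edge=ev.donor_edge, recipient_edge=ev.recipient_edge,
            gamma=ev.gamma, time=ev.time * config.plastome_rate_scale)
        for ev in model.reticulations
    ]
    pmodel = SpeciesTreeModel(ptree_template, p_events)
    prng = np.random.default_rng(s_plastome)
    # chloroplast capture: the uniparental plastome takes the donor path
    # deterministically rather than with probability gamma
    plastome = simulate_contained_gene_tree(
        pmodel, prng, force_reticulations=config.plastome_capture)

    truth = {
        "seed": config.seed,
        "reticulations": [
            {"donor": sorted(ev.donor_edge)[:3],
             "recipient_clades": sorted({clade_map[t]
                                         for t in ev.recipient_edge}),
             "donor_clades": sorted({clade_map[t] for t in ev.donor_edge}),
             "gamma": ev.gamma,
             "time": ev.time}
            for ev in model.reticulations
        ],
        "n_nni_per_locus": truth_perturb,
        "dropped_loci": dropped,
        "plastome_capture": bool(config.plastome_capture),
    }
    return SyntheticStudy(model=model, clade_map=clade_map,
                          gene_trees=gene_trees, plastome_tree=plastome,
                          truth=truth, config=config)
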
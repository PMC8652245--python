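"""Normalized tree-to-tree distances and per-locus distance profiling.

Three topology-only distances between a gene tree and a species tree are
provided, each normalized to [0, 1] with 0 meaning identical split sets:

* RF — Robinson–Foulds, symmetric difference of split sets over their
  total count ``(|S1\\S2|+|S2\\S1|)/(|S1|+|S2|)``;
* NYE — generalized RF with Jaccard-based split similarity, scored by an
  exact maximum-weight one-to-one matching, ``1 − 2S/(|S1|+|S2|)``;
* CI — clustering-information distance, matching splits by mutual
  clustering information, ``(H1+H2−2M)/(H1+H2)``.

All are defined for polytomous trees.  Profiling applies the study's
filters: collapse gene-tree edges below a support threshold, keep only
loci whose clade occupancy strictly exceeds a minimum, prune both trees to
the shared tips, then record one distance per requested metric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .errors import DegenerateTreeError, EmptyProfileError, TreeValidationError
from .splits import mutual_information_matrix, nye_score_matrix, split_masks, split_matrix
from .treeio import PhyloTree, clade_occupancy, collapse_low_support, prune_to_taxa

log = logging.getLogger(__name__)

METRICS = ("RF", "NYE", "CI")

__all__ = [
    "AnalysisOptions",
    "DistanceRecord",
    "DistanceProfile",
    "rf_distance",
    "nye_distance",
    "ci_distance",
    "tree_distances",
    "distance_profile",
]


@dataclass(frozen=True)
class AnalysisOptions:
    """Filter thresholds and metric selection for distance profiling."""

    collapse_threshold: float = 0.33
    occupancy_min: float = 0.75
    metrics: tuple[str, ...] = METRICS

    def __post_init__(self):
        if not (0.0 <= self.collapse_threshold <= 1.0):
            raise TreeValidationError("collapse_threshold must lie in [0, 1]")
        if not (0.0 <= self.occupancy_min <= 1.0):
            raise TreeValidationError("occupancy_min must lie in [0, 1]")
        bad = set(self.metrics) - set(METRICS)
        if bad:
            raise TreeValidationError(f"unknown metrics: {sorted(bad)}")


@dataclass(frozen=True)
class DistanceRecord:
    locus_id: str
    metric: str
    distance: float
    n_shared_tips: int
    occupancy: float


@dataclass
class DistanceProfile:
    """Per-locus distances of gene trees to a species tree within a clade."""

    clade_name: str
    records: list[DistanceRecord]
    summary: dict[str, tuple[int, float, float]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.summary:
            self.summary = self._summarize()

    def _summarize(self) -> dict[str, tuple[int, float, float]]:
        out = {}
        for metric in METRICS:
            vals = self.distances(metric)
            if vals:
                arr = np.asarray(vals)
                sd = float(arr.std(ddof=1)) if len(arr) > 1 else float("nan")
                out[metric] = (len(arr), float(arr.mean()), sd)
        return out

    def distances(self, metric: str) -> list[float]:
        return [r.distance for r in self.records if r.metric == metric]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.locus_id, self.clade_name, r.metric, r.distance,
              r.n_shared_tips, r.occupancy) for r in self.records],
            columns=["locus_id", "clade", "metric", "distance",
                     "n_shared_tips", "occupancy"],
        )


# ---------------------------------------------------------------------------
# Pairwise distances
# ---------------------------------------------------------------------------

def _shared_restriction(t1: PhyloTree, t2: PhyloTree):
    """Prune both trees to their shared tips; return split masks and size."""
    tips1, tips2 = set(t1.tip_labels()), set(t2.tip_labels())
    shared = tips1 & tips2
    if len(shared) < 4:
        raise DegenerateTreeError(
            f"trees share {len(shared)} < 4 tips")
    if tips1 - shared:
        t1 = prune_to_taxa(t1, shared)
    if tips2 - shared:
        t2 = prune_to_taxa(t2, shared)
    labels = sorted(shared)
    index = {lab: i for i, lab in enumerate(labels)}
    return sorted(split_masks(t1, index)), sorted(split_masks(t2, index)), len(labels)


def _matching_value(score: np.ndarray) -> float:
    """Value of a maximum-weight one-to-one split matching."""
    if score.size == 0:
        return 0.0
    rows, cols = linear_sum_assignment(score, maximize=True)
    return float(score[rows, cols].sum())


def _entropies(masks: list[int], n: int) -> float:
    total = 0.0
    for m in masks:
        a = m.bit_count()
        b = n - a
        total += -(a / n) * np.log2(a / n) - (b / n) * np.log2(b / n)
    return float(total)


def tree_distances(t1: PhyloTree, t2: PhyloTree,
                   metrics: Sequence[str] = METRICS) -> dict[str, float | None]:
    """All requested normalized distances computed on one shared restriction.

    Returns ``None`` for a metric whose normalization is undefined (both
    trees are stars on the shared tips).
    """
    s1, s2, n = _shared_restriction(t1, t2)
    out: dict[str, float | None] = {}
    total = len(s1) + len(s2)
    need_matrix = any(m in metrics for m in ("NYE", "CI"))
    if need_matrix:
        from .splits import _cells
        m1 = split_matrix(s1, n)
        m2 = split_matrix(s2, n)
        cells = _cells(m1, m2)
    if "RF" in metrics:
        if total == 0:
            out["RF"] = None
        else:
            shared = len(set(s1) & set(s2))
            out["RF"] = (total - 2 * shared) / total
    if "NYE" in metrics:
        if total == 0:
            out["NYE"] = None
        else:
            s = _matching_value(nye_score_matrix(m1, m2, cells))
            out["NYE"] = 1.0 - 2.0 * s / total
    if "CI" in metrics:
        h1 = _entropies(s1, n)
        h2 = _entropies(s2, n)
        if h1 + h2 == 0.0:
            out["CI"] = None
        else:
            mval = _matching_value(mutual_information_matrix(m1, m2, cells))
            out["CI"] = (h1 + h2 - 2.0 * mval) / (h1 + h2)
    # numerical guard: distances live in [0, 1]
    for k, v in out.items():
        if v is not None:
            out[k] = min(max(v, 0.0), 1.0)
    return out


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> float | None:
    """Normalized Robinson–Foulds distance on the shared-tip restriction."""
    return tree_distances(t1, t2, ("RF",))["RF"]


def nye_distance(t1: PhyloTree, t2: PhyloTree) -> float | None:
    """Nye generalized-RF distance under an exact optimal split matching."""
    return tree_distances(t1, t2, ("NYE",))["NYE"]


def ci_distance(t1: PhyloTree, t2: PhyloTree) -> float | None:
    """Clustering-information distance under an exact optimal matching."""
    return tree_distances(t1, t2, ("CI",))["CI"]


# ---------------------------------------------------------------------------
# Profiling
# ---------------------------------------------------------------------------

def distance_profile(species_tree: PhyloTree,
                     gene_trees: Iterable[tuple[str, PhyloTree]],
                     clade_taxa: Iterable[str] | str = "all",
                     opts: AnalysisOptions = AnalysisOptions(),
                     clade_name: str | None = None) -> DistanceProfile:
    """Per-locus distances of gene trees to the species tree within a clade.

    For each gene tree: edges with support strictly below the collapse
    threshold are contracted; the locus is kept only if its occupancy of
    ``clade_taxa`` strictly exceeds ``occupancy_min``; both trees are then
    pruned to the clade tips present in the gene tree and every requested
    metric is recorded.  Loci sharing fewer than four clade tips with the
    species tree are skipped with a warning.
    """
    if isinstance(clade_taxa, str):
        if clade_taxa != "all":
            raise TreeValidationError("clade_taxa must be a taxon set or 'all'")
        clade = set(species_tree.tip_labels())
        name = clade_name or "all"
    else:
        clade = set(clade_taxa)
        name = clade_name or "clade"
    missing = clade - set(species_tree.tip_labels())
    if missing:
        raise TreeValidationError(
            f"clade taxa absent from species tree: {sorted(missing)[:5]}")

    species_clade = prune_to_taxa(species_tree, clade) if \
        clade != set(species_tree.tip_labels()) else species_tree

    records: list[DistanceRecord] = []
    for locus_id, gtree in gene_trees:
        occ = clade_occupancy(gtree, clade)
        if not occ > opts.occupancy_min:
            continue
        shared = clade & set(gtree.tip_labels())
        if len(shared) < 4:
            log.warning("locus %s: only %d shared clade tips; skipped",
                        locus_id, len(shared))
            continue
        g = collapse_low_support(gtree, opts.collapse_threshold) \
            if opts.collapse_threshold > 0 else gtree
        if shared != set(g.tip_labels()):
            g = prune_to_taxa(g, shared)
        sp = prune_to_taxa(species_clade, shared) if shared != clade \
            else species_clade
        dists = tree_distances(sp, g, opts.metrics)
        for metric in opts.metrics:
            d = dists.get(metric)
            if d is None:
                log.warning("locus %s: %s distance undefined; skipped",
                            locus_id, metric)
                continue
            records.append(DistanceRecord(locus_id, metric, d,
                                          len(shared), occ))
    if not records:
        raise EmptyProfileError(
            f"no loci survive occupancy > {opts.occupancy_min} in clade {name!r}")
    return DistanceProfile(clade_name=name, records=records)
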
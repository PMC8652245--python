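"""Statistical layer: ILS-adequacy tests and among-clade comparisons.

The central scientific question is whether the discordance observed
between gene trees and the species tree exceeds what incomplete lineage
sorting alone would produce.  The answer is framed as:

* a two-tailed Welch's t-test comparing per-locus observed distances with
  distances of gene trees simulated under the multispecies coalescent on
  the same species tree (the ILS null), per clade and per metric;
* a one-way ANOVA across clades, with Tukey HSD post-hoc comparisons
  (Tukey–Kramer for unbalanced groups) summarized as a compact letter
  display, where clades sharing a letter are not significantly different.

Test statistics are computed from their defining formulas; p-values come
from the corresponding scipy.stats distributions (t, F, studentized
range).  Raw p-values are reported per test with no multiplicity
adjustment across clades or metrics.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .distances import AnalysisOptions, DistanceProfile, distance_profile
from .errors import EmptyProfileError, TreeValidationError
from .msc_sim import SpeciesTreeModel, simulate_gene_trees
from .treeio import PhyloTree

__all__ = [
    "TestResult",
    "AdequacyResult",
    "GroupComparison",
    "welch_t_test",
    "one_way_anova",
    "tukey_letters",
    "ils_adequacy_test",
    "among_clade_comparison",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    group_summaries: tuple[tuple[int, float, float], ...] = ()


@dataclass(frozen=True)
class AdequacyResult:
    """Observed-vs-ILS-expected contrast for one clade and metric."""

    clade: str
    metric: str
    observed: tuple[int, float, float]  # (n, mean, SD)
    expected: tuple[int, float, float]
    welch: TestResult
    excess: int  # +1 when observed mean exceeds the ILS expectation


@dataclass(frozen=True)
class GroupComparison:
    anova: TestResult
    tukey_pairs: tuple[tuple[str, str, float, float], ...]
    letters: Mapping[str, str]
    group_stats: Mapping[str, tuple[int, float, float]] = field(
        default_factory=dict)


def _summary(x: np.ndarray) -> tuple[int, float, float]:
    return (len(x), float(np.mean(x)),
            float(np.std(x, ddof=1)) if len(x) > 1 else float("nan"))


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-tailed Welch's t-test (unequal variances)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise TreeValidationError("each sample needs >= 2 values")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        raise TreeValidationError("both samples degenerate (zero variance)")
    nx, ny = len(x), len(y)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(float(t), float(df), float(p),
                      (_summary(x), _summary(y)))


def one_way_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """Classical one-way fixed-effects ANOVA."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise TreeValidationError("need >= 2 groups")
    if any(len(g) < 2 for g in arrs):
        raise TreeValidationError("each group needs >= 2 values")
    all_vals = np.concatenate(arrs)
    grand = all_vals.mean()
    n_total = len(all_vals)
    k = len(arrs)
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in arrs)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in arrs)
    df1, df2 = k - 1, n_total - k
    if ssw == 0.0:
        f = 0.0 if ssb == 0.0 else float("inf")
        p = 1.0 if ssb == 0.0 else 0.0
    else:
        f = (ssb / df1) / (ssw / df2)
        p = float(sps.f.sf(f, df1, df2))
    return TestResult(float(f), (float(df1), float(df2)), p,
                      tuple(_summary(g) for g in arrs))


def _compact_letters(names: list[str], means: dict[str, float],
                     sig_pairs: set[tuple[str, str]]) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups share a letter iff no significant difference separates them.
    Columns are ordered by the smallest mean they contain, so the display
    is invariant under relabeling.
    """
    cols: list[set[str]] = [set(names)]
    for a, b in sorted(sig_pairs):
        for col in [c for c in cols if a in c and b in c]:
            cols.remove(col)
            cols.extend([col - {a}, col - {b}])
        # absorb columns contained in another
        cols = [c for c in cols
                if c and not any(c < other for other in cols)]
        # deduplicate
        uniq: list[set[str]] = []
        for c in cols:
            if c not in uniq:
                uniq.append(c)
        cols = uniq
    cols.sort(key=lambda c: min(means[g] for g in c))
    alphabet = string.ascii_lowercase
    letters: dict[str, list[str]] = {g: [] for g in names}
    for i, col in enumerate(cols):
        for g in col:
            letters[g].append(alphabet[i % 26] * (1 + i // 26))
    return {g: "".join(sorted(v)) for g, v in letters.items()}


def tukey_letters(groups: Mapping[str, Sequence[float]],
                  alpha: float = 0.05) -> GroupComparison:
    """All-pairs Tukey HSD with a compact letter display.

    Uses the studentized-range distribution with the pooled within-group
    variance; unbalanced group sizes are handled with the Tukey–Kramer
    standard error.  Letters are assigned so two groups share a letter iff
    their adjusted p-value is >= alpha.
    """
    names = sorted(groups)
    arrs = {g: np.asarray(groups[g], dtype=float) for g in names}
    anova = one_way_anova([arrs[g] for g in names])
    k = len(names)
    n_total = sum(len(a) for a in arrs.values())
    df_w = n_total - k
    msw = sum(((a - a.mean()) ** 2).sum() for a in arrs.values()) / df_w
    means = {g: float(a.mean()) for g, a in arrs.items()}
    pairs = []
    sig: set[tuple[str, str]] = set()
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            diff = means[a] - means[b]
            se = np.sqrt(msw / 2.0 * (1.0 / len(arrs[a]) + 1.0 / len(arrs[b])))
            if se == 0.0:
                p = 1.0 if diff == 0.0 else 0.0
            else:
                q = abs(diff) / se
                p = float(sps.studentized_range.sf(q, k, df_w))
            pairs.append((a, b, float(diff), p))
            if p < alpha:
                sig.add((a, b))
    letters = _compact_letters(names, means, sig)
    return GroupComparison(
        anova=anova, tukey_pairs=tuple(pairs), letters=letters,
        group_stats={g: _summary(arrs[g]) for g in names})


# ---------------------------------------------------------------------------
# Pipeline-level tests
# ---------------------------------------------------------------------------

def expected_profile(model: SpeciesTreeModel,
                     simulated: Sequence[tuple[str, PhyloTree]] | None,
                     clade_taxa, opts: AnalysisOptions,
                     n_sim: int = 1000, seed: int | None = 0,
                     clade_name: str | None = None) -> DistanceProfile:
    """ILS-expected distance profile from simulated, uncollapsed gene trees.

    Simulated trees are binary and carry no supports, so only the pruning
    filter applies; they are complete, so occupancy is always 1.
    """
    if simulated is None:
        trees = simulate_gene_trees(model, n_sim, seed)
        simulated = [(f"sim_{i + 1:04d}", t) for i, t in enumerate(trees)]
    sim_opts = AnalysisOptions(collapse_threshold=0.0,
                               occupancy_min=opts.occupancy_min,
                               metrics=opts.metrics)
    return distance_profile(model.tree, simulated, clade_taxa, sim_opts,
                            clade_name=clade_name)


def ils_adequacy_test(model: SpeciesTreeModel,
                      observed_gene_trees: Sequence[tuple[str, PhyloTree]],
                      clade_taxa="all",
                      metric: str = "CI",
                      n_sim: int = 1000,
                      seed: int = 0,
                      opts: AnalysisOptions = AnalysisOptions(),
                      clade_name: str | None = None,
                      simulated: Sequence[tuple[str, PhyloTree]] | None = None,
                      ) -> AdequacyResult:
    """Is observed discordance explicable by incomplete lineage sorting?

    Observed gene trees are profiled with the usual filters (support
    collapsing, strict occupancy); the null is ``n_sim`` complete gene
    trees simulated under the multispecies coalescent on the species tree
    (pre-simulated trees may be supplied to share one null across
    clades).  A two-tailed Welch's t-test compares the per-locus distance
    samples; ``excess = +1`` flags observed discordance above the ILS
    expectation.
    """
    one_metric = AnalysisOptions(collapse_threshold=opts.collapse_threshold,
                                 occupancy_min=opts.occupancy_min,
                                 metrics=(metric,))
    try:
        obs = distance_profile(model.tree, observed_gene_trees, clade_taxa,
                               one_metric, clade_name=clade_name)
    except EmptyProfileError as e:
        raise EmptyProfileError(
            f"too few observed trees for the adequacy test: {e}") from e
    obs_d = obs.distances(metric)
    if len(obs_d) < 2:
        raise EmptyProfileError(
            "fewer than two observed loci survive the occupancy filter")
    exp = expected_profile(model, simulated, clade_taxa, one_metric,
                           n_sim=n_sim, seed=seed, clade_name=clade_name)
    exp_d = exp.distances(metric)
    welch = welch_t_test(obs_d, exp_d)
    mean_obs, mean_exp = float(np.mean(obs_d)), float(np.mean(exp_d))
    return AdequacyResult(
        clade=obs.clade_name, metric=metric,
        observed=_summary(np.asarray(obs_d)),
        expected=_summary(np.asarray(exp_d)),
        welch=welch,
        excess=+1 if mean_obs > mean_exp else -1,
    )


def among_clade_comparison(species_tree: PhyloTree,
                           gene_trees: Sequence[tuple[str, PhyloTree]],
                           clade_map: Mapping[str, str],
                           metric: str = "CI",
                           opts: AnalysisOptions = AnalysisOptions(),
                           alpha: float = 0.05,
                           min_clade_tips: int = 4,
                           exclude: Sequence[str] = ("outgroup",),
                           ) -> GroupComparison:
    """ANOVA + Tukey letters for per-clade discordance differences."""
    clades: dict[str, list[str]] = {}
    for tip, clade in clade_map.items():
        clades.setdefault(clade, []).append(tip)
    groups: dict[str, list[float]] = {}
    one_metric = AnalysisOptions(collapse_threshold=opts.collapse_threshold,
                                 occupancy_min=opts.occupancy_min,
                                 metrics=(metric,))
    for clade, tips in sorted(clades.items()):
        if clade in exclude or len(tips) < min_clade_tips:
            continue
        try:
            prof = distance_profile(species_tree, gene_trees, tips,
                                    one_metric, clade_name=clade)
        except EmptyProfileError:
            continue
        vals = prof.distances(metric)
        if len(vals) >= 2:
            groups[clade] = vals
    if len(groups) < 2:
        raise TreeValidationError(
            "among-clade comparison needs >= 2 clades with >= 2 loci each")
    return tukey_letters(groups, alpha=alpha)


def adequacy_table(results: Sequence[AdequacyResult]) -> pd.DataFrame:
    """Observed/expected summary rows, one per clade x metric."""
    rows = []
    for r in results:
        rows.append((r.clade, r.metric,
                     r.observed[0], r.observed[1], r.observed[2],
                     r.expected[0], r.expected[1], r.expected[2],
                     r.welch.statistic, r.welch.df, r.welch.p_value,
                     r.excess))
    return pd.DataFrame(rows, columns=[
        "clade", "metric", "obs_n", "obs_mean", "obs_sd",
        "exp_n", "exp_mean", "exp_sd", "t", "df", "p", "excess"])
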
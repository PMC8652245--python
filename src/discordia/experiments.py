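"""Canonical validation experiments for the discordance pipeline.

These drivers define the simulation studies used to validate the method:
closed-form coalescent calibration, type-I error of the ILS-adequacy test
under its own null, power against a γ-weighted introgression signal, and
the Robinson–Foulds sign anomaly produced by support-collapsing observed
trees while the ILS expectation stays binary.  Tests and the acceptance
script both run these so the validation study is defined in exactly one
place.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distances import AnalysisOptions, distance_profile
from .msc_sim import (
    ReticulationEvent,
    SpeciesTreeModel,
    simulate_gene_trees,
    three_taxon_concordance_probability,
)
from .stats import expected_profile, ils_adequacy_test
from .synthetic_data import (
    ReticulationSpec,
    SimulationConfig,
    assign_conflict_aware_supports,
    generate_species_tree,
)
from .treeio import PhyloTree, parse_newick

__all__ = [
    "coalescent_calibration",
    "three_clade_species_tree",
    "type1_calibration",
    "power_experiment",
    "sign_anomaly_experiment",
]


def coalescent_calibration(t_values=(0.5, 1.0, 2.0), n: int = 10000,
                           seed: int = 0) -> dict[float, tuple[float, float]]:
    """Empirical vs closed-form 3-taxon concordance probabilities.

    For each internal branch length ``t`` simulates ``n`` gene trees in a
    3-tip species tree and returns ``{t: (empirical, theoretical)}`` where
    the theory is ``1 − (2/3)·exp(−t)``.
    """
    out = {}
    for k, t in enumerate(t_values):
        sp = parse_newick(f"((A:1.5,B:1.5):{t},C:{1.5 + t});")
        model = SpeciesTreeModel(sp)
        conc = 0
        for g in simulate_gene_trees(model, n, seed * 1009 + k):
            node = g.mrca(["A", "B"])
            tips = set()
            stack = [node]
            while stack:
                x = stack.pop()
                if x.is_leaf:
                    tips.add(x.label)
                stack.extend(x.children)
            conc += tips == {"A", "B"}
        out[t] = (conc / n, three_taxon_concordance_probability(t))
    return out


# ---------------------------------------------------------------------------
# A fixed three-clade species tree used by the power experiment
# ---------------------------------------------------------------------------

def _eight_tip_clade(tag: str) -> str:
    t = [f"{tag}{i}" for i in range(1, 9)]
    s1 = f"(({t[0]}:1,{t[1]}:1):1,({t[2]}:1,{t[3]}:1):1):1"
    s2 = f"(({t[4]}:1,{t[5]}:1):1,({t[6]}:1,{t[7]}:1):1):1"
    return f"({s1},{s2})"


@dataclass(frozen=True)
class ThreeCladeTree:
    tree: PhyloTree
    clade_a: tuple[str, ...]
    clade_b: tuple[str, ...]
    clade_c: tuple[str, ...]


def three_clade_species_tree() -> ThreeCladeTree:
    """Ultrametric 26-tip species tree with three 8-tip clades + outgroup.

    Cherries coalesce at 1, subclades at 2, clade crowns at 3 coalescent
    units; clades A and B join at 6, C at 7, the outgroup at 8.  Internal
    branches of ~1 coalescent unit give moderate baseline ILS.
    """
    nwk = (f"((({_eight_tip_clade('a')}:3,{_eight_tip_clade('b')}:3):1,"
           f"{_eight_tip_clade('c')}:4):1,(o1:4,o2:4):4);")
    return ThreeCladeTree(
        tree=parse_newick(nwk),
        clade_a=tuple(f"a{i}" for i in range(1, 9)),
        clade_b=tuple(f"b{i}" for i in range(1, 9)),
        clade_c=tuple(f"c{i}" for i in range(1, 9)),
    )


def type1_calibration(n_replicates: int = 200, seed: int = 0,
                      n_loci: int = 100, n_sim: int = 200,
                      alpha: float = 0.05) -> float:
    """Rejection rate of the adequacy test when the null is true.

    Observed gene trees are drawn from the simulator's own null on a
    20-tip species tree; a well-calibrated two-tailed Welch test rejects
    about ``alpha`` of the time.
    """
    cfg = SimulationConfig(
        n_tips=20, clade_blocks={"cladeA": 8, "cladeB": 6, "outgroup": 6},
        depth_cu=8.0, clade_crown_cu=2.0, seed=seed)
    model, _ = generate_species_tree(cfg)
    opts = AnalysisOptions(collapse_threshold=0.0, occupancy_min=0.75)
    ss = np.random.SeedSequence(seed).spawn(2 * n_replicates)
    rejections = 0
    for rep in range(n_replicates):
        obs = [(f"L{i}", t) for i, t in
               enumerate(simulate_gene_trees(model, n_loci, ss[2 * rep]))]
        res = ils_adequacy_test(model, obs, "all", "CI", n_sim=n_sim,
                                seed=ss[2 * rep + 1], opts=opts)
        rejections += res.welch.p_value < alpha
    return rejections / n_replicates


def power_experiment(n_replicates: int = 50, seed: int = 0,
                     gamma: float = 0.3, n_loci: int = 100,
                     n_sim: int = 200, alpha: float = 0.05) -> dict:
    """Detection of excess within-clade discordance caused by gene flow.

    A reticulation moves genes between two non-sister cherries inside
    clade A with inheritance probability γ, inflating discordance among
    clade-A gene trees; clade C is an untouched control.  Returns the
    rates at which the CI-metric adequacy test rejects with positive
    excess for the recipient clade and rejects at all for the control.
    """
    fix = three_clade_species_tree()
    event = ReticulationEvent(
        donor_edge=frozenset(["a5", "a6"]),
        recipient_edge=frozenset(["a1", "a2"]),
        gamma=gamma, time=1.5)
    alt = SpeciesTreeModel(fix.tree, [event])
    null = SpeciesTreeModel(fix.tree)
    opts = AnalysisOptions(collapse_threshold=0.0, occupancy_min=0.75)
    ss = np.random.SeedSequence(seed + 1).spawn(3 * n_replicates)
    rej_recipient = 0
    rej_control = 0
    for rep in range(n_replicates):
        obs = [(f"L{i}", t) for i, t in
               enumerate(simulate_gene_trees(alt, n_loci, ss[3 * rep]))]
        res_a = ils_adequacy_test(null, obs, fix.clade_a, "CI", n_sim=n_sim,
                                  seed=ss[3 * rep + 1], opts=opts,
                                  clade_name="recipient")
        res_c = ils_adequacy_test(null, obs, fix.clade_c, "CI", n_sim=n_sim,
                                  seed=ss[3 * rep + 2], opts=opts,
                                  clade_name="control")
        rej_recipient += (res_a.welch.p_value < alpha and res_a.excess == +1)
        rej_control += res_c.welch.p_value < alpha
    return {"recipient_rejection_rate": rej_recipient / n_replicates,
            "control_rejection_rate": rej_control / n_replicates}


def sign_anomaly_experiment(seed: int = 0, n_loci: int = 100,
                            n_sim: int = 300,
                            collapse_threshold: float = 0.75) -> dict:
    """Observed-minus-expected mean distances under heavy collapsing.

    Observed gene trees are ILS draws (plus a weak γ=0.1 reticulation)
    whose edges carry bootstrap-like supports that are low exactly where
    the tree conflicts with the species tree; edges below the collapse
    threshold are contracted before profiling.  The ILS expectation uses
    binary, uncollapsed trees.  Because the |S1|+|S2| normalization
    shrinks the RF numerator faster than its denominator when conflicting
    splits vanish, the observed RF mean drops below the expectation while
    the information-weighted CI mean does not: collapsing poorly
    supported edges downplays discordance under RF.
    """
    cfg = SimulationConfig(
        n_tips=30,
        clade_blocks={"cladeA": 10, "cladeB": 8, "cladeC": 6, "outgroup": 6},
        depth_cu=8.0, clade_crown_cu=2.0, seed=21,
        reticulations=(ReticulationSpec(donor="cladeB", recipient="cladeA",
                                        gamma=0.1),))
    model, _ = generate_species_tree(cfg)
    ss = np.random.SeedSequence(seed + 2).spawn(3)
    obs_raw = simulate_gene_trees(model, n_loci, ss[0])
    rng = np.random.default_rng(ss[1])
    obs = [(f"L{i}", assign_conflict_aware_supports(g, model.tree, rng))
           for i, g in enumerate(obs_raw)]
    null = SpeciesTreeModel(model.tree)
    opts = AnalysisOptions(collapse_threshold=collapse_threshold,
                           occupancy_min=0.75)
    obs_prof = distance_profile(model.tree, obs, "all", opts)
    exp_prof = expected_profile(null, None, "all", opts, n_sim=n_sim,
                                seed=ss[2])
    out = {}
    for metric in ("RF", "NYE", "CI"):
        _, om, _ = obs_prof.summary[metric]
        _, em, _ = exp_prof.summary[metric]
        out[metric] = {"observed_mean": om, "expected_mean": em,
                       "difference": om - em}
    return out
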
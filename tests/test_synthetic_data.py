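"""Synthetic study generator: structure, error model, missingness, truth."""

import numpy as np
import pytest

from discordia.distances import rf_distance
from discordia.errors import TreeValidationError
from discordia.splits import nontrivial_splits
from discordia.synthetic_data import (
    ReticulationSpec,
    SimulationConfig,
    SupportModel,
    apply_missingness,
    assign_conflict_aware_supports,
    generate_species_tree,
    generate_study,
    perturb_gene_tree,
)
from discordia.treeio import parse_newick, write_newick


def clade_tips(tree, clade_map, clade):
    return {t for t in tree.tip_labels() if clade_map[t] == clade}


def is_monophyletic(tree, tips):
    node = tree.mrca(tips)
    below = set()
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            below.add(n.label)
        stack.extend(n.children)
    return below == set(tips)


class TestGenerateSpeciesTree:
    def test_blocks_are_monophyletic_and_sized(self):
        cfg = SimulationConfig(
            n_tips=24, clade_blocks={"A": 10, "B": 8, "outgroup": 6},
            seed=3)
        model, cmap = generate_species_tree(cfg)
        t = model.tree
        assert t.n_tips() == 24
        for clade, size in cfg.clade_blocks.items():
            tips = clade_tips(t, cmap, clade)
            assert len(tips) == size
            assert is_monophyletic(t, tips)

    def test_two_block_tree_is_pair_of_sister_clades(self):
        cfg = SimulationConfig(n_tips=10, clade_blocks={"A": 5, "B": 5},
                               seed=1)
        model, cmap = generate_species_tree(cfg)
        assert is_monophyletic(model.tree, clade_tips(model.tree, cmap, "A"))
        assert is_monophyletic(model.tree, clade_tips(model.tree, cmap, "B"))

    def test_depth_and_crown_scaling(self):
        cfg = SimulationConfig(n_tips=20, clade_blocks={"A": 10, "B": 10},
                               depth_cu=6.0, clade_crown_cu=1.5, seed=5)
        model, cmap = generate_species_tree(cfg)
        assert model.depth == pytest.approx(6.0)
        crown = model.tree.mrca(clade_tips(model.tree, cmap, "A"))
        assert model.ages[id(crown)] == pytest.approx(1.5)

    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(n_tips=20, clade_blocks={"A": 12, "B": 8},
                               seed=9)
        m1, _ = generate_species_tree(cfg)
        m2, _ = generate_species_tree(cfg)
        assert write_newick(m1.tree) == write_newick(m2.tree)

    def test_block_sum_mismatch_rejected(self):
        with pytest.raises(TreeValidationError):
            SimulationConfig(n_tips=10, clade_blocks={"A": 4, "B": 4})


class TestPerturbGeneTree:
    def _tree(self, rng):
        from conftest import random_tree_newick
        return parse_newick(random_tree_newick(20, rng))

    def test_zero_rate_keeps_topology_high_support(self, rng):
        t = self._tree(rng)
        out, rec = perturb_gene_tree(t, np.random.default_rng(0),
                                     error_nni_rate=0.0)
        assert rec["n_nni"] == 0
        assert nontrivial_splits(out) == nontrivial_splits(t)
        sups = [n.support for n in out.preorder()
                if n.support is not None]
        assert np.mean(sups) > 0.7

    def test_distance_grows_with_rate(self, rng):
        t = self._tree(rng)
        means = []
        for rate in (0.5, 2.0, 8.0):
            ds = []
            for s in range(12):
                out, _ = perturb_gene_tree(t, np.random.default_rng(s), rate)
                ds.append(rf_distance(t, out))
            means.append(np.mean(ds))
        assert means[0] < means[-1]

    def test_perturbed_edges_get_lower_support(self, rng):
        t = self._tree(rng)
        lows, highs = [], []
        for s in range(20):
            _, rec = perturb_gene_tree(t, np.random.default_rng(s), 2.0)
            lows.extend(rec["perturbed_supports"])
            highs.extend(rec["clean_supports"])
        assert np.mean(lows) < 0.33 < np.mean(highs)
        assert np.mean([v < 0.33 for v in lows]) > 0.75

    def test_tip_set_preserved(self, rng):
        t = self._tree(rng)
        out, _ = perturb_gene_tree(t, np.random.default_rng(3), 5.0)
        assert sorted(out.tip_labels()) == sorted(t.tip_labels())


class TestConflictAwareSupports:
    def test_concordant_edges_high_conflicting_low(self, rng):
        ref = parse_newick("(((a,b),(c,d)),((e,f),(g,h)));")
        gene = parse_newick("(((a,c),(b,d)),((e,f),(g,h)));")
        out = assign_conflict_aware_supports(gene, ref,
                                             np.random.default_rng(0))
        ref_splits = nontrivial_splits(ref)
        for n in out.preorder():
            if n.support is None or not n.children or n.parent is None:
                continue
        # conflicting splits {a,c} / {b,d} should carry low support
        lows, highs = [], []
        for n in out.preorder():
            if n.support is None:
                continue
            tips = set()
            stack = [n]
            while stack:
                x = stack.pop()
                if x.is_leaf:
                    tips.add(x.label)
                stack.extend(x.children)
            if tips in ({"a", "c"}, {"b", "d"}):
                lows.append(n.support)
            else:
                highs.append(n.support)
        assert max(lows) < min(highs)


class TestApplyMissingness:
    def _study_bits(self, seed=2):
        cfg = SimulationConfig(
            n_tips=20, clade_blocks={"A": 8, "B": 6, "outgroup": 6},
            n_loci=30, seed=seed)
        model, cmap = generate_species_tree(cfg)
        from discordia.msc_sim import simulate_gene_trees
        trees = [(f"L{i}", t) for i, t in
                 enumerate(simulate_gene_trees(model, cfg.n_loci, seed))]
        return cfg, cmap, trees

    def test_full_retention_is_identity(self):
        cfg, cmap, trees = self._study_bits()
        cfg = SimulationConfig(
            n_tips=20, clade_blocks={"A": 8, "B": 6, "outgroup": 6},
            n_loci=30, mean_locus_recovery=1.0,
            outgroup_recovery_multiplier=1.0, seed=2)
        kept, dropped = apply_missingness(trees, cfg,
                                          np.random.default_rng(0), cmap)
        assert not dropped
        assert all(k.n_tips() == 20 for _, k in kept)

    def test_retention_matches_binomial_expectation(self):
        cfg, cmap, trees = self._study_bits()
        kept, _ = apply_missingness(trees, cfg, np.random.default_rng(1),
                                    cmap)
        counts = {}
        for _, t in kept:
            for tip in t.tip_labels():
                counts[tip] = counts.get(tip, 0) + 1
        ingroup = [counts.get(t, 0) for t, c in cmap.items()
                   if c != "outgroup"]
        expect = cfg.mean_locus_recovery * cfg.n_loci
        se = np.sqrt(cfg.n_loci * cfg.mean_locus_recovery
                     * (1 - cfg.mean_locus_recovery) / len(ingroup))
        assert abs(np.mean(ingroup) - expect) < 4 * se
        outgroup = [counts.get(t, 0) for t, c in cmap.items()
                    if c == "outgroup"]
        assert np.mean(outgroup) < np.mean(ingroup)

    def test_zero_retention_errors(self):
        cfg, cmap, trees = self._study_bits()
        tiny = SimulationConfig(
            n_tips=20, clade_blocks={"A": 8, "B": 6, "outgroup": 6},
            n_loci=30, mean_locus_recovery=1e-9, seed=2)
        with pytest.raises(TreeValidationError):
            apply_missingness(trees, tiny, np.random.default_rng(0), cmap)


class TestGeneratorCalibration:
    def test_error_free_studies_match_ils_expectation(self):
        """With no gene flow and no estimation error, observed profiles are
        Welch-indistinguishable from the coalescent expectation in the
        overwhelming majority of replicate studies."""
        from discordia.distances import AnalysisOptions
        from discordia.stats import ils_adequacy_test

        nonsig = 0
        reps = 25
        for rep in range(reps):
            cfg = SimulationConfig(
                n_tips=12, clade_blocks={"A": 5, "B": 4, "outgroup": 3},
                n_loci=40, depth_cu=6.0, clade_crown_cu=1.5,
                error_nni_rate=0.0, mean_locus_recovery=1.0,
                outgroup_recovery_multiplier=1.0, seed=300 + rep)
            study = generate_study(cfg)
            res = ils_adequacy_test(
                study.model, study.gene_trees, "all", "CI",
                n_sim=100, seed=900 + rep,
                opts=AnalysisOptions(collapse_threshold=0.33))
            nonsig += res.welch.p_value >= 0.05
        assert nonsig >= 0.8 * reps, nonsig


class TestGenerateStudy:
    def test_byte_identical_reproducibility(self, tmp_path, small_study):
        from discordia.synthetic_data import SimulationConfig, generate_study
        cfg = small_study.config
        again = generate_study(cfg)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        small_study.write(d1)
        again.write(d2)
        for name in ("species.nwk", "genetrees.nwk", "plastome.nwk",
                     "clades.tsv", "truth.json", "config.yaml"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_truth_records_reticulation_recipient(self):
        cfg = SimulationConfig(
            n_tips=24, clade_blocks={"A": 10, "B": 8, "outgroup": 6},
            n_loci=10,
            reticulations=(ReticulationSpec(donor="B", recipient="A",
                                            gamma=0.3),),
            seed=4)
        study = generate_study(cfg)
        assert study.truth["reticulations"][0]["recipient_clades"] == ["A"]
        assert study.truth["reticulations"][0]["gamma"] == pytest.approx(0.3)

    def test_every_gene_tip_in_clade_map(self, small_study):
        for _, g in small_study.gene_trees:
            assert all(t in small_study.clade_map for t in g.tip_labels())

    def test_plastome_capture_moves_recipient_clade(self):
        base = dict(
            n_tips=24, clade_blocks={"A": 10, "B": 8, "outgroup": 6},
            n_loci=4, error_nni_rate=0.0,
            reticulations=(ReticulationSpec(donor="B", recipient="A",
                                            gamma=0.1),),
            depth_cu=12.0, clade_crown_cu=1.0)
        # with capture the plastome of clade A descends through B's stem,
        # so A+B resolve together; informative only when A and B are not
        # already sisters in the species tree
        moved, stayed, informative = 0, 0, 0
        for seed in range(10):
            cap = generate_study(SimulationConfig(
                **base, plastome_capture=True, seed=seed))
            ab = clade_tips(cap.model.tree, cap.clade_map, "A") \
                | clade_tips(cap.model.tree, cap.clade_map, "B")
            if is_monophyletic(cap.model.tree, ab):
                continue  # blocks drawn as sisters: capture is invisible
            informative += 1
            ref = generate_study(SimulationConfig(
                **base, plastome_capture=False, seed=seed))
            moved += is_monophyletic(cap.plastome_tree, ab)
            stayed += is_monophyletic(ref.plastome_tree, ab)
        assert informative >= 3
        assert moved > stayed
        assert moved >= informative - 1
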
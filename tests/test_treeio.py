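"""Tree model, Newick round-trips, rooting, collapsing, pruning."""

import numpy as np
import pytest

from discordia.errors import (
    DegenerateTreeError,
    NewickParseError,
    TreeValidationError,
    UnrootableError,
)
from discordia.splits import nontrivial_splits
from discordia.treeio import (
    PhyloTree,
    clade_occupancy,
    collapse_low_support,
    parse_newick,
    prune_to_taxa,
    read_clade_table,
    read_tree_file,
    root_with_outgroups,
    write_newick,
    write_tree_file,
)

from conftest import random_tree_newick


class TestParseNewick:
    def test_supports_auto_detected_as_percent(self):
        t = parse_newick("((a:1,b:1)90:0.5,c:1.5);")
        (node,) = [n for n in t.preorder() if n.support is not None]
        assert node.support == pytest.approx(0.90)
        assert node.length == pytest.approx(0.5)

    def test_bare_two_leaf_tree(self):
        t = parse_newick("(a,b);")
        assert sorted(t.tip_labels()) == ["a", "b"]
        assert all(n.length is None and n.support is None
                   for n in t.preorder())

    def test_duplicate_tips_rejected(self):
        with pytest.raises(TreeValidationError, match="duplicate"):
            parse_newick("((a,b),(a,c));")

    def test_fractional_supports_kept_as_is(self):
        t = parse_newick("((a,b)0.75:1,(c,d)0.5:1);")
        sups = sorted(n.support for n in t.preorder() if n.support is not None)
        assert sups == [0.5, 0.75]

    @pytest.mark.parametrize("bad", ["((a,b);", "(a,(b,c);", "(a,b)", ""])
    def test_malformed_input_reports_offset(self, bad):
        with pytest.raises(NewickParseError) as err:
            parse_newick(bad)
        assert err.value.offset is not None

    def test_support_above_100_rejected(self):
        with pytest.raises(TreeValidationError, match="support"):
            parse_newick("((a,b)150,(c,d));")

    def test_polytomies_preserved(self):
        t = parse_newick("(a,b,c,d,e);")
        assert len(t.root.children) == 5


class TestWriteNewick:
    def test_roundtrip_preserves_splits_lengths_supports(self, rng):
        for _ in range(15):
            nwk = random_tree_newick(int(rng.integers(4, 40)), rng,
                                     with_support=True)
            t = parse_newick(nwk)
            t2 = parse_newick(write_newick(t))
            assert nontrivial_splits(t) == nontrivial_splits(t2)
            for a, b in zip(t.preorder(), t2.preorder()):
                if a.length is not None:
                    assert b.length == pytest.approx(a.length, abs=1e-9)
                if a.support is not None:
                    assert b.support == pytest.approx(a.support, abs=1e-9)

    def test_lengthless_tree_has_no_colons(self):
        t = parse_newick("((a,b),c);")
        assert ":" not in write_newick(t)

    def test_percent_scale_writes_bootstrap_style(self):
        t = parse_newick("((a:1,b:1)90:0.5,c:1.5);")
        assert ")90:" in write_newick(t, support_scale="percent")
        assert ")0.9:" in write_newick(t, support_scale="fraction")

    def test_large_random_roundtrip(self, rng):
        nwk = random_tree_newick(200, rng, with_support=True)
        t = parse_newick(nwk)
        assert nontrivial_splits(parse_newick(write_newick(t))) \
            == nontrivial_splits(t)


class TestRootWithOutgroups:
    def test_roots_on_pendant_outgroup_edge(self):
        t = parse_newick("(out1,(a,(b,c)));")
        r = root_with_outgroups(t, [{"out1"}, {"melissa"}])
        assert r.rooted
        sides = [sorted(l.label for l in PhyloTree(c, True).leaves())
                 if c.children else [c.label] for c in r.root.children]
        assert ["out1"] in sides

    def test_fallback_to_second_priority_set(self):
        t = parse_newick("((a,b),(c,melissa));")
        r = root_with_outgroups(t, [{"out1"}, {"melissa"}])
        sides = []
        for c in r.root.children:
            stack, labs = [c], []
            while stack:
                n = stack.pop()
                if n.is_leaf:
                    labs.append(n.label)
                stack.extend(n.children)
            sides.append(sorted(labs))
        assert ["melissa"] in sides

    def test_no_outgroup_present_raises(self):
        t = parse_newick("((a,b),(c,d));")
        with pytest.raises(UnrootableError):
            root_with_outgroups(t, [{"out1"}])

    def test_rooting_preserves_unrooted_splits(self, rng):
        for _ in range(10):
            nwk = random_tree_newick(12, rng, with_support=True)
            t = parse_newick(nwk)
            r = root_with_outgroups(t, [{"t0", "t1"}])
            assert nontrivial_splits(r) == nontrivial_splits(t)

    def test_multi_taxon_outgroup_clade(self):
        t = parse_newick("(((o1,o2),a),(b,c));")
        r = root_with_outgroups(t, [{"o1", "o2"}])
        for c in r.root.children:
            stack, labs = [c], set()
            while stack:
                n = stack.pop()
                if n.is_leaf:
                    labs.add(n.label)
                stack.extend(n.children)
            if labs == {"o1", "o2"}:
                return
        raise AssertionError("outgroup clade not subtended by the root")


class TestCollapseLowSupport:
    def test_below_threshold_collapsed(self):
        t = parse_newick("((a,b)30,(c,d)90);", support_scale="percent")
        c = collapse_low_support(t, 0.33)
        assert len(nontrivial_splits(c)) == 1

    def test_exactly_at_threshold_retained(self):
        t = parse_newick("((a,b)33,c,(d,e)90);", support_scale="percent")
        c = collapse_low_support(t, 0.33)
        assert len(nontrivial_splits(c)) == 2
        t2 = parse_newick("((a,b)32,c,(d,e)90);", support_scale="percent")
        assert len(nontrivial_splits(collapse_low_support(t2, 0.33))) == 1

    def test_fully_supported_tree_unchanged(self):
        t = parse_newick("((a,b)99,(c,d)98);", support_scale="percent")
        assert nontrivial_splits(collapse_low_support(t, 0.33)) \
            == nontrivial_splits(t)

    def test_idempotent_and_tipset_stable(self, rng):
        nwk = random_tree_newick(20, rng, with_support=True)
        t = parse_newick(nwk)
        once = collapse_low_support(t, 0.5)
        twice = collapse_low_support(once, 0.5)
        assert nontrivial_splits(once) == nontrivial_splits(twice)
        assert sorted(once.tip_labels()) == sorted(t.tip_labels())

    def test_threshold_out_of_range(self):
        t = parse_newick("((a,b),(c,d));")
        with pytest.raises(TreeValidationError):
            collapse_low_support(t, 1.5)


class TestPruneToTaxa:
    def test_topology_after_pruning(self):
        t = parse_newick("((a,b),(c,d));")
        p = prune_to_taxa(t, {"a", "b", "c"})
        assert sorted(p.tip_labels()) == ["a", "b", "c"]

    def test_pruning_to_all_is_identity(self):
        t = parse_newick("((a:1,b:2):0.5,(c:1,d:1):0.5);")
        p = prune_to_taxa(t, {"a", "b", "c", "d"})
        assert nontrivial_splits(p) == nontrivial_splits(t)

    def test_path_lengths_summed(self):
        t = parse_newick("((a:1,b:1):1,c:2);")
        p = prune_to_taxa(t, {"a", "c"})
        # a sits 1 below the suppressed node, whose 1-long edge merges
        lengths = {n.label: n.length for n in p.leaves()}
        total = sum(n.length for n in p.preorder() if n.length is not None)
        assert total == pytest.approx(4.0)  # a:1 + merged 1+... c:2

    def test_pairwise_path_lengths_preserved(self, rng):
        nwk = random_tree_newick(15, rng)
        t = parse_newick(nwk)

        def path_len(tree, x, y):
            # distances via root paths
            def to_root(label):
                node = next(l for l in tree.leaves() if l.label == label)
                path = {}
                d = 0.0
                while node is not None:
                    path[id(node)] = d
                    d += node.length or 0.0
                    node = node.parent
                return path
            px, py = to_root(x), to_root(y)
            node = next(l for l in tree.leaves() if l.label == y)
            d = 0.0
            while id(node) not in px:
                d += node.length or 0.0
                node = node.parent
            return d + px[id(node)]

        keep = ["t1", "t3", "t5", "t8"]
        p = prune_to_taxa(t, keep)
        for x, y in [("t1", "t3"), ("t5", "t8"), ("t1", "t8")]:
            assert path_len(p, x, y) == pytest.approx(path_len(t, x, y),
                                                      abs=1e-9)

    def test_merged_edge_takes_min_support(self):
        t = parse_newick("(((a,b)40,(c,d)90)80,(e,f)95);",
                         support_scale="percent")
        p = prune_to_taxa(t, {"a", "b", "e", "f"})
        sups = sorted(n.support for n in p.preorder() if n.support is not None)
        # the 40-support edge merges with the 80 path edge -> min 0.4
        assert sups[0] == pytest.approx(0.4)

    def test_too_few_survivors(self):
        t = parse_newick("((a,b),(c,d));")
        with pytest.raises(DegenerateTreeError):
            prune_to_taxa(t, {"a"})


class TestCladeOccupancy:
    @pytest.mark.parametrize("clade,expect", [
        ({"a", "b", "c", "d"}, 1.0),
        ({"a", "b", "x", "y", "z"}, 0.4),
        ({"x", "y"}, 0.0),
    ])
    def test_fraction(self, clade, expect):
        t = parse_newick("((a,b),(c,d));")
        assert clade_occupancy(t, clade) == pytest.approx(expect)

    def test_empty_clade_rejected(self):
        t = parse_newick("((a,b),(c,d));")
        with pytest.raises(TreeValidationError):
            clade_occupancy(t, set())


class TestFileIO:
    def test_tree_file_roundtrip(self, tmp_path, rng):
        trees = [(f"locus_{i}",
                  parse_newick(random_tree_newick(8, rng, with_support=True)))
                 for i in range(4)]
        path = tmp_path / "genes.nwk"
        write_tree_file(path, trees)
        back = read_tree_file(path)
        assert [name for name, _ in back] == [name for name, _ in trees]
        for (_, a), (_, b) in zip(trees, back):
            assert nontrivial_splits(a) == nontrivial_splits(b)

    def test_clade_table_parsing(self, tmp_path):
        path = tmp_path / "clades.tsv"
        path.write_text("# comment\nA_1\tcladeA\nB_1\tcladeB\n")
        assert read_clade_table(path) == {"A_1": "cladeA", "B_1": "cladeB"}

    def test_clade_table_bad_line(self, tmp_path):
        path = tmp_path / "clades.tsv"
        path.write_text("A_1 cladeA\n")  # space, not tab
        with pytest.raises(TreeValidationError):
            read_clade_table(path)
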
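import math

import dendropy
import numpy as np
import pytest

from radiascope import msc
from radiascope.tree import (
    collapse_low_support,
    differing_branches,
    read_newick,
    rf_distance,
    tree_metrics,
    write_newick,
)


class TestNewickIO:
    def test_parse_four_taxon(self, balanced4):
        assert balanced4.taxa == {"A", "B", "C", "D"}
        assert balanced4.bipartitions() == {frozenset({"C", "D"})}
        internal = balanced4.internal_edges()
        assert len(internal) == 1 and internal[0].length == 0.5

    def test_support_and_length_parsed(self):
        t = read_newick("((A:1,B:1)0.97:0.5,(C:1,D:1):0.5);")
        node = t.internal_edges()[0]
        assert node.support == 0.97 and node.length == 0.5

    def test_round_trip_random_20_taxa(self, rng):
        taxa = [f"sp{i}" for i in range(20)]
        t = msc.random_topology(taxa, rng)
        for node in t.preorder():
            if node is not t.root:
                node.length = float(rng.random())
        s = write_newick(t)
        t2 = read_newick(s)
        assert write_newick(t2) == s
        assert t2.bipartitions() == t.bipartitions()

    @pytest.mark.parametrize("bad", ["((A,B);", "(A,(B,);", "((A,B),(A,C));", ""])
    def test_malformed_or_duplicate_errors(self, bad):
        with pytest.raises(ValueError):
            read_newick(bad)

    def test_bipartitions_invariant_to_child_order(self, rng):
        taxa = [f"t{i}" for i in range(10)]
        t = msc.random_topology(taxa, rng)
        ref = t.bipartitions()
        for _ in range(10):
            t2 = t.copy()
            for node in t2.preorder():
                if node.children:
                    order = rng.permutation(len(node.children))
                    node.children = [node.children[i] for i in order]
            assert t2.bipartitions() == ref


class TestRF:
    def test_identical_trees_zero(self, rng):
        t = msc.random_topology([f"t{i}" for i in range(8)], rng)
        assert rf_distance(t, t.copy()) == 0.0

    def test_one_nni_six_taxa(self):
        t1 = read_newick("(((A,B),C),((D,E),F));")
        t2 = read_newick("(((A,C),B),((D,E),F));")
        assert rf_distance(t1, t2) == 2.0
        assert differing_branches(t1, t2) == 1.0
        assert rf_distance(t1, t2, normalized=True) == pytest.approx(2 / 6)

    def test_binary_vs_star(self):
        t1 = read_newick("(((A,B),C),D,E);")
        star = read_newick("(A,B,C,D,E);")
        assert rf_distance(t1, star) == 2.0

    def test_taxon_mismatch_reported(self):
        t1 = read_newick("((A,B),(C,D));")
        t2 = read_newick("((A,B),(C,E));")
        with pytest.raises(ValueError, match="E"):
            rf_distance(t1, t2)

    def test_metric_properties_against_dendropy(self, rng):
        """RF equals dendropy's symmetric difference on 50 random 8-taxon pairs."""
        taxa = [f"t{i}" for i in range(8)]
        tns = dendropy.TaxonNamespace(taxa)
        for _ in range(50):
            t1 = msc.random_topology(taxa, rng)
            t2 = msc.random_topology(taxa, rng)
            mine = rf_distance(t1, t2)
            d1 = dendropy.Tree.get(data=write_newick(t1), schema="newick", taxon_namespace=tns)
            d2 = dendropy.Tree.get(data=write_newick(t2), schema="newick", taxon_namespace=tns)
            d1.encode_bipartitions()
            d2.encode_bipartitions()
            ref = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
            assert mine == ref
            assert mine == rf_distance(t2, t1)
            assert mine >= 0


class TestCollapse:
    def test_all_supported_unchanged(self):
        t = read_newick("(((A,B)0.99:1,C)0.95:1,((D,E)1.0:1,F):1);")
        out = collapse_low_support(t, 0.95)
        assert out.bipartitions() == t.bipartitions()

    @staticmethod
    def _has_split(tree, side):
        side = frozenset(side)
        return side in tree.bipartitions() or (tree.taxa - side) in tree.bipartitions()

    def test_one_low_edge_contracted(self):
        t = read_newick("(((A,B)0.90:1,C)0.99:1,((D,E)0.99:1,F):1);")
        out = collapse_low_support(t, 0.95)
        assert len(out.bipartitions()) == len(t.bipartitions()) - 1
        assert not self._has_split(out, {"A", "B"})

    def test_star_unchanged(self):
        star = read_newick("(A,B,C,D);")
        assert collapse_low_support(star, 0.95).bipartitions() == set()

    def test_zero_threshold_identity_and_idempotent(self):
        t = read_newick("(((A,B)0.5:1,C)0.7:1,(D,E)0.9:1);")
        assert collapse_low_support(t, 0.0).bipartitions() == t.bipartitions()
        once = collapse_low_support(t, 0.8)
        twice = collapse_low_support(once, 0.8)
        assert once.bipartitions() == twice.bipartitions()

    def test_unannotated_edges_kept(self):
        t = read_newick("(((A,B):1,C)0.5:1,(D,E):1,F:1);")
        out = collapse_low_support(t, 0.95)
        assert self._has_split(out, {"A", "B"})
        assert self._has_split(out, {"D", "E"})
        assert not self._has_split(out, {"A", "B", "C"})

    def test_root_edge_contracts_both_sides(self):
        # the two root edges of a rooted tree are one unrooted edge: a low
        # support on either side dissolves the split entirely
        t = read_newick("(((A,B):1,C)0.5:1,(D,E):1);")
        out = collapse_low_support(t, 0.95)
        assert not self._has_split(out, {"D", "E"})
        assert self._has_split(out, {"A", "B"})

    def test_percent_scale_autodetected(self):
        t = read_newick("(((A,B)90:1,C)99:1,(D,E)100:1);")
        out = collapse_low_support(t, 95)
        assert frozenset({"A", "B"}) not in out.bipartitions()
        with pytest.raises(ValueError, match="scale"):
            collapse_low_support(t, 0.95 * 200)

    def test_mixed_scales_error(self):
        t = read_newick("(((A,B)0.9:1,C)99:1,(D,E):1);")
        with pytest.raises(ValueError, match="mixed"):
            collapse_low_support(t, 95)


class TestMetrics:
    def test_ultrametric_clocklikeness_zero(self, balanced4):
        assert tree_metrics(balanced4).clocklikeness == pytest.approx(0.0)

    def test_population_sd_convention(self):
        # root-to-tip distances {1, 1, 1, 2}: population sd sqrt(0.1875),
        # mean 1.25 -> CV = 0.34641... (the n-denominator convention)
        t = read_newick("((A:1,B:1):0,(C:1,D:2):0);")
        m = tree_metrics(t, rooted_for_clock=True)
        assert m.clocklikeness == pytest.approx(math.sqrt(0.1875) / 1.25)

    def test_caterpillar_diameter_brute_force(self, rng):
        taxa = [f"t{i}" for i in range(5)]
        t = msc.random_topology(taxa, rng)
        for n in t.preorder():
            if n is not t.root:
                n.length = float(rng.random()) + 0.1
        # brute-force all-pairs maximum
        leaves = t.leaves()
        depths = t.depths()
        clades = t.clades()
        best = 0.0
        for i, a in enumerate(leaves):
            for b in leaves[i + 1 :]:
                lca = next(
                    n
                    for n in t.preorder()
                    if a.label in clades.get(n, {a.label}) and b.label in clades.get(n, set())
                    and all(
                        not (a.label in clades.get(c, set()) and b.label in clades.get(c, set()))
                        for c in n.children
                    )
                )
                best = max(best, depths[a] + depths[b] - 2 * depths[lca])
        assert t.diameter() == pytest.approx(best)

    def test_stemminess_bounds_and_supports(self):
        t = read_newick("(((A:1,B:1)0.99:2,C:1)0.90:1,(D:1,E:1)0.97:1);")
        m = tree_metrics(t)
        assert 0.0 <= m.stemminess <= 1.0
        assert m.mean_support == pytest.approx((0.99 + 0.90 + 0.97) / 3)
        assert m.prop_support_above[0.95] == pytest.approx(2 / 3)

    def test_zero_depth_clocklikeness_missing(self):
        t = read_newick("((A:0,B:0):0,(C:0,D:0):0);")
        assert tree_metrics(t).clocklikeness is None


class TestRestrict:
    def test_restrict_sums_lengths(self):
        t = read_newick("(((A:1,B:1):2,C:3):1,D:4);")
        r = t.restrict({"A", "C", "D"})
        assert r.taxa == {"A", "C", "D"}
        # A's path length to the AC ancestor: 1 + 2 = 3
        depths = r.depths()
        leaf_a = next(n for n in r.leaves() if n.label == "A")
        assert depths[leaf_a] == pytest.approx(t.depths()[next(n for n in t.leaves() if n.label == "A")])

    def test_restrict_missing_taxon_error(self, balanced4):
        with pytest.raises(ValueError):
            balanced4.restrict({"A", "B", "Z"})
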
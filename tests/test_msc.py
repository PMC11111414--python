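import math

import numpy as np
import pytest

from radiascope import msc
from radiascope.quartets import msc_match_probability
from radiascope.tree import read_newick, rf_distance, write_newick

from conftest import quartet_internal_cu


class TestSpeciesTree:
    def test_determinism(self):
        a = msc.simulate_species_tree(6, seed=1)
        b = msc.simulate_species_tree(6, seed=1)
        assert write_newick(a.tree) == write_newick(b.tree)

    def test_ultrametric(self):
        m = msc.simulate_species_tree(12, seed=2)
        depths = m.tree.depths()
        tips = [depths[t] for t in m.tree.leaves()]
        assert max(tips) - min(tips) < 1e-9 * max(tips)

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            msc.simulate_species_tree(3, seed=0)

    def test_yule_root_age_expectation(self):
        """Backward Yule: E[root age] = sum_{k=2..n} 1/(k*lambda); 500 reps, 3 SE."""
        lam, n, reps = 0.5, 8, 500
        expected = sum(1.0 / (k * lam) for k in range(2, n + 1))
        var = sum(1.0 / (k * lam) ** 2 for k in range(2, n + 1))
        ages = []
        for i in range(reps):
            m = msc.simulate_species_tree(n, birth_rate=lam, seed=10_000 + i)
            ages.append(max(m.tree.depths().values()))
        se = math.sqrt(var / reps)
        assert abs(np.mean(ages) - expected) < 3 * se


class TestUnitConversion:
    @pytest.mark.parametrize(
        "T,ne,g,expected",
        [(1.0, 5.0e5, 1.0, 1.0), (5.0, 1.25e6, 1.0, 2.0)],
    )
    def test_printed_equation(self, T, ne, g, expected):
        t = read_newick(f"((A:{T},B:{T}):{T},(C:{2*T},D:{2*T}));", unit="Ma")
        m = msc.SpeciesTreeModel(t).fill_defaults(ne=ne, gen_time=g)
        cu = msc.time_to_coalescent_units(m)
        node = next(
            n for n in cu.preorder() if not n.is_leaf and n is not cu.root
        )
        assert node.length == pytest.approx(expected)

    def test_round_trip_12_digits(self):
        m = msc.simulate_species_tree(8, seed=3, ne=7.7e5, gen_time=2.3)
        cu = msc.time_to_coalescent_units(m)
        back = msc.coalescent_to_time(cu, m)
        for a, b in zip(m.tree.preorder(), back.preorder()):
            if a.length is not None:
                assert b.length == pytest.approx(a.length, rel=1e-12)

    def test_large_ne_kills_signal(self):
        t = read_newick("((A:1,B:1):1,(C:2,D:2));", unit="Ma")
        m = msc.SpeciesTreeModel(t).fill_defaults(ne=1e15)
        _, _, d, _ = next(x for x in m.branch_table() if x[0] == frozenset({"A", "B"}))
        assert d < 1e-6

    def test_missing_ne_names_branch(self):
        t = read_newick("((A:1,B:1):1,(C:2,D:2));", unit="Ma")
        m = msc.SpeciesTreeModel(t)
        with pytest.raises(ValueError, match="A"):
            msc.time_to_coalescent_units(m)


class TestGeneTrees:
    def _four_taxon(self, d):
        t = read_newick(f"((A:1,B:1):{d},(C:{1+d},D:{1+d}));", unit="Ma")
        return msc.SpeciesTreeModel(t).fill_defaults()  # Ne=5e5, g=1: Ma == CU

    def _match_freq(self, gts):
        hit = 0
        for gt in gts:
            bips = gt.bipartitions()
            if frozenset({"C", "D"}) in bips or frozenset({"A", "B"}) in bips:
                hit += 1
        return hit / len(gts)

    def test_polytomy_limit_one_third(self):
        gts = msc.simulate_gene_trees(self._four_taxon(1e-9), 6000, seed=4)
        q = self._match_freq(gts)
        assert abs(q - 1 / 3) < 3 * math.sqrt((1 / 3) * (2 / 3) / 6000)

    def test_ln2_branch_two_thirds(self):
        d = math.log(2.0)
        gts = msc.simulate_gene_trees(self._four_taxon(d), 10_000, seed=5)
        assert abs(self._match_freq(gts) - 2 / 3) < 0.015

    def test_long_branch_concordant(self):
        gts = msc.simulate_gene_trees(self._four_taxon(10.0), 2000, seed=6)
        assert self._match_freq(gts) > 0.999

    def test_determinism_and_units(self):
        m = self._four_taxon(0.5)
        a = msc.simulate_gene_trees(m, 5, seed=7)
        b = msc.simulate_gene_trees(m, 5, seed=7)
        assert [write_newick(t) for t in a] == [write_newick(t) for t in b]
        subs = msc.simulate_gene_trees(m, 5, seed=7, unit="subs/site")
        # same topologies, scaled lengths
        for ta, ts in zip(a, subs):
            assert ta.bipartitions() == ts.bipartitions()


class TestHybridization:
    def test_gamma_zero_matches_plain(self, caterpillar6_model):
        m = caterpillar6_model
        donor, recip = frozenset({"C"}), frozenset({"E"})
        hyb, rer = msc.simulate_hybrid_gene_trees(m, donor, recip, 0.0, 20, seed=8)
        plain = msc.simulate_gene_trees(m, 20, seed=8)
        assert not rer.any()
        assert [write_newick(t) for t in hyb] == [write_newick(t) for t in plain]

    def test_gamma_one_pure_alternative(self, caterpillar6_model):
        m = caterpillar6_model
        alt = msc.reroute_clade(m, frozenset({"C"}), frozenset({"E"}))
        hyb, rer = msc.simulate_hybrid_gene_trees(
            m, frozenset({"C"}), frozenset({"E"}), 1.0, 400, seed=9
        )
        assert rer.all()
        # with gamma=1 the C+E cherry should dominate (its stem is 1 CU)
        ce = sum(
            1 for t in hyb
            if frozenset({"C", "E"}) in t.bipartitions()
            or t.taxa - frozenset({"C", "E"}) in t.bipartitions()
        )
        expected = msc_match_probability(quartet_internal_cu(alt, "C", "E", "A", "D"))
        assert ce / 400 > 0.5
        assert expected > 0.5

    def test_mixture_matches_closed_form(self, caterpillar6_model):
        """Observed quartet frequencies follow the two-tree MSC mixture."""
        m = caterpillar6_model
        donor, recip = frozenset({"C"}), frozenset({"E"})
        gamma = 0.3
        alt = msc.reroute_clade(m, donor, recip)
        n_loci = 10_000
        gts, _ = msc.simulate_hybrid_gene_trees(m, donor, recip, gamma, n_loci, seed=10)
        # quartet (A, B, C, E): principal pairing ab|ce via closed form each tree
        def p_match(model, quartet, pairing):
            L = quartet_internal_cu(model, *pairing)
            return msc_match_probability(L)

        # P(ab|ce) under principal: separating path for pair (a,b) vs (c,e)
        p_main = p_match(m, None, ("A", "B", "C", "E"))
        p_alt = p_match(alt, None, ("A", "B", "C", "E"))
        expected = (1 - gamma) * p_main + gamma * p_alt
        hit = 0
        for t in gts:
            sub = t.restrict({"A", "B", "C", "E"})
            bips = sub.bipartitions()
            if frozenset({"C", "E"}) in bips or frozenset({"B", "A"}) in bips:
                hit += 1
        assert abs(hit / n_loci - expected) < 0.02

    def test_non_overlapping_branches_error(self, caterpillar6_model):
        m = caterpillar6_model
        # clade {A,B} stem spans [1,2]; clade {A..E} stem spans [4,5]: no overlap
        with pytest.raises(ValueError):
            msc.reroute_clade(m, frozenset("ABCDE"), frozenset({"A", "B"}))


class TestGeneTreeError:
    def test_identity(self, rng):
        gts = [msc.random_topology([f"t{i}" for i in range(8)], rng) for _ in range(5)]
        out = msc.apply_gene_tree_error(gts, 0.0, 0.0, seed=0)
        assert [write_newick(a) for a in out] == [write_newick(a) for a in gts]

    def test_collapse_count_exact(self, rng):
        gts = [msc.random_topology([f"t{i}" for i in range(10)], rng) for _ in range(10)]
        out = msc.apply_gene_tree_error(gts, 0.0, 0.5, seed=1)
        for t in out:
            # binary 10-taxon tree has 7 internal edges; floor(0.5 * 7) = 3 cut
            assert len(t.internal_edges()) == 7 - 3

    def test_rf_nondecreasing_in_p_nni(self, rng):
        taxa = [f"t{i}" for i in range(10)]
        gts = [msc.random_topology(taxa, rng) for _ in range(200)]
        means = []
        for p in (0.0, 0.05, 0.2):
            noisy = msc.apply_gene_tree_error(gts, p, 0.0, seed=2)
            means.append(np.mean([rf_distance(a, b) for a, b in zip(gts, noisy)]))
        assert means[0] <= means[1] <= means[2]
        assert means[0] == 0.0

    def test_branch_length_noise_median_one(self, rng):
        gts = [msc.random_topology([f"t{i}" for i in range(6)], rng) for _ in range(300)]
        noisy = msc.apply_branch_length_noise(gts, 0.3, seed=3)
        ratios = []
        for a, b in zip(gts, noisy):
            for na, nb in zip(a.preorder(), b.preorder()):
                if na is not a.root and na.length:
                    ratios.append(nb.length / na.length)
        assert abs(np.median(ratios) - 1.0) < 0.05
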
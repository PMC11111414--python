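import itertools
import math

import numpy as np
import pytest

from radiascope import msc, quartets
from radiascope.quartets import (
    CoalescentLength,
    QuartetSupport,
    asymmetry_pvalue,
    asymmetry_test,
    benjamini_hochberg,
    branch_quartet_frequencies,
    branch_quartet_frequencies_enum,
    coalescent_branch_length,
    estimate_species_tree,
    local_posterior,
    local_posterior_quadrature,
    msc_match_probability,
    multilocus_bootstrap,
    polytomy_test,
    topology_key,
    total_quartet_score,
    total_quartet_score_enum,
    QuartetLabeler,
)
from radiascope.tree import read_newick, rf_distance, write_newick


def random_instance(rng, max_taxa=8, max_gts=8):
    """Random species tree + gene trees with missing taxa and polytomies."""
    n = int(rng.integers(5, max_taxa + 1))
    taxa = [f"T{i}" for i in range(n)]
    sp = msc.random_topology(taxa, rng)
    gts = []
    for _ in range(int(rng.integers(2, max_gts + 1))):
        k = int(rng.integers(4, n + 1))
        sub = [taxa[i] for i in rng.choice(n, size=k, replace=False)]
        gt = msc.random_topology(sub, rng)
        if rng.random() < 0.5:
            gt = msc.apply_gene_tree_error(
                [gt], 0.0, float(rng.random() * 0.6), seed=int(rng.integers(1 << 30))
            )[0]
        gts.append(gt)
    return sp, gts


class TestBranchFrequencies:
    def test_identical_gene_trees_full_support(self, rng):
        sp = msc.random_topology([f"T{i}" for i in range(7)], rng)
        gts = [sp.copy() for _ in range(5)]
        for qs in branch_quartet_frequencies(sp, gts):
            assert qs.q1 == pytest.approx(1.0)

    def test_handcrafted_six_taxon_matches_oracle(self):
        sp = read_newick("(((A,B),C),((D,E),F));")
        gts = [
            read_newick("(((A,C),B),((D,E),F));"),
            read_newick("(((A,B),C),((D,F),E));"),
            read_newick("((A,B),(C,(D,E)),F);"),  # polytomy at root
            read_newick("(((A,B),D),((C,E),F));"),
            read_newick("((A,(B,C)),(E,F));"),  # missing D
        ]
        fast = branch_quartet_frequencies(sp, gts, weighting="raw")
        slow = branch_quartet_frequencies_enum(sp, gts, weighting="raw")
        assert len(fast) == 3
        for f, s in zip(fast, slow):
            assert f.branch == s.branch
            assert (f.n1, f.n2, f.n3) == pytest.approx((s.n1, s.n2, s.n3))

    @pytest.mark.parametrize("weighting", ["raw", "per-gene"])
    def test_oracle_equivalence_random(self, rng, weighting):
        for _ in range(60):
            sp, gts = random_instance(rng)
            fast = branch_quartet_frequencies(sp, gts, weighting=weighting)
            slow = branch_quartet_frequencies_enum(sp, gts, weighting=weighting)
            for f, s in zip(fast, slow):
                assert f.branch == s.branch
                assert (f.n1, f.n2, f.n3) == pytest.approx((s.n1, s.n2, s.n3))

    def test_msc_expectation_d_half(self):
        t = read_newick("((A:1,B:1):0.5,(C:1.5,D:1.5));", unit="Ma")
        m = msc.SpeciesTreeModel(t).fill_defaults()
        gts = msc.simulate_gene_trees(m, 10_000, seed=1)
        (qs,) = branch_quartet_frequencies(m.tree, gts)
        assert abs(qs.q1 - msc_match_probability(0.5)) < 0.015

    def test_frequencies_sum_to_one(self, rng):
        sp, gts = random_instance(rng)
        for qs in branch_quartet_frequencies(sp, gts):
            if qs.effective_n > 0:
                assert sum(qs.frequencies) == pytest.approx(1.0)


class TestTotalScore:
    def test_candidate_equal_to_only_topology(self, rng):
        t = msc.random_topology([f"T{i}" for i in range(6)], rng)
        count, frac = total_quartet_score(t, [t.copy()] * 4)
        assert frac == pytest.approx(1.0)

    def test_five_taxon_all_topologies_match_oracle(self, rng):
        taxa = [f"T{i}" for i in range(5)]
        gts = [msc.random_topology(taxa, rng) for _ in range(6)]
        labeler = QuartetLabeler(gts, taxa)
        seen = set()
        for _ in range(40):
            cand = msc.random_topology(taxa, rng)
            key = topology_key(cand)
            if key in seen:
                continue
            seen.add(key)
            assert labeler.score(cand)[0] == pytest.approx(
                total_quartet_score_enum(cand, gts)[0]
            )
        assert len(seen) >= 10  # covered most of the 15 topologies

    def test_true_tree_beats_nni_neighbours(self):
        m = msc.simulate_species_tree(8, birth_rate=0.1, seed=5)
        gts = msc.simulate_gene_trees(m, 1000, seed=6)
        labeler = QuartetLabeler(gts, m.tree.taxa)
        true_score = labeler.score(m.tree)[0]
        from radiascope.quartets import _nni_neighbours

        for nb in _nni_neighbours(m.tree):
            assert labeler.score(nb)[0] <= true_score + 1e-9

    def test_empty_gene_trees_error(self, rng):
        t = msc.random_topology(["a", "b", "c", "d"], rng)
        with pytest.raises(ValueError):
            total_quartet_score(t, [])


class TestCoalescentLength:
    def test_inversion_points(self):
        assert coalescent_branch_length(1 / 3) == CoalescentLength(0.0, False)
        assert coalescent_branch_length(2 / 3).d == pytest.approx(math.log(2))
        assert coalescent_branch_length(1.0) == CoalescentLength(10.0, True)
        assert coalescent_branch_length(0.1).d == 0.0

    def test_round_trip(self):
        for d in (0.1, 0.7, 2.5):
            q1 = msc_match_probability(d)
            assert coalescent_branch_length(q1).d == pytest.approx(d)


class TestLocalPosterior:
    def test_symmetry_and_prior(self):
        assert local_posterior((10, 10, 10)) == pytest.approx((1 / 3,) * 3)
        assert local_posterior((0, 0, 0)) == pytest.approx((1 / 3,) * 3)

    @pytest.mark.parametrize("ns", [(60, 25, 15), (12, 3, 2), (3.7, 2.2, 1.1)])
    def test_closed_form_equals_quadrature(self, ns):
        cf = local_posterior(ns)
        qd = local_posterior_quadrature(ns)
        assert cf == pytest.approx(qd, abs=1e-6)

    def test_monotone_in_n1(self):
        prev = 0.0
        for n1 in (5, 10, 20, 40, 80):
            pp = local_posterior((n1, 5, 5))[0]
            assert pp >= prev
            prev = pp


class TestPolytomyTest:
    def test_uniform_counts(self):
        assert polytomy_test((100, 100, 100)) == pytest.approx(1.0)

    def test_worked_examples(self):
        # (200,50,50): X2 = 150; (40,30,30): X2 = 2 -> p = exp(-1)
        assert polytomy_test((200, 50, 50)) == pytest.approx(2.7e-33, rel=0.05)
        assert polytomy_test((40, 30, 30)) == pytest.approx(math.exp(-1))

    def test_zero_counts_missing(self):
        assert polytomy_test((0, 0, 0)) is None


class TestAsymmetry:
    def test_equal_counts_half(self):
        assert asymmetry_pvalue(500, 500) == 0.5

    def test_worked_example(self):
        p = asymmetry_pvalue(550, 450)
        assert p == pytest.approx(0.001565 / 2, rel=1e-2)
        assert asymmetry_pvalue(450, 550) == pytest.approx(1 - 0.001565 / 2, rel=1e-2)

    def test_bh_step_up(self):
        assert benjamini_hochberg([0.01, 0.02, 0.04]) == pytest.approx(
            [0.03, 0.03, 0.04]
        )
        # monotone step-up: adjusted values are nondecreasing in the raw order
        ps = [0.005, 0.04, 0.03, 0.8]
        adj = benjamini_hochberg(ps)
        order = np.argsort(ps)
        assert all(
            adj[order[i]] <= adj[order[i + 1]] + 1e-12 for i in range(len(ps) - 1)
        )

    def test_table_families(self):
        branches = [
            QuartetSupport(frozenset({"x"}), (frozenset(),) * 4, 500, 300, 200),
            QuartetSupport(frozenset({"y"}), (frozenset(),) * 4, 400, 310, 290),
        ]
        df = asymmetry_test(branches)
        assert set(df["comparison"]) == {"main", "alt"}
        assert len(df) == 4
        assert ((df["p_bh"] >= df["p_raw"]) | df["p_bh"].isna()).all()


class TestBootstrap:
    def test_homogeneous_full_support(self, rng):
        t = msc.random_topology([f"T{i}" for i in range(6)], rng)
        support, failed = multilocus_bootstrap([t.copy()] * 5, 50, seed=0)
        assert failed == 0
        assert all(v == 1.0 for v in support.values())

    def test_matches_exhaustive_resample_expectation(self):
        A = read_newick("((a,b),(c,d),e);")
        B = read_newick("((a,c),(b,d),e);")
        gts = [A, A, B]
        ref = estimate_species_tree(gts)
        exact = {b: 0 for b in ref.bipartitions()}
        for combo in itertools.product(range(3), repeat=3):
            est = estimate_species_tree([gts[i] for i in combo])
            bips = est.bipartitions()
            for b in exact:
                exact[b] += b in bips
        support, _ = multilocus_bootstrap(gts, 3000, seed=4, reference=ref)
        for b, cnt in exact.items():
            assert abs(support[b] - cnt / 27) < 0.03

    def test_seeded_reproducibility(self, rng):
        taxa = [f"T{i}" for i in range(5)]
        gts = [msc.random_topology(taxa, rng) for _ in range(6)]
        s1, _ = multilocus_bootstrap(gts, 30, seed=9)
        s2, _ = multilocus_bootstrap(gts, 30, seed=9)
        assert s1 == s2


class TestEstimator:
    def test_single_topology_recovered(self, rng):
        t = msc.random_topology([f"T{i}" for i in range(7)], rng)
        est = estimate_species_tree([t.copy()] * 3)
        assert est.bipartitions() == t.bipartitions()

    def test_disconnected_taxa_error(self):
        g1 = read_newick("((a,b),(c,d));")
        g2 = read_newick("((e,f),(g,h));")
        with pytest.raises(ValueError, match="never co-occur"):
            estimate_species_tree([g1, g2])

    def test_consistency_on_msc_data(self):
        """True topology recovered from 2,000 clean loci (moderate ILS)."""
        hits = 0
        for rep in range(8):
            m = msc.simulate_species_tree(10, birth_rate=0.3, seed=300 + rep)
            for clade, T, d, _ in m.branch_table():
                if 2 <= len(clade) <= 8 and d < 0.5 and T > 0:
                    m.ne[clade] = T * 1e6 / (2 * 0.5)  # floor internal d at 0.5
            gts = msc.simulate_gene_trees(m, 2000, seed=400 + rep)
            est = estimate_species_tree(gts)
            hits += est.bipartitions() == m.tree.bipartitions()
        assert hits >= 7
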
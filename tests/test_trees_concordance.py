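"""Concordance factors, CF asymmetry, concordance trees, tree conflict."""

import warnings

import dendropy
import numpy as np
import pytest
from scipy import stats

from introkit.trees_concordance import (AdmixtureEstimate, Clade,
                                        ConcordanceEstimate, TreeError,
                                        asymmetry_test, bipartition_conflicts,
                                        concordance_factor,
                                        constraint_skeleton, excess_cf,
                                        parse_tree, primary_concordance_tree,
                                        rf_distance, tree_bipartitions,
                                        tree_taxa)

UNIVERSE6 = frozenset("abcdef")


def est(taxa, cf, lo=None, hi=None, universe=UNIVERSE6, n=100):
    return ConcordanceEstimate(clade=Clade.of(taxa, universe), cf=cf,
                               ci_low=cf if lo is None else lo,
                               ci_high=cf if hi is None else hi,
                               n_genes=n, method="indicator")


# ---------------------------------------------------------------------------
# clades


class TestClade:
    def test_canonical_form_is_smaller_side(self):
        c = Clade.of({"a", "b", "c", "d"}, UNIVERSE6)
        assert c.side == frozenset({"e", "f"})
        assert Clade.of({"e", "f"}, UNIVERSE6) == c

    def test_conflict_detection(self):
        ab = Clade.of({"a", "b"}, UNIVERSE6)
        bc = Clade.of({"b", "c"}, UNIVERSE6)
        cd = Clade.of({"c", "d"}, UNIVERSE6)
        assert ab.conflicts_with(bc) and bc.conflicts_with(ab)
        assert not ab.conflicts_with(cd)
        abc = Clade.of({"a", "b", "c"}, UNIVERSE6)
        assert not ab.conflicts_with(abc)  # nested

    def test_degenerate_sides_rejected(self):
        with pytest.raises(TreeError):
            Clade.of(set(), UNIVERSE6)
        with pytest.raises(TreeError):
            Clade.of(UNIVERSE6, UNIVERSE6)


# ---------------------------------------------------------------------------
# concordance factors


class TestConcordanceFactor:
    def test_clade_in_every_tree_gives_cf_one(self):
        trees = [parse_tree("((a,b),(c,(d,(e,f))));") for _ in range(12)]
        c = Clade.of({"a", "b"}, UNIVERSE6)
        e = concordance_factor(trees, c, n_boot=200, seed=1)
        assert (e.cf, e.ci_low, e.ci_high) == (1.0, 1.0, 1.0)
        assert e.n_genes == 12 and e.method == "indicator"

    def test_ten_locus_bootstrap_matches_exact_binomial_quantiles(self):
        """Percentile bootstrap of a 0/1 indicator mean is Binomial(10, 3/10)/10."""
        with_clade = parse_tree("(((a,b),c),(d,(e,f)));")
        without = parse_tree("(((a,c),b),(d,(e,f)));")
        trees = [with_clade] * 3 + [without] * 7
        c = Clade.of({"a", "b"}, UNIVERSE6)
        e = concordance_factor(trees, c, n_boot=10_000, seed=7)
        assert e.cf == pytest.approx(0.3)
        lo_exact = stats.binom.ppf(0.025, 10, 0.3) / 10
        hi_exact = stats.binom.ppf(0.975, 10, 0.3) / 10
        assert abs(e.ci_low - lo_exact) <= 0.05
        assert abs(e.ci_high - hi_exact) <= 0.05

    def test_posterior_sample_method(self):
        a = parse_tree("(((a,b),c),(d,(e,f)));")
        b = parse_tree("(((a,c),b),(d,(e,f)));")
        loci = [[a, a, b, b], [a, b, b, b]]  # per-locus tree samples
        c = Clade.of({"a", "b"}, UNIVERSE6)
        e = concordance_factor(loci, c, n_boot=100, seed=2)
        assert e.method == "posterior-mean"
        assert e.cf == pytest.approx((0.5 + 0.25) / 2)

    def test_absent_clade_taxa_raise(self):
        trees = [parse_tree("((a,b),(c,d));")]
        with pytest.raises(TreeError, match="absent"):
            concordance_factor(trees, Clade.of({"x", "y"}, {"x", "y", "z", "w"}),
                               n_boot=10, seed=0)

    def test_interval_covers_true_frequency(self):
        """CI coverage for a clade with true per-locus frequency 0.305."""
        rng = np.random.default_rng(123)
        with_clade = parse_tree("(((a,b),c),(d,(e,f)));")
        alt1 = parse_tree("(((a,c),b),(d,(e,f)));")
        alt2 = parse_tree("(((b,c),a),(d,(e,f)));")
        c = Clade.of({"a", "b"}, UNIVERSE6)
        covered = within = 0
        n_rep = 60
        for rep in range(n_rep):
            picks = rng.choice(3, size=500, p=[0.305, 0.4, 0.295])
            trees = [(with_clade, alt1, alt2)[k] for k in picks]
            e = concordance_factor(trees, c, n_boot=500, seed=rep)
            covered += e.ci_low <= 0.305 <= e.ci_high
            within += e.ci_low <= e.cf <= e.ci_high
        assert within == n_rep
        assert covered / n_rep >= 0.90


class TestAsymmetry:
    def test_disjoint_intervals_significant(self):
        a = est({"a", "b", "c"}, 0.305, 0.272, 0.339)
        b = est({"b", "c", "d"}, 0.136, 0.112, 0.162)
        assert asymmetry_test(a, b)

    def test_identical_intervals_not_significant(self):
        a = est({"a", "b"}, 0.2, 0.1, 0.3)
        assert not asymmetry_test(a, a)

    def test_shared_endpoint_counts_as_overlap(self):
        assert not asymmetry_test((0.10, 0.20), (0.20, 0.30))
        assert asymmetry_test((0.10, 0.19), (0.20, 0.30))


class TestExcessCf:
    def test_single_mirror(self):
        adm = excess_cf(est({"a", "b", "c"}, 0.305, 0.272, 0.339),
                        [est({"b", "c", "d"}, 0.092)])
        assert adm.excess == pytest.approx(0.213)
        assert adm.significant
        assert "21%" in adm.interpretation

    def test_mean_of_multiple_alternatives(self):
        adm = excess_cf(est({"a", "b", "c"}, 0.188, 0.17, 0.205),
                        [est({"a", "d"}, 0.052, 0.039, 0.06),
                         est({"a", "e"}, 0.041, 0.027, 0.058)])
        assert adm.excess == pytest.approx(0.1415)
        assert "14%" in adm.interpretation

    def test_equal_cfs_give_zero_excess_not_significant(self):
        adm = excess_cf(est({"a", "b"}, 0.2, 0.15, 0.25),
                        [est({"b", "c"}, 0.2, 0.15, 0.25)])
        assert adm.excess == 0
        assert not adm.significant

    def test_empty_alternatives_rejected(self):
        with pytest.raises(TreeError):
            excess_cf(est({"a", "b"}, 0.2), [])


# ---------------------------------------------------------------------------
# primary concordance tree


def brute_force_compatible(clades):
    """Oracle: pairwise compatibility via the four-intersection test."""
    return all(not a.conflicts_with(b) for a in clades for b in clades if a != b)


class TestPrimaryConcordanceTree:
    def test_compatible_clades_all_present(self):
        cf_table = [est({"a", "b"}, 0.9), est({"a", "b", "c"}, 0.8),
                    est({"e", "f"}, 0.7)]
        tree = primary_concordance_tree(cf_table)
        bips = set(tree_bipartitions(tree))
        for e in cf_table:
            assert e.clade in bips

    def test_higher_cf_wins_conflicts(self):
        universe = frozenset("abcd")
        ab = ConcordanceEstimate(Clade.of({"a", "b"}, universe), 0.4, 0.3, 0.5,
                                 10, "indicator")
        bc = ConcordanceEstimate(Clade.of({"b", "c"}, universe), 0.3, 0.2, 0.4,
                                 10, "indicator")
        tree = primary_concordance_tree([ab, bc])
        bips = set(tree_bipartitions(tree))
        assert ab.clade in bips and bc.clade not in bips

    def test_random_cf_tables_give_valid_trees(self):
        rng = np.random.default_rng(31)
        taxa = list("abcdefgh")
        universe = frozenset(taxa)
        for rep in range(25):
            clades = set()
            while len(clades) < 8:
                k = rng.integers(2, 7)
                clades.add(Clade.of(rng.choice(taxa, size=k, replace=False),
                                    universe))
            table = [ConcordanceEstimate(c, float(rng.random()) * 0.5 + 0.25,
                                         0.2, 0.9, 10, "indicator")
                     for c in clades]
            tree = primary_concordance_tree(table)
            assert tree_taxa(tree) == universe
            bips = list(tree_bipartitions(tree))
            assert brute_force_compatible(bips)
            # every accepted clade beats or is compatible with the rest:
            # no rejected clade is compatible with the whole accepted set
            accepted = set(bips)
            for e in sorted(table, key=lambda e: -e.cf):
                if e.clade not in accepted:
                    assert any(e.clade.conflicts_with(c) for c in accepted)

    def test_plurality_topology_of_simulated_gene_trees_recovered(self):
        from introkit.synthetic_data import Scenario, simulate_gene_trees
        sc = Scenario(topology="quartet", tau12=1.0, tau_root=2.0, n_loci=300,
                      seed=44)
        trees = [parse_tree(t.newick()) for t in simulate_gene_trees(sc)]
        universe = frozenset({"P1", "P2", "P3", "O"})
        table = [concordance_factor(trees, Clade.of(pair, universe),
                                    n_boot=100, seed=1)
                 for pair in ({"P1", "P2"}, {"P1", "P3"}, {"P2", "P3"})]
        pct = primary_concordance_tree(table)
        assert rf_distance(pct, parse_tree("(((P1,P2),P3),O);")) == 0


# ---------------------------------------------------------------------------
# bipartition conflicts


class TestBipartitionConflicts:
    def test_identical_trees_have_no_conflicts(self):
        t = parse_tree("((a,b),(c,(d,(e,f))));")
        assert bipartition_conflicts(t, parse_tree("((a,b),(c,(d,(e,f))));")) == []

    def test_mito_nuclear_toy_conflict(self):
        nuclear = parse_tree("((ophrys,tarsalis),(americanus,sansoni));")
        mito = parse_tree("(((ophrys,americanus),sansoni),tarsalis);")
        conflicts = bipartition_conflicts(nuclear, mito)
        universe = frozenset({"ophrys", "tarsalis", "americanus", "sansoni"})
        target = Clade.of({"ophrys", "tarsalis"}, universe)
        assert any(target in pair for pair in conflicts)

    def test_symmetric_when_unfiltered(self):
        a = parse_tree("((a,b),((c,d),(e,f)));")
        b = parse_tree("((a,c),((b,d),(e,f)));")
        ab = {(x.side, y.side) for x, y in bipartition_conflicts(a, b)}
        ba = {(y.side, x.side) for x, y in bipartition_conflicts(b, a)}
        assert ab == ba

    def test_support_filter_drops_weak_bipartitions(self):
        a = parse_tree("((a,b)95,((c,d)40,(e,f)99));")
        b = parse_tree("((a,c)0,((b,d)0,(e,f)0));")
        all_conf = bipartition_conflicts(a, b, min_support=0)
        strong = bipartition_conflicts(a, b, min_support=90)
        weak_side = frozenset({"c", "d"})
        assert any(x.side == weak_side for x, _ in all_conf)
        assert not any(weak_side in (x.side, y.side) for x, y in strong)

    def test_too_few_shared_taxa_rejected(self):
        with pytest.raises(TreeError, match="shared"):
            bipartition_conflicts(parse_tree("((a,b),(c,x));"),
                                  parse_tree("((a,b),(c,y));"))

    def test_rf_matches_dendropy_on_random_pairs(self):
        rng = np.random.default_rng(55)
        taxa = [f"t{i}" for i in range(8)]

        def random_newick():
            nodes = list(taxa)
            rng.shuffle(nodes)
            while len(nodes) > 1:
                i, j = sorted(rng.choice(len(nodes), 2, replace=False),
                              reverse=True)
                a, b = nodes[i], nodes[j]
                del nodes[i], nodes[j]
                nodes.append(f"({a},{b})")
            return nodes[0] + ";"

        tns = dendropy.TaxonNamespace()
        for _ in range(100):
            na, nb = random_newick(), random_newick()
            ta = parse_tree(na, taxon_namespace=tns)
            tb = parse_tree(nb, taxon_namespace=tns)
            mine = rf_distance(ta, tb)
            ta.encode_bipartitions()
            tb.encode_bipartitions()
            oracle = dendropy.calculate.treecompare.symmetric_difference(ta, tb)
            assert mine == oracle
            assert (mine == 0) == (len(bipartition_conflicts(ta, tb)) == 0 and
                                   mine == 0)


# ---------------------------------------------------------------------------
# constraint skeleton


class TestConstraintSkeleton:
    def test_all_strong_supports_unchanged(self):
        t = parse_tree("(((a,b)95,c)92,((d,e)99,f)90);")
        out = constraint_skeleton(t, min_support=90)
        assert rf_distance(out, t) == 0

    def test_weak_edges_collapsed_exactly(self):
        t = parse_tree("((((a,b)95,c)85,(d,e)100)60,f);")
        out = constraint_skeleton(t, min_support=90)
        kept = {c.side for c in tree_bipartitions(out)}
        assert frozenset({"a", "b"}) in kept
        assert frozenset({"d", "e"}) in kept
        assert frozenset({"a", "b", "c"}) not in kept

    def test_unlabeled_node_warns_and_collapses(self):
        t = parse_tree("(((a,b),c)95,(d,(e,f)));")
        with pytest.warns(UserWarning, match="support"):
            out = constraint_skeleton(t, min_support=90)
        assert frozenset({"a", "b"}) not in {c.side for c in tree_bipartitions(out)}
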
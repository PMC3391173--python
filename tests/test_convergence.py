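"""Convergent-pair counting, its theoretical maximum and random-tree null."""

import networkx as nx
import numpy as np
import pytest
from scipy import stats

import phyloconverge as pc
from phyloconverge.chardata import TaxonRecord, TaxonTable
from phyloconverge.synthetic import plant_convergent_scenario, table1_like_table

from _oracles import brute_force_max_pairs, unrooted_signature
from conftest import random_tree


def table_of(rows):
    return TaxonTable([TaxonRecord(*r) for r in rows])


class TestPairCount:
    def test_single_qualifying_cherry(self):
        table = table_of([("A", "G1", "wing"), ("B", "G1", "body")])
        count, pairs = pc.convergent_pair_count(pc.parse_newick("(A,B);"), table)
        assert count == 1
        assert pairs[0].host_group == "G1"
        assert {pairs[0].niche_a, pairs[0].niche_b} == {"wing", "body"}

    def test_equal_niches_or_different_groups_do_not_qualify(self):
        table = table_of(
            [("A", "G1", "wing"), ("B", "G1", "wing"),
             ("C", "G2", "wing"), ("D", "G3", "body")]
        )
        count, _ = pc.convergent_pair_count(pc.parse_newick("((A,B),(C,D));"), table)
        assert count == 0

    def test_missing_niche_member_never_qualifies(self):
        table = table_of([("A", "G1", "wing"), ("B", "G1", None)])
        count, _ = pc.convergent_pair_count(pc.parse_newick("(A,B);"), table)
        assert count == 0

    def test_polytomy_strict_vs_matched(self):
        table = table_of(
            [("A", "G1", "wing"), ("B", "G1", "body"), ("C", "G1", "head")]
        )
        tree = pc.parse_newick("(A,B,C);")
        assert pc.convergent_pair_count(tree, table, "strict")[0] == 0
        count, pairs = pc.convergent_pair_count(tree, table, "matched")
        assert count == 1 and len(pairs) == 1

    def test_polytomy_matching_is_maximal(self):
        # four tips in one polytomy, niches w,w,b,b: two disjoint pairs
        table = table_of(
            [("A", "G1", "wing"), ("B", "G1", "wing"),
             ("C", "G1", "body"), ("D", "G1", "body")]
        )
        tree = pc.parse_newick("(A,B,C,D);")
        assert pc.convergent_pair_count(tree, table, "matched")[0] == 2

    def test_unmatched_tip_raises(self):
        table = table_of([("A", "G1", "wing")])
        with pytest.raises(KeyError, match="B"):
            pc.convergent_pair_count(pc.parse_newick("(A,B);"), table)


class TestMaxPairs:
    def test_fixture_attains_fourteen(self, table1):
        assert pc.max_convergent_pairs(table1) == 14

    def test_single_niche_gives_zero(self):
        table = table_of([("A", "G1", "wing"), ("B", "G1", "wing")])
        assert pc.max_convergent_pairs(table) == 0

    def test_three_one_class_sizes(self):
        table = table_of(
            [("A", "G1", "body"), ("B", "G1", "body"),
             ("C", "G1", "body"), ("D", "G1", "wing")]
        )
        assert pc.max_convergent_pairs(table) == 1
        assert brute_force_max_pairs(table) == 1

    def test_empty_annotation_raises(self):
        with pytest.raises(ValueError):
            pc.max_convergent_pairs(table_of([("A", "G1", None)]))

    @pytest.mark.parametrize("seed", range(60))
    def test_formula_matches_bruteforce_and_networkx(self, seed):
        g = np.random.default_rng(seed)
        n_groups = int(g.integers(1, 5))
        sizes = [int(s) for s in g.integers(1, 5, size=n_groups)]
        while sum(sizes) > 12:  # keep the brute-force oracle exact & fast
            sizes[int(np.argmax(sizes))] -= 1
        table = table1_like_table(
            n_groups,
            sizes,
            {n: p for n, p in zip(("wing", "body", "head", "generalist"),
                                  g.dirichlet(np.ones(4)))},
            rng=g,
        )
        expected = brute_force_max_pairs(table)
        assert pc.max_convergent_pairs(table) == expected
        graph = nx.Graph()
        ann = [r for r in table if r.niche is not None]
        graph.add_nodes_from(r.taxon for r in ann)
        for i, a in enumerate(ann):
            for b in ann[i + 1:]:
                if a.host_group == b.host_group and a.niche != b.niche:
                    graph.add_edge(a.taxon, b.taxon)
        assert len(nx.max_weight_matching(graph, maxcardinality=True)) == expected

    @pytest.mark.parametrize("seed", range(25))
    def test_upper_bounds_count_on_random_trees(self, table1, seed):
        cap = pc.max_convergent_pairs(table1)
        taxa = [r.taxon for r in table1.annotated]
        tree = pc.random_topology(taxa, rng=np.random.default_rng(seed))
        count, _ = pc.convergent_pair_count(tree, table1)
        assert 0 <= count <= cap

    def test_bound_attained_by_constructed_tree(self, table1):
        ingroup = table1.annotated
        sc = None
        # a planted scenario on the fixture itself: pair up a maximum
        # matching as cherries and attach the rest pectinately
        from phyloconverge.synthetic import _join
        from phyloconverge.treeio import Node, PhyloTree

        by_group = {}
        for r in ingroup:
            by_group.setdefault(r.host_group, []).append(r)
        units, used = [], set()
        for recs in by_group.values():
            pool = list(recs)
            while True:
                pair = next(
                    ((i, j) for i in range(len(pool)) for j in range(i + 1, len(pool))
                     if pool[i].niche != pool[j].niche),
                    None,
                )
                if pair is None:
                    break
                i, j = pair
                units.append(_join(Node(label=pool[i].taxon), Node(label=pool[j].taxon)))
                used |= {pool[i].taxon, pool[j].taxon}
                del pool[j], pool[i]
        backbone = units.pop()
        for u in units:
            backbone = _join(u, backbone)
        for r in ingroup:
            if r.taxon not in used:
                backbone = _join(Node(label=r.taxon), backbone)
        tree = PhyloTree(backbone)
        count, _ = pc.convergent_pair_count(tree, table1)
        assert count == pc.max_convergent_pairs(table1) == 14


class TestRandomTopology:
    def test_three_taxa(self, rng):
        t = pc.random_topology(["a", "b", "c"], rng=rng)
        assert sorted(t.tip_labels) == ["a", "b", "c"] and t.is_binary()

    @pytest.mark.parametrize("model", ["pda_uniform", "yule"])
    def test_binary_with_requested_leaves(self, model, rng):
        taxa = [f"t{i}" for i in range(12)]
        t = pc.random_topology(taxa, model=model, rng=rng)
        assert sorted(t.tip_labels) == sorted(taxa)
        assert t.is_binary()

    def test_too_few_taxa(self, rng):
        with pytest.raises(ValueError):
            pc.random_topology(["a"], rng=rng)

    def test_pda_uniform_over_five_taxon_topologies(self):
        rng = np.random.default_rng(99)
        taxa = list("abcde")
        counts = {}
        n = 3000
        for _ in range(n):
            sig = unrooted_signature(pc.random_topology(taxa, rng=rng))
            counts[sig] = counts.get(sig, 0) + 1
        assert len(counts) == 15
        chi2 = stats.chisquare(list(counts.values()))
        assert chi2.pvalue > 1e-3


class TestNullTest:
    def test_no_shared_groups_gives_p_one(self):
        table = table_of(
            [(f"t{i}", f"G{i}", "wing" if i % 2 else "body") for i in range(6)]
        )
        tree = pc.random_topology(table.taxa, rng=np.random.default_rng(1))
        res = pc.convergence_null_test(table, tree, n_trees=30, seed=2)
        assert res.observed == 0
        assert set(res.null_sample) == {0.0}
        assert res.p_plus_one == 1.0

    def test_planted_maximum_is_detected(self):
        sc = plant_convergent_scenario(5, 2, 5, seed=4)
        res = pc.convergence_null_test(sc.table, sc.tree, n_trees=100, seed=6)
        assert res.observed == 5
        assert res.p_plus_one <= 0.02

    def test_outgroups_excluded_from_null_by_default(self, table1):
        taxa = table1.taxa  # includes the 4 unannotated outgroups
        tree = pc.random_topology(taxa, rng=np.random.default_rng(3))
        res = pc.convergence_null_test(table1, tree, n_trees=5, seed=9)
        assert res.n_reps == 5  # and no error from unannotated taxa

    def test_label_shuffle_mode(self):
        sc = plant_convergent_scenario(4, 2, 4, seed=12)
        res = pc.convergence_null_test(
            sc.table, sc.tree, n_trees=50, model="label_shuffle", seed=13
        )
        assert res.observed == 4
        assert max(res.null_sample) <= 4

    def test_calibration_under_the_null_model(self):
        """Observed trees drawn from the null itself should rarely reject."""
        table = table1_like_table(5, 3, {"wing": 0.5, "body": 0.5}, seed=21)
        rej = 0
        n = 150
        for i in range(n):
            tree = pc.random_topology(
                table.taxa, rng=np.random.default_rng([31, i])
            )
            res = pc.convergence_null_test(table, tree, n_trees=60, seed=1000 + i)
            rej += res.p_plus_one <= 0.05
        assert rej / n <= 0.09  # super-uniform null, small-sample slack
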
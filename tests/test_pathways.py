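"""Pathway mapping, clique percolation (with brute-force oracle), CPWP/CPBP
classification, enrichment and transcript-feature comparison."""

from fractions import Fraction
from itertools import combinations
from math import comb

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cernet import comparison, inference, pathways
from cernet.types import GeneSetCollection


def brute_force_cpm(g: nx.Graph, k: int):
    """Oracle: enumerate all k-cliques, join those sharing k-1 nodes, take
    connected components of the clique graph."""
    cliques = [
        frozenset(c)
        for c in combinations(g.nodes, k)
        if all(g.has_edge(u, v) for u, v in combinations(c, 2))
    ]
    cg = nx.Graph()
    cg.add_nodes_from(range(len(cliques)))
    for i, j in combinations(range(len(cliques)), 2):
        if len(cliques[i] & cliques[j]) == k - 1:
            cg.add_edge(i, j)
    comms = set()
    for comp in nx.connected_components(cg):
        members = frozenset().union(*(cliques[i] for i in comp))
        comms.add(members)
    return comms


SETS = GeneSetCollection(
    sets={"A": frozenset({"g1", "g2", "g3"}), "B": frozenset({"g4", "g5"})}
)


class TestPathwaySubnetwork:
    def test_keeps_only_fully_annotated_edges(self, make_net):
        net = make_net([("g1", "g2"), ("g1", "x9")])
        sub = pathways.pathway_subnetwork(net, SETS)
        assert sub.edge_set() == {("g1", "g2")}

    def test_no_pathway_genes_gives_empty(self, make_net):
        net = make_net([("x1", "x2")])
        assert pathways.pathway_subnetwork(net, SETS).n_edges == 0

    def test_idempotent_and_identity_when_all_annotated(self, make_net):
        net = make_net([("g1", "g2"), ("g2", "g3")])
        once = pathways.pathway_subnetwork(net, SETS)
        twice = pathways.pathway_subnetwork(once, SETS)
        assert once.edge_set() == net.edge_set() == twice.edge_set()


class TestCliquePercolation:
    def test_shared_edge_triangles_merge(self):
        g = nx.Graph([(1, 2), (2, 3), (1, 3), (2, 4), (3, 4)])
        comms = pathways.clique_percolation(g, k=3)
        assert [set(c.members) for c in comms] == [{1, 2, 3, 4}]

    def test_disjoint_triangles_stay_separate(self):
        g = nx.Graph([(1, 2), (2, 3), (1, 3), (4, 5), (5, 6), (4, 6)])
        comms = pathways.clique_percolation(g, k=3)
        assert {frozenset(c.members) for c in comms} == {
            frozenset({1, 2, 3}),
            frozenset({4, 5, 6}),
        }

    def test_triangle_free_graph_has_no_communities(self):
        g = nx.path_graph(6)
        assert pathways.clique_percolation(g, k=3) == []

    def test_k_below_three_rejected(self):
        with pytest.raises(ValueError):
            pathways.clique_percolation(nx.Graph([(1, 2)]), k=2)

    @pytest.mark.parametrize("k", [3, 4])
    def test_matches_brute_force_oracle(self, k):
        for seed in range(25):
            g = nx.gnp_random_graph(12, 0.35, seed=seed)
            got = {c.members for c in pathways.clique_percolation(g, k=k)}
            assert got == brute_force_cpm(g, k)

    def test_community_invariants(self):
        g = nx.gnp_random_graph(20, 0.3, seed=1)
        for c in pathways.clique_percolation(g, k=3):
            assert c.size >= 3
            sub = g.subgraph(c.members)
            assert any(
                all(sub.has_edge(u, v) for u, v in combinations(tri, 2))
                for tri in combinations(c.members, 3)
            )


class TestCommonModules:
    def test_five_clique_of_common_hubs(self, make_net):
        hubs = [f"g{i}" for i in range(1, 6)]
        sets = GeneSetCollection(sets={"P": frozenset(hubs)})
        net = make_net([(a, b) for a, b in combinations(hubs, 2)])
        mods = pathways.common_modules(net, sets, hubs, k=3)
        assert len(mods) == 1 and mods[0].community.size == 5

    def test_no_triangles_no_modules(self, make_net):
        hubs = ["g1", "g2", "g3", "g4"]
        sets = GeneSetCollection(sets={"P": frozenset(hubs)})
        net = make_net([("g1", "g2"), ("g3", "g4")])
        assert pathways.common_modules(net, sets, hubs, k=3) == []

    def test_planted_clique_recovered_from_study(self, small_study, small_networks):
        merged = comparison.merge_networks(
            small_networks, network_id="global", level="global"
        )
        clique = sorted(small_study.truth.clique_genes)
        mods = pathways.common_modules(
            merged, small_study.pathways, clique, k=3
        )
        assert mods, "planted clique module not found"
        best = max(len(set(clique) & m.community.members) for m in mods)
        assert best >= len(clique) - 2

    def test_disease_count_annotation(self, make_net):
        hubs = ["g1", "g2", "g3"]
        sets = GeneSetCollection(sets={"P": frozenset(hubs)})
        net = make_net([(a, b) for a, b in combinations(hubs, 2)])
        counts = {("g1", "g2"): 4, ("g1", "g3"): 2, ("g2", "g3"): 1}
        mods = pathways.common_modules(
            net, sets, hubs, k=3, edge_disease_counts=counts
        )
        got = dict(
            ((r.gene_a, r.gene_b), r.n_diseases)
            for r in mods[0].edges.itertuples(index=False)
        )
        assert got == counts


class TestPairClassification:
    def test_worked_examples(self):
        assert pathways.classify_pair("g1", "g2", SETS).label == "CPWP"
        assert pathways.classify_pair("g1", "g2", SETS).witnesses == {"A"}
        assert pathways.classify_pair("g1", "g4", SETS).label == "CPBP"
        assert pathways.classify_pair("g1", "g9", SETS).label == "unclassified"

    def test_cpwp_cpbp_partition_annotated_edges(self, small_networks, small_study):
        merged = comparison.merge_networks(
            small_networks, network_id="global", level="global"
        )
        classified = pathways.classify_network_pairs(merged, small_study.pathways)
        counts = pathways.crosstalk_counts(classified)
        annotated = small_study.pathways.all_genes
        n_both = sum(
            1 for a, b in merged.graph.edges if a in annotated and b in annotated
        )
        assert counts["CPWP"] + counts["CPBP"] == n_both
        assert sum(counts.values()) == merged.n_edges


class TestNormalizedDegree:
    def test_max_degree_node_scores_one(self, make_net):
        sets = GeneSetCollection(sets={"P": frozenset({"hub", "leaf0"})})
        net = make_net([("hub", f"leaf{i}") for i in range(5)])
        table = pathways.normalized_pathway_degree(net, sets)
        by_gene = dict(zip(table.gene, table.normalized_degree))
        assert by_gene["hub"] == 1.0
        assert by_gene["leaf0"] == pytest.approx(1 / 5)
        assert ((table.normalized_degree >= 0) & (table.normalized_degree <= 1)).all()

    def test_absent_pathway_gene_omitted(self, make_net):
        sets = GeneSetCollection(sets={"P": frozenset({"hub", "ghost"})})
        net = make_net([("hub", "leaf")])
        table = pathways.normalized_pathway_degree(net, sets)
        assert "ghost" not in set(table.gene)


class TestEnrichment:
    def test_exact_tail_example(self):
        # universe 20, set 5, query 5, overlap 4: p = 76/15504 = 1/204
        universe = [f"u{i}" for i in range(20)]
        sets = GeneSetCollection(sets={"S": frozenset(universe[:5])})
        query = universe[1:5] + [universe[10]]
        table = pathways.geneset_enrichment(query, sets, universe)
        expected = sum(
            Fraction(comb(5, i) * comb(15, 5 - i), comb(20, 5)) for i in (4, 5)
        )
        assert table.p[0] == pytest.approx(float(expected), rel=1e-12)

    def test_zero_overlap_and_degenerate_bounds(self):
        universe = [f"u{i}" for i in range(10)]
        sets = GeneSetCollection(
            sets={"S": frozenset(universe[:3]), "T": frozenset(universe)}
        )
        table = pathways.geneset_enrichment(universe[5:], sets, universe)
        by = dict(zip(table.pathway, table.p))
        assert by["S"] == 1.0  # zero overlap
        assert by["T"] == pytest.approx(1.0)  # query = universe boundary
        assert (table.p <= 1.0).all()

    def test_query_outside_universe_rejected(self):
        sets = GeneSetCollection(sets={"S": frozenset({"a"})})
        with pytest.raises(ValueError):
            pathways.geneset_enrichment(["zzz"], sets, ["a", "b"])

    def test_bh_applied_across_sets(self):
        universe = [f"u{i}" for i in range(30)]
        sets = GeneSetCollection(
            sets={f"S{j}": frozenset(universe[j : j + 5]) for j in range(4)}
        )
        table = pathways.geneset_enrichment(universe[:5], sets, universe)
        assert (table.q_bh >= table.p - 1e-15).all()


class TestTranscriptFeatures:
    def _features(self, rng, n=50, shift=1.0):
        genes = [f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)]
        length = np.concatenate(
            [rng.lognormal(8, 0.3, n) * shift, rng.lognormal(8, 0.3, n)]
        )
        return pd.DataFrame(
            {
                "transcript_length": length,
                "exon_count": np.concatenate(
                    [rng.poisson(12, n) + 1, rng.poisson(8, n) + 1]
                ),
                "conservation_score": rng.random(2 * n),
            },
            index=genes,
        )

    def test_identical_distributions_near_half(self):
        rng = np.random.default_rng(0)
        feats = self._features(rng, shift=1.0)
        # compare a group against itself: p is exactly the 0.5 boundary
        same = [f"a{i}" for i in range(50)]
        table = pathways.compare_transcript_features(same, same, feats)
        assert table.loc[0, "p"] == pytest.approx(0.5)

    def test_complete_separation_significant(self):
        rng = np.random.default_rng(1)
        feats = self._features(rng, shift=10.0)
        table = pathways.compare_transcript_features(
            [f"a{i}" for i in range(50)], [f"b{i}" for i in range(50)], feats
        )
        p_len = table.set_index("feature").loc["transcript_length", "p"]
        assert p_len < 0.001

    def test_missing_genes_excluded(self):
        rng = np.random.default_rng(2)
        feats = self._features(rng)
        table = pathways.compare_transcript_features(
            [f"a{i}" for i in range(50)] + ["missing1"],
            [f"b{i}" for i in range(50)],
            feats,
        )
        assert len(table) == 3

    def test_planted_feature_signal_in_study(self, small_study):
        truth = small_study.truth
        planted = {g for pr in truth.planted_pairs for g in pr} | truth.clique_genes
        assoc = planted & small_study.pathways.all_genes
        other = set(small_study.features.index) - assoc
        table = pathways.compare_transcript_features(
            assoc, other, small_study.features
        )
        assert (table.p < 0.01).all()
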
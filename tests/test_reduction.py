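"""Knowledge-driven graph coarsening: eligibility, partitioning, medians."""

import numpy as np
import pytest

from drugraph.errors import ValidationError
from drugraph.graph import CancerGraph, NodeAnnotation
from drugraph.reduction import (
    find_merge_groups,
    merge_eligible,
    merge_group,
    reduce_graph,
    reduction_stats,
)

from conftest import random_annotated_graph


# -- independent oracle: enumerate eligible pairs, run union-find -------------

class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def brute_force_partition(graph, clusters):
    uf = _UnionFind(graph.node_ids)
    for u, v in graph.edges:
        nu, nv = graph.node(u), graph.node(v)
        ok = (
            not nu.is_kinase and not nv.is_kinase
            and not nu.is_virtual and not nv.is_virtual
            and nu.dge == nv.dge
            and u in clusters and v in clusters and clusters[u] == clusters[v]
        )
        if ok:
            uf.union(u, v)
    groups = {}
    for x in graph.node_ids:
        groups.setdefault(uf.find(x), set()).add(x)
    return sorted(groups.values(), key=lambda s: min(s))


class TestEligibility:
    def test_worked_example_pair(self, worked_example):
        g, clusters = worked_example
        cmap = dict(zip(clusters["gene"], clusters["cluster"]))
        assert merge_eligible(g, "d", "f", cmap)
        assert merge_eligible(g, "a", "b", cmap)

    def test_kinases_never_eligible(self, worked_example):
        g, clusters = worked_example
        cmap = dict(zip(clusters["gene"], clusters["cluster"]))
        cmap["1"] = cmap["4"] = "BPX"
        assert not merge_eligible(g, "1", "4", cmap)

    def test_dge_mismatch_blocks_merge(self, worked_example):
        g, clusters = worked_example
        cmap = dict(zip(clusters["gene"], clusters["cluster"]))
        cmap["d"] = cmap["e"] = "BPX"  # same cluster but down vs normal
        assert not merge_eligible(g, "d", "e", cmap)

    def test_missing_cluster_is_singleton(self, worked_example, caplog):
        g, _ = worked_example
        with caplog.at_level("WARNING"):
            assert not merge_eligible(g, "a", "b", {"a": "BP1"})
        assert any("cluster" in r.message for r in caplog.records)


class TestMergeGroups:
    def test_worked_example_groups(self, worked_example):
        g, clusters = worked_example
        groups = [s for s in find_merge_groups(g, clusters) if len(s) > 1]
        assert sorted(map(sorted, groups)) == [["a", "b"], ["c", "e"], ["d", "f", "g"]]

    def test_no_eligible_pairs_gives_identity_partition(self, worked_example):
        g, _ = worked_example
        groups = find_merge_groups(g, {n: f"BP{i}" for i, n in enumerate(g.node_ids)})
        assert all(len(s) == 1 for s in groups)

    def test_partition_equals_union_find_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            graph, clusters = random_annotated_graph(rng, n_nodes=50, edge_p=0.08)
            ours = find_merge_groups(graph, clusters)
            assert sorted(map(sorted, ours)) == sorted(
                map(sorted, brute_force_partition(graph, clusters))
            )

    def test_partition_property(self):
        rng = np.random.default_rng(5)
        graph, clusters = random_annotated_graph(rng, n_nodes=40)
        groups = find_merge_groups(graph, clusters)
        flat = [x for s in groups for x in s]
        assert sorted(flat) == sorted(graph.node_ids)  # cover, disjoint


class TestMergeGroup:
    def test_median_of_three(self, worked_example):
        g, _ = worked_example
        virtual, _ = merge_group(g, {"d", "f", "g"})
        # members carry associations {absent->0, 1.9, 2.3}
        assert virtual.dga_disease == 1.9
        assert virtual.dge == "down"
        assert virtual.members == ("d", "f", "g")

    def test_even_cardinality_median_is_midpoint_mean(self, worked_example):
        g, _ = worked_example
        virtual, _ = merge_group(g, {"c", "e"})
        assert virtual.dga_disease == pytest.approx((0.0 + 2.6) / 2)

    def test_identical_annotations_unchanged(self):
        nodes = [NodeAnnotation(gene_id=g, dge="up", dga_disease=4.0)
                 for g in ("a", "b", "c")]
        g = CancerGraph(("c", "d"), "skin", nodes,
                        {("a", "b"): 600.0, ("b", "c"): 700.0})
        virtual, _ = merge_group(g, {"a", "b", "c"})
        assert virtual.dga_disease == 4.0 and virtual.dge == "up"

    def test_collapsed_edge_weight_is_median(self, worked_example):
        g, _ = worked_example
        _, rewired = merge_group(g, {"d", "f", "g"})
        # outside neighbor e is reached through weights {600, 800}
        assert rewired[("e", "merged:d+f+g")] == 700.0

    def test_group_with_kinase_is_contract_violation(self, worked_example):
        g, _ = worked_example
        with pytest.raises(ValidationError):
            merge_group(g, {"1", "a"})


class TestReduceGraph:
    def test_worked_example_counts(self, worked_example):
        g, clusters = worked_example
        reduced, rmap = reduce_graph(g, clusters)
        assert reduced.n_nodes == 9  # 4 kinases + 3 virtual + h + i
        virtuals = [n for n in reduced.nodes if n.is_virtual]
        assert len(virtuals) == 3
        assert rmap.node_reduction_pct == pytest.approx(100 * 4 / 13)
        stats = reduction_stats(rmap)
        assert stats["n_merge_groups"] == 3

    def test_all_kinase_graph_is_noop(self):
        nodes = [NodeAnnotation(gene_id=g, is_kinase=True) for g in "abc"]
        g = CancerGraph(("c", "d"), "skin", nodes, {("a", "b"): 600.0})
        reduced, rmap = reduce_graph(g, {x: "BP0" for x in "abc"})
        assert reduced.n_nodes == 3 and reduced.edges == g.edges
        assert rmap.node_reduction_pct == 0.0

    def test_no_eligible_pair_survives_reduction(self):
        rng = np.random.default_rng(11)
        graph, clusters = random_annotated_graph(rng, n_nodes=200, edge_p=0.02)
        reduced, _ = reduce_graph(graph, clusters)
        for u, v in reduced.edges:
            nu, nv = reduced.node(u), reduced.node(v)
            if nu.is_virtual or nv.is_virtual:
                continue
            assert not merge_eligible(reduced, u, v, clusters)

    def test_idempotent(self):
        rng = np.random.default_rng(13)
        graph, clusters = random_annotated_graph(rng, n_nodes=60)
        once, _ = reduce_graph(graph, clusters)
        twice, rmap = reduce_graph(once, clusters)
        assert twice.n_nodes == once.n_nodes and twice.edges == once.edges

    def test_monotone_counts_and_kinase_fraction(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            graph, clusters = random_annotated_graph(rng, n_nodes=50, edge_p=0.1)
            reduced, rmap = reduce_graph(graph, clusters)
            assert reduced.n_nodes <= graph.n_nodes
            assert reduced.n_edges <= graph.n_edges
            assert rmap.kinase_fraction_after >= rmap.kinase_fraction_before
            if rmap.nodes_after < rmap.nodes_before and any(
                n.is_kinase for n in graph.nodes
            ):
                assert rmap.kinase_fraction_after > rmap.kinase_fraction_before

    def test_connectivity_preserved(self):
        import networkx as nx

        rng = np.random.default_rng(19)
        graph, clusters = random_annotated_graph(rng, n_nodes=40, edge_p=0.08)
        reduced, _ = reduce_graph(graph, clusters)
        member_of = {}
        for n in reduced.nodes:
            for m in n.members:
                member_of[m] = n.gene_id
        g0, g1 = graph.to_networkx(), reduced.to_networkx()
        for comp in nx.connected_components(g0):
            comp = list(comp)
            images = {member_of[x] for x in comp}
            sub = g1.subgraph(images)
            assert nx.is_connected(sub) if len(images) > 1 else True

    def test_label_tissue_and_id_unchanged(self, worked_example):
        g, clusters = worked_example
        reduced, _ = reduce_graph(g, clusters)
        assert reduced.instance_id == g.instance_id
        assert reduced.label == g.label and reduced.tissue == g.tissue
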
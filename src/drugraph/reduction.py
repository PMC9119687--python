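"""Knowledge-driven graph coarsening.

Connected groups of non-kinase proteins that share the same differential-
expression category and belong to the same biological-process cluster are
collapsed into single virtual nodes.  Numeric annotations of a merged node
and the weights of collapsed parallel edges are medians over the group
(absent annotations enter as 0; the median of an even-cardinality multiset is
the mean of the two middle values).  Kinase nodes are never merged, so the
kinase fraction of the graph can only grow — the point of the procedure is a
smaller graph that is denser in informative (kinase) nodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ValidationError
from .graph import CancerGraph, NodeAnnotation, _canon

log = logging.getLogger(__name__)


def cluster_map(go_clusters: pd.DataFrame) -> dict[str, str]:
    return {g: str(c) for g, c in go_clusters[["gene", "cluster"]].itertuples(index=False)}


def merge_eligible(
    graph: CancerGraph,
    u: str,
    v: str,
    clusters: dict[str, str],
    _warned: set | None = None,
) -> bool:
    """True iff adjacent original nodes u, v may merge: both non-kinase,
    identical expression category, and the same biological-process cluster.

    A node missing a cluster assignment is treated as its own singleton
    cluster (never eligible) and logged once.
    """
    nu, nv = graph.node(u), graph.node(v)
    if nu.is_virtual or nv.is_virtual:
        return False
    if nu.is_kinase or nv.is_kinase:
        return False
    if nu.dge != nv.dge:
        return False
    for n in (nu, nv):
        if n.gene_id not in clusters:
            if _warned is None or n.gene_id not in _warned:
                log.warning("gene %s has no cluster assignment; treated as singleton",
                            n.gene_id)
                if _warned is not None:
                    _warned.add(n.gene_id)
            return False
    return clusters[u] == clusters[v]


def find_merge_groups(
    graph: CancerGraph, clusters: dict[str, str] | pd.DataFrame
) -> list[set[str]]:
    """Partition node ids into merge groups: the connected components of the
    eligibility subgraph (singletons included).  Deterministic given input."""
    if isinstance(clusters, pd.DataFrame):
        clusters = cluster_map(clusters)
    warned: set[str] = set()
    elig = nx.Graph()
    elig.add_nodes_from(graph.node_ids)
    for u, v in graph.edges:
        if merge_eligible(graph, u, v, clusters, warned):
            elig.add_edge(u, v)
    comps = [set(c) for c in nx.connected_components(elig)]
    return sorted(comps, key=lambda c: min(c))


def _median(values: list[float]) -> float:
    return float(np.median(values)) if values else 0.0


def merge_group(
    graph: CancerGraph, group: set[str]
) -> tuple[NodeAnnotation, dict[tuple[str, str], float]]:
    """Collapse one merge group (size >= 2) into a virtual node.

    Returns the virtual annotation and its rewired edges keyed by
    (virtual_id, outside_node).  Numeric annotations are medians over the
    members with absent values entering as 0; parallel edges from the group
    to one outside node collapse to the median of their weights; edges
    internal to the group vanish.
    """
    if len(group) < 2:
        raise ValidationError("merge group must have size >= 2")
    members = sorted(group)
    anns = [graph.node(g) for g in members]
    if any(a.is_kinase for a in anns):
        raise ValidationError(f"merge group {members} contains a kinase")
    dges = {a.dge for a in anns}
    if len(dges) != 1:
        raise ValidationError(f"merge group {members} mixes dge categories {dges}")
    vid = "merged:" + "+".join(members)

    def med(attr: str) -> float | None:
        m = _median([getattr(a, attr) or 0.0 for a in anns])
        return m if m > 0 else None

    virtual = NodeAnnotation(
        gene_id=vid,
        is_kinase=False,
        dge=dges.pop(),
        dga_disease=med("dga_disease"),
        dga_disgenet=med("dga_disgenet"),
        pic50=med("pic50"),
        is_virtual=True,
        members=tuple(members),
    )
    outside: dict[str, list[float]] = {}
    gset = set(members)
    for (u, v), w in graph.edges.items():
        if u in gset and v not in gset:
            outside.setdefault(v, []).append(w)
        elif v in gset and u not in gset:
            outside.setdefault(u, []).append(w)
    rewired = {_canon(vid, n): _median(ws) for n, ws in outside.items()}
    return virtual, rewired


@dataclass
class ReductionMap:
    """Provenance from original nodes to merged nodes plus size statistics."""

    groups: list[set[str]]
    nodes_before: int
    nodes_after: int
    edges_before: int
    edges_after: int
    kinase_fraction_before: float
    kinase_fraction_after: float

    @property
    def node_reduction_pct(self) -> float:
        if self.nodes_before == 0:
            return 0.0
        return 100.0 * (self.nodes_before - self.nodes_after) / self.nodes_before

    @property
    def edge_reduction_pct(self) -> float:
        if self.edges_before == 0:
            return 0.0
        return 100.0 * (self.edges_before - self.edges_after) / self.edges_before


def reduce_graph(
    graph: CancerGraph, clusters: dict[str, str] | pd.DataFrame
) -> tuple[CancerGraph, ReductionMap]:
    """Single-pass reduction: find merge groups, collapse each non-singleton
    one.  Virtual nodes are never re-merged, so the operation is idempotent.
    Label, tissue and instance id are unchanged; the feature matrix of the
    result is recomputed from the new annotations.
    """
    if isinstance(clusters, pd.DataFrame):
        clusters = cluster_map(clusters)
    groups = find_merge_groups(graph, clusters)
    merged_of: dict[str, str] = {}
    new_nodes: list[NodeAnnotation] = []
    new_edges: dict[tuple[str, str], float] = {}
    for grp in groups:
        if len(grp) >= 2:
            virtual, rewired = merge_group(graph, grp)
            new_nodes.append(virtual)
            for m in grp:
                merged_of[m] = virtual.gene_id
    for n in graph.nodes:
        if n.gene_id not in merged_of:
            new_nodes.append(n)
    # surviving edges between unmerged nodes, then rewired group edges; a
    # rewired edge may join two virtual nodes (collapse both endpoints).
    collapsed: dict[tuple[str, str], list[float]] = {}
    for (u, v), w in graph.edges.items():
        cu, cv = merged_of.get(u, u), merged_of.get(v, v)
        if cu == cv:
            continue  # internal to one group
        collapsed.setdefault(_canon(cu, cv), []).append(w)
    for key, ws in collapsed.items():
        new_edges[key] = _median(ws)

    reduced = CancerGraph(
        instance_id=graph.instance_id,
        tissue=graph.tissue,
        nodes=sorted(new_nodes, key=lambda n: n.gene_id),
        edges=new_edges,
        label=graph.label,
        # medians of weights that all pass the threshold still pass it
        min_confidence=graph.min_confidence,
    )
    rmap = ReductionMap(
        groups=groups,
        nodes_before=graph.n_nodes,
        nodes_after=reduced.n_nodes,
        edges_before=graph.n_edges,
        edges_after=reduced.n_edges,
        kinase_fraction_before=graph.kinase_fraction(),
        kinase_fraction_after=reduced.kinase_fraction(),
    )
    return reduced, rmap


def reduction_stats(rmap: ReductionMap) -> dict:
    """Human-readable summary of one reduction."""
    return {
        "nodes_before": rmap.nodes_before,
        "nodes_after": rmap.nodes_after,
        "node_reduction_pct": rmap.node_reduction_pct,
        "edges_before": rmap.edges_before,
        "edges_after": rmap.edges_after,
        "edge_reduction_pct": rmap.edge_reduction_pct,
        "kinase_fraction_before": rmap.kinase_fraction_before,
        "kinase_fraction_after": rmap.kinase_fraction_after,
        "n_merge_groups": sum(1 for g in rmap.groups if len(g) >= 2),
    }
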
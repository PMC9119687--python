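"""Core domain types: annotated cancer-specific graphs and their feature encoding.

A :class:`CancerGraph` represents one (cell line, drug) instance: an undirected
protein network whose nodes carry differential-expression categories, disease-gene
association scores, kinase-inhibition potencies and a kinase flag, plus a binary
response label (1 = cytotoxic, 0 = cytostatic) and a tissue tag used for grouped
cross-validation.  Virtual nodes produced by graph reduction keep the list of
original genes they absorbed in ``members``.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import GraphFormatError, ValidationError

DGE_CATEGORIES = ("up", "down", "normal")

#: number of entries produced by :func:`encode_features`
FEATURE_DIM = 7

GRAPH_FORMAT_VERSION = "1"


@dataclass(frozen=True)
class NodeAnnotation:
    """Per-protein annotation attached to one graph node.

    ``dga_disease`` is on the 1-10 scale, ``dga_disgenet`` on the 0.01-1 scale;
    ``pic50`` is -log10(IC50 in molar) and is only present when it passed the
    potency threshold at construction.  ``None`` means "no annotation".
    Virtual (merged) nodes may carry median values below the source-database
    minimum because absent member annotations enter the median as 0.
    """

    gene_id: str
    is_kinase: bool = False
    dge: str = "normal"
    dga_disease: float | None = None
    dga_disgenet: float | None = None
    pic50: float | None = None
    is_virtual: bool = False
    members: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.gene_id:
            raise ValidationError("node with empty gene_id")
        if self.dge not in DGE_CATEGORIES:
            raise ValidationError(
                f"node {self.gene_id!r}: unknown dge category {self.dge!r}"
            )
        members = self.members if self.members else (self.gene_id,)
        object.__setattr__(self, "members", tuple(members))
        if self.is_virtual != (len(self.members) > 1):
            raise ValidationError(
                f"node {self.gene_id!r}: is_virtual must match |members|>1"
            )
        if self.is_virtual and self.is_kinase:
            raise ValidationError(f"node {self.gene_id!r}: virtual nodes are never kinases")
        lo_dis, lo_dg = (0.0, 0.0) if self.is_virtual else (1.0, 0.01)
        if self.dga_disease is not None and not lo_dis <= self.dga_disease <= 10.0:
            raise ValidationError(
                f"node {self.gene_id!r}: dga_disease {self.dga_disease} outside [1,10]"
            )
        if self.dga_disgenet is not None and not lo_dg <= self.dga_disgenet <= 1.0:
            raise ValidationError(
                f"node {self.gene_id!r}: dga_disgenet {self.dga_disgenet} outside [0.01,1]"
            )
        if self.pic50 is not None and self.pic50 <= 0:
            raise ValidationError(f"node {self.gene_id!r}: pic50 must be positive")


def encode_features(node: NodeAnnotation) -> np.ndarray:
    """Encode one node annotation as a fixed-length 7-vector.

    Layout: ``[dge=up, dge=down, dge=normal, dga_disease/10, dga_disgenet,
    pic50/10, is_kinase]``.  One-hot differential expression guarantees no
    all-zero row, which keeps cosine similarities in the attention mechanism
    well defined; absent scores map to 0 ("no useful information").
    """
    if node.dge not in DGE_CATEGORIES:
        raise ValidationError(f"unknown dge category {node.dge!r}")
    v = np.zeros(FEATURE_DIM, dtype=np.float64)
    v[DGE_CATEGORIES.index(node.dge)] = 1.0
    if node.dga_disease is not None:
        v[3] = node.dga_disease / 10.0
    if node.dga_disgenet is not None:
        v[4] = node.dga_disgenet
    if node.pic50 is not None:
        v[5] = node.pic50 / 10.0
    v[6] = 1.0 if node.is_kinase else 0.0
    return v


def _canon(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


@dataclass
class CancerGraph:
    """One labeled (cell line, drug) network instance.

    ``edges`` maps canonically ordered node-id pairs to confidence weights
    (STRING-style, kept on the raw 0-1000 scale; merged edges may be
    non-integer medians).  ``label`` is 1 for a cytotoxic response, 0 for a
    cytostatic one, ``None`` when unlabeled.
    """

    instance_id: tuple[str, str]
    tissue: str
    nodes: list[NodeAnnotation]
    edges: dict[tuple[str, str], float] = field(default_factory=dict)
    label: int | None = None
    min_confidence: float = 0.0

    def __post_init__(self):
        self.instance_id = tuple(self.instance_id)
        ids = [n.gene_id for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate node ids in graph")
        known = set(ids)
        canon_edges: dict[tuple[str, str], float] = {}
        for (u, v), w in self.edges.items():
            if u == v:
                raise ValidationError(f"self-loop on {u!r}")
            if u not in known or v not in known:
                raise ValidationError(f"edge ({u!r},{v!r}) references unknown node")
            if w < self.min_confidence:
                raise ValidationError(
                    f"edge ({u!r},{v!r}) weight {w} below confidence threshold "
                    f"{self.min_confidence}"
                )
            key = _canon(u, v)
            if key in canon_edges and canon_edges[key] != w:
                raise ValidationError(f"conflicting weights for edge {key}")
            canon_edges[key] = float(w)
        self.edges = canon_edges

    # -- convenience accessors -------------------------------------------------

    @property
    def node_ids(self) -> list[str]:
        return [n.gene_id for n in self.nodes]

    def node(self, gene_id: str) -> NodeAnnotation:
        for n in self.nodes:
            if n.gene_id == gene_id:
                return n
        raise KeyError(gene_id)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def X(self) -> np.ndarray:
        """Feature matrix X^(0): one encoded row per node, in node order."""
        if not self.nodes:
            return np.zeros((0, FEATURE_DIM))
        return np.stack([encode_features(n) for n in self.nodes])

    def adjacency(self) -> np.ndarray:
        """Dense binary adjacency matrix in node order (weights do not enter)."""
        idx = {g: i for i, g in enumerate(self.node_ids)}
        A = np.zeros((self.n_nodes, self.n_nodes))
        for u, v in self.edges:
            A[idx[u], idx[v]] = A[idx[v], idx[u]] = 1.0
        return A

    def edge_index(self) -> np.ndarray:
        """(2, 2E) array of directed integer edges, both orientations."""
        idx = {g: i for i, g in enumerate(self.node_ids)}
        if not self.edges:
            return np.zeros((2, 0), dtype=np.int64)
        pairs = []
        for u, v in self.edges:
            pairs.append((idx[u], idx[v]))
            pairs.append((idx[v], idx[u]))
        return np.array(pairs, dtype=np.int64).T

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for n in self.nodes:
            g.add_node(n.gene_id, annotation=n)
        for (u, v), w in self.edges.items():
            g.add_edge(u, v, weight=w)
        return g

    def permuted(self, order: list[int]) -> "CancerGraph":
        """Return a copy with nodes listed in the given order (same graph)."""
        return replace(self, nodes=[self.nodes[i] for i in order], edges=dict(self.edges))

    def kinase_fraction(self) -> float:
        if not self.nodes:
            return 0.0
        return sum(n.is_kinase for n in self.nodes) / len(self.nodes)


# -- serialization -------------------------------------------------------------

_NODE_COLS = [
    "gene_id", "is_kinase", "dge", "dga_disease", "dga_disgenet",
    "pic50", "is_virtual", "members",
]


def _fmt(x: float | None) -> str:
    return "" if x is None else repr(float(x))


def write_graph(graph: CancerGraph, path) -> None:
    """Write a graph container: an uncompressed ZIP archive holding a node TSV,
    an edge TSV and a JSON metadata record (inspectable with ``unzip -p``)."""
    nodes_buf = io.StringIO()
    nodes_buf.write("\t".join(_NODE_COLS) + "\n")
    for n in graph.nodes:
        nodes_buf.write(
            "\t".join(
                [
                    n.gene_id,
                    str(int(n.is_kinase)),
                    n.dge,
                    _fmt(n.dga_disease),
                    _fmt(n.dga_disgenet),
                    _fmt(n.pic50),
                    str(int(n.is_virtual)),
                    ",".join(n.members),
                ]
            )
            + "\n"
        )
    edges_buf = io.StringIO()
    edges_buf.write("protein_a\tprotein_b\tweight\n")
    for (u, v), w in sorted(graph.edges.items()):
        edges_buf.write(f"{u}\t{v}\t{w!r}\n")
    meta = {
        "format_version": GRAPH_FORMAT_VERSION,
        "cell_line": graph.instance_id[0],
        "drug": graph.instance_id[1],
        "tissue": graph.tissue,
        "label": graph.label,
        "min_confidence": graph.min_confidence,
    }
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_STORED) as zf:
        zf.writestr("meta.json", json.dumps(meta, indent=1))
        zf.writestr("nodes.tsv", nodes_buf.getvalue())
        zf.writestr("edges.tsv", edges_buf.getvalue())


def read_graph(path) -> CancerGraph:
    """Read a graph container written by :func:`write_graph`.

    Raises :class:`GraphFormatError` on truncated archives or unknown format
    versions; never returns a partial graph.
    """
    try:
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            nodes_txt = zf.read("nodes.tsv").decode()
            edges_txt = zf.read("edges.tsv").decode()
    except (zipfile.BadZipFile, KeyError, OSError, json.JSONDecodeError) as exc:
        raise GraphFormatError(f"cannot read graph container {path}: {exc}") from exc
    if meta.get("format_version") != GRAPH_FORMAT_VERSION:
        raise GraphFormatError(
            f"unsupported graph format version {meta.get('format_version')!r}"
        )
    nodes = []
    lines = nodes_txt.splitlines()
    if not lines or lines[0].split("\t") != _NODE_COLS:
        raise GraphFormatError("node table header mismatch")
    for line in lines[1:]:
        f = line.split("\t")
        if len(f) != len(_NODE_COLS):
            raise GraphFormatError(f"malformed node row: {line!r}")
        nodes.append(
            NodeAnnotation(
                gene_id=f[0],
                is_kinase=bool(int(f[1])),
                dge=f[2],
                dga_disease=float(f[3]) if f[3] else None,
                dga_disgenet=float(f[4]) if f[4] else None,
                pic50=float(f[5]) if f[5] else None,
                is_virtual=bool(int(f[6])),
                members=tuple(f[7].split(",")),
            )
        )
    edges: dict[tuple[str, str], float] = {}
    elines = edges_txt.splitlines()
    if not elines or elines[0].split("\t") != ["protein_a", "protein_b", "weight"]:
        raise GraphFormatError("edge table header mismatch")
    for line in elines[1:]:
        f = line.split("\t")
        if len(f) != 3:
            raise GraphFormatError(f"malformed edge row: {line!r}")
        edges[(f[0], f[1])] = float(f[2])
    label = meta["label"]
    return CancerGraph(
        instance_id=(meta["cell_line"], meta["drug"]),
        tissue=meta["tissue"],
        nodes=nodes,
        edges=edges,
        label=int(label) if label is not None else None,
        min_confidence=float(meta.get("min_confidence", 0.0)),
    )
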
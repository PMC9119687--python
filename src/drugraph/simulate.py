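"""Synthetic generation of the six omics input tables.

The generator emulates the statistical structure the method assumes: a
scale-free PPI scaffold whose confidence scores pass the default filter, a
~2% kinase fraction (the regime in which reduction enriches kinase density),
categorical differential expression per cell line, bounded disease-gene
association scores on the two database scales, sparse kinase-inhibition
profiles above the potency threshold, and growth-rate records whose labels
follow a planted mechanism: an instance tends to be cytotoxic when the drug
inhibits kinases that are simultaneously up-regulated in the cell line and
strongly disease-associated.  That coupling of topology-anchored kinase
features with the label is what a trained network has to rediscover.

Also provides the 13-node worked-example fixture used throughout the tests
(a breast-adenocarcinoma cell line treated with a dual SRC/ABL-family kinase
inhibitor).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .build import BuildConfig, build_dataset, pic50_from_ic50_nm
from .errors import ValidationError
from .graph import CancerGraph, NodeAnnotation
from .tables import OmicsTables

TISSUE_NAMES = [
    "digestive system",
    "respiratory system",
    "haematopoietic and lymphoid tissue",
    "breast tissue",
    "female reproductive system",
    "skin",
    "nervous system",
    "excretory system",
    "others",
]


@dataclass(frozen=True)
class PlantedRule:
    """Generative label mechanism.

    For an instance (cell line, drug), let s be the number of kinases that
    are simultaneously up-regulated in the cell line, inhibited by the drug
    (pIC50 >= ``pic50_threshold``) and disease-associated above ``dga_cut``
    (on the normalized [0,1] feature scale).  The instance is cytotoxic
    (GRmax drawn negative) with probability sigmoid(signal_strength*s -
    offset); the final label is flipped with probability ``label_noise``.
    """

    signal_strength: float = 12.0
    offset: float = 6.0
    label_noise: float = 0.05
    dga_cut: float = 0.2
    pic50_threshold: float = pic50_from_ic50_nm(500.0)


@dataclass
class SimConfig:
    """Study conditions for the synthetic world (defaults chosen once to
    mirror the assumed data structure at desk scale; see docs/methods.md)."""

    n_genes: int = 150
    kinase_fraction: float = 0.02
    ba_m: int = 2  # preferential-attachment degree of the scaffold
    n_cell_lines: int = 50
    n_tissues: int = 5
    n_drugs: int = 10
    dge_up_rate: float = 0.25
    dge_down_rate: float = 0.15
    n_clusters: int = 12
    cluster_coherence: float = 0.7
    kip_sparsity: float = 0.6
    pic50_max: float = 10.0
    sub_threshold_fraction: float = 0.0
    dga_presence_kinase: float = 0.8
    dga_presence: float = 0.3
    inf_gr50_fraction: float = 0.05
    rule: PlantedRule = field(default_factory=PlantedRule)

    def __post_init__(self):
        probs = [
            self.kinase_fraction, self.dge_up_rate, self.dge_down_rate,
            self.cluster_coherence, self.kip_sparsity, self.sub_threshold_fraction,
            self.dga_presence_kinase, self.dga_presence, self.inf_gr50_fraction,
            self.rule.label_noise,
        ]
        if any(p < 0 or p > 1 for p in probs):
            raise ValidationError("all probabilities must lie in [0,1]")
        if self.dge_up_rate + self.dge_down_rate > 1:
            raise ValidationError("dge up+down rates exceed 1")

    @property
    def n_kinases(self) -> int:
        return round(self.n_genes * self.kinase_fraction)


@dataclass
class Scaffold:
    genes: list[str]
    kinases: frozenset[str]
    ppi_edges: pd.DataFrame
    go_clusters: pd.DataFrame
    graph: nx.Graph


def generate_scaffold(config: SimConfig, seed: int) -> Scaffold:
    """Scale-free gene universe: PPI edge table, kinase flags, cluster table.

    Confidence scores are sampled in [500, 1000] so everything passes the
    default filter, except a configurable sub-threshold fraction (for filter
    testing).  Cluster assignments are spatially coherent: in breadth-first
    order each gene copies a neighbor's cluster with probability
    ``cluster_coherence``.
    """
    if config.n_kinases < 1:
        raise ValidationError("kinase_fraction * n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    g = nx.barabasi_albert_graph(config.n_genes, config.ba_m, seed=int(rng.integers(2 ** 31)))
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    relabel = dict(enumerate(genes))
    g = nx.relabel_nodes(g, relabel)
    kinases = frozenset(rng.choice(genes, size=config.n_kinases, replace=False))

    edges = sorted(g.edges())
    scores = rng.integers(500, 1001, size=len(edges)).astype(float)
    sub = rng.random(len(edges)) < config.sub_threshold_fraction
    scores[sub] = rng.integers(0, 500, size=int(sub.sum()))
    ppi = pd.DataFrame(
        {"protein_a": [e[0] for e in edges], "protein_b": [e[1] for e in edges],
         "score": scores}
    )
    for (u, v), s in zip(edges, scores):
        g[u][v]["weight"] = s

    cluster_of: dict[str, int] = {}
    order = list(nx.bfs_tree(g, genes[0])) if g.number_of_edges() else genes
    for gene in order:
        assigned = [cluster_of[n] for n in g.neighbors(gene) if n in cluster_of]
        if assigned and rng.random() < config.cluster_coherence:
            cluster_of[gene] = assigned[int(rng.integers(len(assigned)))]
        else:
            cluster_of[gene] = int(rng.integers(config.n_clusters))
    for gene in genes:  # isolated or unreached genes
        cluster_of.setdefault(gene, int(rng.integers(config.n_clusters)))
    clusters = pd.DataFrame(
        {"gene": genes, "cluster": [f"BP{cluster_of[g]:03d}" for g in genes]}
    )
    return Scaffold(genes=genes, kinases=kinases, ppi_edges=ppi,
                    go_clusters=clusters, graph=g)


@dataclass
class Profiles:
    dge: pd.DataFrame
    dga: pd.DataFrame
    kip: pd.DataFrame
    cell_lines: list[str]
    drugs: list[str]
    tissue_of: dict[str, str]
    disease_mapping: dict[str, str]


def generate_profiles(scaffold: Scaffold, config: SimConfig, seed: int) -> Profiles:
    """Per-cell-line expression, per-disease association and per-drug
    inhibition tables.

    Cell lines partition into tissues; each tissue maps to one disease term
    shared by its cell lines (association scores are disease-level, as in the
    source databases).  Each drug inhibits a sparse random kinase subset with
    pIC50 uniform in [threshold, pic50_max]; every kinase appears in the
    profiling panel, so the kinase universe is recoverable from the table.
    """
    rng = np.random.default_rng(seed)
    tissues = TISSUE_NAMES[: config.n_tissues]
    cell_lines = [f"CL{i:03d}" for i in range(config.n_cell_lines)]
    tissue_of = {cl: tissues[i % len(tissues)] for i, cl in enumerate(cell_lines)}
    disease_mapping = {cl: f"{tissue_of[cl]} carcinoma" for cl in cell_lines}
    drugs = [f"drug{j:02d}" for j in range(config.n_drugs)]

    # DGE: only up/down rows are emitted; unreported genes are 'normal'
    rows = []
    for cl in cell_lines:
        u = rng.random(config.n_genes)
        for gene, x in zip(scaffold.genes, u):
            if x < config.dge_up_rate:
                rows.append((gene, cl, "up"))
            elif x < config.dge_up_rate + config.dge_down_rate:
                rows.append((gene, cl, "down"))
    dge = pd.DataFrame(rows, columns=["gene", "cell_line", "category"])

    rows = []
    for disease in sorted(set(disease_mapping.values())):
        for gene in scaffold.genes:
            p = config.dga_presence_kinase if gene in scaffold.kinases else config.dga_presence
            if rng.random() >= p:
                continue
            if rng.random() < 0.5:
                rows.append((disease, gene, round(rng.uniform(1.0, 10.0), 2), "DISEASE"))
            else:
                rows.append((disease, gene, round(rng.uniform(0.01, 1.0), 3), "DisGeNET"))
    dga = pd.DataFrame(rows, columns=["disease", "gene", "score", "source"])

    kinases = sorted(scaffold.kinases)
    lo = config.rule.pic50_threshold
    rows = []
    for drug in drugs:
        hit = rng.random(len(kinases)) < config.kip_sparsity
        if not hit.any():  # every profiled compound is a kinase inhibitor
            hit[int(rng.integers(len(kinases)))] = True
        for kin, h in zip(kinases, hit):
            if h:
                rows.append((drug, kin, round(rng.uniform(lo, config.pic50_max), 3)))
    covered = {k for _, k, _ in rows}
    for kin in kinases:  # guarantee panel coverage of the whole kinome
        if kin not in covered:
            drug = drugs[int(rng.integers(len(drugs)))]
            rows.append((drug, kin, round(rng.uniform(lo, config.pic50_max), 3)))
    kip = pd.DataFrame(rows, columns=["compound", "kinase", "pic50"])
    return Profiles(dge=dge, dga=dga, kip=kip, cell_lines=cell_lines, drugs=drugs,
                    tissue_of=tissue_of, disease_mapping=disease_mapping)


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def instance_signal(scaffold: Scaffold, profiles: Profiles, rule: PlantedRule,
                    cell_line: str, drug: str) -> int:
    """Ground-truth signal s: kinases up-regulated, inhibited and
    disease-associated above the cut, evaluated directly from the tables."""
    up = set(
        profiles.dge[(profiles.dge["cell_line"] == cell_line)
                     & (profiles.dge["category"] == "up")]["gene"]
    )
    kip = profiles.kip
    inhibited = set(
        kip[(kip["compound"] == drug) & (kip["pic50"] >= rule.pic50_threshold)]["kinase"]
    )
    disease = profiles.disease_mapping[cell_line]
    dga = profiles.dga[profiles.dga["disease"] == disease]
    strong = set()
    for gene, score, source in dga[["gene", "score", "source"]].itertuples(index=False):
        norm = float(score) / 10.0 if source == "DISEASE" else float(score)
        if norm >= rule.dga_cut:
            strong.add(gene)
    return len(scaffold.kinases & up & inhibited & strong)


def plant_labels(
    scaffold: Scaffold, profiles: Profiles, rule: PlantedRule, seed: int,
    inf_gr50_fraction: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the growth-rate table from the planted mechanism.

    Returns the GR table and a ground-truth diagnostics table (signal count,
    clean probability, clean and noisy labels) keyed by instance.
    """
    rng = np.random.default_rng(seed)
    gr_rows, truth_rows = [], []
    for cl in profiles.cell_lines:
        for drug in profiles.drugs:
            s = instance_signal(scaffold, profiles, rule, cl, drug)
            p = _sigmoid(rule.signal_strength * s - rule.offset)
            clean = int(rng.random() < p)
            label = clean if rng.random() >= rule.label_noise else 1 - clean
            mag = rng.uniform(1e-6, 1.0)
            gr_max = -mag if label == 1 else mag
            gr50 = math.inf if rng.random() < inf_gr50_fraction else float(
                10.0 ** rng.normal(-7.0, 1.0)
            )
            gr_rows.append((cl, drug, gr50, gr_max, profiles.tissue_of[cl]))
            truth_rows.append((cl, drug, s, p, clean, label))
    gr = pd.DataFrame(gr_rows, columns=["cell_line", "drug", "gr50", "gr_max", "tissue"])
    truth = pd.DataFrame(
        truth_rows, columns=["cell_line", "drug", "signal", "p_cytotoxic",
                             "label_clean", "label"]
    )
    return gr, truth


def generate_tables(config: SimConfig, seed: int) -> tuple[OmicsTables, dict, pd.DataFrame]:
    """End-to-end generation of a validated :class:`OmicsTables`, the cell
    line to disease mapping, and the ground-truth diagnostics table."""
    scaffold = generate_scaffold(config, seed)
    profiles = generate_profiles(scaffold, config, seed + 1)
    gr, truth = plant_labels(scaffold, profiles, config.rule, seed + 2,
                             config.inf_gr50_fraction)
    tables = OmicsTables(
        ppi_edges=scaffold.ppi_edges,
        dge=profiles.dge,
        dga=profiles.dga,
        kip=profiles.kip,
        gr=gr,
        go_clusters=scaffold.go_clusters,
    )
    return tables, profiles.disease_mapping, truth


def write_tables(tables: OmicsTables, disease_mapping: dict, outdir) -> dict[str, str]:
    """Write the six TSV tables plus the disease mapping; returns the paths."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}
    for name in ("ppi_edges", "dge", "dga", "kip", "gr", "go_clusters"):
        path = os.path.join(outdir, f"{name}.tsv")
        getattr(tables, name).to_csv(path, sep="\t", index=False)
        paths[name] = path
    mpath = os.path.join(outdir, "disease_mapping.tsv")
    pd.DataFrame(sorted(disease_mapping.items()),
                 columns=["cell_line", "disease"]).to_csv(mpath, sep="\t", index=False)
    paths["disease_mapping"] = mpath
    return paths


def generate_dataset(
    config: SimConfig, seed: int, reduce: bool = True
) -> tuple[list[CancerGraph], pd.DataFrame]:
    """Generate tables, build every accepted instance graph and (optionally)
    reduce each one.  Returns the graphs and the ground-truth table."""
    from .reduction import reduce_graph

    tables, disease_mapping, truth = generate_tables(config, seed)
    build_cfg = BuildConfig(disease_mapping=disease_mapping)
    graphs, _ = build_dataset(tables, build_cfg)
    if reduce:
        cmap = {g: str(c) for g, c in
                tables.go_clusters[["gene", "cluster"]].itertuples(index=False)}
        graphs = [reduce_graph(g, cmap)[0] for g in graphs]
    return graphs, truth


# ---------------------------------------------------------------------------
# the 13-node worked-example fixture
# ---------------------------------------------------------------------------

_WE_DGE = {
    "1": "up", "2": "normal", "3": "normal", "4": "normal",
    "a": "up", "b": "up", "c": "normal", "d": "down", "e": "normal",
    "f": "down", "g": "down", "h": "normal", "i": "down",
}
_WE_DGA = {"1": 5.2, "4": 3.4, "e": 2.6, "f": 1.9, "g": 2.3}
_WE_PIC50 = {"1": 6.8, "3": 8.8}
_WE_CLUSTERS = {
    "a": "BP1", "b": "BP1", "c": "BP2", "e": "BP2", "d": "BP3", "f": "BP3",
    "g": "BP3", "h": "BP4", "i": "BP5", "1": "BP6", "2": "BP7", "3": "BP8",
    "4": "BP9",
}
# Synthetic adjacency for the worked example, constructed so that every
# stated property holds: merge groups a-b, c-e and d-f-g are connected and
# eligible, no other pair is, group d-f-g reaches its outside neighbor e
# through weights {600, 800} (median 700 after merging), and the kinases
# carry the annotations listed above.
_WE_EDGES = {
    ("a", "b"): 700.0, ("c", "e"): 650.0, ("d", "f"): 800.0, ("f", "g"): 750.0,
    ("d", "e"): 600.0, ("e", "f"): 800.0, ("1", "i"): 900.0, ("1", "a"): 850.0,
    ("1", "e"): 950.0, ("2", "e"): 900.0, ("3", "c"): 880.0, ("4", "g"): 820.0,
    ("4", "h"): 760.0, ("h", "i"): 700.0, ("1", "4"): 560.0,
}
_WE_KINASES = {"1", "2", "3", "4"}


def worked_example_fixture() -> tuple[CancerGraph, pd.DataFrame]:
    """The 13-node worked example: a breast-adenocarcinoma cell line with a
    dual-family kinase inhibitor.

    Kinase nodes 1-4 (EGFR, JAK2, JAK1, SRC) and non-kinase nodes a-i (NANOG,
    EP300, IL10RA, HIF1A, STAT3, HSP90AA1, PXN, CRK, CBL); node 1 is
    up-regulated with disease association 5.2 and pIC50 6.8, node 3 carries
    pIC50 8.8, node 4 association 3.4, nodes e/f/g associations 2.6/1.9/2.3.
    GRmax is -0.96, so the label is positive (cytotoxic).  Returns the graph
    and its biological-process cluster table.
    """
    nodes = [
        NodeAnnotation(
            gene_id=g,
            is_kinase=g in _WE_KINASES,
            dge=_WE_DGE[g],
            dga_disease=_WE_DGA.get(g),
            pic50=_WE_PIC50.get(g),
        )
        for g in sorted(_WE_DGE)
    ]
    graph = CancerGraph(
        instance_id=("MDA-MB-468", "dasatinib"),
        tissue="breast tissue",
        nodes=nodes,
        edges=dict(_WE_EDGES),
        label=1,
        min_confidence=500.0,
    )
    clusters = pd.DataFrame(
        sorted(_WE_CLUSTERS.items()), columns=["gene", "cluster"]
    )
    return graph, clusters


def worked_example_tables() -> tuple[OmicsTables, dict[str, str]]:
    """The worked example expressed as raw input tables, so that the full
    build pipeline reproduces :func:`worked_example_fixture`."""
    cl, drug, disease = "MDA-MB-468", "dasatinib", "breast adenocarcinoma"
    ppi = pd.DataFrame(
        [(u, v, w) for (u, v), w in sorted(_WE_EDGES.items())],
        columns=["protein_a", "protein_b", "score"],
    )
    dge = pd.DataFrame(
        [(g, cl, c) for g, c in sorted(_WE_DGE.items()) if c != "normal"],
        columns=["gene", "cell_line", "category"],
    )
    dga = pd.DataFrame(
        [(disease, g, s, "DISEASE") for g, s in sorted(_WE_DGA.items())],
        columns=["disease", "gene", "score", "source"],
    )
    # sub-threshold reference rows register kinases 2 and 4 in the panel
    kip = pd.DataFrame(
        [(drug, "1", 6.8), (drug, "3", 8.8),
         ("staurosporine", "2", 5.0), ("staurosporine", "4", 5.5)],
        columns=["compound", "kinase", "pic50"],
    )
    gr = pd.DataFrame(
        [(cl, drug, 3.0e-6, -0.96, "breast tissue")],
        columns=["cell_line", "drug", "gr50", "gr_max", "tissue"],
    )
    _, clusters = worked_example_fixture()
    tables = OmicsTables(ppi_edges=ppi, dge=dge, dga=dga, kip=kip, gr=gr,
                         go_clusters=clusters)
    return tables, {cl: disease}
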
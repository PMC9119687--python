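"""Assembly of labeled (cell line, drug) graphs from the omics tables.

The base network is the confidence-filtered PPI graph (edges kept when the
STRING-style combined score is >= ``min_confidence``, default 500).  For each
cell line-drug combination with an accepted growth-rate record, every protein
is annotated with its expression category for the cell line, the association
scores of the cell line's disease, and the drug's inhibition potency when it
passes the pIC50 threshold (default 6.3, i.e. IC50 <= 500 nM).  The graph
label is the sign of GRmax: negative GRmax means the drug shrank the
population (cytotoxic, label 1), positive means growth arrest only
(cytostatic, label 0).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import EmptyNetworkError, ValidationError
from .graph import CancerGraph, NodeAnnotation, _canon
from .tables import OmicsTables

log = logging.getLogger(__name__)


def pic50_from_ic50_nm(ic50_nm: float) -> float:
    """pIC50 = -log10(IC50 in molar) for a concentration given in nanomolar."""
    if ic50_nm <= 0:
        raise ValueError("IC50 must be positive")
    return -math.log10(ic50_nm * 1e-9)


@dataclass(frozen=True)
class GRRecord:
    """One growth-rate inhibition measurement for a (cell line, drug) pair."""

    cell_line: str
    drug: str
    gr50: float
    gr_max: float
    tissue: str
    n_gr50: int = 1  # number of GR50 values reported for this pair


@dataclass(frozen=True)
class LabelResult:
    accepted: bool
    label: int | None = None
    reason: str | None = None


@dataclass
class BuildConfig:
    """Thresholds and lookups used during graph assembly."""

    min_confidence: float = 500.0
    min_pic50: float = pic50_from_ic50_nm(500.0)  # 6.30103..., printed as 6.3
    disease_mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.min_confidence < 0:
            raise ValidationError("min_confidence must be >= 0")
        if self.min_pic50 <= 0:
            raise ValidationError("min_pic50 must be > 0")


def build_ppi_network(ppi_edges: pd.DataFrame, min_confidence: float = 500.0) -> nx.Graph:
    """Build the undirected simple PPI graph from the edge table.

    The threshold is inclusive (a score of exactly 500 is kept), self-pairs are
    dropped, and duplicate or reversed pairs collapse to the maximum score.
    Raises :class:`EmptyNetworkError` when nothing survives.
    """
    df = ppi_edges[ppi_edges["score"] >= min_confidence]
    df = df[df["protein_a"] != df["protein_b"]]
    g = nx.Graph()
    for a, b, s in df[["protein_a", "protein_b", "score"]].itertuples(index=False):
        s = float(s)
        if g.has_edge(a, b):
            g[a][b]["weight"] = max(g[a][b]["weight"], s)
        else:
            g.add_edge(a, b, weight=s)
    if g.number_of_edges() == 0:
        raise EmptyNetworkError(
            f"no PPI edge passes the confidence threshold {min_confidence}"
        )
    return g


def label_from_gr(record: GRRecord) -> LabelResult:
    """Label one GR record or reject it.

    Negative GRmax -> cytotoxic (label 1); positive (or zero, by convention)
    GRmax -> cytostatic (label 0).  Records with an infinite GR50 or with
    multiple GR50 values for the same pair are rejected.
    """
    gr_max = float(record.gr_max)
    if math.isnan(gr_max):
        raise ValidationError(
            f"non-numeric gr_max for ({record.cell_line}, {record.drug})"
        )
    if record.n_gr50 > 1:
        return LabelResult(False, reason="multiple GR50 values")
    if math.isinf(record.gr50):
        return LabelResult(False, reason="infinite GR50")
    return LabelResult(True, label=1 if gr_max < 0 else 0)


def build_instance(
    cell_line: str,
    drug: str,
    tables: OmicsTables,
    config: BuildConfig,
    ppi: nx.Graph | None = None,
    gr_record: GRRecord | None = None,
) -> CancerGraph:
    """Assemble one annotated, labeled graph for a (cell line, drug) pair.

    The full filtered PPI network is carried (not an induced subgraph of
    annotated genes); unreported expression defaults to 'normal'; when a
    kinase-drug pair has several retained pIC50 measurements the maximum is
    used.
    """
    if ppi is None:
        ppi = build_ppi_network(tables.ppi_edges, config.min_confidence)
    kinases = tables.kinase_genes

    dge_map = {
        g: c
        for g, c in tables.dge[tables.dge["cell_line"] == cell_line][
            ["gene", "category"]
        ].itertuples(index=False)
    }
    disease = config.disease_mapping.get(cell_line, cell_line)
    dga = tables.dga[tables.dga["disease"] == disease]
    dga_disease = {
        g: float(s)
        for g, s in dga[dga["source"] == "DISEASE"][["gene", "score"]].itertuples(index=False)
    }
    dga_disgenet = {
        g: float(s)
        for g, s in dga[dga["source"] == "DisGeNET"][["gene", "score"]].itertuples(index=False)
    }
    kip = tables.kip[(tables.kip["compound"] == drug)
                     & (tables.kip["pic50"] >= config.min_pic50)]
    pic50 = kip.groupby("kinase")["pic50"].max().to_dict()

    if gr_record is None:
        match = [r for r in gr_records(tables.gr)
                 if r.cell_line == cell_line and r.drug == drug]
        gr_record = match[0] if match else None
    label, tissue = None, ""
    if gr_record is not None:
        res = label_from_gr(gr_record)
        if not res.accepted:
            raise ValidationError(
                f"({cell_line}, {drug}): GR record rejected ({res.reason})"
            )
        label, tissue = res.label, gr_record.tissue

    nodes = []
    for gene in sorted(ppi.nodes):
        is_kin = gene in kinases
        nodes.append(
            NodeAnnotation(
                gene_id=gene,
                is_kinase=is_kin,
                dge=dge_map.get(gene, "normal"),
                dga_disease=dga_disease.get(gene),
                dga_disgenet=dga_disgenet.get(gene),
                pic50=pic50.get(gene) if is_kin else None,
            )
        )
    edges = {_canon(u, v): float(d["weight"]) for u, v, d in ppi.edges(data=True)}
    return CancerGraph(
        instance_id=(cell_line, drug),
        tissue=tissue,
        nodes=nodes,
        edges=edges,
        label=label,
        min_confidence=config.min_confidence,
    )


@dataclass
class BuildReport:
    """Per-pair rejection reasons plus the accepted label balance."""

    rejections: list[tuple[str, str, str]] = field(default_factory=list)
    n_positive: int = 0
    n_negative: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rejections, columns=["cell_line", "drug", "reason"])


def gr_records(gr: pd.DataFrame) -> list[GRRecord]:
    """Collapse the GR table into one record per (cell line, drug) pair,
    counting how many GR50 values were reported for it."""
    out = []
    for (cl, dr), grp in gr.groupby(["cell_line", "drug"], sort=True):
        row = grp.iloc[0]
        out.append(
            GRRecord(
                cell_line=cl,
                drug=dr,
                gr50=float(row["gr50"]),
                gr_max=float(row["gr_max"]),
                tissue=str(row["tissue"]),
                n_gr50=len(grp),
            )
        )
    return out


def build_dataset(
    tables: OmicsTables, config: BuildConfig
) -> tuple[list[CancerGraph], BuildReport]:
    """Build one labeled graph per accepted (cell line, drug) combination.

    Pairs whose GR record is rejected (infinite GR50, multiple GR50 values)
    are listed in the report with the rule that fired; pairs absent from the
    annotation tables are skipped with a reason.
    """
    report = BuildReport()
    graphs: list[CancerGraph] = []
    if len(tables.gr) == 0:
        return graphs, report
    ppi = build_ppi_network(tables.ppi_edges, config.min_confidence)
    known_cell_lines = set(tables.dge["cell_line"])
    known_drugs = set(tables.kip["compound"])
    for rec in gr_records(tables.gr):
        res = label_from_gr(rec)
        if not res.accepted:
            report.rejections.append((rec.cell_line, rec.drug, res.reason))
            continue
        if rec.cell_line not in known_cell_lines and not _has_dga(tables, config, rec.cell_line):
            report.rejections.append((rec.cell_line, rec.drug, "cell line absent from all tables"))
            continue
        if rec.drug not in known_drugs:
            report.rejections.append((rec.cell_line, rec.drug, "drug absent from KIP table"))
            continue
        g = build_instance(rec.cell_line, rec.drug, tables, config, ppi=ppi, gr_record=rec)
        graphs.append(g)
        if g.label == 1:
            report.n_positive += 1
        else:
            report.n_negative += 1
    log.info(
        "built %d graphs (%d positive, %d negative), %d rejections",
        len(graphs), report.n_positive, report.n_negative, len(report.rejections),
    )
    return graphs, report


def _has_dga(tables: OmicsTables, config: BuildConfig, cell_line: str) -> bool:
    disease = config.disease_mapping.get(cell_line, cell_line)
    return bool((tables.dga["disease"] == disease).any())
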
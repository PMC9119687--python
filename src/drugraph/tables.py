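"""Validated ingestion of the six tabular omics inputs.

The tables follow the conventions of their public sources: a STRING-style PPI
edge table (combined confidence 0-1000), a categorical differential-expression
table, a disease-gene association table mixing two score scales (DISEASE 1-10,
DisGeNET 0.01-1), a kinase-inhibition table (pIC50), a growth-rate table
(GR50/GRmax per cell line and drug, with a tissue group) and a gene-to-
biological-process-cluster table.  All files are TSV with a header row; gene
identifiers are opaque strings matched exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

log = logging.getLogger(__name__)

SCHEMAS: dict[str, list[str]] = {
    "ppi_edges": ["protein_a", "protein_b", "score"],
    "dge": ["gene", "cell_line", "category"],
    "dga": ["disease", "gene", "score", "source"],
    "kip": ["compound", "kinase", "pic50"],
    "gr": ["cell_line", "drug", "gr50", "gr_max", "tissue"],
    "go_clusters": ["gene", "cluster"],
}

DGA_RANGES = {"DISEASE": (1.0, 10.0), "DisGeNET": (0.01, 1.0)}


@dataclass
class OmicsTables:
    """Container of the six validated input tables."""

    ppi_edges: pd.DataFrame
    dge: pd.DataFrame
    dga: pd.DataFrame
    kip: pd.DataFrame
    gr: pd.DataFrame
    go_clusters: pd.DataFrame

    def __post_init__(self):
        for f in fields(self):
            validate_table(f.name, getattr(self, f.name))

    @property
    def kinase_genes(self) -> frozenset[str]:
        """Kinase universe: every kinase that appears in the profiling panel."""
        return frozenset(self.kip["kinase"])


def _check_columns(name: str, df: pd.DataFrame) -> None:
    for col in SCHEMAS[name]:
        if col not in df.columns:
            raise SchemaError(f"table {name!r}: missing column {col!r}")


def _bad_rows(name: str, mask: pd.Series, why: str) -> None:
    if mask.any():
        rows = list(mask[mask].index[:5])
        raise ValidationError(f"table {name!r}: {why} (rows {rows})")


def validate_table(name: str, df: pd.DataFrame) -> pd.DataFrame:
    """Validate one table against its declared schema and score ranges."""
    if name not in SCHEMAS:
        raise SchemaError(f"unknown table {name!r}")
    _check_columns(name, df)
    if name == "ppi_edges":
        s = pd.to_numeric(df["score"], errors="coerce")
        _bad_rows(name, s.isna(), "non-numeric confidence score")
        _bad_rows(name, (s < 0) | (s > 1000), "confidence score outside [0,1000]")
        _bad_rows(name, (df["protein_a"] == "") | (df["protein_b"] == ""), "empty identifier")
    elif name == "dge":
        _bad_rows(name, ~df["category"].isin(["up", "down", "normal"]),
                  "category not in {up, down, normal}")
        _bad_rows(name, (df["gene"] == "") | (df["cell_line"] == ""), "empty identifier")
    elif name == "dga":
        _bad_rows(name, ~df["source"].isin(DGA_RANGES), "source not in {DISEASE, DisGeNET}")
        s = pd.to_numeric(df["score"], errors="coerce")
        _bad_rows(name, s.isna(), "non-numeric association score")
        for src, (lo, hi) in DGA_RANGES.items():
            mask = (df["source"] == src) & ((s < lo) | (s > hi))
            _bad_rows(name, mask, f"{src} score outside [{lo:g},{hi:g}]")
    elif name == "kip":
        s = pd.to_numeric(df["pic50"], errors="coerce")
        _bad_rows(name, s.isna(), "non-numeric pIC50")
        _bad_rows(name, s <= 0, "pIC50 must be positive")
    elif name == "gr":
        gmax = pd.to_numeric(df["gr_max"], errors="coerce")
        _bad_rows(name, gmax.isna(), "non-numeric gr_max")
        _bad_rows(name, ~np.isfinite(gmax), "gr_max must be finite")
        _bad_rows(name, df["tissue"] == "", "missing tissue label")
        if len(df) == 0:
            log.warning("growth-rate table is empty: no instances can be built")
    elif name == "go_clusters":
        _bad_rows(name, (df["gene"] == "") | (df["cluster"].astype(str) == ""),
                  "empty identifier")
    return df


def read_omics_tables(paths: dict[str, str], schema_config: dict | None = None) -> OmicsTables:
    """Read and validate the six input tables from TSV files.

    ``paths`` maps table names (:data:`SCHEMAS` keys) to file locations.
    ``schema_config`` may rename columns: ``{table: {file_column: schema_column}}``.
    Raises :class:`SchemaError` for missing columns and :class:`ValidationError`
    with row indices for out-of-range scores.
    """
    schema_config = schema_config or {}
    frames = {}
    for name in SCHEMAS:
        if name not in paths:
            raise SchemaError(f"no path given for table {name!r}")
        df = pd.read_csv(paths[name], sep="\t", dtype=str, keep_default_na=False)
        if name in schema_config:
            df = df.rename(columns=schema_config[name])
        _check_columns(name, df)
        frames[name] = _coerce(name, df)
    return OmicsTables(**frames)


def _coerce(name: str, df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    numeric = {"ppi_edges": ["score"], "dga": ["score"], "kip": ["pic50"],
               "gr": ["gr50", "gr_max"]}.get(name, [])
    for col in numeric:
        df[col] = pd.to_numeric(df[col], errors="coerce")  # "inf" parses to inf
    return df
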
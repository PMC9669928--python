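"""Readers and writers for the TSV/CSV/JSON artefacts of the pipeline.

Matrices are TSV with the analyte id in the first column and sample ids
as header; metadata is CSV with (sample_id, subgroup, mrss, visit).
Every writer round-trips: re-reading an output yields an equal in-memory
object.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .anchor import CascadeReport, IdentifierMap
from .containers import ExpressionMatrix, TraitTable
from .errors import SchemaError
from .modules import EigengeneSet, ModuleAssignment

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_metadata",
    "write_metadata",
    "read_identifier_map",
    "write_identifier_map",
    "write_module_assignment",
    "read_eigengenes",
    "write_eigengenes",
    "write_cascade_report",
]

_NA_MARKERS = ("", "NA")


def read_expression_matrix(path, compartment: str = "unspecified", visit: str = "baseline") -> ExpressionMatrix:
    """Read an analyte x sample TSV/CSV matrix.

    The first column holds analyte ids; empty cells and ``NA`` are
    missing.  Duplicate analyte ids and non-numeric cells are hard errors
    naming the offender.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=list(_NA_MARKERS), keep_default_na=False)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise SchemaError(f"{path.name}: duplicate analyte id(s): {dupes}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.argmax()]
            raise SchemaError(f"{path.name}: non-numeric value at row {row!r}, column {col!r}")
        df[col] = coerced
    return ExpressionMatrix(df, compartment=compartment, visit=visit)


def write_expression_matrix(expr: ExpressionMatrix, path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    expr.data.to_csv(path, sep=sep, index_label="analyte_id")


def read_metadata(path) -> TraitTable:
    """Read and validate the sample metadata CSV."""
    df = pd.read_csv(path, na_values=list(_NA_MARKERS), keep_default_na=False)
    return TraitTable(df)


def write_metadata(traits: TraitTable, path) -> None:
    traits.df.to_csv(path, index=False)


def read_identifier_map(path) -> IdentifierMap:
    df = pd.read_csv(path, sep="\t")
    if not {"gene_symbol", "protein_assay"} <= set(df.columns):
        raise SchemaError("identifier map needs columns gene_symbol, protein_assay")
    if df["gene_symbol"].duplicated().any():
        dupes = df.loc[df["gene_symbol"].duplicated(), "gene_symbol"].tolist()
        raise SchemaError(f"genes mapped more than once: {dupes}")
    return IdentifierMap(dict(zip(df["gene_symbol"], df["protein_assay"])))


def write_identifier_map(idmap: IdentifierMap, path) -> None:
    idmap.to_frame().to_csv(path, sep="\t", index=False)


def write_module_assignment(assign: ModuleAssignment, path) -> None:
    """Two-column TSV: analyte_id, module_colour."""
    pd.DataFrame(
        {"analyte_id": assign.labels.index, "module_colour": assign.as_colors().to_numpy()}
    ).to_csv(path, sep="\t", index=False)


def read_module_assignment(path, min_size: int = 30) -> ModuleAssignment:
    """Rebuild a ModuleAssignment from the two-column TSV; module ids are
    re-derived by decreasing size (grey stays 0)."""
    df = pd.read_csv(path, sep="\t")
    if not {"analyte_id", "module_colour"} <= set(df.columns):
        raise SchemaError("module assignment needs columns analyte_id, module_colour")
    colors = df.set_index("analyte_id")["module_colour"]
    counts = colors[colors != "grey"].value_counts()
    order = sorted(counts.index, key=lambda c: (-counts[c], list(colors).index(c)))
    color_to_id = {c: i + 1 for i, c in enumerate(order)}
    color_to_id["grey"] = 0
    labels = colors.map(color_to_id).astype(int)
    return ModuleAssignment(
        labels=labels,
        colors={i: c for c, i in color_to_id.items()},
        min_size=min_size,
    )


def write_eigengenes(mes: EigengeneSet, path) -> None:
    mes.me.to_csv(path, sep="\t", index_label="module")


def read_eigengenes(path) -> EigengeneSet:
    me = pd.read_csv(path, sep="\t", index_col=0)
    return EigengeneSet(me=me)


def write_cascade_report(report: CascadeReport, out_dir) -> None:
    """One TSV per stage plus a JSON summary of stage sizes and lists."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for stage, table in report.tables.items():
        table.to_csv(out_dir / f"{stage}.tsv", sep="\t", index_label="analyte")
    with open(out_dir / "cascade_summary.json", "w") as fh:
        json.dump(report.summary(), fh, indent=2)


def frames_equal(a: pd.DataFrame, b: pd.DataFrame, tol: float = 0.0) -> bool:
    """Round-trip equality helper (exact by default)."""
    if list(a.index) != list(b.index) or list(a.columns) != list(b.columns):
        return False
    return bool(np.allclose(a.to_numpy(), b.to_numpy(), atol=tol, equal_nan=True))
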
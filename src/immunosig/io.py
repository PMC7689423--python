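"""Readers and writers for the pipeline's tabular interchange formats.

Expression tables are TSV (comma auto-detected) with the first column
holding gene ids, an optional ``probe_class`` column, and one column per
sample.  A leading ``# state=raw|normalized`` comment records the
matrix state; files without it are assumed raw.  Clinical tables are
TSV keyed by ``sample_id``.  Gene and sample ids are case-sensitive and
matched exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .containers import ClinicalTable, ExpressionMatrix, ValidationError

_STATE_PREFIX = "# state="


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                return "," if ("," in line and "\t" not in line) else "\t"
    return "\t"


def read_expression(path: str | Path, state: str | None = None) -> ExpressionMatrix:
    """Read a genes x samples expression table.

    Parameters
    ----------
    path
        TSV/CSV file, first column gene ids, optional ``probe_class``
        column, remaining columns samples.
    state
        Override the state recorded in (or absent from) the header.
    """
    path = Path(path)
    header_state = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith(_STATE_PREFIX):
            header_state = first[len(_STATE_PREFIX):].strip()
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, comment="#", index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise ValidationError(f"duplicated gene row(s): {dupes}")
    probe_class = None
    if "probe_class" in df.columns:
        probe_class = df.pop("probe_class").astype(str)
    values = df.astype(float)
    final_state = state or header_state or "raw"
    return ExpressionMatrix(values, probe_class, final_state)


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    out = m.values.copy()
    if m.probe_class is not None:
        out.insert(0, "probe_class", m.probe_class)
    with open(path, "w") as fh:
        fh.write(f"{_STATE_PREFIX}{m.state}\n")
        out.to_csv(fh, sep="\t", index_label="gene_id")


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read a per-sample clinical TSV/CSV keyed by ``sample_id``."""
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, comment="#", index_col="sample_id")
    df.index = df.index.astype(str)
    return ClinicalTable(df)


def write_clinical(c: ClinicalTable, path: str | Path) -> None:
    c.table.to_csv(Path(path), sep="\t", index_label="sample_id")


def read_signature(path: str | Path) -> "GeneSignature":
    """Read a gene-signature JSON: {"name", "cell_type", "genes"}."""
    from .signatures import GeneSignature

    with open(path) as fh:
        obj = json.load(fh)
    return GeneSignature(name=obj["name"], cell_type=obj["cell_type"],
                         genes=list(obj["genes"]))


def write_signature(sig: "GeneSignature", path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({"name": sig.name, "cell_type": sig.cell_type,
                   "genes": list(sig.genes)}, fh, indent=2)
        fh.write("\n")


def read_cell_atlas(path: str | Path) -> pd.DataFrame:
    """Read a cell-type x gene atlas TSV into a validated DataFrame."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), comment="#", index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        raise ValidationError("duplicate cell types in atlas")
    if df.columns.duplicated().any():
        raise ValidationError("duplicate genes in atlas")
    if (df.to_numpy() < 0).any():
        raise ValidationError("negative expression in atlas")
    return df.astype(float)


def write_cell_atlas(atlas: pd.DataFrame, path: str | Path) -> None:
    atlas.to_csv(Path(path), sep="\t", index_label="cell_type")
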
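"""Readers and writers for the pipeline's on-disk formats.

Supported formats: Matrix Market triplets with sidecar gene/barcode lists
(the CellRanger-style trio), dense TSV matrices, MSigDB-dialect GMT gene
sets, and header-bearing CSV/TSV metadata and clinical tables. Gene
identifiers are matched case-insensitively after whitespace trimming,
because public matrices and signature files mix symbol casings.
"""

from __future__ import annotations

import logging
from importlib import resources as _resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import (
    CellAnnotation,
    ClinicalTable,
    DataContractError,
    ExpressionMatrix,
    GeneSignature,
    validate_score_table,
    VALID_POPULATIONS,
)

log = logging.getLogger("glupart")


def canonical_gene(symbol: str) -> str:
    """Canonical form used for all gene-identifier matching."""
    return symbol.strip().upper()


def _read_id_list(path: Path) -> list[str]:
    # Accept 1-column barcode lists and 2-column features files (id, symbol);
    # for 2+ columns the second column (symbol) wins, per CellRanger layout.
    rows = [
        line.rstrip("\n").split("\t")
        for line in Path(path).read_text().splitlines()
        if line.strip()
    ]
    if not rows:
        raise DataContractError(f"empty identifier list: {path}")
    if len(rows[0]) >= 2:
        return [r[1] for r in rows]
    return [r[0] for r in rows]


def read_matrix(
    path: str | Path,
    format: str = "mtx-triplet",
    genes_path: str | Path | None = None,
    barcodes_path: str | Path | None = None,
    layer: str = "counts",
    genes_in_rows: bool = True,
) -> ExpressionMatrix:
    """Read an expression matrix into genes x units orientation.

    Parameters
    ----------
    format
        ``mtx-triplet`` expects ``path`` to be the .mtx file plus sidecar
        ``genes_path``/``barcodes_path`` lists (defaults: genes.tsv and
        barcodes.tsv next to the .mtx). ``dense-tsv`` expects a TSV with
        gene ids in the first column and unit ids in the header.
    genes_in_rows
        Declares the on-disk orientation; set False for units x genes
        files, which are transposed on load.
    """
    path = Path(path)
    if format == "mtx-triplet":
        genes_path = Path(genes_path) if genes_path else path.parent / "genes.tsv"
        barcodes_path = (
            Path(barcodes_path) if barcodes_path else path.parent / "barcodes.tsv"
        )
        m = scipy.io.mmread(path)
        values = np.asarray(
            m.todense() if scipy.sparse.issparse(m) else m, dtype=float
        )
        gene_ids = _read_id_list(genes_path)
        unit_ids = _read_id_list(barcodes_path)
        if not genes_in_rows:
            values = values.T
        if values.shape[0] != len(gene_ids):
            raise DataContractError(
                f"mtx declares {values.shape[0]} genes but id file lists "
                f"{len(gene_ids)}"
            )
        if values.shape[1] != len(unit_ids):
            raise DataContractError(
                f"mtx declares {values.shape[1]} units but barcode file lists "
                f"{len(unit_ids)}"
            )
    elif format == "dense-tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if not genes_in_rows:
            df = df.T
        values = df.to_numpy(dtype=float)
        gene_ids = [str(g) for g in df.index]
        unit_ids = [str(u) for u in df.columns]
    else:
        raise ValueError(f"unknown matrix format {format!r}")
    return ExpressionMatrix(values, gene_ids, unit_ids, layer=layer)


def write_matrix_mtx(matrix: ExpressionMatrix, out_dir: str | Path) -> dict[str, Path]:
    """Write the mtx + genes.tsv + barcodes.tsv trio; returns written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mtx": out_dir / "matrix.mtx",
        "genes": out_dir / "genes.tsv",
        "barcodes": out_dir / "barcodes.tsv",
    }
    sparse = scipy.sparse.coo_matrix(matrix.values)
    scipy.io.mmwrite(paths["mtx"], sparse)
    paths["genes"].write_text("".join(f"{g}\n" for g in matrix.gene_ids))
    paths["barcodes"].write_text("".join(f"{u}\n" for u in matrix.unit_ids))
    return paths


def read_gmt(path: str | Path) -> list[GeneSignature]:
    """Parse a GMT file: one signature per tab-separated line of
    name, description, gene, gene, ... Duplicate genes within a line are
    collapsed (order kept) with a logged warning."""
    signatures = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise DataContractError(
                f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3"
            )
        name, description, *genes = fields
        genes = [canonical_gene(g) for g in genes if g.strip()]
        deduped = list(dict.fromkeys(genes))
        if len(deduped) != len(genes):
            log.warning(
                "signature %s: collapsed %d duplicate gene(s)",
                name,
                len(genes) - len(deduped),
            )
        signatures.append(GeneSignature(name, tuple(deduped), description))
    return signatures


def bundled_signatures() -> dict[str, GeneSignature]:
    """The built-in glutamine-metabolism (9 genes) and cytotoxicity
    (6 genes) signatures, keyed by name."""
    ref = _resources.files("glupart") / "resources" / "signatures.gmt"
    with _resources.as_file(ref) as p:
        sigs = read_gmt(p)
    return {s.name: s for s in sigs}


def read_cell_metadata(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> CellAnnotation:
    """Read a cell metadata table into a CellAnnotation.

    ``columns`` maps required names to the file's column names, e.g.
    ``{"cell_id": "barcode"}``. Population labels are matched
    case-insensitively against the enum; anything unrecognised becomes
    "other" (the count is logged)."""
    colmap = {"cell_id": "cell_id", "patient_id": "patient_id",
              "population": "population"}
    colmap.update(columns or {})
    df = pd.read_csv(path, sep=sep if sep else _infer_sep(path))
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise DataContractError(f"metadata missing mandatory columns {missing}")
    out = pd.DataFrame(
        {std: df[src].astype(str) for std, src in colmap.items()}
    )
    lowered = {p.lower(): p for p in VALID_POPULATIONS}
    mapped = out["population"].str.strip().str.lower().map(lowered)
    n_other = int(mapped.isna().sum())
    if n_other:
        log.info("mapped %d unrecognised population label(s) to 'other'", n_other)
    out["population"] = mapped.fillna("other")
    return CellAnnotation(out)


def read_clinical(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
    time_unit: str = "days",
    sep: str | None = None,
) -> ClinicalTable:
    """Read a clinical CSV/TSV. Time units are declared, never inferred."""
    colmap = {"sample_id": "sample_id", "time": "time", "status": "status"}
    colmap.update(columns or {})
    df = pd.read_csv(path, sep=sep if sep else _infer_sep(path))
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise DataContractError(f"clinical table missing mandatory columns {missing}")
    renamed = df.rename(columns={src: std for std, src in colmap.items()})
    return ClinicalTable(renamed, time_unit=time_unit)


def write_scores(path: str | Path, table: pd.DataFrame) -> Path:
    """Write a score table as TSV with full float precision."""
    validate_score_table(table)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return path


def read_scores(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    return validate_score_table(table)


def _infer_sep(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","
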
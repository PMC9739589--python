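"""Cell/gene quality filters and log-normalization for count matrices.

The filter thresholds mirror a common single-cell QC recipe for liver
tumor atlases: keep cells with more than ``min_genes_per_cell`` detected
genes, drop cells with high mitochondrial fraction, low ribosomal
fraction, or high hemoglobin fraction, then keep genes expressed in at
least ``min_cells_per_gene`` of the surviving cells. Note the ribosomal
rule excludes cells with a LOW ribosomal proportion (<= 2%); unusual, but
kept as printed in the recipe this reproduces — see docs/methods.md.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .containers import DataContractError, ExpressionMatrix


class DegenerateResultError(RuntimeError):
    """A statistically valid operation produced an empty/degenerate result
    (e.g. QC removed every cell). Distinct from contract and I/O errors."""


@dataclass
class QCThresholds:
    min_genes_per_cell: int = 50
    min_cells_per_gene: int = 3
    max_mito_frac: float = 0.04
    min_ribo_frac: float = 0.02
    max_hemo_frac: float = 0.10
    mito_prefixes: tuple[str, ...] = ("MT-",)
    ribo_prefixes: tuple[str, ...] = ("RPS", "RPL")
    hemo_prefixes: tuple[str, ...] = ("HBA", "HBB", "HBD", "HBE", "HBG",
                                      "HBM", "HBQ", "HBZ")

    def __post_init__(self) -> None:
        for f in (self.max_mito_frac, self.min_ribo_frac, self.max_hemo_frac):
            if not 0.0 <= f <= 1.0:
                raise DataContractError("QC fractions must lie in [0, 1]")
        if self.min_genes_per_cell < 0 or self.min_cells_per_gene < 0:
            raise DataContractError("QC counts must be >= 0")


@dataclass
class QCReport:
    n_cells_in: int
    n_genes_in: int
    removed_low_genes: int
    removed_mito: int
    removed_ribo: int
    removed_hemo: int
    removed_genes: int
    n_cells_out: int
    n_genes_out: int

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2) + "\n")
        return path

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        lines = ["metric\tvalue"] + [f"{k}\t{v}" for k, v in asdict(self).items()]
        path.write_text("\n".join(lines) + "\n")
        return path


def _prefix_mask(gene_ids: list[str], prefixes: tuple[str, ...]) -> np.ndarray:
    upper = [g.upper() for g in gene_ids]
    return np.array(
        [any(g.startswith(p) for p in prefixes) for g in upper], dtype=bool
    )


def qc_filter(
    matrix: ExpressionMatrix, thresholds: QCThresholds | None = None
) -> tuple[ExpressionMatrix, QCReport]:
    """Apply cell filters, then the gene filter, in that fixed order.

    Cells are retained iff detected-gene count > min_genes_per_cell AND
    mito fraction < max_mito_frac AND ribo fraction > min_ribo_frac AND
    hemo fraction < max_hemo_frac (inequalities strict, matching the
    stated exclusion rules). Genes are then retained iff expressed in
    >= min_cells_per_gene of the surviving cells, so removing cells can
    never resurrect a gene.
    """
    if matrix.layer != "counts":
        raise DataContractError(f"qc_filter needs a counts layer, got {matrix.layer}")
    thr = thresholds or QCThresholds()
    v = matrix.values
    totals = v.sum(axis=0)
    detected = (v > 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        safe_tot = np.where(totals > 0, totals, 1.0)
        mito = v[_prefix_mask(matrix.gene_ids, thr.mito_prefixes)].sum(axis=0) / safe_tot
        ribo = v[_prefix_mask(matrix.gene_ids, thr.ribo_prefixes)].sum(axis=0) / safe_tot
        hemo = v[_prefix_mask(matrix.gene_ids, thr.hemo_prefixes)].sum(axis=0) / safe_tot

    pass_genes = detected > thr.min_genes_per_cell
    pass_mito = mito < thr.max_mito_frac
    # min_ribo_frac = 0 disables the rule (otherwise cells without any
    # ribosomal gene could never pass the strict inequality).
    pass_ribo = (
        ribo > thr.min_ribo_frac
        if thr.min_ribo_frac > 0
        else np.ones_like(ribo, dtype=bool)
    )
    pass_hemo = hemo < thr.max_hemo_frac
    keep_cells = pass_genes & pass_mito & pass_ribo & pass_hemo

    # Per-criterion removals counted independently (a cell can fail several).
    report_kw = dict(
        n_cells_in=matrix.n_units,
        n_genes_in=matrix.n_genes,
        removed_low_genes=int((~pass_genes).sum()),
        removed_mito=int((~pass_mito).sum()),
        removed_ribo=int((~pass_ribo).sum()),
        removed_hemo=int((~pass_hemo).sum()),
    )

    cellf = v[:, keep_cells]
    keep_genes = (cellf > 0).sum(axis=1) >= thr.min_cells_per_gene
    out_values = cellf[keep_genes, :]
    if out_values.size == 0:
        raise DegenerateResultError(
            "QC removed every cell or every gene; relax thresholds"
        )
    out = ExpressionMatrix(
        out_values,
        [g for g, k in zip(matrix.gene_ids, keep_genes) if k],
        [u for u, k in zip(matrix.unit_ids, keep_cells) if k],
        layer="counts",
    )
    report = QCReport(
        **report_kw,
        removed_genes=int((~keep_genes).sum()),
        n_cells_out=out.n_units,
        n_genes_out=out.n_genes,
    )
    return out, report


def log_normalize(
    matrix: ExpressionMatrix, scale_factor: float = 10_000.0
) -> ExpressionMatrix:
    """Library-size normalize and log-transform:
    entry (g, c) -> ln(1 + count[g,c] / total[c] * scale_factor)."""
    if matrix.layer != "counts":
        raise DataContractError(
            f"log_normalize needs a counts layer, got {matrix.layer}"
        )
    totals = matrix.values.sum(axis=0)
    if (totals == 0).any():
        zero = [u for u, t in zip(matrix.unit_ids, totals) if t == 0]
        raise DataContractError(f"zero-total cells cannot be normalized: {zero[:5]}")
    values = np.log1p(matrix.values / totals * scale_factor)
    return ExpressionMatrix(
        values, list(matrix.gene_ids), list(matrix.unit_ids), layer="lognorm"
    )
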
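"""Single-sample gene-set enrichment (ssGSEA) scoring.

For one unit (cell or bulk sample) the score is a rank-weighted running
sum: genes are ordered by decreasing expression, and at each position the
weighted empirical CDF of in-set genes (weights = expression rank^alpha)
minus the uniform empirical CDF of out-of-set genes is accumulated; the
raw score is the sum of that difference over all positions. With
normalization enabled, raw scores are divided by (max - min) across the
units scored together, so the normalization frame matters: per-patient
scoring puts a patient's tumor and CD8T cells on one comparable scale.

The score depends on expression only through within-unit ranks, so any
strictly monotone per-unit transform of the input leaves it unchanged;
ties get average ranks, which keeps scoring permutation-equivariant on
tie-heavy sparse data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import (
    CellAnnotation,
    DataContractError,
    ExpressionMatrix,
    GeneSignature,
)
from .io import bundled_signatures, canonical_gene

log = logging.getLogger("glupart")


@dataclass
class SsgseaParams:
    """Scoring parameters.

    weight_exponent
        Exponent alpha applied to the expression rank when weighting
        in-set genes; 0.25 follows the published convention of the
        single-sample enrichment algorithm this engine implements.
    normalize_across_units
        Divide raw scores by (max - min) over the units scored together.
    min_set_genes_present
        Minimum signature genes that must match the matrix.
    """

    weight_exponent: float = 0.25
    normalize_across_units: bool = True
    min_set_genes_present: int = 2

    def __post_init__(self) -> None:
        if not np.isfinite(self.weight_exponent) or self.weight_exponent < 0:
            raise DataContractError("weight_exponent must be finite and >= 0")
        if self.min_set_genes_present < 1:
            raise DataContractError("min_set_genes_present must be >= 1")


def match_signature(
    matrix: ExpressionMatrix, signature: GeneSignature, min_present: int
) -> np.ndarray:
    """Boolean in-set mask over matrix genes, case-insensitive matching.
    Signature genes absent from the matrix are dropped with a warning."""
    canon = {canonical_gene(g): i for i, g in enumerate(matrix.gene_ids)}
    hits = [canon[canonical_gene(g)] for g in signature.genes
            if canonical_gene(g) in canon]
    n_missing = len(signature.genes) - len(hits)
    if n_missing:
        log.warning(
            "signature %s: %d gene(s) absent from matrix", signature.name, n_missing
        )
    if len(hits) < min_present:
        raise DataContractError(
            f"signature {signature.name!r}: only {len(hits)} gene(s) matched, "
            f"need >= {min_present}"
        )
    mask = np.zeros(matrix.n_genes, dtype=bool)
    mask[hits] = True
    if mask.all():
        raise DataContractError(
            f"signature {signature.name!r} covers every gene; out-set is empty"
        )
    return mask


def _raw_scores(values: np.ndarray, in_set: np.ndarray, alpha: float) -> np.ndarray:
    """Vectorized raw running-sum scores for all units (columns)."""
    n_genes, n_units = values.shape
    # Average ranks of expression within each unit; the most expressed
    # gene gets rank n_genes. Walk order is descending expression with
    # ties broken by gene index (stable), so scoring is deterministic.
    ranks = rankdata(values, axis=0)
    order = np.argsort(-values, axis=0, kind="stable")
    ordered_ranks = np.take_along_axis(ranks, order, axis=0)
    ordered_inset = in_set[order]

    weights = np.where(ordered_inset, np.abs(ordered_ranks) ** alpha, 0.0)
    cdf_in = np.cumsum(weights, axis=0) / weights.sum(axis=0, keepdims=True)
    n_out = n_genes - int(in_set.sum())
    cdf_out = np.cumsum(~ordered_inset, axis=0) / n_out
    return (cdf_in - cdf_out).sum(axis=0)


def ssgsea_score(
    matrix: ExpressionMatrix,
    signature: GeneSignature,
    params: SsgseaParams | None = None,
) -> pd.DataFrame:
    """Score every unit of ``matrix`` against ``signature``.

    Returns a ScoreTable DataFrame with columns unit_id, signature_name,
    score. Scoring is deterministic (no RNG anywhere).
    """
    params = params or SsgseaParams()
    in_set = match_signature(matrix, signature, params.min_set_genes_present)
    raw = _raw_scores(matrix.values, in_set, params.weight_exponent)
    scores = raw
    if params.normalize_across_units:
        span = raw.max() - raw.min()
        if span > 0:
            scores = raw / span
    return pd.DataFrame(
        {
            "unit_id": matrix.unit_ids,
            "signature_name": signature.name,
            "score": scores,
        }
    )


def score_populations(
    matrix: ExpressionMatrix,
    annotation: CellAnnotation,
    signatures: list[GeneSignature],
    params: SsgseaParams | None = None,
    frame: str = "within-patient",
    populations: tuple[str, str] = ("tumor", "CD8T"),
) -> tuple[pd.DataFrame, list[dict]]:
    """Per-cell signature scores with patient/population columns attached.

    ``frame`` controls the normalization frame: "within-patient" scores
    each patient's tumor + CD8T cells together (the default, making
    GStumor and GSimmune comparable within a patient); "global" scores
    all annotated cells in one frame.

    Returns (score table, report). The report lists per-patient problems
    — e.g. a patient with zero cells of a required population — without
    dropping the other patients.
    """
    params = params or SsgseaParams()
    annotation.check_covers(matrix)
    meta = annotation.table.set_index("cell_id")
    report: list[dict] = []
    frames: list[pd.DataFrame] = []

    if frame == "global":
        cells = [u for u in matrix.unit_ids
                 if meta.loc[u, "population"] in populations]
        sub = matrix.subset_units(cells)
        for sig in signatures:
            frames.append(ssgsea_score(sub, sig, params))
    elif frame == "within-patient":
        for patient in annotation.patients():
            by_pop = {p: annotation.cells_of(patient, p) for p in populations}
            missing = [p for p, cells in by_pop.items() if not cells]
            if missing:
                report.append(
                    {
                        "patient_id": patient,
                        "problem": "missing_population",
                        "detail": ",".join(missing),
                    }
                )
                continue
            cells = [c for p in populations for c in by_pop[p]]
            sub = matrix.subset_units(cells)
            for sig in signatures:
                frames.append(ssgsea_score(sub, sig, params))
    else:
        raise ValueError(f"unknown normalization frame {frame!r}")

    if not frames:
        return (
            pd.DataFrame(
                columns=["unit_id", "signature_name", "score", "patient_id",
                         "population"]
            ),
            report,
        )
    out = pd.concat(frames, ignore_index=True)
    out["patient_id"] = meta.loc[out["unit_id"], "patient_id"].to_numpy()
    out["population"] = meta.loc[out["unit_id"], "population"].to_numpy()
    return out, report


def cytotoxic_score(
    matrix: ExpressionMatrix,
    annotation: CellAnnotation,
    params: SsgseaParams | None = None,
    frame: str = "within-patient",
) -> pd.DataFrame:
    """Cytotoxicity (GZMA, GZMB, PRF1, IFNG, EOMES, NKG7) ssGSEA scores
    restricted to CD8T cells."""
    sig = bundled_signatures()["CYTOTOXICITY"]
    cd8 = annotation.table[annotation.table["population"] == "CD8T"]
    if cd8.empty:
        raise DataContractError("no CD8T cells to score")
    sub_annot = CellAnnotation(cd8.copy())
    sub = matrix.subset_units(sub_annot.cell_ids)
    if frame == "within-patient":
        frames = []
        for patient in sub_annot.patients():
            cells = sub_annot.cells_of(patient)
            frames.append(ssgsea_score(sub.subset_units(cells), sig, params))
        out = pd.concat(frames, ignore_index=True)
    else:
        out = ssgsea_score(sub, sig, params)
    meta = sub_annot.table.set_index("cell_id")
    out["patient_id"] = meta.loc[out["unit_id"], "patient_id"].to_numpy()
    out["population"] = "CD8T"
    return out
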
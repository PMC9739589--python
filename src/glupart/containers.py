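"""Typed in-memory containers for the partitioning pipeline.

The analysis moves four kinds of object between stages: an expression
matrix (genes x units, where a unit is a cell or a bulk sample), a cell
annotation (cell -> patient, population), named gene signatures, and a
clinical table of survival records. Containers validate their invariants
at construction so downstream code can assume them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

VALID_LAYERS = ("counts", "lognorm", "fpkm", "score-ready")
VALID_POPULATIONS = ("tumor", "CD8T", "other")


class DataContractError(ValueError):
    """An input violates a container invariant (duplicate ids, negative
    counts, bad dimensions ...). Distinct from I/O failures."""


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen, dups = set(), set()
        for i in ids:
            (dups if i in seen else seen).add(i)
        raise DataContractError(f"duplicate {what}: {sorted(dups)[:5]}")
    return ids


@dataclass
class ExpressionMatrix:
    """Dense genes x units expression matrix with identifier lists.

    ``layer`` records the value scale: raw ``counts`` (integer-valued),
    ``lognorm`` (ln(1 + CP10K)), ``fpkm`` bulk values, or generic
    ``score-ready`` values. Counts and FPKM must be finite and >= 0.
    """

    values: np.ndarray
    gene_ids: list[str]
    unit_ids: list[str]
    layer: str = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataContractError("expression values must be 2-dimensional")
        self.gene_ids = _check_unique(self.gene_ids, "gene_ids")
        self.unit_ids = _check_unique(self.unit_ids, "unit_ids")
        if self.values.shape != (len(self.gene_ids), len(self.unit_ids)):
            raise DataContractError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.unit_ids)} units"
            )
        if self.layer not in VALID_LAYERS:
            raise DataContractError(f"unknown layer {self.layer!r}")
        if not np.all(np.isfinite(self.values)):
            raise DataContractError("non-finite expression values")
        if self.layer in ("counts", "fpkm") and (self.values < 0).any():
            raise DataContractError(f"negative values in {self.layer} layer")
        if self.layer == "counts" and not np.allclose(
            self.values, np.round(self.values)
        ):
            raise DataContractError("counts layer must be integer-valued")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_units(self, unit_ids: Sequence[str]) -> "ExpressionMatrix":
        pos = {u: i for i, u in enumerate(self.unit_ids)}
        idx = [pos[u] for u in unit_ids]
        return ExpressionMatrix(
            self.values[:, idx], list(self.gene_ids), list(unit_ids), self.layer
        )

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        pos = self.gene_index()
        idx = [pos[g] for g in gene_ids]
        return ExpressionMatrix(
            self.values[idx, :], list(gene_ids), list(self.unit_ids), self.layer
        )


@dataclass
class CellAnnotation:
    """Maps each cell to a patient and population label.

    Population labels come from the closed set {tumor, CD8T, other};
    readers fold unrecognised labels into "other".
    """

    table: pd.DataFrame  # columns: cell_id, patient_id, population

    def __post_init__(self) -> None:
        required = {"cell_id", "patient_id", "population"}
        missing = required - set(self.table.columns)
        if missing:
            raise DataContractError(f"annotation missing columns {sorted(missing)}")
        self.table = self.table.reset_index(drop=True).copy()
        self.table["cell_id"] = self.table["cell_id"].astype(str)
        self.table["patient_id"] = self.table["patient_id"].astype(str)
        _check_unique(self.table["cell_id"].tolist(), "cell_id")
        bad = set(self.table["population"]) - set(VALID_POPULATIONS)
        if bad:
            raise DataContractError(f"populations outside enum: {sorted(bad)}")

    @property
    def cell_ids(self) -> list[str]:
        return self.table["cell_id"].tolist()

    def patients(self) -> list[str]:
        return sorted(self.table["patient_id"].unique())

    def cells_of(self, patient_id: str, population: str | None = None) -> list[str]:
        t = self.table[self.table["patient_id"] == patient_id]
        if population is not None:
            t = t[t["population"] == population]
        return t["cell_id"].tolist()

    def check_covers(self, matrix: ExpressionMatrix) -> None:
        missing = set(matrix.unit_ids) - set(self.cell_ids)
        if missing:
            raise DataContractError(
                f"{len(missing)} matrix units lack annotation, e.g. "
                f"{sorted(missing)[:3]}"
            )


@dataclass(frozen=True)
class GeneSignature:
    """A named, ordered gene list (one GMT record)."""

    name: str
    genes: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.genes) < 2:
            raise DataContractError(
                f"signature {self.name!r} needs >= 2 genes, got {len(self.genes)}"
            )
        if len(set(self.genes)) != len(self.genes):
            raise DataContractError(f"signature {self.name!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ClinicalTable:
    """Per-sample survival records: time > 0, status in {0 censored, 1 event},
    plus arbitrary numeric/binary covariate columns. ``time_unit`` is
    declared by the caller (days or months), never inferred."""

    table: pd.DataFrame  # columns: sample_id, time, status, covariates...
    time_unit: str = "days"

    def __post_init__(self) -> None:
        required = {"sample_id", "time", "status"}
        missing = required - set(self.table.columns)
        if missing:
            raise DataContractError(f"clinical table missing columns {sorted(missing)}")
        self.table = self.table.reset_index(drop=True).copy()
        self.table["sample_id"] = self.table["sample_id"].astype(str)
        _check_unique(self.table["sample_id"].tolist(), "sample_id")
        t = self.table["time"].to_numpy(dtype=float)
        if not np.all(np.isfinite(t)) or (t <= 0).any():
            raise DataContractError("survival times must be finite and > 0")
        s = set(self.table["status"].astype(int))
        if not s <= {0, 1}:
            raise DataContractError(f"status values outside {{0,1}}: {sorted(s)}")
        self.table["status"] = self.table["status"].astype(int)

    @property
    def covariate_names(self) -> list[str]:
        return [
            c for c in self.table.columns if c not in ("sample_id", "time", "status")
        ]

    def subset(self, sample_ids: Sequence[str]) -> "ClinicalTable":
        t = self.table[self.table["sample_id"].isin(set(map(str, sample_ids)))]
        return ClinicalTable(t.copy(), self.time_unit)


# Score tables are plain DataFrames with a fixed column contract; a light
# validator keeps them honest without inventing another wrapper class.
SCORE_COLUMNS = ("unit_id", "signature_name", "score")


def validate_score_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the ScoreTable contract: one row per (unit, signature),
    finite scores, mandatory columns present."""
    missing = set(SCORE_COLUMNS) - set(table.columns)
    if missing:
        raise DataContractError(f"score table missing columns {sorted(missing)}")
    if table.duplicated(subset=["unit_id", "signature_name"]).any():
        raise DataContractError("duplicate (unit_id, signature_name) rows")
    if not np.all(np.isfinite(table["score"].to_numpy(dtype=float))):
        raise DataContractError("non-finite scores")
    return table
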
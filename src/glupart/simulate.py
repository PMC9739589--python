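"""Synthetic cohorts with the structure the partitioning analysis assumes.

simulate_cohort draws per-cell gene counts from a negative binomial whose
log-mean carries a population x signature-membership shift: in a patient
with dominance effect delta > 0 the glutamine-signature genes are
elevated (by exp(delta)) in tumor cells relative to that patient's CD8T
cells, and in nondominant patients the cytotoxicity genes are elevated in
CD8T cells. A truth table records each patient's intended group, so
classification accuracy is measurable. Randomness flows from one master
seed through per-patient substreams, so adding patients never reshuffles
earlier ones.

simulate_survival draws exponential event times whose hazard is
baseline * exp(log_hr_per_score_sd * standardized score), with
independent uniform censoring calibrated to an approximate target rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    CellAnnotation,
    ClinicalTable,
    DataContractError,
    ExpressionMatrix,
    GeneSignature,
)
from .io import bundled_signatures, canonical_gene


def _default_glutamine() -> GeneSignature:
    return bundled_signatures()["GLUTAMINE_METABOLISM"]


def _default_cytotox() -> GeneSignature:
    return bundled_signatures()["CYTOTOXICITY"]


@dataclass
class CohortSpec:
    """Conditions of a simulated single-cell cohort.

    dominance_effect
        Log-scale mean shift of signature genes in tumor vs CD8T cells for
        intended-dominant patients; a scalar applies to the first
        ``n_dominant`` patients (the rest get 0), or pass a per-patient
        array. delta > 0 marks a patient intended-dominant.
    cytotox_effect
        Log-scale elevation of the cytotoxicity genes in CD8T cells of
        intended-NONdominant patients (the dominant group's CD8T cells
        are the ones with weakened cytotoxicity).
    nb_dispersion
        Negative-binomial size (shape) parameter; var = mu + mu^2/size.
    """

    n_patients: int = 10
    cells_per_population: int = 100
    n_genes: int = 500
    signature_genes: GeneSignature = field(default_factory=_default_glutamine)
    cytotox_genes: GeneSignature = field(default_factory=_default_cytotox)
    dominance_effect: float | np.ndarray = 1.5
    n_dominant: int | None = None
    cytotox_effect: float = 1.0
    nb_dispersion: float = 2.0
    library_size_mean: float = 5000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.cells_per_population < 1 or self.n_genes < 1:
            raise DataContractError("cohort sizes must be positive")
        if self.nb_dispersion <= 0 or self.library_size_mean <= 0:
            raise DataContractError("dispersion and library size must be > 0")

    def per_patient_delta(self) -> np.ndarray:
        if isinstance(self.dominance_effect, np.ndarray) or isinstance(
            self.dominance_effect, (list, tuple)
        ):
            delta = np.asarray(self.dominance_effect, dtype=float)
            if delta.size != self.n_patients:
                raise DataContractError(
                    "per-patient dominance_effect length must equal n_patients"
                )
            return delta
        n_dom = self.n_patients if self.n_dominant is None else self.n_dominant
        delta = np.zeros(self.n_patients)
        delta[:n_dom] = float(self.dominance_effect)
        return delta


@dataclass
class SurvivalSpec:
    n_samples: int = 363
    baseline_hazard: float = 1.0 / 1000.0
    log_hr_per_score_sd: float = np.log(2.0)
    censor_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.baseline_hazard <= 0:
            raise DataContractError("n_samples and baseline_hazard must be positive")
        if not 0.0 <= self.censor_rate < 1.0:
            raise DataContractError("censor_rate must lie in [0, 1)")


def _gene_universe(spec: CohortSpec) -> list[str]:
    named = list(
        dict.fromkeys(
            [canonical_gene(g) for g in spec.signature_genes.genes]
            + [canonical_gene(g) for g in spec.cytotox_genes.genes]
        )
    )
    if len(named) > spec.n_genes:
        raise DataContractError(
            f"n_genes={spec.n_genes} too small for {len(named)} signature genes"
        )
    fillers = [f"FILLER{i:05d}" for i in range(spec.n_genes - len(named))]
    return named + fillers


def simulate_cohort(
    spec: CohortSpec,
) -> tuple[ExpressionMatrix, CellAnnotation, pd.DataFrame]:
    """Simulate counts, annotation and a per-patient truth table.

    Returns (counts matrix, annotation, truth) where truth has columns
    patient_id, delta, intended_group.
    """
    genes = _gene_universe(spec)
    n_genes = len(genes)
    sig_mask = np.isin(genes, [canonical_gene(g) for g in spec.signature_genes.genes])
    cyt_mask = np.isin(genes, [canonical_gene(g) for g in spec.cytotox_genes.genes])
    delta = spec.per_patient_delta()

    master = np.random.SeedSequence(spec.seed)
    # Gene baseline abundances shared by the whole cohort (own substream).
    base_rng = np.random.default_rng(master.spawn(1)[0])
    rel_abund = np.exp(base_rng.normal(0.0, 1.0, size=n_genes))
    rel_abund /= rel_abund.sum()

    n_cells_pp = 2 * spec.cells_per_population
    blocks, cell_rows = [], []
    for p in range(spec.n_patients):
        # Independent substream per patient keyed by index, so earlier
        # patients are unchanged when n_patients grows.
        rng = np.random.default_rng(
            np.random.SeedSequence(spec.seed, spawn_key=(1, p))
        )
        lib = rng.lognormal(
            mean=np.log(spec.library_size_mean), sigma=0.25, size=n_cells_pp
        )
        # columns: first tumor cells, then CD8T cells
        log_shift = np.zeros((n_genes, n_cells_pp))
        log_shift[np.ix_(sig_mask, np.arange(spec.cells_per_population))] = delta[p]
        if delta[p] <= 0:  # intended nondominant: cytotoxic CD8T compartment
            log_shift[
                np.ix_(cyt_mask, np.arange(spec.cells_per_population, n_cells_pp))
            ] = spec.cytotox_effect
        mu = rel_abund[:, None] * np.exp(log_shift) * lib[None, :]
        # NB via gamma-Poisson mixture: shape=size, scale=mu/size.
        lam = rng.gamma(shape=spec.nb_dispersion, scale=mu / spec.nb_dispersion)
        blocks.append(rng.poisson(lam).astype(float))
        pid = f"P{p + 1:02d}"
        for c in range(n_cells_pp):
            pop = "tumor" if c < spec.cells_per_population else "CD8T"
            cell_rows.append((f"{pid}_{pop}_{c % spec.cells_per_population:04d}",
                              pid, pop))

    values = np.concatenate(blocks, axis=1)
    annot = CellAnnotation(
        pd.DataFrame(cell_rows, columns=["cell_id", "patient_id", "population"])
    )
    matrix = ExpressionMatrix(values, genes, annot.cell_ids, layer="counts")
    truth = pd.DataFrame(
        {
            "patient_id": [f"P{p + 1:02d}" for p in range(spec.n_patients)],
            "delta": delta,
            "intended_group": np.where(delta > 0, "dominant", "nondominant"),
        }
    )
    return matrix, annot, truth


def simulate_survival(spec: SurvivalSpec, scores: np.ndarray | pd.Series
                      ) -> ClinicalTable:
    """Exponential survival with score-proportional hazard and uniform
    censoring calibrated to ~``censor_rate``."""
    scores = pd.Series(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise DataContractError("scores must be finite")
    if scores.size != spec.n_samples:
        raise DataContractError(
            f"need {spec.n_samples} scores, got {scores.size}"
        )
    sd = scores.std(ddof=0)
    z = (scores - scores.mean()) / (sd if sd > 0 else 1.0)
    hazard = spec.baseline_hazard * np.exp(spec.log_hr_per_score_sd * z.to_numpy())

    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(2,)))
    t_event = rng.exponential(1.0 / hazard)
    if spec.censor_rate == 0.0:
        time, status = t_event, np.ones(spec.n_samples, dtype=int)
    else:
        tau = _censor_horizon(t_event, spec.censor_rate)
        c = rng.uniform(0.0, tau, size=spec.n_samples)
        status = (t_event <= c).astype(int)
        time = np.minimum(t_event, c)
    ids = (
        scores.index.astype(str)
        if not isinstance(scores.index, pd.RangeIndex)
        else [f"S{i + 1:04d}" for i in range(spec.n_samples)]
    )
    return ClinicalTable(
        pd.DataFrame({"sample_id": ids, "time": time, "status": status,
                      "score": scores.to_numpy()})
    )


def _censor_horizon(t_event: np.ndarray, rate: float) -> float:
    """Uniform-censoring horizon tau with E[fraction censored] ~= rate:
    P(C < T) = E[min(T, tau)] / tau for C ~ U(0, tau), which falls from 1
    to 0 as tau grows; bisect on tau."""
    lo, hi = 1e-9, float(t_event.max()) * 1e3

    def censored_frac(tau: float) -> float:
        return float(np.minimum(t_event, tau).mean()) / tau

    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if censored_frac(mid) > rate:
            lo = mid
        else:
            hi = mid
    return np.sqrt(lo * hi)
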
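"""Simulation studies over the pipeline: classification calibration and
power, Cox hazard-ratio recovery, and the marker-screen permutation null.

These are the package's operating-characteristic checks: each one runs
the real pipeline (simulate -> normalize -> score -> classify / fit) on
synthetic cohorts and summarizes how often the statistics do what they
should. Patients are simulated in batches so large calibration runs stay
within ordinary memory.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .containers import CellAnnotation
from .io import bundled_signatures
from .markers import find_markers
from .partitioning import classify_cohort
from .qc import log_normalize
from .scoring import SsgseaParams, score_populations
from .simulate import CohortSpec, SurvivalSpec, simulate_cohort, simulate_survival
from .survival import cox_screen


def _derived_seed(seed: int, *key: int) -> int:
    """A stable sub-seed below 2**31 derived from (seed, key)."""
    return int(
        np.random.SeedSequence(seed, spawn_key=tuple(key)).generate_state(1)[0]
        % (2**31)
    )


def classify_cohort_spec(
    spec: CohortSpec,
    params: SsgseaParams | None = None,
    alpha_gate: float = 0.05,
) -> pd.DataFrame:
    """simulate -> log-normalize -> score -> classify for one cohort spec;
    returns dominance results merged with the simulation truth."""
    matrix, annot, truth = simulate_cohort(spec)
    lognorm = log_normalize(matrix)
    glut = spec.signature_genes
    scores, _ = score_populations(lognorm, annot, [glut], params)
    results, _ = classify_cohort(scores, alpha_gate=alpha_gate)
    return results.merge(truth, on="patient_id")


def dominance_classification_run(
    delta: float,
    n_patients: int,
    cells_per_population: int = 100,
    n_genes: int = 500,
    seed: int = 0,
    batch_size: int = 50,
    alpha_gate: float = 0.05,
) -> pd.DataFrame:
    """Classify ``n_patients`` simulated patients, all with dominance
    effect ``delta``, batching the simulation; returns per-patient results
    with the truth columns attached.

    The cytotoxicity shift is zeroed here: these runs measure the
    classifier's response to the glutamine effect alone, and because
    ssGSEA is rank-based, a population shift in any other genes would
    displace signature-gene ranks and contaminate the calibration."""
    out = []
    for b, start in enumerate(range(0, n_patients, batch_size)):
        n_b = min(batch_size, n_patients - start)
        spec = CohortSpec(
            n_patients=n_b,
            cells_per_population=cells_per_population,
            n_genes=n_genes,
            dominance_effect=delta,
            cytotox_effect=0.0,
            seed=_derived_seed(seed, 10, b),
        )
        res = classify_cohort_spec(spec, alpha_gate=alpha_gate)
        res["batch"] = b
        out.append(res)
    return pd.concat(out, ignore_index=True)


def null_dominant_rate(
    n_patients: int = 2000, seed: int = 0, **kwargs
) -> tuple[float, int]:
    """Fraction of zero-effect patients labelled dominant. Expected near
    0.025: one tail of the two-sided 0.05 Wilcoxon gate intersected with
    the dominance_score > 0 requirement."""
    res = dominance_classification_run(0.0, n_patients, seed=seed, **kwargs)
    return float((res["group"] == "dominant").mean()), len(res)


def power_dominant_rate(
    delta: float = 1.5,
    n_patients: int = 200,
    cells_per_population: int = 100,
    seed: int = 0,
    **kwargs,
) -> tuple[float, int]:
    """Fraction of intended-dominant patients recovered as dominant."""
    res = dominance_classification_run(
        delta, n_patients, cells_per_population=cells_per_population,
        seed=seed, **kwargs
    )
    dom = res[res["intended_group"] == "dominant"]
    return float((dom["group"] == "dominant").mean()), len(dom)


def cox_recovery_rate(
    log_hr: float = float(np.log(2.0)),
    n_samples: int = 500,
    n_replicates: int = 50,
    censor_rate: float = 0.3,
    hr_window: tuple[float, float] = (1.6, 2.5),
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Fraction of replicates whose univariate Cox hazard ratio per score
    SD falls inside ``hr_window``; also returns all estimates."""
    hrs = []
    for r in range(n_replicates):
        rep_seed = _derived_seed(seed, 20, r)
        rng = np.random.default_rng(rep_seed)
        scores = pd.Series(rng.normal(size=n_samples))
        spec = SurvivalSpec(
            n_samples=n_samples,
            log_hr_per_score_sd=log_hr,
            censor_rate=censor_rate,
            seed=rep_seed,
        )
        clinical = simulate_survival(spec, scores)
        fit = cox_screen(clinical, ["score"])
        uni = fit[(fit["model"] == "univariate") & (fit["covariate"] == "score")]
        hrs.append(float(uni["hazard_ratio"].iloc[0]))
    hrs = np.array(hrs)
    ok = (hrs >= hr_window[0]) & (hrs <= hr_window[1])
    return float(ok.mean()), hrs


def marker_null_fraction(
    n_genes: int = 200,
    n_cells: int = 100,
    n_permutations: int = 100,
    seed: int = 0,
) -> tuple[float, int]:
    """Mean fraction of genes called at p < 0.05 (ignoring the fold-change
    gate) when group labels are random — the marker screen's type-I rate."""
    spec = CohortSpec(
        n_patients=1,
        cells_per_population=n_cells // 2,
        n_genes=n_genes,
        dominance_effect=0.0,
        seed=_derived_seed(seed, 30),
    )
    matrix, annot, _ = simulate_cohort(spec)
    lognorm = log_normalize(matrix)
    rng = np.random.default_rng(_derived_seed(seed, 31))
    fractions = []
    n_units = lognorm.n_units
    for _ in range(n_permutations):
        perm = rng.permutation(n_units)
        labels = pd.Series(
            np.where(np.arange(n_units)[np.argsort(perm)] < n_units // 2, "a", "b"),
            index=lognorm.unit_ids,
        )
        mk = find_markers(lognorm, labels, group_a="a")
        fractions.append(float((mk["p_value"] < 0.05).mean()))
    return float(np.mean(fractions)), n_genes * n_permutations
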
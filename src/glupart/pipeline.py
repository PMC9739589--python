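"""One-shot pipeline: simulate/load -> QC -> normalize -> score ->
partition -> markers -> (optional) survival, with a hashed artifact
manifest and JSON-lines logging.

The pipeline is pure dataflow: each stage reads the previous stage's
in-memory outputs and writes its own files; nothing mutates an earlier
stage's artifacts (the manifest hash of every file is taken once, when
the file is written, and re-hashed at the end as a consistency check).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import DataContractError
from .io import (
    bundled_signatures,
    read_cell_metadata,
    read_matrix,
    write_matrix_mtx,
    write_scores,
)
from .markers import find_markers
from .partitioning import classify_cohort, compare_groups, composition_ratio
from .qc import DegenerateResultError, QCThresholds, log_normalize, qc_filter
from .scoring import SsgseaParams, cytotoxic_score, score_populations
from .simulate import CohortSpec, SurvivalSpec, simulate_cohort, simulate_survival
from .survival import cox_screen, km_at, km_estimate, logrank_test, median_split

log = logging.getLogger("glupart")


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


_KNOWN_SECTIONS = {
    "seed", "out_dir", "simulate", "inputs", "qc", "scoring", "partition",
    "markers", "survival",
}


@dataclass
class RunConfig:
    seed: int
    out_dir: Path
    simulate: dict[str, Any] | None = None
    inputs: dict[str, Any] | None = None
    qc: dict[str, Any] = field(default_factory=dict)
    scoring: dict[str, Any] = field(default_factory=dict)
    partition: dict[str, Any] = field(default_factory=dict)
    markers: dict[str, Any] = field(default_factory=dict)
    survival: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_mapping(cls, raw: dict[str, Any]) -> "RunConfig":
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping")
        unknown = set(raw) - _KNOWN_SECTIONS
        if unknown:
            raise ConfigError(f"unknown config sections: {sorted(unknown)}")
        if "seed" not in raw or "out_dir" not in raw:
            raise ConfigError("config requires 'seed' and 'out_dir'")
        if not isinstance(raw["seed"], int):
            raise ConfigError("seed must be an integer")
        has_sim = bool(raw.get("simulate"))
        has_inputs = bool(raw.get("inputs"))
        if has_sim == has_inputs:
            raise ConfigError("exactly one of 'simulate' or 'inputs' is required")
        if has_inputs:
            inputs = raw["inputs"]
            for key in ("matrix", "metadata"):
                if key not in inputs:
                    raise ConfigError(f"inputs section requires '{key}'")
                if not Path(inputs[key]).exists():
                    raise ConfigError(f"input path does not exist: {inputs[key]}")
        return cls(
            seed=raw["seed"],
            out_dir=Path(raw["out_dir"]),
            simulate=raw.get("simulate"),
            inputs=raw.get("inputs"),
            qc=raw.get("qc") or {},
            scoring=raw.get("scoring") or {},
            partition=raw.get("partition") or {},
            markers=raw.get("markers") or {},
            survival=raw.get("survival") or {},
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text())
        except FileNotFoundError as err:
            raise ConfigError(str(err)) from err
        except yaml.YAMLError as err:
            raise ConfigError(f"malformed YAML: {err}") from err
        return cls.from_mapping(raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _RunLog:
    def __init__(self, path: Path):
        self.path = path
        self.path.write_text("")

    def event(self, stage: str, **payload: Any) -> None:
        rec = {"ts": time.time(), "stage": stage, **payload}
        with self.path.open("a") as fh:
            fh.write(json.dumps(rec, default=str) + "\n")
        log.info("%s: %s", stage, payload)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run all stages; returns the artifact manifest (also written to
    manifest.json). Raises ConfigError / DataContractError /
    DegenerateResultError for the CLI to map to exit codes."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    runlog = _RunLog(out / "log.jsonl")
    artifacts: dict[str, str] = {}

    def register(path: Path) -> None:
        artifacts[str(path.relative_to(out))] = _sha256(path)

    runlog.event("start", version=__version__, seed=config.seed)
    sigs = bundled_signatures()
    glut = sigs["GLUTAMINE_METABOLISM"]

    # ---- acquire data -------------------------------------------------
    if config.simulate is not None:
        spec = CohortSpec(seed=config.seed, **config.simulate)
        matrix, annot, truth = simulate_cohort(spec)
        truth_path = out / "truth.tsv"
        truth.to_csv(truth_path, sep="\t", index=False)
        register(truth_path)
        for p in write_matrix_mtx(matrix, out / "sim").values():
            register(p)
        meta_path = out / "sim" / "metadata.tsv"
        annot.table.to_csv(meta_path, sep="\t", index=False)
        register(meta_path)
        runlog.event("simulate", n_patients=spec.n_patients,
                     n_cells=matrix.n_units, n_genes=matrix.n_genes)
    else:
        inputs = config.inputs or {}
        matrix = read_matrix(
            inputs["matrix"],
            format=inputs.get("format", "mtx-triplet"),
            genes_path=inputs.get("genes"),
            barcodes_path=inputs.get("barcodes"),
        )
        annot = read_cell_metadata(inputs["metadata"])
        runlog.event("load", n_cells=matrix.n_units, n_genes=matrix.n_genes)

    # ---- qc + normalize ----------------------------------------------
    qc_kwargs = dict(config.qc)
    if config.simulate is not None:
        # Simulated cohorts carry no ribosomal genes; the low-ribosome
        # exclusion would remove every cell, so it is off unless asked for.
        qc_kwargs.setdefault("min_ribo_frac", 0.0)
    thresholds = QCThresholds(**qc_kwargs)
    filtered, report = qc_filter(matrix, thresholds)
    register(report.to_json(out / "qc_report.json"))
    register(report.to_tsv(out / "qc_report.tsv"))
    annot_kept = annot.table[annot.table["cell_id"].isin(filtered.unit_ids)]
    from .containers import CellAnnotation

    annot = CellAnnotation(annot_kept.copy())
    lognorm = log_normalize(filtered)
    runlog.event("qc", cells=filtered.n_units, genes=filtered.n_genes)

    # ---- scoring ------------------------------------------------------
    params = SsgseaParams(
        weight_exponent=config.scoring.get("weight_exponent", 0.25),
        normalize_across_units=config.scoring.get("normalize_across_units", True),
        min_set_genes_present=config.scoring.get("min_set_genes_present", 2),
    )
    frame = config.scoring.get("frame", "within-patient")
    glut_scores, score_report = score_populations(
        lognorm, annot, [glut], params, frame=frame
    )
    register(write_scores(out / "scores.tsv", glut_scores))
    cyt_scores = cytotoxic_score(lognorm, annot, params, frame=frame)
    register(write_scores(out / "cytotox_scores.tsv", cyt_scores))
    runlog.event("score", n_rows=len(glut_scores), problems=score_report)

    # ---- partition ----------------------------------------------------
    alpha_gate = config.partition.get("alpha_gate", 0.05)
    results, part_report = classify_cohort(glut_scores, alpha_gate=alpha_gate)
    dom_path = out / "dominance.tsv"
    results.to_csv(dom_path, sep="\t", index=False, float_format="%.17g")
    register(dom_path)
    runlog.event(
        "partition",
        n_dominant=int((results["group"] == "dominant").sum()),
        n_nondominant=int((results["group"] == "nondominant").sum()),
        problems=part_report,
    )

    comparisons = []
    if results["group"].nunique() == 2:
        cd8_glut = glut_scores[glut_scores["population"] == "CD8T"]
        for name, table in (("cd8_glutamine_score", cd8_glut),
                            ("cd8_cytotoxic_score", cyt_scores)):
            cmp_res = compare_groups(table, results, statistic_name=name)
            comparisons.append(vars(cmp_res))
        frac = composition_ratio(annot)
        comparisons.append(
            {
                "statistic_name": "tumor_fraction_by_group",
                "group_a": "dominant",
                "group_b": "nondominant",
                "stat": float(
                    frac[results.set_index("patient_id")["group"] == "dominant"].mean()
                ),
                "p_value": float("nan"),
                "effect_direction": "summary",
                "n_a": int((results["group"] == "dominant").sum()),
                "n_b": int((results["group"] == "nondominant").sum()),
            }
        )
    cmp_path = out / "comparisons.tsv"
    pd.DataFrame(comparisons).to_csv(cmp_path, sep="\t", index=False)
    register(cmp_path)

    # ---- markers ------------------------------------------------------
    if results["group"].nunique() == 2:
        group_of = results.set_index("patient_id")["group"]
        cd8_cells = annot.table[annot.table["population"] == "CD8T"]
        labels = cd8_cells["patient_id"].map(group_of)
        labels.index = cd8_cells["cell_id"]
        cd8_matrix = lognorm.subset_units(cd8_cells["cell_id"].tolist())
        mk = find_markers(
            cd8_matrix,
            labels,
            group_a="dominant",
            p_gate=config.markers.get("p_gate", 0.05),
            logfc_gate=config.markers.get("logfc_gate", 0.25),
        )
        mk_path = out / "markers.tsv"
        mk.to_csv(mk_path, sep="\t", index=False, float_format="%.17g")
        register(mk_path)
        runlog.event("markers", n_significant=int(mk["significant"].sum()))

    # ---- survival (optional bulk arm) ----------------------------------
    if config.survival.get("enabled", False):
        surv_kw = {
            k: v for k, v in config.survival.items() if k not in ("enabled",)
        }
        sspec = SurvivalSpec(seed=config.seed, **surv_kw)
        rng = np.random.default_rng(np.random.SeedSequence(config.seed,
                                                           spawn_key=(3,)))
        bulk_scores = pd.Series(
            rng.normal(size=sspec.n_samples),
            index=[f"S{i + 1:04d}" for i in range(sspec.n_samples)],
        )
        clinical = simulate_survival(sspec, bulk_scores)
        clin_path = out / "clinical.tsv"
        clinical.table.to_csv(clin_path, sep="\t", index=False,
                              float_format="%.17g")
        register(clin_path)

        labels = median_split(bulk_scores)
        labels.index = clinical.table["sample_id"]
        chi2, p = logrank_test(clinical, labels)
        km_rows = []
        for grp in ("high", "low"):
            ids = labels[labels == grp].index
            curve = km_estimate(clinical.subset(ids))
            for t, s, r in zip(curve.event_times, curve.survival_probs,
                               curve.at_risk):
                km_rows.append({"group": grp, "time": t, "survival": s,
                                "at_risk": r})
        km_path = out / "km.tsv"
        pd.DataFrame(km_rows).to_csv(km_path, sep="\t", index=False,
                                     float_format="%.17g")
        register(km_path)
        cox = cox_screen(clinical, ["score"])
        cox_path = out / "cox.tsv"
        cox.to_csv(cox_path, sep="\t", index=False, float_format="%.17g")
        register(cox_path)
        runlog.event("survival", logrank_chi2=chi2, logrank_p=p)

    # ---- manifest ------------------------------------------------------
    for rel, digest in artifacts.items():
        if _sha256(out / rel) != digest:
            raise RuntimeError(f"artifact {rel} changed after it was written")
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    runlog.event("done", n_artifacts=len(artifacts))
    return manifest
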
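"""Per-patient dominance score and Wilcoxon-gated classification.

A patient's dominance score is the difference of median per-cell
glutamine-signature scores, median(tumor cells) - median(CD8T cells).
The patient is called "dominant" (tumor out-scores its CD8T compartment)
only when the dominance score is positive AND a two-sided Wilcoxon
rank-sum test between the two per-cell score vectors gives p < 0.05;
everything else — including the boundary p == 0.05 — is "nondominant".

The Wilcoxon test here is exact (full enumeration of the rank-sum null)
for tie-free samples with at most 10 observations per group, and a
tie-corrected normal approximation with continuity correction otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import rankdata

from .containers import DataContractError

DOMINANCE_COLUMNS = [
    "patient_id", "gs_tumor_median", "gs_immune_median", "dominance_score",
    "wilcoxon_p", "group", "n_tumor", "n_cd8t",
]


@dataclass
class GroupComparison:
    statistic_name: str
    group_a: str
    group_b: str
    stat: float
    p_value: float
    effect_direction: str  # "a_greater", "b_greater" or "none"
    n_a: int
    n_b: int


@lru_cache(maxsize=None)
def _ranksum_counts(n: int, k: int) -> np.ndarray:
    """counts[s] = number of k-subsets of ranks {1..n} with rank sum s.
    Dynamic program over items; total sums bounded by n(n+1)/2."""
    max_sum = n * (n + 1) // 2
    table = np.zeros((k + 1, max_sum + 1), dtype=np.int64)
    table[0, 0] = 1
    for item in range(1, n + 1):
        for kk in range(min(item, k), 0, -1):
            table[kk, item:] += table[kk - 1, :-item]
    return table[k]


def wilcoxon_rank_sum(
    x: np.ndarray,
    y: np.ndarray,
    alternative: str = "two-sided",
    method: str = "auto",
) -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum test; returns (rank sum of x, p).

    method "auto" uses the exact null distribution (full enumeration)
    when both samples have <= 10 observations and there are no ties, and
    the normal approximation with tie correction and a 0.5 continuity
    correction otherwise; "approx" forces the latter. Degenerate nulls
    (all pooled values identical) return p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DataContractError("wilcoxon_rank_sum requires non-empty samples")
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    nx, ny = x.size, y.size
    n = nx + ny
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w = float(ranks[:nx].sum())
    has_ties = np.unique(pooled).size < n

    if method == "auto" and nx <= 10 and ny <= 10 and not has_ties:
        counts = _ranksum_counts(n, nx)
        total = counts.sum()
        sums = np.arange(counts.size)
        wi = int(round(w))
        if alternative == "less":
            p = counts[sums <= wi].sum() / total
        elif alternative == "greater":
            p = counts[sums >= wi].sum() / total
        else:
            mu = nx * (n + 1) / 2.0
            p = counts[np.abs(sums - mu) >= abs(wi - mu) - 1e-9].sum() / total
        return w, float(min(p, 1.0))

    mu = nx * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1.0))
    var = nx * ny / 12.0 * (n + 1.0 - tie_term)
    if var <= 0:
        return w, 1.0
    sd = np.sqrt(var)
    if alternative == "two-sided":
        z = max(abs(w - mu) - 0.5, 0.0) / sd
        p = 2.0 * sps.norm.sf(z)
    elif alternative == "greater":
        z = (w - mu - 0.5) / sd
        p = sps.norm.sf(z)
    else:
        z = (w - mu + 0.5) / sd
        p = sps.norm.cdf(z)
    return w, float(min(p, 1.0))


def dominance(
    scores: pd.DataFrame,
    patient_id: str,
    alpha_gate: float = 0.05,
    signature_name: str | None = None,
) -> dict:
    """DominanceResult row for one patient from a per-cell ScoreTable
    (columns unit_id, patient_id, population, score)."""
    t = scores[scores["patient_id"] == patient_id]
    if signature_name is not None:
        t = t[t["signature_name"] == signature_name]
    tumor = t.loc[t["population"] == "tumor", "score"].to_numpy(dtype=float)
    cd8 = t.loc[t["population"] == "CD8T", "score"].to_numpy(dtype=float)
    if tumor.size == 0 or cd8.size == 0:
        raise DataContractError(
            f"patient {patient_id}: needs >= 1 scored tumor and CD8T cell "
            f"(got {tumor.size} tumor, {cd8.size} CD8T)"
        )
    gs_tumor = float(np.median(tumor))
    gs_immune = float(np.median(cd8))
    d = gs_tumor - gs_immune
    _, p = wilcoxon_rank_sum(tumor, cd8, alternative="two-sided")
    group = "dominant" if (d > 0 and p < alpha_gate) else "nondominant"
    return {
        "patient_id": patient_id,
        "gs_tumor_median": gs_tumor,
        "gs_immune_median": gs_immune,
        "dominance_score": d,
        "wilcoxon_p": p,
        "group": group,
        "n_tumor": int(tumor.size),
        "n_cd8t": int(cd8.size),
    }


def classify_cohort(
    scores: pd.DataFrame,
    alpha_gate: float = 0.05,
    signature_name: str | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Dominance classification for every patient in a ScoreTable.

    Patients lacking one population yield a report entry, not a silent
    drop. Returns (results DataFrame, report)."""
    results, report = [], []
    for patient in sorted(scores["patient_id"].astype(str).unique()):
        try:
            results.append(dominance(scores, patient, alpha_gate, signature_name))
        except DataContractError as err:
            report.append({"patient_id": patient, "problem": str(err)})
    return pd.DataFrame(results, columns=DOMINANCE_COLUMNS), report


def compare_groups(
    values: pd.DataFrame,
    results: pd.DataFrame,
    statistic_name: str,
    group_a: str = "dominant",
    group_b: str = "nondominant",
    value_col: str = "score",
    patient_level: bool = False,
) -> GroupComparison:
    """Wilcoxon comparison of per-cell values between two patient groups.

    ``values`` carries one row per cell (patient_id + value column, e.g.
    CD8T glutamine or cytotoxicity scores); ``results`` assigns each
    patient to a group. Cells are pooled across patients within each
    group by default; ``patient_level=True`` compares per-patient medians
    instead.
    """
    groups = results.set_index("patient_id")["group"]
    member = values["patient_id"].astype(str).map(groups)
    a = values.loc[member == group_a, value_col].to_numpy(dtype=float)
    b = values.loc[member == group_b, value_col].to_numpy(dtype=float)
    if a.size == 0:
        raise DataContractError(f"group {group_a!r} has no cells")
    if b.size == 0:
        raise DataContractError(f"group {group_b!r} has no cells")
    if patient_level:
        va = values.loc[member == group_a].groupby("patient_id")[value_col].median()
        vb = values.loc[member == group_b].groupby("patient_id")[value_col].median()
        a, b = va.to_numpy(), vb.to_numpy()
    stat, p = wilcoxon_rank_sum(a, b, alternative="two-sided")
    med_a, med_b = float(np.median(a)), float(np.median(b))
    direction = (
        "a_greater" if med_a > med_b else "b_greater" if med_b > med_a else "none"
    )
    return GroupComparison(
        statistic_name=statistic_name,
        group_a=group_a,
        group_b=group_b,
        stat=stat,
        p_value=p,
        effect_direction=direction,
        n_a=int(a.size),
        n_b=int(b.size),
    )


def composition_ratio(annotation) -> pd.Series:
    """Per-patient tumor-cell fraction n_tumor / n_total."""
    t = annotation.table
    total = t.groupby("patient_id").size()
    if (total == 0).any():
        raise DataContractError("patient with zero cells")
    tumor = (
        t[t["population"] == "tumor"].groupby("patient_id").size().reindex(
            total.index, fill_value=0
        )
    )
    return (tumor / total).rename("tumor_fraction")


def correlate(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson correlation with its t-distribution p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise DataContractError("correlation needs >= 3 paired observations")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
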
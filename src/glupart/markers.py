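"""Differential-expression screening and pre-ranked gene-set enrichment.

find_markers screens genes between two cell groups with a per-gene
Wilcoxon rank-sum test and an average log fold change computed on the
de-logged scale: avg_logFC = ln((mean(expm1(A)) + 1) / (mean(expm1(B)) + 1)),
the pseudocount convention of the common single-cell toolkits. The
"significant" view applies the raw thresholds p < 0.05 and avg_logFC >
0.25 per direction; Benjamini-Hochberg FDR is reported alongside but not
used for selection.

preranked_gsea computes the classical weighted Kolmogorov-Smirnov running
-sum enrichment score on a ranked gene list (weight = |rank statistic|,
exponent 1) with a gene-label permutation p-value (add-one smoothing, so
p >= 1/(n_permutations + 1)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .containers import DataContractError, ExpressionMatrix, GeneSignature
from .io import canonical_gene

MARKER_COLUMNS = ["gene", "avg_logFC", "p_value", "q_value", "direction",
                  "significant"]


@dataclass
class GseaResult:
    set_name: str
    enrichment_score: float
    nominal_p: float
    n_genes_matched: int
    n_permutations: int


def find_markers(
    matrix: ExpressionMatrix,
    labels: pd.Series | dict,
    group_a: str | None = None,
    p_gate: float = 0.05,
    logfc_gate: float = 0.25,
    log_base: str = "e",
    min_group_size: int = 3,
) -> pd.DataFrame:
    """Marker screen between two cell groups on a lognorm matrix.

    ``labels`` maps unit_id -> group label (exactly two labels).
    ``group_a`` picks the reference direction (default: first label in
    sorted order); direction "up_in_a" means higher in group_a.
    """
    if matrix.layer != "lognorm":
        raise DataContractError(f"find_markers needs lognorm layer, got {matrix.layer}")
    labels = pd.Series(labels)
    labels.index = labels.index.astype(str)
    missing = set(matrix.unit_ids) - set(labels.index)
    if missing:
        raise DataContractError(f"{len(missing)} units lack a group label")
    lab = labels.loc[matrix.unit_ids]
    uniq = sorted(lab.unique())
    if len(uniq) != 2:
        raise DataContractError(f"need exactly 2 groups, got {uniq}")
    if group_a is None:
        group_a = uniq[0]
    group_b = [u for u in uniq if u != group_a][0]
    a_mask = (lab == group_a).to_numpy()
    if a_mask.sum() < min_group_size or (~a_mask).sum() < min_group_size:
        raise DataContractError(
            f"both groups need >= {min_group_size} cells "
            f"(got {int(a_mask.sum())} vs {int((~a_mask).sum())})"
        )

    va = matrix.values[:, a_mask]
    vb = matrix.values[:, ~a_mask]
    # Tie-corrected normal approximation with continuity correction; exact
    # enumeration is pointless at per-gene scale and tie density.
    _, pvals = mannwhitneyu(
        va, vb, axis=1, alternative="two-sided", method="asymptotic"
    )
    pvals = np.asarray(pvals, dtype=float)

    mean_a = np.expm1(va).mean(axis=1)
    mean_b = np.expm1(vb).mean(axis=1)
    logfc = np.log((mean_a + 1.0) / (mean_b + 1.0))
    if log_base == "2":
        logfc = logfc / np.log(2.0)
    elif log_base != "e":
        raise ValueError(f"unknown log_base {log_base!r}")

    q = multipletests(pvals, method="fdr_bh")[1]
    direction = np.where(logfc > 0, "up_in_a", "up_in_b")
    significant = (pvals < p_gate) & (np.abs(logfc) > logfc_gate)
    out = pd.DataFrame(
        {
            "gene": matrix.gene_ids,
            "avg_logFC": logfc,
            "p_value": pvals,
            "q_value": q,
            "direction": direction,
            "significant": significant,
        }
    )
    out.attrs["group_a"] = group_a
    out.attrs["group_b"] = group_b
    return out


def significant_markers(markers: pd.DataFrame, direction: str | None = None
                        ) -> pd.DataFrame:
    """The screened view: rows passing both raw gates, optionally one
    direction only."""
    view = markers[markers["significant"]]
    if direction is not None:
        view = view[view["direction"] == direction]
    return view.reset_index(drop=True)


def _running_sum_es(stats_desc: np.ndarray, in_set: np.ndarray) -> float:
    """Signed ES: extreme deviation of the weighted-hit minus uniform-miss
    running sum over a descending-ordered statistic vector."""
    weights = np.where(in_set, np.abs(stats_desc), 0.0)
    total_w = weights.sum()
    if total_w == 0:  # all matched stats are exactly zero: unweighted walk
        weights = in_set.astype(float)
        total_w = weights.sum()
    n_out = in_set.size - int(in_set.sum())
    if n_out == 0:
        raise DataContractError("signature covers the whole ranked list")
    dev = np.cumsum(weights) / total_w - np.cumsum(~in_set) / n_out
    return float(dev[np.argmax(np.abs(dev))])


def preranked_gsea(
    ranked_genes: pd.DataFrame | list[tuple[str, float]],
    signature: GeneSignature,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> GseaResult:
    """Enrichment of ``signature`` in a pre-ranked gene list.

    ``ranked_genes``: (gene, rank statistic) pairs or a DataFrame with
    columns gene, stat; duplicates are an error. The list is sorted by
    decreasing statistic internally, ties broken by input order. The
    nominal p is one-sided in the direction of the observed ES, from
    ``n_permutations`` random gene-label permutations.
    """
    if seed is None:
        raise ValueError("preranked_gsea requires an explicit seed")
    if isinstance(ranked_genes, pd.DataFrame):
        genes = ranked_genes["gene"].astype(str).tolist()
        stat = ranked_genes["stat"].to_numpy(dtype=float)
    else:
        genes = [str(g) for g, _ in ranked_genes]
        stat = np.array([s for _, s in ranked_genes], dtype=float)
    canon = [canonical_gene(g) for g in genes]
    if len(set(canon)) != len(canon):
        raise DataContractError("ranked list contains duplicate genes")

    order = np.argsort(-stat, kind="stable")
    stats_desc = stat[order]
    sig_set = {canonical_gene(g) for g in signature.genes}
    in_set = np.array([canon[i] in sig_set for i in order], dtype=bool)
    m = int(in_set.sum())
    if m == 0:
        raise DataContractError(
            f"no gene of signature {signature.name!r} in the ranked list"
        )

    es = _running_sum_es(stats_desc, in_set)

    rng = np.random.default_rng(seed)
    n_genes = in_set.size
    hits = 0
    perm_mask = np.zeros(n_genes, dtype=bool)
    for _ in range(n_permutations):
        perm_mask[:] = False
        perm_mask[rng.choice(n_genes, size=m, replace=False)] = True
        es_perm = _running_sum_es(stats_desc, perm_mask)
        if (es >= 0 and es_perm >= es) or (es < 0 and es_perm <= es):
            hits += 1
    p = (hits + 1.0) / (n_permutations + 1.0)
    return GseaResult(
        set_name=signature.name,
        enrichment_score=es,
        nominal_p=p,
        n_genes_matched=m,
        n_permutations=n_permutations,
    )
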
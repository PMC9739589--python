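"""Shared fixtures and independent oracles.

The oracles here are deliberately naive (explicit loops, enumeration)
and never call the package's engines, so engine/oracle agreement is a
real cross-check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from glupart.containers import CellAnnotation, ExpressionMatrix, GeneSignature


# ---------------------------------------------------------------- oracles
def ssgsea_raw_oracle(values: np.ndarray, in_set: np.ndarray, alpha: float
                      ) -> np.ndarray:
    """Brute-force positional running-sum score, one unit at a time.

    Average ranks computed by explicit counting; walk order is descending
    expression with ties broken by gene index."""
    n_genes, n_units = values.shape
    out = np.empty(n_units)
    for j in range(n_units):
        col = values[:, j]
        ranks = np.empty(n_genes)
        for g in range(n_genes):
            less = int(np.sum(col < col[g]))
            equal = int(np.sum(col == col[g]))  # includes g itself
            ranks[g] = less + (equal + 1) / 2.0
        order = sorted(range(n_genes), key=lambda g: (-col[g], g))
        total_w = sum(ranks[g] ** alpha for g in order if in_set[g])
        n_out = n_genes - int(np.sum(in_set))
        running, cum_in, cum_out = 0.0, 0.0, 0.0
        for g in order:
            if in_set[g]:
                cum_in += ranks[g] ** alpha / total_w
            else:
                cum_out += 1.0 / n_out
            running += cum_in - cum_out
        out[j] = running
    return out


def wilcoxon_exact_oracle(x, y, alternative="two-sided") -> float:
    """Permutation-exact rank-sum p by enumerating every split of the
    pooled sample into groups of sizes |x| and |y|."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n, nx = pooled.size, x.size
    ranks = pd.Series(pooled).rank().to_numpy()
    w_obs = ranks[:nx].sum()
    mu = nx * (n + 1) / 2.0
    count = total = 0
    for idx in itertools.combinations(range(n), nx):
        w = ranks[list(idx)].sum()
        total += 1
        if alternative == "less":
            count += w <= w_obs + 1e-9
        elif alternative == "greater":
            count += w >= w_obs - 1e-9
        else:
            count += abs(w - mu) >= abs(w_obs - mu) - 1e-9
    return count / total


def km_empirical_oracle(times: np.ndarray, t: float) -> float:
    """Empirical survival fraction P(T > t) for fully observed times."""
    times = np.asarray(times, float)
    return float(np.mean(times > t))


# ---------------------------------------------------------------- fixtures
@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def glutamine_signature():
    from glupart.io import bundled_signatures

    return bundled_signatures()["GLUTAMINE_METABOLISM"]


@pytest.fixture
def toy_signature():
    return GeneSignature("TOY", ("G1", "G2", "G3"), "toy set")


def make_matrix(values, layer="score-ready", gene_prefix="G", unit_prefix="U"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values,
        [f"{gene_prefix}{i + 1}" for i in range(values.shape[0])],
        [f"{unit_prefix}{j + 1}" for j in range(values.shape[1])],
        layer=layer,
    )


def make_annotation(cell_ids, patient_ids, populations):
    return CellAnnotation(
        pd.DataFrame(
            {
                "cell_id": cell_ids,
                "patient_id": patient_ids,
                "population": populations,
            }
        )
    )


@pytest.fixture
def small_cohort():
    """A 4-patient simulated cohort, small enough for fast tests."""
    from glupart.simulate import CohortSpec, simulate_cohort

    spec = CohortSpec(
        n_patients=4, cells_per_population=40, n_genes=120, n_dominant=2, seed=7
    )
    return simulate_cohort(spec)
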
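"""Wilcoxon rank-sum, dominance classification, group comparisons."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from glupart.containers import DataContractError
from glupart.partitioning import (
    classify_cohort,
    compare_groups,
    composition_ratio,
    correlate,
    dominance,
    wilcoxon_rank_sum,
)

from conftest import make_annotation, wilcoxon_exact_oracle


# ------------------------------------------------------------- wilcoxon
def test_identical_samples_give_p_one():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    _, p = wilcoxon_rank_sum(x, x.copy())
    assert p == 1.0


def test_exact_one_sided_small_example():
    # x = {1,2}, y = {3,4}: rank sum of x is minimal among C(4,2)=6 splits.
    _, p = wilcoxon_rank_sum([1.0, 2.0], [3.0, 4.0], alternative="less")
    assert p == pytest.approx(1.0 / 6.0, abs=1e-12)


def test_large_shift_is_overwhelming(rng):
    x = rng.normal(1.0, 1.0, size=200)
    y = rng.normal(0.0, 1.0, size=200)
    _, p = wilcoxon_rank_sum(x, y)
    assert p < 1e-10
    # agrees with an independent implementation of the same approximation
    ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                           method="asymptotic").pvalue
    assert p == pytest.approx(ref, rel=1e-6)


def test_exact_matches_full_enumeration_all_small_sizes(rng):
    """Engine's exact path equals split enumeration for every tie-free
    shape with n_x + n_y <= 8."""
    for nx in range(1, 8):
        for ny in range(1, 9 - nx):
            pooled = rng.permutation(np.arange(1.0, nx + ny + 1) * 1.37)
            x, y = pooled[:nx], pooled[nx:]
            for alt in ("two-sided", "less", "greater"):
                _, p = wilcoxon_rank_sum(x, y, alternative=alt)
                assert p == pytest.approx(
                    wilcoxon_exact_oracle(x, y, alt), abs=1e-12
                ), (nx, ny, alt)


def test_exact_matches_scipy_exact(rng):
    for _ in range(20):
        x = rng.normal(size=6)
        y = rng.normal(size=7)
        _, p = wilcoxon_rank_sum(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="exact").pvalue
        assert p == pytest.approx(ref, abs=1e-12)


def test_approx_mode_forced_by_flag():
    x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
    _, p_exact = wilcoxon_rank_sum(x, y)
    _, p_approx = wilcoxon_rank_sum(x, y, method="approx")
    assert p_exact == pytest.approx(0.1, abs=1e-12)  # 2/C(6,3)=2/20
    assert p_approx != p_exact  # normal approximation differs at n=3


def test_empty_sample_is_error():
    with pytest.raises(DataContractError):
        wilcoxon_rank_sum([], [1.0])


# ------------------------------------------------------------- dominance
def _score_table(patients):
    """patients: {pid: (tumor_scores, cd8_scores)} -> ScoreTable frame."""
    rows = []
    for pid, (tum, cd8) in patients.items():
        for i, s in enumerate(tum):
            rows.append((f"{pid}_t{i}", "GS", s, pid, "tumor"))
        for i, s in enumerate(cd8):
            rows.append((f"{pid}_c{i}", "GS", s, pid, "CD8T"))
    return pd.DataFrame(
        rows, columns=["unit_id", "signature_name", "score", "patient_id",
                       "population"]
    )


def test_identical_vectors_are_nondominant():
    v = list(np.linspace(0, 1, 20))
    res = dominance(_score_table({"P1": (v, v)}), "P1")
    assert res["dominance_score"] == 0.0
    assert res["group"] == "nondominant"


def test_unit_shift_is_dominant(rng):
    cd8 = rng.uniform(0, 0.9, size=50)
    tum = cd8 + 1.0
    res = dominance(_score_table({"P1": (list(tum), list(cd8))}), "P1")
    assert res["dominance_score"] == pytest.approx(1.0, abs=1e-12)
    assert res["wilcoxon_p"] < 1e-10
    assert res["group"] == "dominant"
    assert res["n_tumor"] == res["n_cd8t"] == 50


def test_dominance_score_is_exact_median_difference(rng):
    tum = list(rng.normal(size=31))
    cd8 = list(rng.normal(size=30))
    res = dominance(_score_table({"P1": (tum, cd8)}), "P1")
    assert res["dominance_score"] == float(np.median(tum)) - float(np.median(cd8))


def test_negative_score_never_dominant(rng):
    cd8 = rng.uniform(1.0, 2.0, size=40)
    tum = cd8 - 1.0  # hugely significant but in the wrong direction
    res = dominance(_score_table({"P1": (list(tum), list(cd8))}), "P1")
    assert res["wilcoxon_p"] < 1e-8 and res["group"] == "nondominant"


def test_boundary_p_equal_gate_is_nondominant(monkeypatch, rng):
    import glupart.partitioning as part

    monkeypatch.setattr(part, "wilcoxon_rank_sum", lambda *a, **k: (0.0, 0.05))
    tum = list(rng.uniform(1, 2, size=10))
    cd8 = list(rng.uniform(0, 1, size=10))
    res = part.dominance(_score_table({"P1": (tum, cd8)}), "P1")
    assert res["dominance_score"] > 0 and res["group"] == "nondominant"


def test_label_swap_negates_score_and_keeps_p(rng):
    tum = list(rng.normal(0.5, 1.0, size=35))
    cd8 = list(rng.normal(0.0, 1.0, size=45))
    fwd = dominance(_score_table({"P1": (tum, cd8)}), "P1")
    rev = dominance(_score_table({"P1": (cd8, tum)}), "P1")
    assert rev["dominance_score"] == -fwd["dominance_score"]
    assert rev["wilcoxon_p"] == fwd["wilcoxon_p"]


def test_missing_population_gives_report_entry(rng):
    table = _score_table({"P1": (list(rng.normal(size=5)), list(rng.normal(size=5)))})
    table = pd.concat(
        [table, _score_table({"P2": (list(rng.normal(size=5)), [])})],
        ignore_index=True,
    )
    results, report = classify_cohort(table)
    assert results["patient_id"].tolist() == ["P1"]
    assert report[0]["patient_id"] == "P2"


# --------------------------------------------------------- group compare
def _results_frame(groups):
    return pd.DataFrame(
        {"patient_id": list(groups), "group": list(groups.values())}
    )


def test_compare_groups_detects_planted_shift(rng):
    values = []
    groups = {}
    for i in range(6):
        pid = f"P{i}"
        groups[pid] = "dominant" if i < 3 else "nondominant"
        shift = -1.0 if i < 3 else 0.0  # dominant-group CD8T shifted down 1 sigma
        for j, v in enumerate(rng.normal(shift, 1.0, size=60)):
            values.append((f"{pid}_c{j}", "GS", v, pid, "CD8T"))
    table = pd.DataFrame(
        values, columns=["unit_id", "signature_name", "score", "patient_id",
                         "population"]
    )
    cmp_res = compare_groups(table, _results_frame(groups), "cd8_glutamine")
    assert cmp_res.p_value < 1e-6
    assert cmp_res.effect_direction == "b_greater"  # nondominant higher
    assert cmp_res.n_a == cmp_res.n_b == 180


def test_compare_groups_type_one_error_calibrated(rng):
    """Both groups from one distribution: rejection rate at the 0.05 gate
    stays near nominal over 200 replicates."""
    rejections = 0
    n_reps = 200
    for _ in range(n_reps):
        values = []
        groups = {}
        for i in range(4):
            pid = f"P{i}"
            groups[pid] = "dominant" if i < 2 else "nondominant"
            for j, v in enumerate(rng.normal(size=125)):
                values.append((f"{pid}_c{j}", "GS", v, pid, "CD8T"))
        table = pd.DataFrame(
            values,
            columns=["unit_id", "signature_name", "score", "patient_id",
                     "population"],
        )
        cmp_res = compare_groups(table, _results_frame(groups), "null")
        rejections += cmp_res.p_value < 0.05
    assert 0.02 <= rejections / n_reps <= 0.09


def test_compare_groups_single_tied_value_gives_p_one():
    table = pd.DataFrame(
        {
            "unit_id": ["a", "b"],
            "signature_name": "GS",
            "score": [0.5, 0.5],
            "patient_id": ["P1", "P2"],
            "population": "CD8T",
        }
    )
    res = compare_groups(
        table, _results_frame({"P1": "dominant", "P2": "nondominant"}), "tied"
    )
    assert res.p_value == 1.0 and res.effect_direction == "none"


def test_compare_groups_empty_group_is_named_error():
    table = pd.DataFrame(
        {
            "unit_id": ["a"],
            "signature_name": "GS",
            "score": [0.5],
            "patient_id": ["P1"],
            "population": "CD8T",
        }
    )
    with pytest.raises(DataContractError, match="nondominant"):
        compare_groups(table, _results_frame({"P1": "dominant"}), "x")


# ------------------------------------------------- composition/correlation
def test_composition_ratio_simple_counts():
    annot = make_annotation(
        [f"c{i}" for i in range(100)],
        ["P1"] * 100,
        ["tumor"] * 30 + ["CD8T"] * 70,
    )
    frac = composition_ratio(annot)
    assert frac["P1"] == pytest.approx(0.30)


def test_correlate_perfect_and_formula(rng):
    x = rng.normal(size=5)
    r, p = correlate(x, x)
    assert r == pytest.approx(1.0)
    y = rng.normal(size=5)
    r, _ = correlate(x, y)
    direct = np.cov(x, y, ddof=1)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
    assert r == pytest.approx(direct, abs=1e-12)


def test_correlate_needs_three_points():
    with pytest.raises(DataContractError):
        correlate([1.0, 2.0], [3.0, 4.0])
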
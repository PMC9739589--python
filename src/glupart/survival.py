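"""Score-based cohort stratification and survival analysis.

The bulk workflow dichotomizes samples at the median signature score
(ties at the median go to "low" — deterministic and order-independent),
estimates Kaplan-Meier curves per stratum, compares them with the
two-group log-rank test, and screens covariates through a univariate ->
multivariate Cox cascade: every covariate is fit alone, those with
univariate p < 0.2 enter one joint model, and p <= 0.05 marks the joint-
model keepers. The Kaplan-Meier and log-rank statistics are computed
directly from their closed forms; Cox models are fit with lifelines
using Breslow tie handling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy.stats import chi2 as chi2_dist

from .containers import ClinicalTable, DataContractError
from .qc import DegenerateResultError

log = logging.getLogger("glupart")


@dataclass
class KMCurve:
    """Product-limit estimate: survival probability after each distinct
    event time, with the number at risk just before it."""

    event_times: np.ndarray
    survival_probs: np.ndarray
    at_risk: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.event_times) <= 0):
            raise DataContractError("event times must be strictly increasing")
        if np.any(np.diff(self.survival_probs) > 1e-12):
            raise DataContractError("survival probabilities must be non-increasing")


def median_split(scores: pd.Series | np.ndarray) -> pd.Series:
    """Label samples "high" (score > median) or "low" (score <= median)."""
    s = pd.Series(scores, dtype=float)
    if s.size < 2:
        raise DataContractError("median_split needs >= 2 samples")
    med = float(s.median())
    if (s == s.iloc[0]).all():
        raise DegenerateResultError("all scores identical; median split degenerate")
    labels = pd.Series(np.where(s > med, "high", "low"), index=s.index)
    log.info(
        "median split at %.6g: %d high / %d low",
        med, int((labels == "high").sum()), int((labels == "low").sum()),
    )
    return labels


def km_estimate(records: ClinicalTable) -> KMCurve:
    """Kaplan-Meier product-limit estimator over one group."""
    t = records.table["time"].to_numpy(dtype=float)
    e = records.table["status"].to_numpy(dtype=int)
    if t.size == 0:
        raise DataContractError("km_estimate needs >= 1 record")
    event_times = np.unique(t[e == 1])
    surv, probs, at_risk = 1.0, [], []
    for ti in event_times:
        n_i = int((t >= ti).sum())
        d_i = int(((t == ti) & (e == 1)).sum())
        surv *= 1.0 - d_i / n_i
        probs.append(surv)
        at_risk.append(n_i)
    return KMCurve(event_times, np.array(probs), np.array(at_risk, dtype=int))


def km_at(curve: KMCurve, t: float) -> float:
    """Right-continuous step value S(t); S(0) = 1."""
    if t < 0:
        raise DataContractError("survival time must be >= 0")
    idx = np.searchsorted(curve.event_times, t, side="right") - 1
    return 1.0 if idx < 0 else float(curve.survival_probs[idx])


def logrank_test(records: ClinicalTable, labels: pd.Series) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, p) with 1 df.

    ``labels`` maps sample_id -> group label (exactly two labels).
    """
    tab = records.table.copy()
    labels = pd.Series(labels)
    labels.index = labels.index.astype(str)
    tab["group"] = tab["sample_id"].map(labels)
    if tab["group"].isna().any():
        raise DataContractError("some samples lack a group label")
    groups = sorted(tab["group"].unique())
    if len(groups) != 2:
        raise DataContractError(f"log-rank needs exactly 2 groups, got {groups}")
    t = tab["time"].to_numpy(dtype=float)
    e = tab["status"].to_numpy(dtype=int)
    g0 = (tab["group"] == groups[0]).to_numpy()

    obs0, exp0, var = 0.0, 0.0, 0.0
    for ti in np.unique(t[e == 1]):
        at_risk = t >= ti
        n = int(at_risk.sum())
        n0 = int((at_risk & g0).sum())
        d = int(((t == ti) & (e == 1)).sum())
        d0 = int(((t == ti) & (e == 1) & g0).sum())
        obs0 += d0
        exp0 += d * n0 / n
        if n > 1:
            var += d * (n0 / n) * (1 - n0 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = (obs0 - exp0) ** 2 / var
    return float(chi2), float(chi2_dist.sf(chi2, df=1))


def _fit_cox(df: pd.DataFrame, covariates: list[str]) -> pd.DataFrame | None:
    """One Cox fit; returns the summary frame or None on non-convergence."""
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(
                df[["time", "status"] + covariates],
                duration_col="time",
                event_col="status",
            )
    except Exception as err:  # lifelines raises ConvergenceError and friends
        log.warning("Cox fit failed for %s: %s", covariates, err)
        return None
    return cph.summary


def cox_screen(
    records: ClinicalTable,
    candidate_covariates: list[str],
    univariate_gate: float = 0.2,
    multivariate_gate: float = 0.05,
    force_covariates: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Univariate -> multivariate Cox screening cascade.

    Each candidate is fit univariately (Breslow ties); candidates with
    univariate p < ``univariate_gate`` — plus any in ``force_covariates``
    — enter one multivariate model. Returns a tidy frame with columns
    covariate, model, hazard_ratio, ci_low, ci_high, p_value, selected;
    ``selected`` marks univariate rows passing the gate and multivariate
    rows with p <= ``multivariate_gate``. Non-convergent covariates are
    flagged with NaN estimates, never fatal.
    """
    missing = [c for c in candidate_covariates
               if c not in records.table.columns]
    if missing:
        raise DataContractError(f"covariates absent from clinical table: {missing}")
    df = records.table
    n_events = int(df["status"].sum())
    if n_events < 10:
        log.warning("only %d events; Cox estimates will be unstable", n_events)

    rows = []
    entrants = []
    for cov in candidate_covariates:
        summ = _fit_cox(df, [cov])
        if summ is None:
            rows.append(
                dict(covariate=cov, model="univariate", hazard_ratio=np.nan,
                     ci_low=np.nan, ci_high=np.nan, p_value=np.nan,
                     selected=False, converged=False)
            )
            continue
        r = summ.loc[cov]
        p = float(r["p"])
        passed = p < univariate_gate
        rows.append(
            dict(covariate=cov, model="univariate",
                 hazard_ratio=float(np.exp(r["coef"])),
                 ci_low=float(np.exp(r["coef lower 95%"])),
                 ci_high=float(np.exp(r["coef upper 95%"])),
                 p_value=p, selected=passed, converged=True)
        )
        if passed:
            entrants.append(cov)
    for cov in force_covariates:
        if cov not in entrants and cov in candidate_covariates:
            entrants.append(cov)

    if len(entrants) >= 1:
        summ = _fit_cox(df, entrants)
        if summ is not None:
            for cov in entrants:
                r = summ.loc[cov]
                p = float(r["p"])
                rows.append(
                    dict(covariate=cov, model="multivariate",
                         hazard_ratio=float(np.exp(r["coef"])),
                         ci_low=float(np.exp(r["coef lower 95%"])),
                         ci_high=float(np.exp(r["coef upper 95%"])),
                         p_value=p, selected=p <= multivariate_gate,
                         converged=True)
                )
        else:
            for cov in entrants:
                rows.append(
                    dict(covariate=cov, model="multivariate",
                         hazard_ratio=np.nan, ci_low=np.nan, ci_high=np.nan,
                         p_value=np.nan, selected=False, converged=False)
                )
    return pd.DataFrame(rows)
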
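"""Linking natural variables to survival: the mallostasis diagnostics.

Natural-variable values are carried into a time-dependent proportional-
hazards analysis via start-stop formatting (stepwise-constant covariates).
Per-variable risk is summarized by a concordance index on baseline values
and an age- and sex-adjusted Cox log-hazard ratio (delegated to lifelines).
The central diagnostic correlates each variable's equilibrium drift rate
mu_age with its risk measures and tests sign agreement between drift and
risk direction (Fisher exact) — mallostasis means the drift points toward
risk. The composite score b = mu_age . z exploits that alignment as a
survival predictor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import AGE_COL, ID_COL, LongitudinalCohort
from .estimation import FitResult
from .model import AnalyticState, mean_solution

__all__ = [
    "to_start_stop",
    "concordance_index",
    "fit_hazard_coefficients",
    "RiskTable",
    "drift_risk_correlation",
    "DriftRiskResult",
    "composite_score",
    "stratify_by_quartile",
    "back_project",
]


# ---------------------------------------------------------------------------
# Start-stop formatting
# ---------------------------------------------------------------------------

def to_start_stop(cohort: LongitudinalCohort, z_values: pd.DataFrame) -> pd.DataFrame:
    """One row per covariate-constant interval: (id, start, stop, event, z..., age, sex).

    Covariates are taken from the interval's starting visit; the final
    interval runs from the last visit to the event/censoring age and carries
    the event flag. Individuals with no follow-up beyond their single visit
    contribute no rows (counted in the ``attrs['n_no_followup']`` audit).
    """
    if cohort.events is None:
        raise ValueError("cohort has no event data")
    z_cols = [c for c in z_values.columns if c.startswith("z")]
    merged = z_values.copy()
    merged["sex"] = cohort.data["sex"].to_numpy(float) if "sex" in cohort.data.columns else 0.0

    rows = []
    n_no_followup = 0
    for iid, grp in merged.groupby(ID_COL, sort=False):
        ev = cohort.events.loc[iid]
        e_age, e_status = float(ev["event_age"]), int(ev["event_status"])
        ages = grp[AGE_COL].to_numpy(float)
        if (ages > e_age).any():
            raise ValueError(f"individual {iid!r} has a visit after its event age")
        stops = np.append(ages[1:], e_age)
        events = np.zeros(len(ages), dtype=int)
        events[-1] = e_status
        for k in range(len(ages)):
            if stops[k] <= ages[k]:  # no follow-up time on the final interval
                n_no_followup += 1
                continue
            row = {
                ID_COL: iid,
                "start": ages[k],
                "stop": stops[k],
                "event": events[k],
                "age": ages[k],
                "sex": grp["sex"].iloc[k],
            }
            for c in z_cols:
                row[c] = grp[c].iloc[k]
            rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["n_no_followup"] = n_no_followup
    return out


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------

def concordance_index(scores, event_age, event_status) -> float:
    """C-index over comparable pairs, ties in score counting one half.

    A pair is comparable when the earlier time belongs to an observed event.
    The sign convention follows the survival literature: C > 0.5 means
    individuals with *smaller* scores experience the event earlier (small
    values are bad).
    """
    s = np.asarray(scores, float)
    t = np.asarray(event_age, float)
    e = np.asarray(event_status, int)
    # pair (i, j) comparable if t_i < t_j and e_i == 1
    ti, tj = t[:, None], t[None, :]
    si, sj = s[:, None], s[None, :]
    comparable = (ti < tj) & (e[:, None] == 1)
    n_comp = comparable.sum()
    if n_comp == 0:
        raise ValueError("no comparable pairs")
    concordant = comparable & (si < sj)
    tied = comparable & (si == sj)
    return float((concordant.sum() + 0.5 * tied.sum()) / n_comp)


# ---------------------------------------------------------------------------
# Per-variable risk
# ---------------------------------------------------------------------------

@dataclass
class RiskTable:
    """Per natural variable: C-index, adjusted Cox coefficient, drift."""

    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def fit_hazard_coefficients(
    records: pd.DataFrame,
    mu_age: np.ndarray | None = None,
    adjust: tuple[str, ...] = ("age", "sex"),
) -> RiskTable:
    """Per-variable time-dependent Cox fits plus baseline C-indices.

    Each natural variable is fitted separately, adjusted for age and sex,
    by maximizing the standard partial likelihood on the start-stop records
    (lifelines). Non-convergence or collinearity flags the variable rather
    than failing. The C-index scores each individual by its first-interval
    (baseline) value of that variable.
    """
    from lifelines import CoxTimeVaryingFitter
    from lifelines.exceptions import ConvergenceError

    z_cols = sorted(
        (c for c in records.columns if c.startswith("z") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    if records["event"].sum() < 2:
        raise ValueError("need at least 2 events")
    adjust = tuple(a for a in adjust if a in records.columns and records[a].nunique() > 1)

    base = records.groupby(ID_COL, sort=False).head(1)
    last = records.groupby(ID_COL, sort=False).tail(1)
    event_age = last["stop"].to_numpy(float)
    event_status = last["event"].to_numpy(int)

    rows = []
    for j, zc in enumerate(z_cols):
        cols = [ID_COL, "start", "stop", "event", zc, *adjust]
        df = records[cols].copy()
        beta = se = np.nan
        flagged = False
        collinear = any(
            np.corrcoef(df[zc], df[a])[0, 1] ** 2 > 1 - 1e-10 for a in adjust
        ) or df[zc].nunique() == 1
        if collinear:
            flagged = True
        else:
            ctv = CoxTimeVaryingFitter(penalizer=1e-6)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    ctv.fit(
                        df, id_col=ID_COL, event_col="event",
                        start_col="start", stop_col="stop", show_progress=False,
                    )
                beta = float(ctv.params_[zc])
                se = float(ctv.standard_errors_[zc])
            except (ConvergenceError, np.linalg.LinAlgError, ValueError):
                flagged = True
        c = concordance_index(base[zc].to_numpy(float), event_age, event_status)
        rows.append(
            {
                "natural_variable": zc,
                "c_index": c,
                "beta": beta,
                "beta_se": se,
                "mu_age": np.nan if mu_age is None else float(mu_age[j]),
                "flagged": flagged,
            }
        )
    return RiskTable(table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Drift vs risk
# ---------------------------------------------------------------------------

@dataclass
class DriftRiskResult:
    corr_c_index: float
    p_c_index: float
    corr_beta: float
    p_beta: float
    fisher_table: np.ndarray
    fisher_odds: float
    fisher_p: float
    n_agree: int
    n_total: int
    degenerate: bool = False


def drift_risk_correlation(risk: RiskTable, dichotomy: str = "c_index") -> DriftRiskResult:
    """Correlate the drift mu_age with per-variable risk, and test sign agreement.

    Risk direction is +1 when high values are risky: sign(0.5 - C) under the
    C-index convention, sign(beta) under the Cox convention. Mallostasis
    predicts sign(mu_age) equals the risk direction; the 2x2 sign table is
    tested with the two-sided Fisher exact (hypergeometric) test. A table
    with an empty margin (all drifts one sign, or all risks one direction)
    is flagged degenerate.
    """
    t = risk.table
    if len(t) < 3:
        raise ValueError("need >= 3 natural variables")
    mu_age = t["mu_age"].to_numpy(float)
    c = t["c_index"].to_numpy(float)
    beta = t["beta"].to_numpy(float)

    corr_c, p_c = stats.pearsonr(mu_age, c)
    ok = np.isfinite(beta)
    if ok.sum() >= 3 and np.std(beta[ok]) > 0:
        corr_b, p_b = stats.pearsonr(mu_age[ok], beta[ok])
    else:
        corr_b, p_b = np.nan, np.nan

    risk_dir = np.sign(0.5 - c) if dichotomy == "c_index" else np.sign(beta)
    drift_dir = np.sign(mu_age)
    use = (risk_dir != 0) & (drift_dir != 0)
    table = np.array(
        [
            [np.sum((drift_dir[use] > 0) & (risk_dir[use] > 0)),
             np.sum((drift_dir[use] > 0) & (risk_dir[use] < 0))],
            [np.sum((drift_dir[use] < 0) & (risk_dir[use] > 0)),
             np.sum((drift_dir[use] < 0) & (risk_dir[use] < 0))],
        ],
        dtype=int,
    )
    degenerate = (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any()
    odds, fisher_p = stats.fisher_exact(table, alternative="two-sided")
    n_agree = int(table[0, 0] + table[1, 1])
    return DriftRiskResult(
        corr_c_index=float(corr_c),
        p_c_index=float(p_c),
        corr_beta=float(corr_b),
        p_beta=float(p_b),
        fisher_table=table,
        fisher_odds=float(odds),
        fisher_p=float(fisher_p),
        n_agree=n_agree,
        n_total=int(use.sum()),
        degenerate=bool(degenerate),
    )


# ---------------------------------------------------------------------------
# Composite score and stratified survival
# ---------------------------------------------------------------------------

def composite_score(mu_age: np.ndarray, z: np.ndarray) -> np.ndarray | float:
    """b = mu_age . z — the drift-weighted health score (higher-|b| along the
    drift direction means further along the mallostatic trajectory)."""
    z = np.asarray(z, float)
    mu_age = np.asarray(mu_age, float)
    return z @ mu_age


def stratify_by_quartile(
    scores: pd.Series | pd.DataFrame,
    event_age: np.ndarray,
    event_status: np.ndarray,
    entry_age: np.ndarray | None = None,
):
    """Kaplan-Meier survival by baseline-score quartile.

    ``scores`` is per-individual (index = id). Quartiles are assigned by a
    stable sort on (score, id), so boundary ties break deterministically.
    Returns (assignments DataFrame, fitted KaplanMeierFitter per quartile,
    logrank ordering statistic result).
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    s = pd.Series(np.asarray(scores, float).ravel(), index=scores.index if hasattr(scores, "index") else None)
    n = len(s)
    if n < 8:
        raise ValueError("need >= 8 individuals for quartiles")
    order = np.lexsort((np.asarray(s.index.astype(str)), s.to_numpy()))
    quart = np.empty(n, dtype=int)
    quart[order] = (np.arange(n) * 4) // n + 1

    event_age = np.asarray(event_age, float)
    event_status = np.asarray(event_status, int)
    fitters = {}
    for q in (1, 2, 3, 4):
        sel = quart == q
        km = KaplanMeierFitter(label=f"Q{q}")
        entry = None if entry_age is None else np.asarray(entry_age, float)[sel]
        km.fit(event_age[sel], event_status[sel], entry=entry, label=f"Q{q}")
        fitters[q] = km
    test = multivariate_logrank_test(event_age, quart, event_status)
    assign = pd.DataFrame({"score": s.to_numpy(), "quartile": quart}, index=s.index)
    return assign, fitters, test


def back_project(
    fit: FitResult, j: int, ages: np.ndarray, state: AnalyticState | None = None
) -> pd.DataFrame:
    """Contribution of natural variable j to each observed biomarker's mean.

    Returns P[:, j] * <z_j>(age) for each requested age. By default
    <z_j>(age) follows the steady-state drift implied by the fit
    (linear-in-age with slope mu_age,j and offset mu_age,j/lambda_j);
    pass an AnalyticState to use the full transient mean trajectory.
    """
    m = fit.basis.m
    if not (0 <= j < m):
        raise IndexError(f"natural-variable index {j} out of range [0, {m})")
    ages = np.asarray(ages, float)
    if state is not None:
        z_mean = np.asarray(mean_solution(state, ages), float)
    else:
        lam = float(fit.basis.eigenvalues[j])
        if lam >= 0:
            raise ValueError("steady-state back-projection requires lambda < 0")
        mu_age = float(fit.params.mu_age[j])
        mu0 = float(fit.params.mu0[j])
        z_mean = mu_age / lam + mu0 + mu_age * ages
    contrib = np.outer(fit.basis.P[:, j], z_mean)
    out = pd.DataFrame(contrib, index=fit.params_observed.biomarker_names,
                       columns=[f"age_{a:g}" for a in np.atleast_1d(ages)])
    out.index.name = "biomarker"
    return out
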
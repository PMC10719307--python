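"""Post-fit stability and homeostasis diagnostics.

Everything here works on the natural variables z = P^-1 y of a fitted
network: recovery-rate spectra, mean deviation from the (drifting)
equilibrium scaled by the steady-state dispersion sqrt(sigma^2 / 2|lambda|),
the memory-vs-drift split of each deviation, and the cross-variable
correlations that diagnose mallostasis (deviation vs drift) and noise
accumulation (variance vs recovery rate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import AGE_COL, ID_COL, LongitudinalCohort
from .estimation import FitResult
from .model import AnalyticState, memory_drift

__all__ = [
    "StabilityReport",
    "stability_report",
    "deviation_drift_correlation",
    "variance_rate_correlation",
    "rate_spectrum",
    "compensation_decomposition",
    "convert_timescale",
]


@dataclass
class StabilityReport:
    """One row per natural variable (see ``table`` columns)."""

    table: pd.DataFrame
    age_window: tuple[float, float]
    t0: float  # reference age for the memory term (population baseline)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def stability_report(
    fit: FitResult,
    cohort: LongitudinalCohort | None = None,
    age_window: tuple[float, float] | None = None,
) -> StabilityReport:
    """Summarize each natural variable's stability and homeostasis.

    ``age_window`` restricts which visits enter the mean deviation
    <z - mu~> and the empirical variance; the memory/drift split uses the
    population baseline age as reference time t0 and the window end as t.
    """
    z_table = fit.natural_z(cohort)
    c = fit.completed_cohort if cohort is None else cohort
    ages = z_table[AGE_COL].to_numpy(float)
    if age_window is None:
        age_window = (float(ages.min()), float(ages.max()))
    lo, hi = age_window
    keep = (ages >= lo) & (ages <= hi)
    if not keep.any():
        raise ValueError(f"no visits in age window {age_window}")

    m = fit.basis.m
    lam = fit.basis.eigenvalues
    mu_age = fit.params.mu_age
    sigma2 = np.diag(fit.params.Sigma)

    # per-visit equilibrium in the natural basis
    x = c.data[fit.params_observed.plain_covariates].to_numpy(float) if fit.params_observed.plain_covariates else np.empty((len(ages), 0))
    xa = fit.params.augment(x, ages)
    mu_tilde = xa @ fit.params.Lambda.T
    z = z_table[[f"z{j + 1}" for j in range(m)]].to_numpy(float)
    dev = z - mu_tilde

    mean_dev = dev[keep].mean(axis=0)
    var_z = z[keep].var(axis=0, ddof=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = np.sqrt(np.where(lam < 0, sigma2 / (2.0 * np.abs(lam)), np.nan))
    scaled_dev = mean_dev / dispersion

    # memory/drift at the window end, referenced to the population baseline age
    first = z_table.groupby(ID_COL, sort=False).head(1).index.to_numpy()
    t0 = float(ages[first].mean())
    dev0 = dev[first].mean(axis=0)
    t_end = float(ages[keep].max())
    memory = np.zeros(m)
    drift = np.zeros(m)
    for j in range(m):
        st = AnalyticState(
            lam=float(lam[j]), mu0=0.0, mu_age=float(mu_age[j]),
            z0_mean=0.0, z0_var=0.0, sigma2=float(sigma2[j]),
        )
        memory[j], drift[j] = memory_drift(st, t_end, t0, float(dev0[j]))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.abs(memory) / np.abs(drift)

    table = pd.DataFrame(
        {
            "natural_variable": [f"z{j + 1}" for j in range(m)],
            "eigenvalue": lam,
            "recovery_rate": -lam,
            "mu_age": mu_age,
            "mean_deviation": mean_dev,
            "dispersion": dispersion,
            "scaled_deviation": scaled_dev,
            "memory": memory,
            "drift": drift,
            "memory_drift_ratio": ratio,
            "steady_state": ratio < 1.0,
            "variance": var_z,
        }
    )
    return StabilityReport(table=table, age_window=(lo, hi), t0=t0)


def deviation_drift_correlation(report: StabilityReport) -> tuple[float, float]:
    """Pearson correlation of mean deviation <z - mu~> with the drift mu_age.

    In steady state the deviation equals mu_age/lambda, so drifting variables
    lag their moving equilibrium in proportion to their drift — the expected
    correlation is strongly negative. Returns (nan, nan) when either vector
    has zero variance.
    """
    t = report.table
    if len(t) < 3:
        raise ValueError("need >= 3 natural variables")
    a, b = t["mean_deviation"].to_numpy(), t["mu_age"].to_numpy()
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def variance_rate_correlation(report: StabilityReport) -> tuple[float, float]:
    """Pearson correlation of log Var(z_j) with log recovery rate.

    Slow variables integrate noise longest (steady-state variance is
    sigma^2 / 2|lambda|), so the expected relation is negative; with a common
    noise strength it is an exact line of slope -1 on the log-log scale.
    """
    t = report.table
    rates = t["recovery_rate"].to_numpy(float)
    var = t["variance"].to_numpy(float)
    bad = [n for n, r, v in zip(t["natural_variable"], rates, var) if r <= 0 or v <= 0]
    if bad:
        raise ValueError(f"nonpositive rate or variance for {bad}")
    if len(t) < 2:
        raise ValueError("need >= 2 natural variables")
    r, p = stats.pearsonr(np.log(var), np.log(rates))
    return float(r), float(p)


def rate_spectrum(fit: FitResult) -> tuple[np.ndarray, np.ndarray]:
    """(natural-variable rates -lambda_j, observed-biomarker diagonal rates -W_jj).

    Both sorted ascending. With material interactions the eigen rates extend
    beyond the diagonal range on both ends.
    """
    natural = np.sort(-fit.basis.eigenvalues)
    diagonal = np.sort(-np.diag(fit.params_observed.W))
    return natural, diagonal


def compensation_decomposition(fit: FitResult, cohort: LongitudinalCohort | None = None) -> pd.DataFrame:
    """Split each biomarker's mean rate of change into recovery vs interaction.

    recovery_j = W_jj <y_j - mu_j>; interaction_j = sum_{k!=j} W_jk <y_k - mu_k>.
    Their sum approximates the empirical <dy_j>/<dt> on the same visits.
    """
    c = fit.completed_cohort if cohort is None else cohort
    p = fit.params_observed
    y = c.biomarker_matrix()
    ages = c.data[AGE_COL].to_numpy(float)
    x = c.data[p.plain_covariates].to_numpy(float) if p.plain_covariates else np.empty((len(ages), 0))
    mu = p.augment(x, ages) @ p.Lambda.T
    dev = (y - mu).mean(axis=0)
    W = p.W
    recovery = np.diag(W) * dev
    interaction = W @ dev - recovery

    from .cohort import make_transition_pairs

    pairs = make_transition_pairs(c)
    dy = np.array([pr.y_to - pr.y_from for pr in pairs])
    dt = np.array([pr.dt for pr in pairs])
    empirical = dy.mean(axis=0) / dt.mean()

    return pd.DataFrame(
        {
            "biomarker": p.biomarker_names,
            "recovery": recovery,
            "interaction": interaction,
            "total": recovery + interaction,
            "empirical_rate": empirical,
        }
    )


def convert_timescale(
    rates: np.ndarray, median_survival_source: float, median_survival_target: float
) -> np.ndarray:
    """Rescale rates between species/strains by the ratio of median survivals.

    A rate in source time units becomes rate * (median_source/median_target)
    per target-equivalent unit (e.g. mouse weeks to human-equivalent years).
    """
    if median_survival_source <= 0 or median_survival_target <= 0:
        raise ValueError("median survivals must be positive")
    return np.asarray(rates, float) * (median_survival_source / median_survival_target)


# ---------------------------------------------------------------------------
# Plot panels (rate spectrum, homeostasis scatter)
# ---------------------------------------------------------------------------

def plot_rate_spectrum(fit: FitResult, ax=None):
    """Natural-variable rates (solid) vs network diagonal rates (dotted)."""
    import matplotlib.pyplot as plt

    natural, diagonal = rate_spectrum(fit)
    if ax is None:
        _, ax = plt.subplots()
    for r in natural:
        ax.axvline(r, color="C0", lw=1.5)
    for r in diagonal:
        ax.axvline(r, color="C1", ls=":", lw=1.2)
    ax.set_xscale("log")
    ax.set_xlabel("recovery rate")
    ax.set_yticks([])
    return ax


def plot_homeostasis(report: StabilityReport, ax=None):
    """Scaled deviation from equilibrium vs recovery rate, one point per z_j."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = report.table
    ax.scatter(t["recovery_rate"], t["scaled_deviation"])
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xscale("log")
    ax.set_xlabel("recovery rate")
    ax.set_ylabel("mean deviation / equilibrium dispersion")
    return ax
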
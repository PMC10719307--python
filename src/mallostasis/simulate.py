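"""Synthetic longitudinal cohorts with mortality coupled to the latent state.

The generator produces exactly the data structure the estimators assume:
unequally spaced visits, element-wise missingness, a sex covariate, and
death/censoring driven by a proportional-hazards link on the natural
variables, hazard = baseline_hazard * exp(beta . z). Separate RNG streams
(dynamics, missingness, survival) are spawned from the master seed so that
toggling missingness does not perturb trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import AGE_COL, ID_COL, LongitudinalCohort
from .model import (
    AGE_COVARIATE,
    CONST_COL,
    ModelParameters,
    NaturalBasis,
    from_natural,
    to_natural,
)

__all__ = [
    "SimulationConfig",
    "GroundTruthBundle",
    "simulate_cohort",
    "apply_missingness",
    "mallostatic_scenario",
]


@dataclass
class SimulationConfig:
    """Ground truth and study design for one simulated cohort.

    Ages are in the cohort's time unit (years by default). ``params`` is the
    ground-truth model in the observed-biomarker basis; ``basis`` its
    eigendecomposition (used for the hazard link and the latent table).
    ``hazard_coefficients`` (beta) act on the natural variables z.
    """

    n_individuals: int
    params: ModelParameters
    basis: NaturalBasis
    visit_interval_mean: float = 3.0
    visit_interval_jitter: float = 1.0
    max_visits: int = 10
    baseline_age_range: tuple[float, float] = (65.0, 75.0)
    baseline_mean: np.ndarray | None = None  # mean of y at first visit
    baseline_cov: np.ndarray | None = None
    missing_rate: float = 0.0
    missing_pattern: str = "random"
    hazard_coefficients: np.ndarray | None = None
    baseline_hazard: float = 0.0
    censoring_age: float = 95.0
    seed: int = 0
    time_unit: str = "years"

    def __post_init__(self) -> None:
        if self.n_individuals < 1 or self.max_visits < 1:
            raise ValueError("counts must be >= 1")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.baseline_hazard < 0:
            raise ValueError("baseline_hazard must be >= 0")
        m = self.params.m
        if self.baseline_mean is None:
            self.baseline_mean = np.zeros(m)
        if self.baseline_cov is None:
            self.baseline_cov = np.eye(m)
        if self.hazard_coefficients is None:
            self.hazard_coefficients = np.zeros(m)
        self.baseline_mean = np.asarray(self.baseline_mean, float)
        self.baseline_cov = np.asarray(self.baseline_cov, float)
        self.hazard_coefficients = np.asarray(self.hazard_coefficients, float)


@dataclass
class GroundTruthBundle:
    """Simulated cohort together with the truth that generated it."""

    cohort: LongitudinalCohort
    params: ModelParameters
    basis: NaturalBasis
    latent_z: pd.DataFrame  # id, age, z1..zm at every visit
    config: SimulationConfig


def _streams(seed: int) -> dict[str, np.random.Generator]:
    dyn, miss, surv = np.random.SeedSequence(seed).spawn(3)
    return {
        "dynamics": np.random.default_rng(dyn),
        "missingness": np.random.default_rng(miss),
        "survival": np.random.default_rng(surv),
    }


def simulate_cohort(config: SimulationConfig) -> GroundTruthBundle:
    """Simulate forward visit by visit; death/censoring truncates follow-up.

    Biomarkers evolve by the one-step model with Gaussian noise of covariance
    Sigma*dt. Between consecutive visits the hazard is held constant at
    baseline_hazard * exp(beta . z(start)), so the event time within an
    interval is an exponential waiting time; after the last visit the hazard
    stays frozen at the last observed state until death or the censoring age.
    """
    rngs = _streams(config.seed)
    dyn, surv = rngs["dynamics"], rngs["survival"]
    params, basis = config.params, config.basis
    m, n = params.m, config.n_individuals
    eigvals = np.linalg.eigvalsh((params.Sigma + params.Sigma.T) / 2)
    if eigvals.min() < -1e-10 * max(1.0, eigvals.max()):
        raise ValueError("Sigma must be positive semi-definite")
    # PSD square root tolerant of zero noise
    w, V = np.linalg.eigh((params.Sigma + params.Sigma.T) / 2)
    L = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))

    lo, hi = config.baseline_age_range
    t = dyn.uniform(lo, hi, size=n)
    sex = dyn.integers(0, 2, size=n).astype(float)
    y = config.baseline_mean + dyn.standard_normal((n, m)) @ np.linalg.cholesky(
        config.baseline_cov + 1e-12 * np.eye(m)
    ).T

    has_sex = "sex" in params.plain_covariates
    x = sex[:, None] if has_sex else np.empty((n, 0))
    beta = config.hazard_coefficients
    h0 = config.baseline_hazard

    alive = np.ones(n, dtype=bool)
    event_age = np.full(n, np.nan)
    event_status = np.zeros(n, dtype=int)

    rows_y, rows_t, rows_id = [], [], []
    visit_counts = np.zeros(n, dtype=int)

    for _ in range(config.max_visits):
        active = alive & (t <= config.censoring_age)
        if not active.any():
            break
        for i in np.flatnonzero(active):
            rows_id.append(i)
        rows_t.append(t[active].copy())
        rows_y.append(y[active].copy())
        visit_counts[active] += 1

        dt = config.visit_interval_mean + dyn.uniform(
            -config.visit_interval_jitter, config.visit_interval_jitter, size=n
        )
        dt = np.clip(dt, 0.1 * config.visit_interval_mean, None)

        # survival over the coming interval, hazard frozen at current state
        if h0 > 0:
            z = to_natural(basis, y)
            hazard = h0 * np.exp(z @ beta)
            wait = surv.exponential(1.0, size=n) / hazard
            died = active & (wait < dt)
            cens_t = np.minimum(t + dt, config.censoring_age)
            death_t = t + wait
            newly_dead = died & (death_t <= config.censoring_age)
            event_age[newly_dead] = death_t[newly_dead]
            event_status[newly_dead] = 1
            alive[newly_dead] = False
        # step the dynamics for everyone still alive
        mu = (params.augment(x, t) @ params.Lambda.T)
        noise = dyn.standard_normal((n, m)) @ L.T * np.sqrt(dt)[:, None]
        y = y + ((y - mu) @ params.W.T) * dt[:, None] + noise
        t = t + dt

    # follow-up after the last visit: frozen hazard until death or censoring
    if h0 > 0:
        pending = alive
        z = to_natural(basis, y)
        hazard = h0 * np.exp(z @ beta)
        wait = surv.exponential(1.0, size=n) / hazard
        death_t = t + wait
        late_death = pending & (death_t <= config.censoring_age)
        event_age[late_death] = death_t[late_death]
        event_status[late_death] = 1
        alive[late_death] = False
    censored = alive | np.isnan(event_age)
    event_age[censored] = config.censoring_age
    event_status[censored] = 0

    ids = np.array([f"i{i:05d}" for i in range(n)])
    order = np.argsort(np.array(rows_id), kind="stable")
    flat_id = np.array(rows_id)[order]
    flat_t = np.concatenate(rows_t)[order]
    flat_y = np.vstack(rows_y)[order]

    data = pd.DataFrame({ID_COL: ids[flat_id], AGE_COL: flat_t})
    for j, name in enumerate(params.biomarker_names):
        data[name] = flat_y[:, j]
    if has_sex:
        data["sex"] = sex[flat_id]

    # censor any visit recorded after a death drawn in a previous interval
    ev = pd.DataFrame({"event_age": event_age, "event_status": event_status}, index=ids)
    ev.index.name = ID_COL
    keep = ~((data[AGE_COL].to_numpy() > event_age[flat_id]) & (event_status[flat_id] == 1))
    data = data[keep].reset_index(drop=True)
    flat_y = flat_y[keep]

    z_all = to_natural(basis, flat_y)
    latent = pd.DataFrame({ID_COL: data[ID_COL], AGE_COL: data[AGE_COL]})
    for j in range(m):
        latent[f"z{j + 1}"] = z_all[:, j]

    cohort = LongitudinalCohort(
        data=data,
        biomarker_names=list(params.biomarker_names),
        covariate_names=["sex"] if has_sex else [],
        events=ev,
        time_unit=config.time_unit,
    )
    if config.missing_rate > 0:
        cohort = apply_missingness(
            cohort, config.missing_pattern, config.missing_rate, rngs["missingness"]
        )
    return GroundTruthBundle(cohort=cohort, params=params, basis=basis, latent_z=latent, config=config)


def apply_missingness(
    cohort: LongitudinalCohort,
    pattern: str,
    rate: float,
    seed: int | np.random.Generator,
) -> LongitudinalCohort:
    """Blank biomarker cells; never touches id/age/covariates.

    ``"random"``: each cell independently missing with probability ``rate``.
    ``"staggered"``: the biomarker panel is split in two halves measured on
    alternating visits (emulating staggered assay panels), so no visit
    carries both halves.
    """
    if not (0.0 <= rate < 1.0) and pattern == "random":
        raise ValueError("rate must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = cohort.copy()
    vals = out.data[out.biomarker_names].to_numpy(float)
    if pattern == "random":
        if rate > 0:
            mask = rng.random(vals.shape) < rate
            vals[mask] = np.nan
    elif pattern == "staggered":
        half = cohort.m // 2
        visit_index = out.data.groupby(ID_COL, sort=False).cumcount().to_numpy()
        panel_a = visit_index % 2 == 0
        vals[np.ix_(panel_a, np.arange(half, cohort.m))] = np.nan
        vals[np.ix_(~panel_a, np.arange(0, half))] = np.nan
    else:
        raise ValueError(f"unknown pattern {pattern!r}")
    for j, name in enumerate(out.biomarker_names):
        out.data[name] = vals[:, j]

    fully_missing = (
        out.data[out.biomarker_names].isna().all(axis=1).groupby(out.data[ID_COL]).all()
    )
    if fully_missing.any():
        import warnings

        warnings.warn(
            f"{int(fully_missing.sum())} individual(s) have no observed biomarker "
            "values at any visit; kept in the cohort",
            stacklevel=2,
        )
    return out


def mallostatic_scenario(m: int, n: int, seed: int) -> SimulationConfig:
    """Canonical test scenario: a stable network with two drifting variables.

    Constructs an orthogonal random basis P and log-spaced recovery rates
    whose slowest timescale (40 time units) is comparable to the simulated
    lifespan. Exactly the two slowest natural variables carry a nonzero
    equilibrium drift, and the hazard coefficients beta are proportional to
    that drift — the mallostasis structure the pipeline must rediscover.
    """
    if m < 3:
        raise ValueError("scenario requires m >= 3")
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((m, m))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))  # deterministic sign convention

    rates = np.geomspace(0.025, 0.5, m)  # slowest timescale 40, fastest 2
    lam = -rates  # ascending rate == descending lambda: least stable first
    basis = NaturalBasis(P=Q, eigenvalues=lam, is_orthogonal=True)

    mu_age_z = np.zeros(m)
    mu_age_z[0] = -0.015  # per time unit, standardized scale
    mu_age_z[1] = -0.010
    t_mid = 70.0
    mu0_z = -mu_age_z * t_mid  # equilibrium crosses 0 at the mid-study age
    sex_z = rng.normal(0.0, 0.2, size=m)
    sigma2 = 0.05
    Sigma_z = sigma2 * np.eye(m)

    Lambda_z = np.column_stack([mu0_z, sex_z, mu_age_z])
    W = Q @ np.diag(lam) @ Q.T
    params = ModelParameters(
        W=W,
        Lambda=Q @ Lambda_z,
        Sigma=Q @ Sigma_z @ Q.T,
        biomarker_names=[f"bm{j + 1}" for j in range(m)],
        covariate_names=[CONST_COL, "sex", AGE_COVARIATE],
    )

    # start near the drifting steady state, with an extra offset on the
    # slowest variable so memory terms are exercised
    ss_dev = mu_age_z / lam
    z0 = ss_dev.copy()
    z0[0] += 0.2
    ss_var = sigma2 / (2.0 * rates)
    baseline_mean = from_natural(basis, z0)
    baseline_cov = Q @ np.diag(ss_var) @ Q.T

    beta = 50.0 * mu_age_z  # hazard aligned with drift, the mallostatic link

    return SimulationConfig(
        n_individuals=n,
        params=params,
        basis=basis,
        visit_interval_mean=3.0,
        visit_interval_jitter=1.0,
        max_visits=10,
        baseline_age_range=(65.0, 75.0),
        baseline_mean=baseline_mean,
        baseline_cov=baseline_cov,
        missing_rate=0.2,
        hazard_coefficients=beta,
        baseline_hazard=0.015,
        censoring_age=95.0,
        seed=seed,
    )
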
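# mallostasis

Network dynamical-stability analysis of longitudinal aging biomarkers.

As organisms age, most health biomarkers drift steadily away from their
youthful values. This package models that process by operationalizing
homeostasis as a **multivariate mean-reverting stochastic process** with an
age-drifting equilibrium, for researchers working with longitudinal cohort
data (repeated biomarker panels with death or disease-onset follow-up).

## The model

Biomarkers **y** observed at unequally spaced ages *t* evolve as

```
y[n+1] = y[n] + W Δt (y[n] − μ[n]) + ε,     ε ~ N(0, Σ|Δt|)
μ[n]   = μ₀ + Λ x[n] + μ_age t[n]
```

where **W** is the biomarker interaction network (diagonal entries:
self-recovery; off-diagonal: compensation between biomarkers), **Σ** the
noise covariance per unit time, and the equilibrium **μ** drifts linearly
with age at rate **μ_age** (allostasis). Eigen-decomposing **W** gives
*natural variables* `z = P⁻¹y` with decoupled means; each relaxes toward its
own moving equilibrium at recovery rate −λⱼ. Stability analysis, survival
linkage and model assessment all operate on these natural variables:

- In steady state each natural variable lags its moving equilibrium by
  `⟨z − μ⟩ = μ_age/λ`, so strongly drifting variables sit far from
  equilibrium — and when the drift direction coincides with the mortality
  risk direction, the equilibrium itself is worsening: **mallostasis**.
- The drift vector defines a composite health score `b = μ_ageᵀz` that
  stratifies survival.
- Parameters are estimated by closed-form maximum-likelihood moment ratios
  (iterated ×5 with in-loop imputation of missing values), and models are
  compared by out-of-sample bootstrap with the .632 error estimator.

No external cohort downloads are needed: the `simulate` module generates
cohorts with the full structure the method assumes (irregular visits,
missingness, sex covariate, mortality coupled to the latent health state).

## Worked example

```python
import numpy as np
from mallostasis import (mallostatic_scenario, simulate_cohort, standardize, fit,
                         FitConfig, stability_report, to_start_stop,
                         fit_hazard_coefficients, drift_risk_correlation)

config = mallostatic_scenario(m=5, n=1000, seed=1)   # 2 drifting natural variables
bundle = simulate_cohort(config)
cohort, scaling = standardize(bundle.cohort)
result = fit(cohort, FitConfig(model_form="full"))

print("recovery rates:", np.round(result.recovery_rates, 3))
report = stability_report(result)
print(report.table[["natural_variable", "recovery_rate", "mu_age",
                    "scaled_deviation", "steady_state"]].round(3).to_string(index=False))

records = to_start_stop(result.completed_cohort, result.natural_z())
risk = fit_hazard_coefficients(records, mu_age=result.params.mu_age)
link = drift_risk_correlation(risk)
print(f"corr(mu_age, beta) = {link.corr_beta:.3f}, "
      f"sign agreement {link.n_agree}/{link.n_total}")
```

Output:

```
recovery rates: [0.021 0.047 0.109 0.239 0.502]
natural_variable  recovery_rate  mu_age  scaled_deviation  steady_state
              z1          0.021  -0.028             0.862         False
              z2          0.047   0.011            -0.196          True
              z3          0.109  -0.000             0.083         False
              z4          0.239  -0.001             0.113          True
              z5          0.502   0.001            -0.129          True
corr(mu_age, beta) = 0.990, sign agreement 4/5
```

The fitted recovery-rate spectrum spans 0.02–0.5 per year (the slowest
timescale, ~40 years, is comparable to the remaining lifespan). The two
slowest natural variables carry essentially all of the estimated equilibrium
drift `mu_age` and the largest deviations from equilibrium on the
equilibrium-dispersion scale (`scaled_deviation`); their age- and
sex-adjusted Cox log-hazard ratios correlate with the drift at 0.990 — the
drift points toward the risk direction, which is the mallostasis signature
the cohort was constructed to carry.

The same pipeline runs from the shell:

```sh
mallostasis --seed 1 --out demo_out demo --n 500 --m 5
```

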
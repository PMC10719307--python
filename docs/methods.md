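# Methods

## Model

The core object is a discrete-time linear mean-reverting process for a
biomarker vector y observed at irregular ages t (one step per visit):

    y[n+1] = y[n] + W Δt[n+1] (y[n] − μ[n]) + ε[n+1],   ε ~ N(0, Σ|Δt|)
    μ[n]   = μ₀ + Λ x[n] + μ_age t[n]

This is the Euler form of a multivariate Ornstein–Uhlenbeck process whose
equilibrium moves linearly with age. The constant 1 and the age t are folded
into the covariate vector, so μ₀ and μ_age are named columns of Λ; accessors
expose them by name. We deliberately implement the Euler form, not an exact
matrix-exponential discretization: the estimators below are moment
identities of the Euler form, and the simulator generates data from the same
form, so estimation and generation are mutually consistent. Intervals longer
than the fastest recovery timescale therefore carry genuine discretization
content, which is part of the method, not an approximation error.

Diagonalizing W (eigenvectors P, eigenvalues λ sorted so index 1 is least
stable) yields natural variables z = P⁻¹y with decoupled mean dynamics. For
one natural variable the continuous-time limit gives closed forms used
throughout:

- mean: ⟨z⟩(t) = (⟨z₀⟩ − μ_age/λ − μ₀)e^{λt} + μ_age/λ + μ₀ + μ_age·t
- steady state (λ<0, |λ|t≫1): ⟨z⟩ss = μ(t) + μ_age/λ, drifting at rate μ_age
  with constant lag μ_age/λ behind the moving equilibrium
- deviation split: ⟨z−μ⟩(t) = dev(t₀)e^{λ(t−t₀)} (memory)
  + (μ_age/λ)(1−e^{λ(t−t₀)}) (drift)
- variance: Var(t) = Var₀e^{2λt} − σ²/(2λ)(1−e^{2λt}) → σ²/(2|λ|)

λ = 0 is handled by the analytic limits (constant mean; drift term
−μ_age(t−t₀); variance Var₀ + σ²t), switched at |λ| < 1e−12.

## Estimation

Parameters are estimated by the closed-form moment-ratio estimators

    Λ̂ = ⟨|Δt| y xᵀ⟩⟨|Δt| x xᵀ⟩⁻¹ − W⁻¹⟨sign(Δt)(y′−y)xᵀ⟩⟨|Δt| x xᵀ⟩⁻¹
    Ŵ = ⟨sign(Δt)(y′−y)(y−μ)ᵀ⟩ (⟨|Δt|(y−μ)(y−μ)ᵀ⟩)⁻¹

with expectations taken as unweighted averages over all transition pairs,
pooling individuals. The sign/|Δt| factors are kept verbatim, so
negative-interval pairs are legal. Within one pass the two estimators are
alternated to their joint fixed point (tolerance 1e−12, capped at 100
alternations, initialized from a coordinate-wise diagonal regression, which
keeps the W⁻¹ term well-posed). The outer loop runs a fixed 5 passes whose
only feedback channel is imputation: after each pass, originally missing
entries are re-imputed with the current model's one-step prediction (the
equilibrium mean at first visits). On complete data the fit is therefore
iteration-count invariant, which is tested. A parameter-change log is
emitted but not acted on. Ridge default is 1e−8·trace/m on inverted moment
matrices — numerical insurance only.

Model forms: "full" (the estimators above), "diagonal" (per-coordinate
|Δt|-weighted linear regression of Δz/Δt on (z, 1, x, t); |Δt| is the
natural maximum-likelihood weight since the rate's noise variance is
σ²/|Δt|), and "null" (W = 0, equilibrium only — the no-dynamics baseline).
Principal-component rotation (orthogonal, from the pooled visits after
carry imputation, since the model mean is unavailable before fitting) is the
default preprocessing; it makes the fitted network near-symmetric, and a
fitted W whose asymmetry is below half its largest entry is symmetrized
before the final eigendecomposition. Σ is estimated at the end from
residuals r = y′ − prediction as ⟨r rᵀ/|Δt|⟩, symmetrized and
eigenvalue-clipped to PSD.

The imputation ladder offers carry forward/back, per-individual means, the
conditional-Gaussian (population multivariate-normal) mean given the visit's
observed entries, and the model mean; the default ladder is carry →
model-mean. Optionally, dead individuals are extended past their event on
their median pre-death cadence with model-mean-imputed synthetic visits
(flagged `post_event`) — this reduces the mortality-selection bias discussed
below.

## Synthetic cohorts

The simulator generates exactly the data structure the estimators assume:
baseline ages uniform on 65–75 (years), visits every 3 ± 1 years up to 10
visits or the censoring age 95, a sex covariate, element-wise
missing-completely-at-random blanking, and death times drawn per inter-visit
interval from a proportional-hazards link h = h₀·exp(βᵀz) with the hazard
frozen at the interval's starting state. Because the covariate is constant
within an interval, the piecewise-constant-hazard draw reduces exactly to
one exponential waiting time per interval, which is how it is implemented.
Follow-up continues after the last visit with the hazard frozen at the last
state. Three RNG streams (dynamics, missingness, survival) are spawned from
the master seed, so disabling missingness leaves trajectories bit-identical.

The canonical `mallostatic_scenario(m, n, seed)` builds a random orthogonal
basis, recovery rates log-spaced from 0.025 to 0.5 per year (slowest
timescale 40 years, comparable to the simulated remaining lifespan), noise
σ² = 0.05 per natural variable (steady-state SD 1.0 for the slowest mode,
matching a standardized scale), equilibrium drift on exactly the two slowest
natural variables (−0.015 and −0.010 per year, intercepts chosen so the
equilibrium crosses zero at age 70), small random sex loadings, baseline
states at the drifting steady state plus a +0.2 offset on the slowest mode
(so memory terms are exercised), baseline hazard 0.015/yr, and hazard
coefficients β = 50·μ̃_age — the mallostasis structure (drift aligned with
risk) built in as ground truth for the pipeline to rediscover. With these
settings roughly a quarter of individuals die before censoring.

What the simulator does not emulate: informative (non-MCAR) missingness,
u-shaped lifespan biomarker trajectories, individual-level parameter
heterogeneity, and measurement batch effects. Passing tests therefore show
the pipeline recovers the model's own structure under realistic sampling,
noise, missingness and mortality — not that real cohorts satisfy the model.

## Diagnostics and survival linkage

The stability report evaluates, per natural variable: the recovery rate −λ,
drift μ̃_age, mean deviation ⟨z−μ̃⟩ over an age window, the equilibrium
dispersion √(σ²/2|λ|) (the model-consistent native scale used to
standardize deviations; chosen because the steady-state SD is the only
model-intrinsic dispersion), the memory/drift split at the window end with
the population mean baseline age as reference time t₀, a steady-state flag
at |memory/drift| < 1, and the empirical Var(z). Cross-variable Pearson
correlations (two-sided t-based p-values) diagnose mallostasis
(deviation vs drift; strongly negative in steady state since
⟨z−μ⟩ss = μ_age/λ) and noise accumulation (log Var vs log rate; slope −1
exactly when σ² is common). Timescales convert between species by the ratio
of median survivals.

Survival linkage uses start–stop records (stepwise-constant covariates from
each interval's starting visit; the final interval ends at the event or
censoring age). Per-variable risk combines a hand-implemented concordance
index on baseline values (ties count ½; C > 0.5 means small values are bad;
the brute-force pair enumeration is the tested contract) with an age- and
sex-adjusted Cox time-varying coefficient delegated to lifelines (penalizer
1e−6 for numerical stability; non-convergence and collinearity flag the
variable rather than failing). Drift-vs-risk sign agreement is tested by a
two-sided Fisher exact test of sign(μ̃_age) against the risk direction
(C-index dichotomy by default, β available). The composite score
b = μ̃_ageᵀz stratifies Kaplan–Meier survival by baseline quartile with a
log-rank ordering statistic; quartile ties break by a stable sort on
(score, id). Back-projection maps one natural variable's mean trajectory
onto observed biomarkers as P·ⱼ⟨zⱼ⟩(age), by default along the steady-state
line (slope P_kj·μ̃_age,j).

## Assessment

Bootstrap resampling operates on individuals (all visits travel together),
with out-of-bag individuals forming the test set; all candidate model forms
see identical seeded splits, so comparisons are paired. One-step prediction
errors (RMSE/MAE, pooled over all observed target entries — targets are
never imputed, only predictors, preventing leakage) are combined as
err_632 = 0.632·err_test + 0.368·err_train; 0.632 is the expected unique
fraction of a bootstrap resample. Parameter SEs are across-replicate SDs;
the default replicate count is 100 (reducible for desk-scale runs). Forms
are ranked by RMSE_632 with paired differences flagged at |diff| > 2 SE.

## Numerical and design notes

- Standardization uses the pooled all-visit sample with the n−1 SD;
  a first-visit ("baseline") reference is available. Scaling records allow
  exact inversion (round-trip tested at 1e−10).
- Eigenvalue order: least stable first (largest λ). Symmetry/diagonality
  tolerances 1e−8; transform round trips 1e−10.
- Post-event visits in input files are dropped and counted in an audit
  record, never imputed (they are treated as coding errors).
- A general non-symmetric W with complex eigenvalues is refused with advice
  to use PCA preprocessing, rather than silently taking real parts.
- The fit is fully deterministic given (cohort, config); all simulation and
  resampling randomness flows from explicit seeds.

## Known limitations and observed behavior

- **Slow-mode identifiability.** When a natural variable's recovery
  timescale exceeds the follow-up window (|λ|·T < 1), the regression cannot
  separate λz from μ_age·t (both trend), so μ̂_age for that mode is noisy —
  amplified further by the W⁻¹ factor in the Λ̂ estimator — and its sign can
  flip at moderate cohort sizes. The deviation-vs-drift correlation then
  weakens or changes sign while the memory term dominates the drift term:
  the package's short-follow-up simulations reproduce exactly this regime,
  and its equilibrated fast-rate simulations recover correlations near −1.
- **Finite-sample spectrum bias.** Eigenvalues of the fitted network carry a
  small finite-sample bias at n ≈ 500 (median absolute rate error ~0.005/yr,
  shrinking monotonically through n = 2000). The bootstrap does not remove
  it, since replicates share it.
- **Mortality selection.** With the hazard aligned to a drifting natural
  variable, survivor averages depart from the full-ensemble closed forms (a
  tested property), leaving an n-independent bias in fits on the observed
  survivors; imputing dead individuals mitigates but does not eliminate it.
- The model is population-level and linear; no nonlinear terms, no
  individual-level random effects, no informative censoring.

Simulation sizes used in the test suite (10,000 trajectories for the moment
oracle, n = 100–2000 for estimator recovery, n = 1000 cohorts for the
survival pipeline) were chosen as the smallest sizes at which the checked
quantities are statistically decisive at their 3-SE tolerances.
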
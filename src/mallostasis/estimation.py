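"""Fitting the network model to a longitudinal cohort.

The estimators are closed-form moment ratios over all consecutive-visit
transitions, pooled across individuals:

    Lambda-hat = <|dt| y x^T><|dt| x x^T>^-1
                 - W^-1 <sign(dt) (y' - y) x^T><|dt| x x^T>^-1
    W-hat      = <sign(dt) (y' - y)(y - mu)^T> (<|dt| (y - mu)(y - mu)^T>)^-1

with the full covariate vector x = (1, covariates, age), so the intercept
mu0 and the drift mu_age are recovered as named columns of Lambda. The two
estimators are applied alternately for a fixed number of iterations
(default 5), with missing entries re-imputed from the current model mean
after each pass. Principal-component rotation is available as preprocessing;
the rotated network is near-diagonal so each natural variable can also be
fit independently by |dt|-weighted linear regression ("diagonal" form).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .cohort import (
    AGE_COL,
    ID_COL,
    POST_EVENT_COL,
    LongitudinalCohort,
    TransitionPair,
    _individual_slices,
)
from .model import (
    AGE_COVARIATE,
    CONST_COL,
    ModelParameters,
    NaturalBasis,
    diagonalize,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "fit",
    "pca_preprocess",
    "estimate_W",
    "estimate_Lambda",
    "estimate_Sigma",
    "impute_carry",
    "impute_individual_mean",
    "impute_population_mvn_mean",
]


@dataclass
class FitConfig:
    """Options controlling the iterative maximum-likelihood fit."""

    n_iterations: int = 5
    preprocessing: str = "pca"  # "pca" | "none"
    model_form: str = "full"  # "full" | "diagonal" | "null"
    include_age_drift: bool = True
    imputation_ladder: tuple[str, ...] = ("carry", "model_mean")
    impute_dead: bool = False
    ridge: float | None = None  # None -> 1e-8 * trace/m of the inverted moment
    seed: int = 0  # unused: the fit is deterministic; kept for config parity

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.ridge is not None and self.ridge < 0:
            raise ValueError("ridge must be >= 0")
        if self.preprocessing not in ("pca", "none"):
            raise ValueError(f"unknown preprocessing {self.preprocessing!r}")
        if self.model_form not in ("full", "diagonal", "null"):
            raise ValueError(f"unknown model_form {self.model_form!r}")
        known = {"carry", "individual_mean", "population_mvn_mean", "model_mean"}
        bad = set(self.imputation_ladder) - known
        if bad:
            raise ValueError(f"unknown imputation rungs: {sorted(bad)}")


@dataclass
class FitResult:
    """Fitted parameters in the natural basis plus the transform from data.

    ``basis`` maps observed biomarkers to natural variables (z = P^-1 y);
    ``params`` is the model in that basis (diagonal W); ``params_observed``
    is the same model expressed on the observed biomarkers.
    """

    params: ModelParameters
    params_observed: ModelParameters
    basis: NaturalBasis
    change_log: list[dict]
    imputation_audit: dict[str, int]
    config: FitConfig
    completed_cohort: LongitudinalCohort  # fully imputed, observed basis

    @property
    def eigenvalues(self) -> np.ndarray:
        return self.basis.eigenvalues

    @property
    def recovery_rates(self) -> np.ndarray:
        return -self.basis.eigenvalues

    def natural_z(self, cohort: LongitudinalCohort | None = None) -> pd.DataFrame:
        """Per-visit natural-variable values (id, age, z1..zm)."""
        c = self.completed_cohort if cohort is None else cohort
        z = c.biomarker_matrix() @ self.basis.P_inv.T
        out = pd.DataFrame({ID_COL: c.data[ID_COL], AGE_COL: c.data[AGE_COL]})
        for j in range(z.shape[1]):
            out[f"z{j + 1}"] = z[:, j]
        return out

    def write_log(self, path) -> None:
        pd.DataFrame(self.change_log).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Pair arrays
# ---------------------------------------------------------------------------

def _pairs_to_arrays(pairs: list[TransitionPair]) -> dict[str, np.ndarray]:
    return {
        "y_from": np.array([p.y_from for p in pairs], float),
        "y_to": np.array([p.y_to for p in pairs], float),
        "x_from": np.array([p.x_from for p in pairs], float),
        "t_from": np.array([p.t_from for p in pairs], float),
        "dt": np.array([p.dt for p in pairs], float),
    }


def _cohort_pair_arrays(values: np.ndarray, cohort: LongitudinalCohort) -> dict[str, np.ndarray]:
    """Pair arrays built from a complete biomarker matrix aligned to cohort rows."""
    ids = cohort.data[ID_COL].to_numpy()
    t = cohort.data[AGE_COL].to_numpy(float)
    x = cohort.covariate_matrix()
    i_from, i_to = [], []
    for start, stop in _individual_slices(ids):
        i_from.extend(range(start, stop - 1))
        i_to.extend(range(start + 1, stop))
    i_from, i_to = np.array(i_from, int), np.array(i_to, int)
    return {
        "y_from": values[i_from],
        "y_to": values[i_to],
        "x_from": x[i_from],
        "t_from": t[i_from],
        "dt": t[i_to] - t[i_from],
        "i_from": i_from,
        "i_to": i_to,
    }


def _augment_x(arr: dict[str, np.ndarray], covariate_names: list[str]) -> np.ndarray:
    """(1, x, t) design rows in the order of ``covariate_names``."""
    n = len(arr["dt"])
    cols, k = [], 0
    for name in covariate_names:
        if name == CONST_COL:
            cols.append(np.ones(n))
        elif name == AGE_COVARIATE:
            cols.append(arr["t_from"])
        else:
            cols.append(arr["x_from"][:, k])
            k += 1
    return np.column_stack(cols)


def _auto_ridge(mat: np.ndarray, ridge: float | None) -> float:
    if ridge is not None:
        return ridge
    return 1e-8 * np.trace(mat) / mat.shape[0]


# ---------------------------------------------------------------------------
# Moment estimators
# ---------------------------------------------------------------------------

def _estimate_W_arrays(arr: dict, mu: np.ndarray, ridge: float | None) -> np.ndarray:
    dev = arr["y_from"] - mu
    dy = arr["y_to"] - arr["y_from"]
    s = np.sign(arr["dt"])[:, None]
    a = np.abs(arr["dt"])[:, None]
    num = (s * dy).T @ dev / len(dev)
    den = (a * dev).T @ dev / len(dev)
    r = _auto_ridge(den, ridge)
    if r == 0:
        cond = np.linalg.cond(den)
        if cond > 1e12:
            vals, vecs = np.linalg.eigh((den + den.T) / 2)
            weak = [i for i, v in enumerate(vals) if v < 1e-12 * max(vals.max(), 1.0)]
            raise np.linalg.LinAlgError(
                f"deviation moment matrix is singular along eigendirections {weak}; "
                "add ridge or provide deviations spanning all coordinates"
            )
    return num @ np.linalg.inv(den + r * np.eye(len(den)))


def estimate_W(
    pairs: list[TransitionPair], mu: np.ndarray, ridge: float | None = None
) -> np.ndarray:
    """Moment-ratio network estimate from transition pairs.

    ``mu`` is the per-pair equilibrium (one row per pair, evaluated at the
    starting visit).
    """
    return _estimate_W_arrays(_pairs_to_arrays(pairs), np.asarray(mu, float), ridge)


def _estimate_Lambda_arrays(
    arr: dict, xa: np.ndarray, W: np.ndarray, ridge: float | None
) -> np.ndarray:
    a = np.abs(arr["dt"])[:, None]
    s = np.sign(arr["dt"])[:, None]
    dy = arr["y_to"] - arr["y_from"]
    xx = (a * xa).T @ xa / len(xa)
    r = _auto_ridge(xx, ridge)
    xx_inv = np.linalg.inv(xx + r * np.eye(len(xx)))
    yx = (a * arr["y_from"]).T @ xa / len(xa)
    dyx = (s * dy).T @ xa / len(xa)
    try:
        W_inv = np.linalg.inv(W)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "W is singular; run more iterations or use the diagonal model form"
        ) from None
    return yx @ xx_inv - W_inv @ dyx @ xx_inv


def estimate_Lambda(
    pairs: list[TransitionPair],
    W: np.ndarray,
    covariate_names: list[str],
    ridge: float | None = None,
) -> np.ndarray:
    """Covariate-loading estimate given the current network W.

    Columns follow ``covariate_names`` (must contain "const"; "age" binds to
    the starting-visit age), so mu0 and mu_age come out as named columns.
    """
    arr = _pairs_to_arrays(pairs)
    xa = _augment_x(arr, covariate_names)
    return _estimate_Lambda_arrays(arr, xa, np.asarray(W, float), ridge)


def _estimate_Sigma_arrays(arr: dict, W: np.ndarray, mu: np.ndarray) -> np.ndarray:
    pred = arr["y_from"] + ((arr["y_from"] - mu) @ W.T) * arr["dt"][:, None]
    resid = arr["y_to"] - pred
    a = np.abs(arr["dt"])[:, None]
    S = (resid / a).T @ resid / len(resid)
    S = (S + S.T) / 2
    vals, vecs = np.linalg.eigh(S)
    return vecs @ np.diag(np.clip(vals, 0.0, None)) @ vecs.T


def estimate_Sigma(pairs: list[TransitionPair], params: ModelParameters) -> np.ndarray:
    """Residual-based noise covariance per unit time (symmetrized, PSD-clipped)."""
    arr = _pairs_to_arrays(pairs)
    xa = _augment_x(arr, params.covariate_names)
    mu = xa @ params.Lambda.T
    return _estimate_Sigma_arrays(arr, params.W, mu)


def _diagonal_wls(arr: dict, xa: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Coordinate-wise |dt|-weighted regression of dy/dt on (y, x).

    Model per coordinate: dy_j/dt = W_jj * y_j - W_jj * Lambda_j . x, so the
    regression slope on y_j is W_jj and the loadings are -coef_x / W_jj.
    Returns (diagonal of W, Lambda).
    """
    m = arr["y_from"].shape[1]
    c = xa.shape[1]
    w = np.sqrt(np.abs(arr["dt"]))
    rate = (arr["y_to"] - arr["y_from"]) / arr["dt"][:, None]
    W_diag = np.zeros(m)
    Lambda = np.zeros((m, c))
    for j in range(m):
        X = np.column_stack([arr["y_from"][:, j : j + 1], xa])
        coef, *_ = np.linalg.lstsq(X * w[:, None], rate[:, j] * w, rcond=None)
        W_diag[j] = coef[0]
        if abs(coef[0]) < 1e-12:
            Lambda[j] = 0.0
        else:
            Lambda[j] = -coef[1:] / coef[0]
    return W_diag, Lambda


# ---------------------------------------------------------------------------
# Imputation ladder
# ---------------------------------------------------------------------------

def impute_carry(cohort: LongitudinalCohort) -> LongitudinalCohort:
    """Last observation carried forward, then first carried back, per individual."""
    out = cohort.copy()
    g = out.data.groupby(ID_COL, sort=False)
    filled = g[out.biomarker_names].ffill()
    filled = filled.groupby(out.data[ID_COL], sort=False).bfill()
    out.data[out.biomarker_names] = filled
    return out


def impute_individual_mean(cohort: LongitudinalCohort) -> LongitudinalCohort:
    """Fill each missing entry with that individual's mean of observed values."""
    out = cohort.copy()
    means = out.data.groupby(ID_COL, sort=False)[out.biomarker_names].transform("mean")
    out.data[out.biomarker_names] = out.data[out.biomarker_names].fillna(means)
    return out


def _nearest_psd(S: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh((S + S.T) / 2)
    return vecs @ np.diag(np.clip(vals, 1e-12, None)) @ vecs.T


def impute_population_mvn_mean(cohort: LongitudinalCohort) -> LongitudinalCohort:
    """Conditional-Gaussian mean imputation per visit.

    Pooled mean and covariance are estimated from observed values (pairwise
    complete); each visit's missing block is filled with the conditional mean
    given that visit's observed entries. Visits with nothing observed get the
    pooled mean.
    """
    out = cohort.copy()
    df = out.data[out.biomarker_names]
    mu = df.mean().to_numpy(float)
    S = df.cov().to_numpy(float)
    if np.isnan(S).any():
        S = np.where(np.isnan(S), 0.0, S)
    vals = np.linalg.eigvalsh((S + S.T) / 2)
    if vals.min() < 0:
        warnings.warn("pooled covariance not PSD; projecting to nearest PSD", stacklevel=2)
        S = _nearest_psd(S)
    y = df.to_numpy(float)
    miss = np.isnan(y)
    patterns = {}
    for i in range(len(y)):
        if miss[i].any():
            patterns.setdefault(miss[i].tobytes(), []).append(i)
    for key, rows in patterns.items():
        mask = np.frombuffer(key, dtype=bool)
        o, mset = ~mask, mask
        if not o.any():
            y[np.ix_(rows, mset.nonzero()[0])] = mu[mset]
            continue
        Soo = S[np.ix_(o.nonzero()[0], o.nonzero()[0])]
        Smo = S[np.ix_(mset.nonzero()[0], o.nonzero()[0])]
        gain = Smo @ np.linalg.pinv(Soo)
        obs = y[np.ix_(rows, o.nonzero()[0])]
        y[np.ix_(rows, mset.nonzero()[0])] = mu[mset] + (obs - mu[o]) @ gain.T
    out.data[out.biomarker_names] = y
    return out


_LADDER_FUNCS = {
    "carry": impute_carry,
    "individual_mean": impute_individual_mean,
    "population_mvn_mean": impute_population_mvn_mean,
}


def _synthesize_post_event_visits(cohort: LongitudinalCohort) -> LongitudinalCohort:
    """Extend dead individuals past their event on their pre-death cadence.

    Synthetic visits carry NaN biomarkers (filled by model-mean imputation in
    the fit loop) and are flagged ``post_event``; the schedule continues at
    each individual's median inter-visit interval until the cohort's last
    observed age.
    """
    if cohort.events is None:
        return cohort
    out = cohort.copy()
    out.data[POST_EVENT_COL] = False
    horizon = float(out.data[AGE_COL].max())
    new_rows = []
    for iid, grp in out.data.groupby(ID_COL, sort=False):
        ev = out.events.loc[iid]
        if ev["event_status"] != 1:
            continue
        ages = grp[AGE_COL].to_numpy(float)
        cadence = float(np.median(np.diff(ages))) if len(ages) > 1 else 1.0
        t = ages[-1] + cadence
        while t <= horizon:
            row = {ID_COL: iid, AGE_COL: t, POST_EVENT_COL: True}
            for c in out.covariate_names:
                row[c] = grp[c].iloc[-1]
            for b in out.biomarker_names:
                row[b] = np.nan
            new_rows.append(row)
            t += cadence
    if new_rows:
        out.data = pd.concat([out.data, pd.DataFrame(new_rows)], ignore_index=True)
        out.data = out.data.sort_values([ID_COL, AGE_COL], kind="stable").reset_index(drop=True)
        out.validate()
    return out


# ---------------------------------------------------------------------------
# PCA preprocessing
# ---------------------------------------------------------------------------

def pca_preprocess(cohort: LongitudinalCohort) -> tuple[LongitudinalCohort, NaturalBasis]:
    """Orthogonal rotation to principal components of the pooled visits.

    Missing values are carry-imputed before computing the rotation (the model
    mean is not available at this stage). Components are ordered by
    decreasing variance; their stability ordering is established after
    fitting. The returned basis carries placeholder zero eigenvalues.
    """
    if cohort.n_visits < cohort.m:
        raise ValueError("fewer visits than biomarkers; PCA is underdetermined")
    work = impute_carry(cohort) if cohort.missing_mask().any() else cohort
    y = work.biomarker_matrix()
    if np.isnan(y).any():
        y = np.where(np.isnan(y), np.nanmean(y, axis=0), y)
    pca = PCA(n_components=cohort.m)
    pca.fit(y)
    P = pca.components_.T  # columns are PCs; orthogonal
    z = y @ P
    names = [f"pc{j + 1}" for j in range(cohort.m)]
    rotated = work.with_biomarkers(z, names)
    basis = NaturalBasis(P=P, eigenvalues=np.zeros(cohort.m), is_orthogonal=True)
    return rotated, basis


# ---------------------------------------------------------------------------
# The iterative fit
# ---------------------------------------------------------------------------

def fit(cohort: LongitudinalCohort, config: FitConfig | None = None) -> FitResult:
    """Iterative maximum-likelihood fit with in-loop imputation.

    The cohort should be standardized. Each iteration (fixed count, default
    5) re-imputes originally missing entries from the current model mean,
    then re-estimates Lambda and W. The fit is deterministic. Returns the
    model in the natural (eigen) basis together with the transform and the
    observed-basis parameters.
    """
    config = config or FitConfig()
    if config.impute_dead:
        cohort = _synthesize_post_event_visits(cohort)
    mask = cohort.missing_mask()
    audit = {"n_missing": int(mask.sum()), "n_synthetic_visits": 0}
    if POST_EVENT_COL in cohort.data.columns:
        audit["n_synthetic_visits"] = int(cohort.data[POST_EVENT_COL].sum())

    # ladder rungs before model_mean
    work = cohort
    for rung in config.imputation_ladder:
        if rung == "model_mean":
            break
        if work.missing_mask().any():
            work = _LADDER_FUNCS[rung](work)
            audit[f"filled_after_{rung}"] = int(mask.sum() - work.missing_mask().sum())
    y = work.biomarker_matrix()
    if np.isnan(y).any():  # biomarkers never observed for an individual
        y = np.where(np.isnan(y), 0.0, y)

    # optional PCA rotation of the fit space
    if config.preprocessing == "pca":
        pca = PCA(n_components=cohort.m)
        pca.fit(y)
        R = pca.components_.T  # y_fit = y @ R, orthogonal
    else:
        R = np.eye(cohort.m)

    cov_names = [CONST_COL] + list(cohort.covariate_names)
    if config.include_age_drift:
        cov_names.append(AGE_COVARIATE)
    fit_names = [f"pc{j + 1}" for j in range(cohort.m)] if config.preprocessing == "pca" else list(cohort.biomarker_names)

    model_mean_on = "model_mean" in config.imputation_ladder and mask.any()
    W = Lam = None
    change_log: list[dict] = []
    arr = None
    for it in range(config.n_iterations):
        v = y @ R
        arr = _cohort_pair_arrays(v, cohort)
        xa = _augment_x(arr, cov_names)
        W_prev, L_prev = W, Lam
        if config.model_form == "null":
            W = np.zeros((cohort.m, cohort.m))
            a = np.abs(arr["dt"])[:, None]
            xx = (a * xa).T @ xa / len(xa)
            r = _auto_ridge(xx, config.ridge)
            Lam = ((a * arr["y_from"]).T @ xa / len(xa)) @ np.linalg.inv(
                xx + r * np.eye(len(xx))
            )
        elif config.model_form == "diagonal":
            W_diag, Lam = _diagonal_wls(arr, xa)
            W = np.diag(W_diag)
        else:  # full: alternate Lambda/W to their joint fixed point, so the
            # outer iterations feed back only through imputation
            if W is None:
                W_diag, _ = _diagonal_wls(arr, xa)  # well-posed initialization
                W = np.diag(W_diag)
            for _ in range(100):
                Lam = _estimate_Lambda_arrays(arr, xa, W, config.ridge)
                mu = xa @ Lam.T
                W_new = _estimate_W_arrays(arr, mu, config.ridge)
                done = np.abs(W_new - W).max() < 1e-12
                W = W_new
                if done:
                    break
        if np.isnan(W).any() or np.isnan(Lam).any():
            raise FloatingPointError(f"NaN in parameters at iteration {it + 1}")
        change_log.append(
            {
                "iteration": it + 1,
                "max_dW": float(np.abs(W - W_prev).max()) if W_prev is not None else np.nan,
                "max_dLambda": float(np.abs(Lam - L_prev).max()) if L_prev is not None else np.nan,
            }
        )
        # model-mean re-imputation of the originally missing entries
        if model_mean_on and config.model_form != "null":
            v = y @ R
            arr_full = _cohort_pair_arrays(v, cohort)
            pred_v = v.copy()
            t_all = cohort.data[AGE_COL].to_numpy(float)
            x_all = cohort.covariate_matrix()
            xa_all = _augment_x(
                {"x_from": x_all, "t_from": t_all, "dt": np.zeros(len(t_all))}, cov_names
            )
            mu_all = xa_all @ Lam.T
            pred_v[:] = mu_all  # first visits: equilibrium mean
            i_from, i_to = arr_full["i_from"], arr_full["i_to"]
            dt = arr_full["dt"][:, None]
            pred_v[i_to] = v[i_from] + ((v[i_from] - mu_all[i_from]) @ W.T) * dt
            pred_y = pred_v @ R.T
            y[mask] = pred_y[mask]

    # final noise covariance from residuals
    v = y @ R
    arr = _cohort_pair_arrays(v, cohort)
    xa = _augment_x(arr, cov_names)
    mu = xa @ Lam.T
    Sigma = _estimate_Sigma_arrays(arr, W, mu)

    params_fit = ModelParameters(
        W=W, Lambda=Lam, Sigma=Sigma, biomarker_names=fit_names, covariate_names=cov_names
    )
    # express on the observed biomarkers, then diagonalize to natural variables
    W_obs = R @ W @ R.T
    asym = np.abs(W_obs - W_obs.T).max()
    if 0 < asym < 0.5 * max(np.abs(W_obs).max(), 1e-12):
        W_obs = (W_obs + W_obs.T) / 2  # near-symmetric after PCA rotation
    params_observed = ModelParameters(
        W=W_obs,
        Lambda=R @ Lam,
        Sigma=R @ Sigma @ R.T,
        biomarker_names=list(cohort.biomarker_names),
        covariate_names=cov_names,
    )
    if config.model_form == "null":
        basis = NaturalBasis(P=np.eye(cohort.m), eigenvalues=np.zeros(cohort.m), is_orthogonal=True)
        params_natural = params_observed
    else:
        basis, params_natural = diagonalize(params_observed)

    completed = cohort.with_biomarkers(y)
    return FitResult(
        params=params_natural,
        params_observed=params_observed,
        basis=basis,
        change_log=change_log,
        imputation_audit=audit,
        config=config,
        completed_cohort=completed,
    )
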
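"""Core mean-reverting network model and its closed-form analytics.

The model is a discrete-time linear stochastic process for a biomarker vector
y observed at unequally spaced ages t:

    y[n+1] = y[n] + W * dt * (y[n] - mu[n]) + eps,   eps ~ N(0, Sigma*|dt|)
    mu[n]  = mu0 + Lambda_cov * x[n] + mu_age * t[n]

W is the biomarker interaction network (per unit time), Sigma the noise
covariance per unit time, and the equilibrium mu drifts linearly with age at
rate mu_age ("allostasis"). The constant intercept mu0 and the age loading
mu_age are stored as named columns of the loading matrix Lambda, so the full
covariate vector is (1, x, t).

Eigen-decomposing W yields "natural variables" z = P^{-1} y whose mean
dynamics decouple: each z_j relaxes toward its own drifting equilibrium at
recovery rate -lambda_j. In one dimension the continuous-time (dt -> 0)
limit is an Ornstein-Uhlenbeck process with a moving mean, and the mean and
variance trajectories have the closed forms implemented below.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

CONST_COL = "const"
AGE_COVARIATE = "age"

__all__ = [
    "ModelParameters",
    "NaturalBasis",
    "AnalyticState",
    "equilibrium",
    "predict_step",
    "to_natural",
    "from_natural",
    "diagonalize",
    "mean_solution",
    "steady_state_mean",
    "steady_state_lag",
    "memory_drift",
    "variance_solution",
    "steady_state_variance",
    "recovery_fraction",
]

_LAMBDA_ZERO_TOL = 1e-12


# ---------------------------------------------------------------------------
# Parameter container
# ---------------------------------------------------------------------------

@dataclass
class ModelParameters:
    """W (m x m), Lambda (m x c) with named covariate columns, Sigma (m x m).

    ``covariate_names`` must contain ``"const"`` (the intercept mu0) and
    normally ``"age"`` (the drift mu_age); remaining columns are ordinary
    covariate loadings such as sex.
    """

    W: np.ndarray
    Lambda: np.ndarray
    Sigma: np.ndarray
    biomarker_names: list[str]
    covariate_names: list[str]

    def __post_init__(self) -> None:
        self.W = np.atleast_2d(np.asarray(self.W, float))
        self.Lambda = np.atleast_2d(np.asarray(self.Lambda, float))
        self.Sigma = np.atleast_2d(np.asarray(self.Sigma, float))
        m = len(self.biomarker_names)
        if self.W.shape != (m, m):
            raise ValueError(f"W must be {m}x{m}, got {self.W.shape}")
        if self.Sigma.shape != (m, m):
            raise ValueError(f"Sigma must be {m}x{m}, got {self.Sigma.shape}")
        if self.Lambda.shape != (m, len(self.covariate_names)):
            raise ValueError(
                f"Lambda must be {m}x{len(self.covariate_names)}, got {self.Lambda.shape}"
            )
        if CONST_COL not in self.covariate_names:
            raise ValueError("covariate_names must include 'const'")
        if not np.allclose(self.Sigma, self.Sigma.T, atol=1e-8):
            raise ValueError("Sigma must be symmetric")
        eig = np.linalg.eigvalsh((self.Sigma + self.Sigma.T) / 2)
        if eig.min() < -1e-8 * max(1.0, eig.max()):
            raise ValueError("Sigma must be positive semi-definite")

    @property
    def m(self) -> int:
        return len(self.biomarker_names)

    @property
    def mu0(self) -> np.ndarray:
        return self.Lambda[:, self.covariate_names.index(CONST_COL)]

    @property
    def mu_age(self) -> np.ndarray:
        if AGE_COVARIATE not in self.covariate_names:
            return np.zeros(self.m)
        return self.Lambda[:, self.covariate_names.index(AGE_COVARIATE)]

    @property
    def plain_covariates(self) -> list[str]:
        """Covariate names excluding the folded constant and age columns."""
        return [c for c in self.covariate_names if c not in (CONST_COL, AGE_COVARIATE)]

    def augment(self, x: np.ndarray, t) -> np.ndarray:
        """Build full covariate vector(s) (1, x, t) in Lambda's column order."""
        x = np.atleast_2d(np.asarray(x, float))
        t = np.atleast_1d(np.asarray(t, float))
        n = max(x.shape[0], t.shape[0])
        if x.shape[0] == 1 and n > 1:
            x = np.repeat(x, n, axis=0)
        if t.shape[0] == 1 and n > 1:
            t = np.repeat(t, n)
        if x.shape[1] != len(self.plain_covariates):
            raise ValueError(
                f"expected {len(self.plain_covariates)} covariates, got {x.shape[1]}"
            )
        cols = []
        plain_iter = iter(range(x.shape[1]))
        for name in self.covariate_names:
            if name == CONST_COL:
                cols.append(np.ones(n))
            elif name == AGE_COVARIATE:
                cols.append(t)
            else:
                cols.append(x[:, next(plain_iter)])
        return np.column_stack(cols)

    # -- plain-text serialization ----------------------------------------
    def to_text(self, path: str | Path) -> None:
        lines = [
            "# model parameter file",
            "biomarkers: " + ",".join(self.biomarker_names),
            "covariates: " + ",".join(self.covariate_names),
        ]
        for label, mat in (("W", self.W), ("Lambda", self.Lambda), ("Sigma", self.Sigma)):
            lines.append(f"[{label}]")
            for row in mat:
                lines.append(" ".join(repr(float(v)) for v in row))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_text(cls, path: str | Path) -> "ModelParameters":
        lines = [ln for ln in Path(path).read_text().splitlines() if ln and not ln.startswith("#")]
        names = lines[0].split(": ", 1)[1].split(",")
        covs = lines[1].split(": ", 1)[1].split(",")
        blocks: dict[str, list[list[float]]] = {}
        current = None
        for ln in lines[2:]:
            if ln.startswith("["):
                current = ln.strip("[]")
                blocks[current] = []
            else:
                blocks[current].append([float(v) for v in ln.split()])
        return cls(
            W=np.array(blocks["W"]),
            Lambda=np.array(blocks["Lambda"]),
            Sigma=np.array(blocks["Sigma"]),
            biomarker_names=names,
            covariate_names=covs,
        )


# ---------------------------------------------------------------------------
# One-step model
# ---------------------------------------------------------------------------

def equilibrium(params: ModelParameters, x: np.ndarray, t) -> np.ndarray:
    """Equilibrium position mu(x, t) = mu0 + Lambda x + mu_age t.

    ``x`` holds the plain covariates (no constant, no age). Accepts a single
    vector or a stack of rows; returns matching shape.
    """
    single = np.asarray(x).ndim <= 1 and np.ndim(t) == 0
    xa = params.augment(x, t)
    mu = xa @ params.Lambda.T
    return mu[0] if single else mu


def predict_step(params: ModelParameters, y, x, t, dt) -> np.ndarray:
    """Conditional mean of the next observation: y + W dt (y - mu(x, t))."""
    y = np.asarray(y, float)
    single = y.ndim == 1
    mu = equilibrium(params, x, t)
    dt = np.asarray(dt, float)
    if not np.all(np.isfinite(dt)):
        raise ValueError("dt must be finite")
    dev = np.atleast_2d(y) - np.atleast_2d(mu)
    step = (dev @ params.W.T) * np.atleast_1d(dt)[:, None]
    out = np.atleast_2d(y) + step
    return out[0] if single else out


# ---------------------------------------------------------------------------
# Natural variables
# ---------------------------------------------------------------------------

@dataclass
class NaturalBasis:
    """Eigenvector transform P with eigenvalues sorted least-stable first.

    z = P^{-1} y; index 0 is the least stable natural variable (largest
    eigenvalue, i.e. smallest recovery rate -lambda).
    """

    P: np.ndarray
    eigenvalues: np.ndarray
    is_orthogonal: bool = False

    def __post_init__(self) -> None:
        self.P = np.atleast_2d(np.asarray(self.P, float))
        self.eigenvalues = np.asarray(self.eigenvalues, float)
        if abs(np.linalg.det(self.P)) < 1e-12:
            raise ValueError("P is singular")
        if self.is_orthogonal and not np.allclose(self.P.T @ self.P, np.eye(len(self.P)), atol=1e-8):
            raise ValueError("P flagged orthogonal but P^T P != I")
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be sorted descending (least stable first)")

    @property
    def m(self) -> int:
        return self.P.shape[0]

    @property
    def P_inv(self) -> np.ndarray:
        return self.P.T if self.is_orthogonal else np.linalg.inv(self.P)

    @property
    def recovery_rates(self) -> np.ndarray:
        return -self.eigenvalues


def to_natural(basis: NaturalBasis, y: np.ndarray) -> np.ndarray:
    """z = P^{-1} y (vector, or rows of a matrix)."""
    y = np.asarray(y, float)
    return y @ basis.P_inv.T


def from_natural(basis: NaturalBasis, z: np.ndarray) -> np.ndarray:
    """y = P z."""
    z = np.asarray(z, float)
    return z @ basis.P.T


def diagonalize(params: ModelParameters) -> tuple[NaturalBasis, ModelParameters]:
    """Eigen-decompose W; return the natural basis and transformed parameters.

    For symmetric W (guaranteed after PCA preprocessing) the basis is
    orthogonal. A non-symmetric W with complex eigenvalues is refused:
    rotate the data to principal components first.
    """
    W = params.W
    symmetric = np.allclose(W, W.T, atol=1e-8 * max(1.0, np.abs(W).max()))
    if symmetric:
        vals, vecs = np.linalg.eigh((W + W.T) / 2)
        orth = True
    else:
        vals, vecs = np.linalg.eig(W)
        if np.abs(vals.imag).max() > 1e-10 * max(1.0, np.abs(vals).max()):
            raise ValueError(
                "W has complex eigenvalues; use PCA preprocessing to obtain a "
                "symmetric network before diagonalizing"
            )
        vals, vecs = vals.real, vecs.real
        orth = False
    order = np.argsort(-vals, kind="stable")  # least stable (largest lambda) first
    vals, vecs = vals[order], vecs[:, order]
    basis = NaturalBasis(P=vecs, eigenvalues=vals, is_orthogonal=orth)
    P_inv = basis.P_inv
    transformed = ModelParameters(
        W=np.diag(vals),
        Lambda=P_inv @ params.Lambda,
        Sigma=P_inv @ params.Sigma @ P_inv.T,
        biomarker_names=[f"z{j + 1}" for j in range(params.m)],
        covariate_names=list(params.covariate_names),
    )
    return basis, transformed


# ---------------------------------------------------------------------------
# Closed-form scalar analytics (one natural variable)
# ---------------------------------------------------------------------------

@dataclass
class AnalyticState:
    """Scalars of one natural variable's mean/variance trajectory.

    ``z0_mean``/``z0_var`` are the ensemble mean and variance at the
    reference age ``t0`` (default 0); ``mu0`` is the equilibrium intercept
    such that mu(t) = mu0 + mu_age * t at absolute age t.
    """

    lam: float
    mu0: float
    mu_age: float
    z0_mean: float
    z0_var: float
    sigma2: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")
        if self.z0_var < 0:
            raise ValueError("z0_var must be >= 0")

    def mu(self, t) -> float:
        return self.mu0 + self.mu_age * np.asarray(t, float)


def mean_solution(state: AnalyticState, t) -> np.ndarray | float:
    """Ensemble mean <z>(t) of the drifting mean-reverting process.

    General solution of d<z>/dt = lam * (<z> - mu(t)). At lam == 0 the drift
    term exerts no pull and the mean stays at its initial value.
    """
    t = np.asarray(t, float)
    dt = t - state.t0
    if abs(state.lam) < _LAMBDA_ZERO_TOL:
        out = np.broadcast_to(state.z0_mean, t.shape).copy() if t.ndim else state.z0_mean
        return out
    lag = state.mu_age / state.lam
    mu_t0 = state.mu(state.t0)
    out = (state.z0_mean - lag - mu_t0) * np.exp(state.lam * dt) + lag + mu_t0 + state.mu_age * dt
    return float(out) if t.ndim == 0 else out


def steady_state_mean(state: AnalyticState, t) -> np.ndarray | float:
    """Long-time mean mu(t) + mu_age/lam, valid for stable lam < 0."""
    if state.lam >= 0:
        raise ValueError("steady state requires lam < 0")
    t = np.asarray(t, float)
    out = state.mu_age / state.lam + state.mu(t)
    return float(out) if t.ndim == 0 else out


def steady_state_lag(state: AnalyticState) -> float:
    """Constant steady-state offset <z - mu> = mu_age / lam (lam < 0)."""
    if state.lam >= 0:
        raise ValueError("steady state requires lam < 0")
    return state.mu_age / state.lam


def memory_drift(state: AnalyticState, t: float, t0: float, observed_dev_at_t0: float) -> tuple[float, float]:
    """Split the predicted deviation <z - mu>(t) into memory and drift terms.

    memory = dev(t0) * exp(lam (t - t0)) carries the initial condition;
    drift = (mu_age/lam) * (1 - exp(lam (t - t0))) is the pull of the moving
    equilibrium. Their sum is the predicted deviation at t.
    """
    if t < t0:
        raise ValueError("t must be >= t0")
    decay = float(np.exp(state.lam * (t - t0)))
    memory = observed_dev_at_t0 * decay
    if abs(state.lam) < _LAMBDA_ZERO_TOL:
        # lam -> 0 limit of (mu_age/lam)(1 - e^{lam d}) is -mu_age * d
        drift = -state.mu_age * (t - t0)
    else:
        drift = (state.mu_age / state.lam) * (1.0 - decay)
    return memory, drift


def variance_solution(state: AnalyticState, t) -> np.ndarray | float:
    """Ensemble variance Var(z)(t): solution of dVar/dt = 2 lam Var + sigma2."""
    t = np.asarray(t, float)
    dt = t - state.t0
    if abs(state.lam) < _LAMBDA_ZERO_TOL:
        out = state.z0_var + state.sigma2 * dt
    else:
        grow = np.exp(2.0 * state.lam * dt)
        out = state.z0_var * grow - state.sigma2 / (2.0 * state.lam) * (1.0 - grow)
    return float(out) if t.ndim == 0 else out


def steady_state_variance(state: AnalyticState) -> float:
    """Equilibrated variance sigma2 / (2 |lam|), for stable lam < 0."""
    if state.lam >= 0:
        raise ValueError("steady-state variance requires lam < 0")
    return state.sigma2 / (2.0 * abs(state.lam))


def recovery_fraction(rate: float, elapsed: float) -> float:
    """Fraction of an initial deviation recovered after ``elapsed`` time.

    A rate of 0.025/yr implies 63% recovery after the characteristic
    timescale 1/rate = 40 yr, and 95% after three timescales.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if elapsed < 0:
        raise ValueError("elapsed must be >= 0")
    return 1.0 - float(np.exp(-rate * elapsed))
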
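"""Maximum-likelihood skew-normal regression per voxel (CP form).

Each voxel's across-subject distribution is modelled as skew-normal in the
centred parameterisation with a linear model on the mean only:

    mu_i(v) = x_i' beta(v),   x_i = (1, age_i, sex_i, age_i * sex_i),

with a common sigma(v) and gamma(v) across subjects.  Sex is coded female=1,
male=0, so the ``age`` coefficient is the male age slope and age+interaction
the female slope.  The likelihood is maximised with a quasi-Newton optimiser
on the unconstrained parameterisation (beta, log sigma, atanh(gamma/g_max))
with g_max = 0.99 * c_gamma, keeping iterates strictly inside the skewness
bound.  Fits that fail after random restarts fall back to the normal (gamma=0)
ordinary-least-squares solution, flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .skewnorm import C_GAMMA, cp_to_dp_arrays, sn_logpdf_dp

__all__ = [
    "DESIGN_COLUMNS",
    "GAMMA_MAX",
    "VoxelFit",
    "ParamMaps",
    "build_design",
    "loglik_cp",
    "init_params",
    "fit_sn_regression",
    "fit_grid",
]

DESIGN_COLUMNS = ("intercept", "age", "sex", "age_sex")
PARAM_NAMES = ("beta0", "beta_age", "beta_sex", "beta_age_sex", "sigma", "gamma")

# fitting keeps gamma strictly interior to the CP bound
GAMMA_MAX = 0.99 * C_GAMMA
_GAMMA_INIT_CLIP = 0.95 * C_GAMMA


@dataclass
class VoxelFit:
    """Result of one voxel's skew-normal regression."""

    beta: np.ndarray          # (4,) mean coefficients
    sigma: float
    gamma: float
    converged: bool
    loglik: float
    clipped: bool = False     # gamma ended on the +-0.99*c_gamma boundary
    normal_fallback: bool = False

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (4,):
            raise ValueError("beta must have 4 coefficients")
        if not (self.sigma > 0):
            raise ValueError("sigma must be positive")
        if not (abs(self.gamma) < C_GAMMA):
            raise ValueError("gamma outside the skew-normal bound")


@dataclass
class ParamMaps:
    """Per-voxel parameter maps over an index set (grid centres or full mask).

    ``coords`` are 0-based voxel indices (V, 3); ``beta`` is (V, 4) in the
    order of :data:`DESIGN_COLUMNS`; ``sigma``/``gamma`` are (V,).  The same
    container serves both the sparse grid fit and the interpolated full-mask
    parameter functions.
    """

    coords: np.ndarray
    shape: tuple
    voxel_size_mm: float
    beta: np.ndarray
    sigma: np.ndarray
    gamma: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=int)
        self.beta = np.asarray(self.beta, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        v = len(self.coords)
        if self.beta.shape != (v, 4) or self.sigma.shape != (v,) or self.gamma.shape != (v,):
            raise ValueError("parameter arrays must share the coordinate index set")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma map must be strictly positive")
        if np.any(np.abs(self.gamma) >= C_GAMMA):
            raise ValueError("gamma map must stay inside the skewness bound")

    @property
    def n_voxels(self) -> int:
        return len(self.coords)

    def param(self, name: str) -> np.ndarray:
        if name == "sigma":
            return self.sigma
        if name == "gamma":
            return self.gamma
        idx = {"beta0": 0, "beta_age": 1, "beta_sex": 2, "beta_age_sex": 3}[name]
        return self.beta[:, idx]

    def to_volume(self, name: str, fill=np.nan) -> np.ndarray:
        """Scatter one parameter into a full 3D array (``fill`` elsewhere)."""
        vol = np.full(self.shape, fill, dtype=float)
        i, j, k = self.coords.T
        vol[i, j, k] = self.param(name)
        return vol


# ---------------------------------------------------------------------------
# Design matrix and likelihood
# ---------------------------------------------------------------------------

def build_design(cov: pd.DataFrame) -> np.ndarray:
    """Four-column design: intercept, age, sex (female=1), age*sex.

    Row order follows the table.  Missing or non-finite covariates raise with
    the offending subject ids.
    """
    required = {"age", "sex"}
    missing_cols = required - set(cov.columns)
    if missing_cols:
        raise ValueError(f"covariate table lacks columns: {sorted(missing_cols)}")
    age = pd.to_numeric(cov["age"], errors="coerce").to_numpy(dtype=float)
    sex = pd.to_numeric(cov["sex"], errors="coerce").to_numpy(dtype=float)
    bad = ~np.isfinite(age) | ~np.isfinite(sex)
    if bad.any():
        ids = (
            cov["subject_id"].to_numpy()[bad].tolist()
            if "subject_id" in cov.columns
            else np.flatnonzero(bad).tolist()
        )
        raise ValueError(f"missing/invalid covariates for subjects: {ids}")
    if np.any(age <= 0):
        raise ValueError("ages must be strictly positive")
    return np.column_stack([np.ones_like(age), age, sex, age * sex])


def loglik_cp(beta, sigma: float, gamma: float, y, X) -> float:
    """CP log-likelihood of a linear-mean skew-normal regression."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")
    resid = y - X @ np.asarray(beta, dtype=float)
    # residuals follow CP(0, sigma, gamma)
    xi0, omega, alpha = cp_to_dp_arrays(0.0, sigma, gamma)
    return float(np.sum(sn_logpdf_dp(resid, xi0, omega, alpha)))


def _check_full_rank(X: np.ndarray) -> None:
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # name the collinear columns via the QR diagonal
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [DESIGN_COLUMNS[j] for j in np.flatnonzero(diag < 1e-8 * diag.max())]
        raise ValueError(f"design matrix is rank deficient (collinear columns: {bad})")


def init_params(y, X) -> VoxelFit:
    """OLS starting values: beta = OLS, sigma = residual SD, gamma = clipped
    moment skewness of the residuals (|gamma| <= 0.95*c_gamma)."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if len(y) <= X.shape[1]:
        raise ValueError("need more observations than mean parameters")
    _check_full_rank(X)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sigma = float(resid.std(ddof=0))
    scale = max(float(np.abs(y).max()), 1.0)
    if not np.isfinite(sigma) or sigma <= 1e-10 * scale:
        raise ValueError("degenerate residual variance: y is exactly linear in X")
    gamma = float(np.clip(stats.skew(resid), -_GAMMA_INIT_CLIP, _GAMMA_INIT_CLIP))
    ll = loglik_cp(beta, sigma, gamma, y, X)
    return VoxelFit(beta=beta, sigma=sigma, gamma=gamma, converged=False, loglik=ll)


# ---------------------------------------------------------------------------
# Optimisation
# ---------------------------------------------------------------------------

def _unpack(theta):
    beta = theta[:4]
    sigma = float(np.exp(theta[4]))
    gamma = float(GAMMA_MAX * np.tanh(theta[5]))
    return beta, sigma, gamma


def _nll(theta, y, X):
    beta, sigma, gamma = _unpack(theta)
    resid = y - X @ beta
    xi0, omega, alpha = cp_to_dp_arrays(0.0, sigma, gamma)
    val = -np.sum(sn_logpdf_dp(resid, xi0, omega, alpha))
    return val if np.isfinite(val) else 1e300


def fit_sn_regression(
    y,
    X,
    *,
    max_iter: int = 500,
    tol: float = 1e-8,
    restarts: int = 2,
    seed: int = 0,
) -> VoxelFit:
    """Maximum-likelihood CP skew-normal regression for one voxel.

    Quasi-Newton (L-BFGS-B) on the unconstrained parameterisation; on
    failure, up to ``restarts`` jittered re-initialisations; final fallback
    is the normal (gamma=0) OLS solution with ``normal_fallback`` set.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    start = init_params(y, X)

    def theta_of(fitv: VoxelFit, jitter: np.ndarray | None = None) -> np.ndarray:
        g = np.clip(fitv.gamma, -_GAMMA_INIT_CLIP, _GAMMA_INIT_CLIP)
        th = np.concatenate(
            [fitv.beta, [np.log(fitv.sigma)], [np.arctanh(g / GAMMA_MAX)]]
        )
        return th if jitter is None else th + jitter

    rng = np.random.default_rng(seed)
    best = None
    for attempt in range(restarts + 1):
        jit = None if attempt == 0 else rng.normal(scale=0.1, size=6)
        res = optimize.minimize(
            _nll,
            theta_of(start, jit),
            args=(y, X),
            method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
        if res.success and np.isfinite(res.fun):
            best = res
            break

    beta, sigma, gamma = _unpack(best.x)
    ll = -float(best.fun)
    converged = bool(best.success) and ll >= start.loglik - 1e-6
    if not np.isfinite(ll) or sigma <= 0 or not converged:
        # normal fallback: OLS with gamma = 0
        ols = init_params(y, X)
        ll0 = loglik_cp(ols.beta, ols.sigma, 0.0, y, X)
        return VoxelFit(
            beta=ols.beta,
            sigma=ols.sigma,
            gamma=0.0,
            converged=False,
            loglik=ll0,
            normal_fallback=True,
        )
    clipped = bool(abs(gamma) >= GAMMA_MAX * np.tanh(6.0))
    if clipped:
        gamma = float(np.sign(gamma) * GAMMA_MAX)
    return VoxelFit(
        beta=beta, sigma=sigma, gamma=gamma, converged=converged,
        loglik=ll, clipped=clipped,
    )


def fit_grid(values, X, grid) -> ParamMaps:
    """Fit one skew-normal regression per grid voxel.

    ``values`` is (n_subjects, V*) with column order matching
    ``grid.coords``.  Voxels are independent; per-voxel failures are logged in
    the metadata, never fatal.
    """
    values = np.asarray(values, dtype=float)
    X = np.asarray(X, dtype=float)
    v_star = len(grid.coords)
    if v_star == 0:
        raise ValueError("empty grid")
    if values.ndim != 2 or values.shape[1] != v_star:
        raise ValueError("values must be (n_subjects, n_grid_voxels)")
    if not np.all(np.isfinite(values)):
        raise ValueError("every grid voxel needs a finite value for every subject")

    beta = np.empty((v_star, 4))
    sigma = np.empty(v_star)
    gamma = np.empty(v_star)
    n_fallback = n_clipped = n_nonconv = 0
    for j in range(v_star):
        fit = fit_sn_regression(values[:, j], X, seed=j)
        beta[j] = fit.beta
        sigma[j] = fit.sigma
        gamma[j] = fit.gamma
        n_fallback += fit.normal_fallback
        n_clipped += fit.clipped
        n_nonconv += not fit.converged
    meta = {
        "n_subjects": int(values.shape[0]),
        "n_grid_voxels": int(v_star),
        "n_normal_fallback": int(n_fallback),
        "n_gamma_clipped": int(n_clipped),
        "n_not_converged": int(n_nonconv),
        "sex_coding": "female=1, male=0",
        "design_columns": list(DESIGN_COLUMNS),
    }
    return ParamMaps(
        coords=grid.coords,
        shape=grid.shape,
        voxel_size_mm=grid.voxel_size_mm,
        beta=beta,
        sigma=sigma,
        gamma=gamma,
        meta=meta,
    )
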
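"""Skew-normal distribution in direct (DP) and centred (CP) parameterisations.

The skew-normal extends the normal distribution with a shape parameter
controlling asymmetry.  In the direct parameterisation (DP) the density is

    f(x; xi, omega, alpha) = (2/omega) * phi(z) * Phi(alpha * z),
    z = (x - xi) / omega,

with location ``xi``, scale ``omega > 0`` and shape ``alpha``.  The centred
parameterisation (CP) re-expresses the same distribution through its first
three moments — mean ``mu``, standard deviation ``sigma`` and standardised
third-moment skewness ``gamma`` — which are the quantities a normative model
actually interprets.  The moment skewness of a skew-normal is bounded:
|gamma| < c_gamma = sqrt(2) * (4 - pi) / (pi - 2)**1.5 ~= 0.9953.

All CDF evaluations go through Owen's T function, which is exact and fast
enough for whole-brain voxel maps; quantiles are obtained by vectorised
bisection with Newton polishing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = [
    "CPParams",
    "DPParams",
    "skewness_bound",
    "C_GAMMA",
    "cp_to_dp",
    "dp_to_cp",
    "sn_pdf",
    "sn_logpdf",
    "sn_cdf",
    "sn_quantile",
    "sample_sn",
]

# E|Z| factor for a standard normal: b = sqrt(2/pi)
_B = np.sqrt(2.0 / np.pi)


def skewness_bound() -> float:
    """Supremum of |gamma| attainable by a skew-normal (|alpha| -> inf)."""
    return float(np.sqrt(2.0) * (4.0 - np.pi) / (np.pi - 2.0) ** 1.5)


C_GAMMA: float = skewness_bound()


@dataclass(frozen=True)
class CPParams:
    """Centred parameterisation: mean, standard deviation, moment skewness."""

    mu: float
    sigma: float
    gamma: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu):
            raise ValueError("mu must be finite")
        if not (self.sigma > 0):
            raise ValueError("sigma must be positive")
        if not (abs(self.gamma) < C_GAMMA):
            raise ValueError(
                f"|gamma| must be strictly below the skew-normal bound "
                f"c_gamma = {C_GAMMA:.6f}; got {self.gamma}"
            )


@dataclass(frozen=True)
class DPParams:
    """Direct parameterisation: location xi, scale omega, shape alpha."""

    xi: float
    omega: float
    alpha: float

    def __post_init__(self) -> None:
        if not (self.omega > 0):
            raise ValueError("omega must be positive")


# ---------------------------------------------------------------------------
# CP <-> DP bijection (array-level primitives + dataclass wrappers)
# ---------------------------------------------------------------------------

def _gamma_to_muz(gamma):
    """Map moment skewness to mu_z = b*delta (mean of the standardised SN)."""
    gamma = np.asarray(gamma, dtype=float)
    t = np.cbrt(2.0 * gamma / (4.0 - np.pi))
    return t / np.sqrt(1.0 + t * t)


def cp_to_dp_arrays(mu, sigma, gamma):
    """Vectorised CP -> DP.  Inputs broadcast; returns (xi, omega, alpha)."""
    mu, sigma, gamma = np.broadcast_arrays(
        np.asarray(mu, float), np.asarray(sigma, float), np.asarray(gamma, float)
    )
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    if np.any(np.abs(gamma) >= C_GAMMA):
        raise ValueError(
            f"|gamma| must be strictly below c_gamma = {C_GAMMA:.6f}"
        )
    muz = _gamma_to_muz(gamma)
    delta = muz / _B
    alpha = delta / np.sqrt(1.0 - delta * delta)
    omega = sigma / np.sqrt(1.0 - muz * muz)
    xi = mu - omega * muz
    return xi, omega, alpha


def dp_to_cp_arrays(xi, omega, alpha):
    """Vectorised DP -> CP.  Returns (mu, sigma, gamma)."""
    xi, omega, alpha = np.broadcast_arrays(
        np.asarray(xi, float), np.asarray(omega, float), np.asarray(alpha, float)
    )
    if np.any(omega <= 0):
        raise ValueError("omega must be positive")
    delta = alpha / np.sqrt(1.0 + alpha * alpha)
    muz = _B * delta
    sigma = omega * np.sqrt(1.0 - muz * muz)
    mu = xi + omega * muz
    gamma = 0.5 * (4.0 - np.pi) * muz ** 3 / (1.0 - muz * muz) ** 1.5
    return mu, sigma, gamma


def cp_to_dp(cp: CPParams) -> DPParams:
    xi, omega, alpha = cp_to_dp_arrays(cp.mu, cp.sigma, cp.gamma)
    return DPParams(float(xi), float(omega), float(alpha))


def dp_to_cp(dp: DPParams) -> CPParams:
    mu, sigma, gamma = dp_to_cp_arrays(dp.xi, dp.omega, dp.alpha)
    return CPParams(float(mu), float(sigma), float(gamma))


# ---------------------------------------------------------------------------
# Density / CDF / quantile / sampling
# ---------------------------------------------------------------------------

def sn_logpdf_dp(x, xi, omega, alpha):
    z = (np.asarray(x, float) - xi) / omega
    return (
        np.log(2.0) - np.log(omega) + stats.norm.logpdf(z) + stats.norm.logcdf(alpha * z)
    )


def sn_cdf_dp(x, xi, omega, alpha):
    """DP CDF: Phi(z) - 2*T(z, alpha), with Owen's T."""
    z = (np.asarray(x, float) - xi) / omega
    out = stats.norm.cdf(z) - 2.0 * special.owens_t(z, alpha)
    # Owen's T round-off can push values a hair outside [0, 1].
    return np.clip(out, 0.0, 1.0)


def _cp_dp(cp: CPParams):
    return cp_to_dp_arrays(cp.mu, cp.sigma, cp.gamma)


def sn_pdf(x, cp: CPParams):
    """Density at ``x`` for a skew-normal given in CP."""
    xi, omega, alpha = _cp_dp(cp)
    return np.exp(sn_logpdf_dp(x, xi, omega, alpha))


def sn_logpdf(x, cp: CPParams):
    xi, omega, alpha = _cp_dp(cp)
    return sn_logpdf_dp(x, xi, omega, alpha)


def sn_cdf(x, cp: CPParams):
    """CDF at ``x`` for a skew-normal given in CP; maps +-inf to 1/0."""
    xi, omega, alpha = _cp_dp(cp)
    return sn_cdf_dp(x, xi, omega, alpha)


def sn_quantile_arrays(p, mu, sigma, gamma):
    """Vectorised quantile for CP arrays (all broadcastable).

    Bisection on [mu - 12 sigma, mu + 12 sigma] (the CP mean/SD bound the
    support region at any valid gamma) followed by Newton polishing; accuracy
    well below 1e-9 in probability.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("p must lie strictly inside (0, 1)")
    xi, omega, alpha = cp_to_dp_arrays(mu, sigma, gamma)
    p, xi, omega, alpha = np.broadcast_arrays(p, xi, omega, alpha)
    sig = np.broadcast_to(np.asarray(sigma, float), p.shape)
    muv = np.broadcast_to(np.asarray(mu, float), p.shape)
    lo = muv - 12.0 * sig
    hi = muv + 12.0 * sig
    lo, hi = lo.copy(), hi.copy()
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        under = sn_cdf_dp(mid, xi, omega, alpha) < p
        lo = np.where(under, mid, lo)
        hi = np.where(under, hi, mid)
    x = 0.5 * (lo + hi)
    for _ in range(3):  # Newton polish
        f = sn_cdf_dp(x, xi, omega, alpha) - p
        dens = np.exp(sn_logpdf_dp(x, xi, omega, alpha))
        step = np.where(dens > 0, f / np.maximum(dens, 1e-300), 0.0)
        x = np.clip(x - step, lo, hi)
    return x


def sn_quantile(p, cp: CPParams):
    """Quantile function of a CP skew-normal; ``p`` strictly in (0, 1)."""
    return sn_quantile_arrays(p, cp.mu, cp.sigma, cp.gamma)


def sample_sn(n: int, cp: CPParams, seed: int) -> np.ndarray:
    """Draw ``n`` variates via the two-normal representation.

    X = xi + omega * (delta*|Z0| + sqrt(1-delta^2)*Z1) with Z0, Z1 iid N(0,1)
    has the skew-normal DP(xi, omega, alpha) law, delta = alpha/sqrt(1+alpha^2).
    Deterministic for a given seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    xi, omega, alpha = _cp_dp(cp)
    delta = alpha / np.sqrt(1.0 + alpha * alpha)
    rng = np.random.default_rng(seed)
    z0 = rng.standard_normal(n)
    z1 = rng.standard_normal(n)
    return xi + omega * (delta * np.abs(z0) + np.sqrt(1.0 - delta * delta) * z1)


def sample_sn_dp_arrays(xi, omega, alpha, size, rng: np.random.Generator):
    """Array sampling used by the phantom: broadcasts DP params over ``size``."""
    delta = alpha / np.sqrt(1.0 + alpha * alpha)
    z0 = rng.standard_normal(size)
    z1 = rng.standard_normal(size)
    return xi + omega * (delta * np.abs(z0) + np.sqrt(1.0 - delta * delta) * z1)
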
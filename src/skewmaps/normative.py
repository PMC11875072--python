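"""Normative transforms: latent-uniform maps, z-maps, quantile curves and
tail deviation scores.

Given fitted parameter functions (mu as a linear function of age, sex and
their interaction; sigma; gamma), a subject's image Y is referenced to the
normative population by the probability integral transform

    U(v) = F_SN(Y(v); mu(v), sigma(v), gamma(v)),    z(v) = Phi^-1(U(v)).

U(v) = 0.5 marks the population median; a z of 3 carries the same tail
probability at every voxel regardless of the local (mu, sigma, gamma).  A
subject-level deviation index u_q^abs summarises the z-map as the mean of the
absolute z-values strictly above their empirical q-quantile (default
q = 0.9999, i.e. the top 0.01% of |z|).

Two routes to a full-mask z-map are provided: transform every voxel through
interpolated parameter maps (``compute_u``/``compute_z``; the default used for
scoring) or compute z only at grid voxels and RBF-interpolate the z-field
itself (``zmaps_via_grid``).  The interpolated-z route assumes the z-field is
spatially smooth; on data with little spatial noise correlation the parameter
route is the calibrated one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .rbf import GridSpec, interpolate_field
from .skewnorm import cp_to_dp_arrays, sn_cdf_dp, sn_quantile_arrays
from .voxelfit import ParamMaps, build_design

__all__ = [
    "U_CLIP",
    "DeviationIndex",
    "predicted_mean",
    "compute_u",
    "compute_z",
    "zmap",
    "zmaps_via_grid",
    "deviation_index",
    "predicted_mean_image",
    "quantile_curves",
    "score_cohort",
]

U_CLIP = 1e-12


@dataclass(frozen=True)
class DeviationIndex:
    """Mean of |z| strictly above the empirical q-quantile of |z|."""

    q: float
    value: float
    subject_id: object = None


def predicted_mean(params: ParamMaps, age: float, sex: float) -> np.ndarray:
    """mu(v) = b0 + b_age*age + b_sex*sex + b_age_sex*age*sex over the index set."""
    x = np.array([1.0, age, sex, age * sex])
    return params.beta @ x


def compute_u(values, params: ParamMaps, age: float, sex: float, *, clip: float = U_CLIP):
    """Latent-uniform map for one subject (or a (n, V) stack of subjects).

    ``values`` are the image intensities at ``params.coords``.  Returns U in
    (0, 1), clipped away from the endpoints so the z-transform stays finite.
    """
    y = np.asarray(values, dtype=float)
    if y.shape[-1] != params.n_voxels:
        raise ValueError(
            f"geometry mismatch: image has {y.shape[-1]} voxels, "
            f"parameter maps have {params.n_voxels}"
        )
    mu = predicted_mean(params, age, sex)
    xi, omega, alpha = cp_to_dp_arrays(mu, params.sigma, params.gamma)
    u = sn_cdf_dp(y, xi, omega, alpha)
    return np.clip(u, clip, 1.0 - clip)


def compute_z(u) -> np.ndarray:
    """z = Phi^-1(U) elementwise; z = 0 exactly when U = 0.5."""
    u = np.asarray(u, dtype=float)
    if np.any((u < 0.0) | (u > 1.0)) or not np.all(np.isfinite(u)):
        raise ValueError("U values must lie in [0, 1]; clip upstream")
    return stats.norm.ppf(u)


def zmap(values, params: ParamMaps, age: float, sex: float) -> np.ndarray:
    """Full z-map via the parameter route (PIT at every voxel)."""
    return compute_z(compute_u(values, params, age, sex))


def zmaps_via_grid(
    grid_values,
    grid_params: ParamMaps,
    grid: GridSpec,
    mask: np.ndarray,
    cov: pd.DataFrame,
    *,
    epsilon_mm: float | None = None,
) -> np.ndarray:
    """z computed at grid voxels, then RBF-interpolated across the mask.

    ``grid_values`` is (n_subjects, V*); returns (n_subjects, V_mask) in the
    order of ``np.argwhere(mask)``.
    """
    X = build_design(cov)
    mask_idx = np.argwhere(np.asarray(mask, dtype=bool))
    out = np.empty((len(X), len(mask_idx)))
    for i, (age, sex) in enumerate(zip(X[:, 1], X[:, 2])):
        z_grid = zmap(grid_values[i], grid_params, age, sex)
        vol = interpolate_field(z_grid, grid, mask, epsilon_mm)
        out[i] = vol[mask_idx[:, 0], mask_idx[:, 1], mask_idx[:, 2]]
    return out


def deviation_index(z, q: float = 0.9999, subject_id=None) -> DeviationIndex:
    """u_q^abs: mean of absolute z-values strictly above their q-quantile.

    The empirical quantile uses linear interpolation of order statistics.  If
    no value is strictly above the threshold (ties at the maximum), falls back
    to the mean of values >= threshold.
    """
    z = np.asarray(z, dtype=float).ravel()
    if z.size == 0:
        raise ValueError("z-map is empty")
    if not (0.0 <= q < 1.0):
        raise ValueError("q must lie in [0, 1)")
    a = np.abs(z)
    if q == 0.0:
        return DeviationIndex(q=q, value=float(a.mean()), subject_id=subject_id)
    t = np.quantile(a, q)
    tail = a[a > t]
    if tail.size == 0:
        tail = a[a >= t]
    return DeviationIndex(q=q, value=float(tail.mean()), subject_id=subject_id)


def predicted_mean_image(
    params: ParamMaps, age: float, sex: float, *, age_range: tuple | None = None
) -> np.ndarray:
    """Predicted mean map at given covariates (values over ``params.coords``).

    Ages outside ``age_range`` only warn: normative surfaces extrapolate with
    reduced reliability at the age boundaries rather than failing.
    """
    if age_range is not None and not (age_range[0] <= age <= age_range[1]):
        import warnings

        warnings.warn(
            f"age {age} outside the training range {age_range}; extrapolating",
            stacklevel=2,
        )
    return predicted_mean(params, age, sex)


def quantile_curves(
    params: ParamMaps,
    voxel: int,
    sex: float,
    ages,
    probs=(0.1, 0.3, 0.5, 0.7, 0.9),
) -> pd.DataFrame:
    """Normative quantile curves at one voxel (``voxel`` indexes params.coords).

    Returns a tidy frame (age, prob, value); curves never cross in age.
    """
    ages = np.asarray(ages, dtype=float)
    probs = np.asarray(probs, dtype=float)
    beta = params.beta[voxel]
    sigma = float(params.sigma[voxel])
    gamma = float(params.gamma[voxel])
    mu = beta[0] + beta[1] * ages + beta[2] * sex + beta[3] * ages * sex
    rows = []
    for p in probs:
        vals = sn_quantile_arrays(p, mu, sigma, gamma)
        rows.append(pd.DataFrame({"age": ages, "prob": p, "value": vals}))
    return pd.concat(rows, ignore_index=True)


def score_cohort(
    images,
    params: ParamMaps,
    cov: pd.DataFrame,
    q: float = 0.9999,
) -> tuple[pd.DataFrame, dict]:
    """Deviation index per subject, with group (diagnosis) medians.

    ``images`` is (n_subjects, V) aligned with ``cov`` rows; subjects with
    missing covariates are skipped and listed in the summary.  Returns the
    per-subject table sorted by subject id and a group-summary dict.
    """
    images = np.asarray(images, dtype=float)
    records = []
    skipped = []
    for i, row in enumerate(cov.itertuples(index=False)):
        age = getattr(row, "age", np.nan)
        sex = getattr(row, "sex", np.nan)
        sid = getattr(row, "subject_id", i)
        diagnosis = getattr(row, "diagnosis", "NA")
        if not (np.isfinite(age) and np.isfinite(sex)):
            skipped.append(sid)
            continue
        z = zmap(images[i], params, float(age), float(sex))
        idx = deviation_index(z, q, subject_id=sid)
        records.append(
            {"subject_id": sid, "q": q, "u_q_abs": idx.value, "diagnosis": diagnosis}
        )
    table = pd.DataFrame(
        records, columns=["subject_id", "q", "u_q_abs", "diagnosis"]
    )
    if len(table):
        table = table.sort_values("subject_id", kind="stable").reset_index(drop=True)
        medians = table.groupby("diagnosis")["u_q_abs"].median().to_dict()
    else:
        medians = {}
    summary = {"q": q, "median_by_diagnosis": medians, "skipped_subjects": skipped}
    return table, summary
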
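"""Synthetic TBM-like phantoms with known ground truth.

The phantom emulates the statistical structure that voxelwise morphometry
maps of an ageing cohort exhibit, without any anatomical realism: values
centred near 1000 (the template-volume convention: larger means local
expansion), a smooth "ventricle-like" ellipsoidal region with elevated mean,
inflated SD and stronger positive skewness, positive mean-SD and
mean-skewness coupling (both driven monotonically by the same mean-elevation
field), skewness mildly positive across the whole mask, and linear age/sex
effects on the mean with opposite signs inside the ventricle region
(expansion with age) versus a cortex-like outer shell (shrinkage with age).

Voxels are sampled independently given their parameters — exactly the
marginal model the fitting stage assumes.  An optional spatial smoothing of
the noise adds realism but breaks voxel independence, so it is off by
default.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .skewnorm import C_GAMMA, cp_to_dp_arrays, sample_sn_dp_arrays
from .voxelfit import ParamMaps

__all__ = ["PhantomSpec", "make_phantom_params", "simulate_cohort", "inject_disease"]

_GAMMA_CAP = 0.95 * C_GAMMA


@dataclass
class PhantomSpec:
    """Ground-truth geometry and parameter levels for a synthetic cohort.

    Defaults describe a 40 mm cube with an 18 mm-radius spherical "brain",
    a central ventricle ellipsoid and a thin cortical shell.  Intensity
    levels follow the template-volume convention (baseline 1000); age slopes
    are in intensity units per year.
    """

    shape: tuple = (40, 40, 40)
    voxel_size_mm: float = 1.0
    brain_radius_mm: float = 18.0
    ventricle_radii_mm: tuple = (5.0, 7.0, 5.0)
    baseline_mean: float = 1000.0
    ventricle_elevation: float = 100.0
    sigma_baseline: float = 25.0
    ventricle_sigma_mult: float = 2.5
    gamma_baseline: float = 0.2
    gamma_ventricle: float = 0.7
    age_slope_inside: float = 2.0      # units/year, ventricle expansion
    age_slope_outside: float = -0.6    # units/year, cortical shrinkage
    sex_effect: float = 5.0
    interaction_effect: float = 0.3
    noise_amp: float = 5.0             # SD of the smooth baseline variation
    smoothness_mm: float = 6.0
    seed: int = 12345

    def __post_init__(self) -> None:
        if self.sigma_baseline <= 0 or self.ventricle_sigma_mult < 1:
            raise ValueError("SD field must stay positive")
        if not (abs(self.gamma_baseline) < _GAMMA_CAP and abs(self.gamma_ventricle) < _GAMMA_CAP):
            raise ValueError("gamma levels must stay inside 0.95 * c_gamma")


def _smooth_field(shape, length_mm, voxel_mm, rng) -> np.ndarray:
    """Unit-variance smooth Gaussian random field."""
    noise = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(noise, sigma=length_mm / voxel_mm, mode="reflect")
    return (f - f.mean()) / f.std()


def make_phantom_params(spec: PhantomSpec) -> tuple[ParamMaps, np.ndarray, dict]:
    """Ground-truth parameter maps, brain mask and region masks.

    Returns ``(params, mask, regions)`` where ``params`` holds the generating
    beta/sigma/gamma at every mask voxel and ``regions`` has boolean
    ``ventricle`` and ``shell`` volumes plus smooth profile volumes used by
    the covariate effects.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    centre = (np.array(shape) - 1) / 2.0
    ii = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1)
    pos_mm = (ii - centre) * spec.voxel_size_mm

    r_brain = np.sqrt((pos_mm ** 2).sum(-1)) / spec.brain_radius_mm
    mask = r_brain <= 1.0
    if not mask.any():
        raise ValueError("phantom spec produces an empty mask")

    # smooth ventricle profile in (0, 1]: Gaussian with per-axis SD equal to
    # the ventricle radii, so the field varies on scales comparable to (or
    # larger than) the fitting grid spacing — the regime the smooth model
    # assumes
    q = ((pos_mm / np.array(spec.ventricle_radii_mm)) ** 2).sum(-1)
    bump = np.exp(-0.5 * q)
    # smooth cortex-shell profile peaking near the brain boundary
    shell_prof = np.exp(-0.5 * ((r_brain - 0.8) / 0.15) ** 2)

    base_noise = spec.noise_amp * _smooth_field(shape, spec.smoothness_mm, spec.voxel_size_mm, rng)
    elevation = spec.ventricle_elevation * bump + base_noise

    m = mask
    elev_m = elevation[m]
    lo, hi = elev_m.min(), elev_m.max()
    span = hi - lo
    # monotone link from the mean-elevation field drives SD and skewness,
    # giving the positive mean-SD / mean-skewness coupling by construction
    e_norm = (elevation - lo) / span if span > 0 else np.zeros_like(elevation)

    beta0 = spec.baseline_mean + elevation
    sigma = spec.sigma_baseline * (1.0 + (spec.ventricle_sigma_mult - 1.0) * e_norm)
    gamma = np.clip(
        spec.gamma_baseline + (spec.gamma_ventricle - spec.gamma_baseline) * e_norm,
        -_GAMMA_CAP,
        _GAMMA_CAP,
    )
    beta_age = spec.age_slope_inside * bump + spec.age_slope_outside * shell_prof
    beta_sex = spec.sex_effect * (bump - 0.3 * shell_prof)
    beta_age_sex = spec.interaction_effect * (bump - 0.5 * shell_prof)

    coords = np.argwhere(mask)
    sel = tuple(coords.T)
    beta = np.column_stack(
        [beta0[sel], beta_age[sel], beta_sex[sel], beta_age_sex[sel]]
    )
    params = ParamMaps(
        coords=coords,
        shape=shape,
        voxel_size_mm=spec.voxel_size_mm,
        beta=beta,
        sigma=sigma[sel],
        gamma=gamma[sel],
        meta={"ground_truth": True, "spec": asdict(spec)},
    )
    regions = {
        "ventricle": (q <= 1.0) & mask,
        "shell": (shell_prof > 0.5) & mask,
        "ventricle_profile": bump,
        "shell_profile": shell_prof,
    }
    return params, mask, regions


def simulate_cohort(
    params: ParamMaps,
    n: int,
    age_range: tuple = (55.0, 90.0),
    sex_ratio: float = 0.5,
    seed: int = 0,
    *,
    spatial_noise_mm: float = 0.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Sample ``n`` subjects from the voxelwise skew-normal model.

    Ages are uniform on ``age_range``; sex is Bernoulli(``sex_ratio``)
    (female=1).  Voxels are independent unless ``spatial_noise_mm`` smooths
    the underlying Gaussian noise (realism flag; alters the marginal model).
    Returns ``(images, covariates)`` with ``images`` of shape (n, V) over
    ``params.coords``.
    """
    if n < 5:
        raise ValueError("need at least 5 subjects for downstream fitting")
    rng = np.random.default_rng(seed)
    ages = rng.uniform(age_range[0], age_range[1], size=n)
    sexes = (rng.random(n) < sex_ratio).astype(float)
    cov = pd.DataFrame(
        {
            "subject_id": [f"sub-{i:04d}" for i in range(n)],
            "age": ages,
            "sex": sexes,
            "diagnosis": "CN",
        }
    )
    xi0, omega, alpha = cp_to_dp_arrays(0.0, params.sigma, params.gamma)
    if spatial_noise_mm > 0:
        # smooth the two generating normal fields, preserving unit variance
        delta = alpha / np.sqrt(1.0 + alpha * alpha)
        vol_shape = params.shape
        sel = tuple(params.coords.T)
        sig_vox = spatial_noise_mm / params.voxel_size_mm
        resid = np.empty((n, params.n_voxels))
        for i in range(n):
            z0 = _smooth_field(vol_shape, sig_vox, 1.0, rng)[sel]
            z1 = _smooth_field(vol_shape, sig_vox, 1.0, rng)[sel]
            resid[i] = xi0 + omega * (delta * np.abs(z0) + np.sqrt(1 - delta ** 2) * z1)
    else:
        resid = sample_sn_dp_arrays(xi0, omega, alpha, (n, params.n_voxels), rng)
    x = np.column_stack([np.ones(n), ages, sexes, ages * sexes])
    images = x @ params.beta.T + resid
    return images, cov


def inject_disease(
    images: np.ndarray,
    params: ParamMaps,
    effect_sd: float,
    regions: dict,
    *,
    shrink_fraction: float = 0.5,
) -> np.ndarray:
    """Add a disease-like deformation pattern to a copy of ``images``.

    Adds ``effect_sd`` generating-SDs inside the ventricle ellipsoid
    (expansion) and subtracts ``shrink_fraction * effect_sd`` SDs in the
    cortex shell (compensating shrinkage).  Voxels outside both regions are
    untouched.
    """
    if effect_sd < 0:
        raise ValueError("effect_sd must be >= 0")
    out = np.array(images, dtype=float, copy=True)
    sel = tuple(params.coords.T)
    vent = regions["ventricle"][sel]
    shell = regions["shell"][sel]
    out[..., vent] += effect_sd * params.sigma[vent]
    out[..., shell] -= shrink_fraction * effect_sd * params.sigma[shell]
    return out
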
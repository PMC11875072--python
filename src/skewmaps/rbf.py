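"""Grid selection and Gaussian radial-basis-function interpolation.

Voxelwise fits are computed only on a sparse regular lattice of in-mask
voxels; any field defined on those centres (parameter maps, z-values) is then
carried to every mask voxel by RBF interpolation with a polynomial offset:

    s(x) = b0 + sum_l b_l * h(||x - kappa_l||),   h(d) = exp(-d^2 / (2 eps^2)),

where the weights solve the bordered linear system

    [ H  1 ] [ b  ]   [ Z ]
    [ 1' 0 ] [ b0 ] = [ c ],   H_jl = h(||kappa_j - kappa_l||),

so that s interpolates the observed values exactly at every centre.  The
side condition on the weights is configurable: ``sum_to_one`` (c = 1) or the
conventional polynomial-orthogonality ``sum_to_zero`` (c = 0); both yield an
exact interpolant and differ only in how the constant offset is apportioned.
Distances are Euclidean in millimetres.  The kernel width defaults to 2/3 of
the grid spacing (5.33 mm on an 8 mm grid) — narrow enough to stay well
conditioned, wide enough to avoid the degenerate "bed of nails" interpolant
that collapses to b0 between centres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.spatial.distance import cdist

from .skewnorm import C_GAMMA

__all__ = [
    "GridSpec",
    "RBFInterpolant",
    "select_grid",
    "gaussian_rbf",
    "default_epsilon",
    "build_interpolant",
    "rbf_predict",
    "interpolate_field",
]

GAMMA_CLAMP = 0.99 * C_GAMMA
COND_THRESHOLD = 1e12


@dataclass
class GridSpec:
    """Regular lattice of in-mask voxels used as fitting/interpolation centres."""

    spacing_mm: float
    coords: np.ndarray          # (V*, 3) integer voxel indices
    shape: tuple
    voxel_size_mm: float

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=int)

    @property
    def positions_mm(self) -> np.ndarray:
        return self.coords.astype(float) * self.voxel_size_mm

    def __len__(self) -> int:
        return len(self.coords)


@dataclass
class RBFInterpolant:
    centres_mm: np.ndarray      # (V*, 3)
    weights: np.ndarray         # (V*,)
    offset: float               # b0
    epsilon_mm: float
    kernel: str = "gaussian"
    constraint: str = "sum_to_one"
    meta: dict = field(default_factory=dict)


def default_epsilon(spacing_mm: float) -> float:
    """Kernel width rule: 66.67% of the grid spacing."""
    return (2.0 / 3.0) * spacing_mm


def select_grid(mask: np.ndarray, spacing_mm: float, voxel_size_mm: float = 1.0) -> GridSpec:
    """Regular lattice anchored at the mask bounding-box minimum corner.

    Steps ``spacing_mm / voxel_size_mm`` voxels per axis (must be a positive
    integer multiple); keeps only lattice points where the mask is true.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    step_f = spacing_mm / voxel_size_mm
    step = int(round(step_f))
    if step < 1 or abs(step_f - step) > 1e-9:
        raise ValueError("spacing must be a positive integer multiple of the voxel size")
    in_mask = np.argwhere(mask)
    lo = in_mask.min(axis=0)
    hi = in_mask.max(axis=0)
    axes = [np.arange(lo[a], hi[a] + 1, step) for a in range(3)]
    lattice = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    keep = mask[lattice[:, 0], lattice[:, 1], lattice[:, 2]]
    coords = lattice[keep]
    if len(coords) == 0:
        raise ValueError(
            "no lattice point falls inside the mask; use a smaller spacing"
        )
    return GridSpec(
        spacing_mm=float(spacing_mm),
        coords=coords,
        shape=mask.shape,
        voxel_size_mm=float(voxel_size_mm),
    )


def gaussian_rbf(d, epsilon_mm: float):
    """Gaussian kernel h(d) = exp(-d^2 / (2 eps^2)); h(0) = 1."""
    if epsilon_mm <= 0:
        raise ValueError("epsilon must be positive")
    d = np.asarray(d, dtype=float)
    return np.exp(-(d * d) / (2.0 * epsilon_mm ** 2))


def build_interpolant(
    centres_mm,
    values,
    epsilon_mm: float,
    *,
    constraint: str = "sum_to_one",
    cond_threshold: float = COND_THRESHOLD,
    ridge: bool = False,
) -> RBFInterpolant:
    """Solve the bordered system for the RBF weights and offset.

    ``constraint`` selects the right-hand side of the border row: 1 for
    ``sum_to_one``, 0 for ``sum_to_zero``.  An ill-conditioned system raises
    unless ``ridge`` adds a small Tikhonov term to the kernel block.
    """
    centres = np.asarray(centres_mm, dtype=float)
    z = np.asarray(values, dtype=float)
    v = len(centres)
    if v < 2:
        raise ValueError("need at least 2 centres")
    if z.shape != (v,):
        raise ValueError("one value per centre required")
    if constraint not in ("sum_to_one", "sum_to_zero"):
        raise ValueError("constraint must be 'sum_to_one' or 'sum_to_zero'")
    d = cdist(centres, centres)
    off_diag = d + np.diag(np.full(v, np.inf))
    if np.min(off_diag) <= 0:
        raise ValueError("duplicated centre coordinates make the system singular")
    h = gaussian_rbf(d, epsilon_mm)
    if ridge:
        h = h + (1e-10 * np.trace(h) / v) * np.eye(v)
    g = np.zeros((v + 1, v + 1))
    g[:v, :v] = h
    g[:v, v] = 1.0
    g[v, :v] = 1.0
    cond = np.linalg.cond(g)
    if cond > cond_threshold and not ridge:
        raise np.linalg.LinAlgError(
            f"interpolation system condition number {cond:.2e} exceeds "
            f"{cond_threshold:.0e}; use a smaller epsilon or ridge=True"
        )
    rhs = np.concatenate([z, [1.0 if constraint == "sum_to_one" else 0.0]])
    sol = linalg.solve(g, rhs, assume_a="sym")
    b, b0 = sol[:v], float(sol[v])
    resid = h @ b + b0 - z
    scale = max(np.abs(z).max(), 1.0)
    return RBFInterpolant(
        centres_mm=centres,
        weights=b,
        offset=b0,
        epsilon_mm=float(epsilon_mm),
        constraint=constraint,
        meta={
            "condition_number": float(cond),
            "max_centre_residual_rel": float(np.abs(resid).max() / scale),
            "weight_sum": float(b.sum()),
            "ridge": bool(ridge),
        },
    )


def rbf_predict(model: RBFInterpolant, query_mm, chunk: int = 200_000) -> np.ndarray:
    """Evaluate s(x) = b0 + sum_l b_l h(||x - kappa_l||) at query points (Q, 3)."""
    q = np.atleast_2d(np.asarray(query_mm, dtype=float))
    out = np.empty(len(q))
    for s in range(0, len(q), chunk):
        d = cdist(q[s : s + chunk], model.centres_mm)
        out[s : s + chunk] = gaussian_rbf(d, model.epsilon_mm) @ model.weights + model.offset
    return out


def interpolate_field(
    grid_values,
    grid: GridSpec,
    mask: np.ndarray,
    epsilon_mm: float | None = None,
    *,
    constraint: str = "sum_to_one",
    clamp: str | None = None,
    ridge: bool = False,
) -> np.ndarray:
    """Carry grid-voxel values to every mask voxel; returns a full 3D volume.

    Grid voxels keep their fitted values exactly; only off-grid mask voxels
    are interpolated.  Out-of-mask voxels are NaN.  ``clamp`` post-processes
    the interpolated field so downstream CP parameters stay valid:
    ``"gamma"`` clips to +-0.99*c_gamma, ``"positive"`` floors at
    1e-6 * median of the grid values.
    """
    mask = np.asarray(mask, dtype=bool)
    z = np.asarray(grid_values, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("grid values must be finite")
    if epsilon_mm is None:
        epsilon_mm = default_epsilon(grid.spacing_mm)
    model = build_interpolant(
        grid.positions_mm, z, epsilon_mm, constraint=constraint, ridge=ridge
    )
    vol = np.full(mask.shape, np.nan)
    mask_idx = np.argwhere(mask)
    vol[mask_idx[:, 0], mask_idx[:, 1], mask_idx[:, 2]] = rbf_predict(
        model, mask_idx.astype(float) * grid.voxel_size_mm
    )
    # exact values at the fitting centres
    vol[grid.coords[:, 0], grid.coords[:, 1], grid.coords[:, 2]] = z
    if clamp == "gamma":
        np.clip(vol, -GAMMA_CLAMP, GAMMA_CLAMP, out=vol)
    elif clamp == "positive":
        floor = 1e-6 * float(np.median(z))
        if floor <= 0:
            floor = 1e-12
        with np.errstate(invalid="ignore"):
            vol[vol < floor] = floor
    elif clamp is not None:
        raise ValueError("clamp must be None, 'gamma' or 'positive'")
    return vol
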
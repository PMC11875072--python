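"""Shared fixtures: a tiny structural phantom and a full-scale fitted study.

The ``study`` fixture runs the whole workflow once per session (generate a
200-subject training cohort on the default 40 mm phantom, fit the 8 mm grid,
interpolate the parameter functions, simulate held-out test subjects with and
without an injected disease effect) and is shared by the recovery,
calibration and detection tests.
"""

import numpy as np
import pytest

from skewmaps.phantom import PhantomSpec, inject_disease, make_phantom_params, simulate_cohort
from skewmaps.pipeline import interpolate_params
from skewmaps.rbf import select_grid
from skewmaps.voxelfit import build_design, fit_grid

TRAIN_SEED = 101
TEST_SEED = 202
N_TRAIN = 200
N_TEST = 50
EFFECT_SD = 3.0


def grid_columns(truth, grid):
    """Column indices of the grid centres within the mask voxel ordering."""
    index = {tuple(c): i for i, c in enumerate(truth.coords)}
    return np.array([index[tuple(c)] for c in grid.coords])


@pytest.fixture(scope="session")
def tiny_phantom():
    spec = PhantomSpec(
        shape=(20, 20, 20),
        brain_radius_mm=8.0,
        ventricle_radii_mm=(2.5, 3.5, 2.5),
        seed=7,
    )
    truth, mask, regions = make_phantom_params(spec)
    return {"spec": spec, "truth": truth, "mask": mask, "regions": regions}


@pytest.fixture(scope="session")
def study():
    spec = PhantomSpec()
    truth, mask, regions = make_phantom_params(spec)
    train_images, train_cov = simulate_cohort(truth, N_TRAIN, seed=TRAIN_SEED)
    grid = select_grid(mask, 8.0, spec.voxel_size_mm)
    cols = grid_columns(truth, grid)
    X = build_design(train_cov)
    grid_params = fit_grid(train_images[:, cols], X, grid)
    params = interpolate_params(grid_params, grid, mask)
    test_images, test_cov = simulate_cohort(truth, N_TEST, seed=TEST_SEED)
    diseased_images = inject_disease(test_images, truth, EFFECT_SD, regions)
    return {
        "spec": spec,
        "truth": truth,
        "mask": mask,
        "regions": regions,
        "grid": grid,
        "grid_cols": cols,
        "train_images": train_images,
        "train_cov": train_cov,
        "X": X,
        "grid_params": grid_params,
        "params": params,
        "test_images": test_images,
        "test_cov": test_cov,
        "diseased_images": diseased_images,
    }
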
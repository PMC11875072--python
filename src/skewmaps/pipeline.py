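"""End-to-end phantom workflow: simulate -> mask -> split -> fit on grid ->
interpolate parameter functions -> z-maps -> deviation scores.

Every artefact is written alongside a manifest recording the config hash and
seed, so a rerun with the same config and seed reproduces the outputs
exactly.  Stage failures abort with the stage name attached.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import normative, phantom, rbf, volio
from .voxelfit import ParamMaps, build_design, fit_grid

__all__ = ["PipelineError", "default_config", "interpolate_params", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


def default_config() -> dict:
    return {
        "seed": 0,
        "phantom": {"n_train": 120, "n_test": 40, "effect_sd": 3.0},
        "mask": {"sigma_voxels": 2.0, "threshold": 0.5},
        "split": {"k": 5},
        "grid": {"spacing_mm": 8.0},
        "rbf": {"epsilon_mm": None, "constraint": "sum_to_one"},
        "score": {"q": 0.9999},
    }


def interpolate_params(
    grid_params: ParamMaps,
    grid: rbf.GridSpec,
    mask: np.ndarray,
    epsilon_mm: float | None = None,
    constraint: str = "sum_to_one",
) -> ParamMaps:
    """RBF-interpolate grid-fitted parameter functions to every mask voxel.

    Sigma is interpolated on its raw scale and floored at a small positive
    value; gamma is clamped inside the skewness bound.  Clamping events are
    counted in the metadata.
    """
    mask = np.asarray(mask, dtype=bool)
    coords = np.argwhere(mask)
    sel = tuple(coords.T)

    def interp(values, clamp=None):
        vol = rbf.interpolate_field(
            values, grid, mask, epsilon_mm, constraint=constraint, clamp=clamp
        )
        return vol[sel]

    beta = np.column_stack([interp(grid_params.beta[:, j]) for j in range(4)])
    sigma_raw = rbf.interpolate_field(
        grid_params.sigma, grid, mask, epsilon_mm, constraint=constraint
    )[sel]
    floor = 1e-6 * float(np.median(grid_params.sigma))
    n_sigma_clamped = int(np.sum(sigma_raw < floor))
    sigma = np.maximum(sigma_raw, floor)
    gamma_raw = rbf.interpolate_field(
        grid_params.gamma, grid, mask, epsilon_mm, constraint=constraint
    )[sel]
    n_gamma_clamped = int(np.sum(np.abs(gamma_raw) > rbf.GAMMA_CLAMP))
    gamma = np.clip(gamma_raw, -rbf.GAMMA_CLAMP, rbf.GAMMA_CLAMP)
    meta = dict(grid_params.meta)
    meta.update(
        {
            "interpolated": True,
            "epsilon_mm": epsilon_mm if epsilon_mm is not None else rbf.default_epsilon(grid.spacing_mm),
            "constraint": constraint,
            "n_sigma_floored": n_sigma_clamped,
            "n_gamma_clamped": n_gamma_clamped,
        }
    )
    return ParamMaps(
        coords=coords,
        shape=mask.shape,
        voxel_size_mm=grid.voxel_size_mm,
        beta=beta,
        sigma=sigma,
        gamma=gamma,
        meta=meta,
    )


def _stage(name):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, str(exc)) from exc
            return False

    return _Ctx()


def run_pipeline(config: dict, outdir) -> dict:
    """Run the full phantom workflow; returns a dict of in-memory results."""
    cfg = default_config()
    for key, val in (config or {}).items():
        if isinstance(val, dict) and key in cfg:
            cfg[key].update(val)
        else:
            cfg[key] = val
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    artefacts = []

    with _stage("simulate"):
        spec_kwargs = cfg.get("phantom_spec", {})
        spec = phantom.PhantomSpec(seed=seed, **spec_kwargs)
        truth, raw_mask, regions = phantom.make_phantom_params(spec)
        n_train = int(cfg["phantom"]["n_train"])
        n_test = int(cfg["phantom"]["n_test"])
        images, cov = phantom.simulate_cohort(truth, n_train + n_test, seed=seed + 1)
        cov_path = outdir / "covariates.csv"
        cov.to_csv(cov_path, index=False)
        artefacts.append(cov_path)

    with _stage("mask"):
        mask, fwhm = volio.build_mask(
            raw_mask.astype(float),
            cfg["mask"]["sigma_voxels"],
            cfg["mask"]["threshold"],
            spec.voxel_size_mm,
        )
        mask_path = outdir / "mask.nii.gz"
        volio.save_volume(mask_path, mask.astype(float), spec.voxel_size_mm)
        artefacts.append(mask_path)
        # restrict images/truth to the smoothed mask (subset of phantom voxels)
        sel_new = np.argwhere(mask & raw_mask)
        old_index = {tuple(c): i for i, c in enumerate(truth.coords)}
        keep = np.array([old_index[tuple(c)] for c in sel_new])
        truth = ParamMaps(
            coords=truth.coords[keep],
            shape=truth.shape,
            voxel_size_mm=truth.voxel_size_mm,
            beta=truth.beta[keep],
            sigma=truth.sigma[keep],
            gamma=truth.gamma[keep],
            meta=truth.meta,
        )
        mask = np.zeros(spec.shape, dtype=bool)
        mask[tuple(truth.coords.T)] = True
        images = images[:, keep]

    with _stage("split"):
        folds = volio.stratified_split(cov.iloc[:n_train], cfg["split"]["k"], seed + 2)
        folds_path = outdir / "folds.csv"
        pd.DataFrame(
            {"subject_id": cov["subject_id"].iloc[:n_train], "fold": folds}
        ).to_csv(folds_path, index=False)
        artefacts.append(folds_path)
        train_idx = np.flatnonzero(folds != 0)  # fold 0 held out

    with _stage("fit"):
        grid = rbf.select_grid(mask, cfg["grid"]["spacing_mm"], spec.voxel_size_mm)
        grid_col = {tuple(c): i for i, c in enumerate(truth.coords)}
        grid_cols = np.array([grid_col[tuple(c)] for c in grid.coords])
        X_train = build_design(cov.iloc[train_idx])
        grid_params = fit_grid(images[np.ix_(train_idx, grid_cols)], X_train, grid)

    with _stage("interpolate"):
        full_params = interpolate_params(
            grid_params,
            grid,
            mask,
            cfg["rbf"]["epsilon_mm"],
            cfg["rbf"]["constraint"],
        )
        artefacts += volio.save_param_maps(outdir / "params", full_params, mask)

    with _stage("score"):
        test_cov = cov.iloc[n_train:].reset_index(drop=True)
        test_images = images[n_train:]
        effect = float(cfg["phantom"]["effect_sd"])
        diseased = phantom.inject_disease(test_images, truth, effect, regions)
        q = float(cfg["score"]["q"])
        table_null, _ = normative.score_cohort(test_images, full_params, test_cov, q)
        dis_cov = test_cov.copy()
        dis_cov["diagnosis"] = "DIS"
        table_dis, _ = normative.score_cohort(diseased, full_params, dis_cov, q)
        scores = pd.concat([table_null, table_dis], ignore_index=True)
        scores_path = outdir / "deviation_scores.csv"
        scores.to_csv(scores_path, index=False)
        artefacts.append(scores_path)
        summary = {
            "q": q,
            "median_by_diagnosis": scores.groupby("diagnosis")["u_q_abs"].median().to_dict(),
            "n_train_fit": int(len(train_idx)),
            "n_test": int(n_test),
            "mask_fwhm_mm": fwhm,
            "n_grid_voxels": int(len(grid)),
        }
        summary_path = outdir / "group_summary.json"
        summary_path.write_text(json.dumps(summary, indent=2))
        artefacts.append(summary_path)

    volio.write_manifest(outdir / "manifest.json", cfg, artefacts, seed)
    return {
        "config": cfg,
        "truth": truth,
        "mask": mask,
        "grid": grid,
        "grid_params": grid_params,
        "params": full_params,
        "scores": scores,
        "summary": summary,
    }
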
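"""End-to-end orchestration of the range-estimation workflow.

Stages: (optionally) simulate a synthetic landscape -> screen and
standardize covariates -> presence-only maxent model -> suitability-
stratified survey design -> (optionally) simulate surveys -> occupancy
model set with DIC averaging -> maxent/occupancy comparison -> range
delineation. Each stage draws its random seed deterministically from the
master seed (SeedSequence spawned per stage index), so a rerun with the
same config reproduces every output byte for byte.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .delineate import (apply_threshold, error_rates, inclusion_level,
                        kde2d, partition_range, select_threshold)
from .design import assign_methods, select_cells
from .grids import (PresenceRecords, RasterStack, bin_to_cells,
                    filter_correlated, read_presences, read_raster_stack,
                    standardize, write_ascii_grid, write_raster_stack,
                    write_presences)
from .maxent import (fit_maxent, predict_hsi, roc_summary, training_gain,
                     variable_contributions)
from .occupancy import (DetectionHistory, OccupancyModelSpec, predict_psi,
                        run_mcmc)
from .selection import (compare_rankings, model_averaged_prediction,
                        run_model_selection)
from .synthetic import (DEFAULT_SCENARIO, generate_covariates,
                        generate_truth, simulate_incidental,
                        simulate_surveys)

__all__ = ["PipelineConfig", "run_pipeline"]

_STAGES = ("simulate", "maxent", "design", "surveys", "occupancy",
           "compare", "delineate")


@dataclass
class PipelineConfig:
    """Run configuration; every stage parameter has a spec'd default."""

    output_dir: str = "occurange_run"
    seed: int = 0
    simulate: dict = dc_field(default_factory=dict)
    inputs: dict = dc_field(default_factory=dict)
    screening: dict = dc_field(default_factory=dict)
    maxent: dict = dc_field(default_factory=dict)
    design: dict = dc_field(default_factory=dict)
    occupancy: dict = dc_field(default_factory=dict)
    selection: dict = dc_field(default_factory=dict)
    delineate: dict = dc_field(default_factory=dict)
    stop_after: str | None = None  # e.g. "maxent" for presence-only mode

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _stage_seed(master: int, stage: str) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(master), _STAGES.index(stage)])


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages and return the run manifest.

    The manifest records the package version, per-stage seeds and
    parameters, and every output path, which suffices to re-run any stage
    in isolation.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "stages": {},
        "outputs": {},
    }

    def done(stage: str) -> bool:
        if config.stop_after is None:
            return False
        return _STAGES.index(stage) > _STAGES.index(config.stop_after)

    # ---------------------------------------------------------- simulate
    sim = {**DEFAULT_SCENARIO, **config.simulate}
    truth = None
    if sim.get("enabled", True):
        ss = _stage_seed(config.seed, "simulate").spawn(3)
        grid = generate_covariates(
            sim["n_rows"], sim["n_cols"], sim["n_cov"],
            smoothness=sim["smoothness"], seed=ss[0],
            cell_size_km=sim.get("cell_size_km", 2.0),
        )
        beta = sim["beta"]
        if not isinstance(beta, dict):
            beta = {f"cov{k + 1}": b for k, b in enumerate(beta)}
        truth = generate_truth(grid, beta, sim["p_true"],
                               alpha=sim["alpha"], seed=ss[1],
                               bias_strength=sim.get("bias_strength", 0.0))
        presences = simulate_incidental(
            truth, sim.get("n_sightings", 391),
            bias_covariate=sim.get("bias_covariate"), seed=ss[2],
        )
        raster_dir = out / "rasters"
        write_raster_stack(grid, raster_dir)
        write_presences(presences, out / "presences.csv")
        write_ascii_grid(out / "true_psi.asc", truth.psi_grid,
                         grid.cell_size_km, grid.ll_corner)
        manifest["stages"]["simulate"] = {
            k: v for k, v in sim.items() if k != "enabled"
        }
        manifest["outputs"]["rasters"] = str(raster_dir)
        manifest["outputs"]["presences"] = str(out / "presences.csv")
    else:
        grid = read_raster_stack(config.inputs["rasters"])
        presences = read_presences(config.inputs["presences"])
    if done("simulate"):
        return _write_manifest(manifest, out)

    # ------------------------------------------------------------ maxent
    mx = {"n_background": 10000, "reg_multiplier": 1.0,
          "r_threshold": 0.7, **config.screening, **config.maxent}
    retained = filter_correlated(grid, mx["r_threshold"])
    std_grid, cov_spec = standardize(grid, retained)
    presence_mask, _ = bin_to_cells(presences, grid)
    presence_cells = np.flatnonzero(presence_mask.ravel()
                                    & ~grid.nodata_mask.ravel())
    n_bg = min(mx["n_background"], std_grid.n_unmasked)
    model = fit_maxent(presence_cells, std_grid, n_background=n_bg,
                       reg_multiplier=mx["reg_multiplier"],
                       seed=_seed_int(_stage_seed(config.seed, "maxent")))
    hsi = predict_hsi(model, std_grid)
    gain = training_gain(model, grid=std_grid)
    roc = roc_summary(hsi, presence_cells, grid.nodata_mask)
    contrib = variable_contributions(
        model, std_grid,
        seed=_seed_int(_stage_seed(config.seed, "maxent")) + 1)
    write_ascii_grid(out / "hsi.asc", hsi, grid.cell_size_km,
                     grid.ll_corner)
    roc.to_frame().to_csv(out / "maxent_roc.csv", index=False)
    contrib.rename("contribution_pct").to_csv(out / "maxent_contributions.csv")
    manifest["stages"]["maxent"] = {
        "retained_covariates": retained, "n_background": n_bg,
        "gain": gain, "auc": roc.auc,
    }
    manifest["outputs"]["hsi"] = str(out / "hsi.asc")
    if done("maxent"):
        return _write_manifest(manifest, out)

    # ------------------------------------------------------------ design
    dz = {"n_weighted": 60, "n_random": 20, "n_camera_cells": 40,
          "pellet_transects": 3, "cameras": 2, **config.design}
    ss = _stage_seed(config.seed, "design").spawn(2)
    design = select_cells(hsi, dz["n_weighted"], dz["n_random"], seed=ss[0],
                          nodata_mask=grid.nodata_mask)
    design = assign_methods(design, dz["n_camera_cells"],
                            dz["pellet_transects"], dz["cameras"],
                            seed=ss[1])
    design.to_frame(grid).to_csv(out / "survey_design.csv", index=False)
    manifest["stages"]["design"] = dz
    manifest["outputs"]["design"] = str(out / "survey_design.csv")
    if done("design"):
        return _write_manifest(manifest, out)

    # ----------------------------------------------------------- surveys
    if truth is not None:
        detections = simulate_surveys(
            design, truth, seed=_stage_seed(config.seed, "surveys"))
        # replace raw covariates with the standardized training values
        rows, cols = design.rows_cols()
        detections.X = pd.DataFrame(
            {n: std_grid.layers[n][rows, cols] for n in retained})
    else:
        detections = DetectionHistory.from_csv(
            config.inputs["detections"], covariates=retained)
    detections.to_csv(out / "detection_histories.csv")
    manifest["outputs"]["detections"] = str(out / "detection_histories.csv")
    if done("surveys"):
        return _write_manifest(manifest, out)

    # --------------------------------------------------------- occupancy
    sel = {"enabled": True, "shortlist_size": 7, "max_size": 4,
           "cum_target": 0.9, "chains": 1, "burn_in": 500,
           "iterations": 2000, **config.selection}
    occ = {"chains": 3, "burn_in": 1000, "iterations": 20000,
           "prior_beta_sd": 10.0, **config.occupancy}
    occ_seed = _seed_int(_stage_seed(config.seed, "occupancy"))
    if sel["enabled"] and len(retained) >= 2:
        comparison, posteriors = run_model_selection(
            detections, retained, shortlist_size=sel["shortlist_size"],
            max_size=sel["max_size"], cum_target=sel["cum_target"],
            chains=sel["chains"], burn_in=sel["burn_in"],
            iterations=sel["iterations"],
            prior_beta_sd=occ["prior_beta_sd"], seed=occ_seed)
        comparison.table.to_csv(out / "model_table.csv", index=False)
        comparison.averaged.to_csv(out / "averaged_parameters.csv",
                                   index=False)
        maps = {}
        for covs in comparison.averaging_set:
            maps[covs] = predict_psi(posteriors[covs], std_grid)[0]
        keys = list(comparison.averaging_set)
        weight_by = {tuple(c.split("+")): w for c, w in
                     zip(comparison.table["covariates"],
                         comparison.table["weight"])}
        wts = np.array([weight_by[c] for c in keys])
        psi_map = model_averaged_prediction(
            [maps[c] for c in keys], wts, np.arange(len(keys)))
        manifest["stages"]["occupancy"] = {
            "mode": "selection+averaging", **sel,
            "averaging_set": ["+".join(c) for c in keys],
        }
    else:
        spec = OccupancyModelSpec(tuple(retained),
                                  prior_beta_sd=occ["prior_beta_sd"],
                                  chains=occ["chains"],
                                  burn_in=occ["burn_in"],
                                  iterations=occ["iterations"])
        posterior = run_mcmc(spec, detections, seed=occ_seed)
        posterior.summary().to_csv(out / "posterior_summary.csv",
                                   index=False)
        psi_map = predict_psi(posterior, std_grid)[0]
        manifest["stages"]["occupancy"] = {"mode": "single-model", **occ}
    write_ascii_grid(out / "psi.asc", psi_map, grid.cell_size_km,
                     grid.ll_corner)
    manifest["outputs"]["psi"] = str(out / "psi.asc")
    if done("occupancy"):
        return _write_manifest(manifest, out)

    # ----------------------------------------------------------- compare
    rs, decile_diff = compare_rankings(hsi, psi_map, grid.nodata_mask)
    write_ascii_grid(out / "decile_difference.asc", decile_diff,
                     grid.cell_size_km, grid.ll_corner)
    manifest["stages"]["compare"] = {"spearman_rs": rs}
    if done("compare"):
        return _write_manifest(manifest, out)

    # --------------------------------------------------------- delineate
    dl = {"target_fnr": 0.05, "include_fraction": 0.995,
          "bandwidth": "auto", **config.delineate}
    survey_points = _survey_detection_points(detections, design, grid)
    pooled = PresenceRecords.concat([presences, survey_points]) \
        if len(survey_points) else presences
    pooled_mask, _ = bin_to_cells(pooled, grid)
    analysis = error_rates(psi_map, pooled_mask, grid.nodata_mask)
    threshold = select_threshold(analysis, dl["target_fnr"])
    suitable, suitable_area = apply_threshold(psi_map, threshold,
                                              grid.cell_size_km,
                                              grid.nodata_mask)
    bw = None if dl["bandwidth"] == "auto" else tuple(dl["bandwidth"])
    surface = kde2d(pooled, grid, bandwidth=bw)
    level = inclusion_level(surface, pooled, grid,
                            dl["include_fraction"])
    partition = partition_range(suitable, surface, level,
                                grid.cell_size_km)
    write_ascii_grid(out / "range_labels.asc",
                     partition.labels.astype(float), grid.cell_size_km,
                     grid.ll_corner, fmt="%d")
    fpr_at = float(analysis.fpr[analysis.thresholds == threshold][0])
    areas = {
        "threshold": threshold,
        "commission_error": fpr_at,
        "area_suitable_km2": partition.area_suitable_km2,
        "area_current_km2": partition.area_current_km2,
        "area_potential_km2": partition.area_potential_km2,
        "kernel_bandwidth": list(surface.bandwidth),
        "included_fraction": surface.included_fraction,
    }
    with open(out / "range_areas.json", "w") as fh:
        json.dump(areas, fh, indent=2)
    manifest["stages"]["delineate"] = {**dl, **areas}
    manifest["outputs"]["range_labels"] = str(out / "range_labels.asc")
    manifest["outputs"]["range_areas"] = str(out / "range_areas.json")
    return _write_manifest(manifest, out)


def _survey_detection_points(detections: DetectionHistory, design,
                             grid: RasterStack) -> PresenceRecords:
    """Cell-centre presence points for surveyed cells with any detection."""
    rows, cols = design.rows_cols()
    hit = detections.any_detection()
    xs, ys = grid.cell_centres()
    n = int(hit.sum())
    return PresenceRecords(
        xs[cols[hit]], ys[rows[hit]],
        source=np.array(["survey"] * n, dtype=object),
        precision_m=np.zeros(n),
    )


def _write_manifest(manifest: dict, out: Path) -> dict:
    path = out / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    manifest["outputs"]["manifest"] = str(path)
    return manifest
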
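"""End-to-end pipeline orchestration.

Stages run in a fixed order — synth, ingest, profile, classify,
polygonize, model, project — each reading the artifacts of the previous
stage from the output directory and writing its own, so any suffix of
the chain can be re-run.  A resolved-config snapshot and a log with
stage timings and warning counts are written alongside the outputs;
given identical inputs, config and seed every stage is deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as cls_mod
from . import habitat, points as pts_mod, scenario as scen_mod, segmentation as seg_mod
from . import synth as synth_mod
from . import voxel
from .grids import HeightRaster, GridSpec, read_ascii_grid, write_ascii_grid

log = logging.getLogger("rockveg")

STAGES = ("synth", "ingest", "profile", "classify", "polygonize", "model", "project")


@dataclass
class PipelineConfig:
    """All pipeline tunables with their standard defaults."""

    cell_size_processing: float = 4.0  # m, voxel/feature grid
    cell_size_dem: float = 2.0  # m, DEM and canopy-height rasters
    window: int = 3  # PVF window, cells
    layer_threshold: float = 20.0  # % PVF triggering a layer
    smooth: bool = True  # apply the vertical Gaussian before layering
    interval_edges: list = field(
        default_factory=lambda: voxel.DEFAULT_INTERVAL_EDGES.tolist()
    )
    max_height: int = 80  # m, voxel ceiling
    pca_variance: float = 0.99
    k_init: int = 20  # initial ISO cluster count
    min_area: float = 0.01  # ISO minimum class area fraction
    merge_tol: float = 0.5  # library merge distance (standardized)
    use_intensity: bool = False  # keep intensity out of classification
    scale_local: float = 2.0  # m, local segmentation scale
    scale_vegetation: float = 5.0  # m, vegetation segmentation scale
    buffer: float = 4.0  # m, plot buffer
    min_cover: float = 0.25  # class-weighted stats coverage floor
    alpha: float = 0.05  # backward-elimination threshold
    rainfall_multiplier: float = 0.8  # scenario
    scenario_mode: str = "delta"
    mossmat_thresholds: tuple | None = None  # (lo, hi) relative brightness
    scene_extent: float = 500.0  # m, synthetic scene side length
    seed: int = 42

    def stage_seed(self, stage: str) -> int:
        return (self.seed + 1000 * STAGES.index(stage)) % (2**31)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


class _WarningCounter(logging.Handler):
    def __init__(self):
        super().__init__(level=logging.WARNING)
        self.count = 0

    def emit(self, record):
        self.count += 1


def run_pipeline(config: PipelineConfig, stages, out_dir: str | Path) -> dict:
    """Execute the requested stages in pipeline order.

    Returns a dict of in-memory artifacts from the stages that ran.
    Unknown stage names and missing upstream artifacts are fatal.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage: {s!r} (choose from {', '.join(STAGES)})")
    stages = [s for s in STAGES if s in stages]
    config.to_yaml(out / "config.yaml")
    artifacts: dict = {}
    timings = {}
    for stage in stages:
        t0 = time.perf_counter()
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            _run_stage(stage, config, out, artifacts)
        timings[stage] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "warnings": len(caught),
        }
        log.info("stage %s done in %.2fs (%d warnings)", stage, timings[stage]["seconds"], len(caught))
    (out / "pipeline_log.json").write_text(json.dumps(timings, indent=1))
    return artifacts


def _need(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{stage}' requires missing upstream artifact: {path.name}"
        )
    return path


def _run_stage(stage: str, cfg: PipelineConfig, out: Path, art: dict) -> None:
    if stage == "synth":
        params = synth_mod.SceneParams(extent=cfg.scene_extent)
        if cfg.scene_extent < 2.5 * params.rock_radius:
            params = dataclasses.replace(
                params, rock_radius=cfg.scene_extent / 2.5, soil_tau=cfg.scene_extent / 16
            )
        scene = synth_mod.gen_scene(cfg.stage_seed("synth"), params)
        cloud = synth_mod.sample_point_cloud(scene, seed=cfg.stage_seed("synth") + 1)
        pts_mod.write_points(cloud, out / "points.csv")
        write_ascii_grid(scene.dem, out / "dem_truth.asc")
        write_ascii_grid(HeightRaster(scene.grid, scene.pds), out / "pds_truth.asc")
        write_ascii_grid(HeightRaster(scene.grid, scene.canopy_height), out / "ch_truth.asc")
        plots = synth_mod.gen_plots(scene, seed=cfg.stage_seed("synth") + 2)
        plots.to_csv(out / "plots.csv", index=False)
        art["scene"] = scene
        art["points_raw"] = cloud

    elif stage == "ingest":
        pts = art.get("points_raw")
        if pts is None:
            pts = pts_mod.read_points(_need(out / "points.csv", stage))
        pts = pts_mod.dedup_runs(pts, cfg.cell_size_processing)
        dem = pts_mod.build_dem(pts, cfg.cell_size_dem)
        pts, n_clamped = pts_mod.normalize_heights(pts, dem)
        chm = pts_mod.canopy_height_raster(pts, cfg.cell_size_dem, dem.grid)
        write_ascii_grid(dem, out / "dem.asc")
        write_ascii_grid(chm, out / "chm.asc")
        pts_mod.write_points(pts, out / "points_norm.csv")
        art.update(points=pts, dem=dem, chm=chm, n_clamped=n_clamped)

    elif stage == "profile":
        pts = art.get("points")
        if pts is None:
            pts = pd.read_csv(_need(out / "points_norm.csv", stage))
            pts["is_ground"] = pts["is_ground"].astype(bool)
        grid = GridSpec.from_bounds(
            pts["x"].min(), pts["y"].min(), pts["x"].max(), pts["y"].max(),
            cfg.cell_size_processing,
        )
        feats = voxel.profile_features(
            pts,
            grid,
            window=cfg.window,
            threshold=cfg.layer_threshold,
            edges=np.asarray(cfg.interval_edges),
            max_height=cfg.max_height,
            smooth=cfg.smooth,
            with_intensity=cfg.use_intensity,
        )
        feats.to_csv(out / "features.csv", index=False)
        art.update(features=feats, feature_grid=grid)

    elif stage == "classify":
        feats = art.get("features")
        if feats is None:
            feats = pd.read_csv(_need(out / "features.csv", stage))
        cols = [c for c in voxel.FEATURE_COLUMNS if c in feats.columns]
        if cfg.use_intensity and "intensity" in feats.columns:
            cols.append("intensity")
        X = feats[cols].to_numpy(dtype=float)
        Z, mean, std, kept = cls_mod.standardize_features(X)
        names = [cols[k] for k in kept]
        scores, pca = cls_mod.pca_reduce(Z, cfg.pca_variance)
        labels, centroids = cls_mod.iso_cluster(
            scores, cfg.k_init, cfg.min_area, seed=cfg.stage_seed("classify")
        )
        # class centroids back in standardized feature space for the library
        feat_centroids = np.vstack(
            [Z[labels == c].mean(axis=0) for c in range(len(centroids))]
        )
        library = cls_mod.summarize_classes(labels, feats, feat_centroids, names, mean, std)
        library.to_json(out / "library.json")
        class_map = np.full((feats["row"].max() + 1, feats["col"].max() + 1), -1, dtype=int)
        class_map[feats["row"], feats["col"]] = labels
        np.savetxt(out / "class_map.txt", class_map, fmt="%d")
        art.update(library=library, class_labels=labels, class_map=class_map)

    elif stage == "polygonize":
        chm = art.get("chm")
        if chm is None:
            chm = read_ascii_grid(_need(out / "chm.asc", stage))
        class_map = art.get("class_map")
        if class_map is None:
            class_map = np.loadtxt(_need(out / "class_map.txt", stage), dtype=int)
            class_map = np.atleast_2d(class_map)
        library = art.get("library")
        if library is None:
            library = cls_mod.StructuralClassLibrary.from_json(_need(out / "library.json", stage))
        feats = art.get("features")
        if feats is None:
            feats = pd.read_csv(_need(out / "features.csv", stage))

        labels_veg = seg_mod.segment(chm, cfg.scale_vegetation)
        polys = seg_mod.polygons_from_labels(labels_veg, chm.grid)
        # cover raster at CHM resolution from the feature grid
        ratio = cfg.cell_size_processing / cfg.cell_size_dem
        cover_feat = np.zeros((class_map.shape[0], class_map.shape[1]))
        cover_feat[feats["row"], feats["col"]] = feats["cover"]
        cover_chm = _upsample(cover_feat, chm.values.shape, ratio)
        class_chm = _upsample(class_map, chm.values.shape, ratio).astype(int)
        seg_mod.attach_polygon_stats(polys, chm, cover_chm)
        for p in polys:
            seg_mod.assign_polygon_class(p, class_chm)
        # moss-mat resolution runs on the finer local-scale segmentation,
        # comparing bare patches against their vegetation-scale surroundings
        if cfg.mossmat_thresholds is not None and art.get("brightness") is not None:
            labels_loc = seg_mod.segment(chm, cfg.scale_local)
            loc_polys = seg_mod.polygons_from_labels(labels_loc, chm.grid)
            seg_mod.attach_polygon_stats(loc_polys, chm, cover_chm)
            bare_loc = [p for p in loc_polys if p.bare]
            seg_mod.mossmat_assign(
                bare_loc, polys, art["brightness"], tuple(cfg.mossmat_thresholds)
            )
            seg_mod.polygons_to_geojson(
                [p for p in bare_loc if p.mossmat], out / "mossmat.geojson"
            )
        seg_mod.polygons_to_geojson(polys, out / "polygons.geojson")
        art.update(polygons=polys)

    elif stage == "model":
        plots_path = _need(out / "plots.csv", stage)
        plots = pd.read_csv(plots_path)
        polys = art.get("polygons")
        library = art.get("library")
        if polys is None or library is None:
            raise FileNotFoundError("stage 'model' requires in-memory polygons/library from 'polygonize'")
        probe_cols = [f"probe{k}_m" for k in range(1, 6)]
        stats = []
        for _, row in plots.iterrows():
            st = habitat.plot_buffer_stats(
                row["x"], row["y"], row["habitat"], polys, library,
                buffer=cfg.buffer, min_cover=cfg.min_cover,
            )
            st.update(
                pDS=habitat.pds_from_probes(row[probe_cols].to_numpy(dtype=float)),
                R=row["rainfall_mm"],
                EV=row["elev_range_m"],
            )
            stats.append(st)
        table = pd.DataFrame(stats)
        table.to_csv(out / "plot_stats.csv", index=False)
        fitted = []
        for response in ("max_ch", "mean_gc"):
            sub = table.dropna(subset=[response])
            if sub[["R", "EV", "pDS"]].std().min() == 0:
                # single-site runs cannot identify R/EV terms; fit on pDS only
                model = habitat.StructureEnvironmentModel.from_dataframe(
                    sub, response, terms=("pDS",), interactions=False
                )
            else:
                model = habitat.StructureEnvironmentModel.from_dataframe(sub, response)
            fitted.append(model.fit(cfg.alpha))
        habitat.save_models(fitted, out / "models.json")
        art.update(plot_stats=table, models=fitted)

    elif stage == "project":
        polys = art.get("polygons")
        library = art.get("library")
        if polys is None or library is None:
            raise FileNotFoundError("stage 'project' requires polygons/library from 'polygonize'")
        scene = art.get("scene")
        rainfall = scene.rainfall if scene is not None else np.nan
        for p in polys:
            if not np.isfinite(p.rainfall):
                p.rainfall = rainfall
        scen = scen_mod.Scenario(cfg.rainfall_multiplier, cfg.scenario_mode)
        classified = [p for p in polys if p.class_id >= 0]
        projection = scen_mod.project_map(classified, library, scen)
        projection.to_csv(out / "projection.csv", index=False)
        summary = scen_mod.area_change_summary(projection)
        summary.to_csv(out / "area_change.csv")
        art.update(projection=projection, area_change=summary)


def _upsample(arr: np.ndarray, target_shape, ratio: float) -> np.ndarray:
    """Nearest-neighbour upsampling of a coarse raster onto a finer grid."""
    arr = np.asarray(arr)
    rows = np.minimum((np.arange(target_shape[0]) / ratio).astype(int), arr.shape[0] - 1)
    cols = np.minimum((np.arange(target_shape[1]) / ratio).astype(int), arr.shape[1] - 1)
    return arr[np.ix_(rows, cols)]
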
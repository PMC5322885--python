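"""End-to-end orchestration: volumes -> per-vertex shapes -> features ->
labeled features -> whole-shape descriptors -> statistics tables.

A run consumes a labeled pial-style surface (VTK) and optionally a segmented
volume plus region labels (NIfTI), and writes a deterministic output tree::

    out/
      run_config.json    manifest.json (sha256 per file)
      labels/            input label copies
      shapes/            per-vertex measure VTKs, spectra/zernike CSVs
      features/          folds.vtk fundi.vtk sulci.vtk
      tables/            per-region statistics CSVs, volume tables

Re-running with identical configuration and inputs reproduces identical
manifest hashes; disabling a downstream stage never changes upstream output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import label_stats, surface_features, vertex_shapes, volumetric_shapes
from .io_formats import (
    LabelField,
    ScalarField,
    ShapeTable,
    read_vtk_surface,
    read_volume,
    write_shape_table,
    write_vtk_surface,
)
from .mesh_graph import build_graph, submesh, voronoi_area
from .surface_features import FundusConfig, SulcusProtocol, default_protocol
from .vertex_shapes import CurvatureConfig, DepthConfig
from .volumetric_shapes import ThickinConfig
from .whole_shape_descriptors import laplace_beltrami_spectrum, zernike_moments

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    surface: str
    out_dir: str
    labels_surface: str | None = None  # VTK whose first label array paints gyri
    segmented_volume: str | None = None
    region_labels_volume: str | None = None
    do_volumes: bool = True
    do_surfaces: bool = True
    do_fundi: bool = True
    do_spectra: bool = True
    do_zernike: bool = True
    n_spectrum: int = 6
    zernike_order: int = 6
    depth: DepthConfig = field(default_factory=DepthConfig)
    curvature: CurvatureConfig = field(default_factory=CurvatureConfig)
    fundus: FundusConfig = field(default_factory=FundusConfig)
    thickin: ThickinConfig = field(default_factory=ThickinConfig)
    min_depth_values: int = 1000
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def run_pipeline(cfg: RunConfig, protocol: SulcusProtocol | None = None) -> Path:
    """Execute the enabled stages; returns the output directory.

    Any stage failure leaves prior outputs in place and records the failure
    point in the manifest.
    """
    out = Path(cfg.out_dir)
    for sub in ("labels", "shapes", "features", "tables"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    (out / "run_config.json").write_text(cfg.to_json() + "\n")
    manifest: dict = {"files": {}, "failed_stage": None, "stage_seconds": {}}

    def _finish() -> Path:
        for f in sorted(out.rglob("*")):
            if f.is_file() and f.name != "manifest.json":
                digest = hashlib.sha256(f.read_bytes()).hexdigest()
                manifest["files"][str(f.relative_to(out))] = digest
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return out

    stage = "read"
    try:
        mesh, fields = read_vtk_surface(cfg.surface)
        graph = build_graph(mesh)
        labels = None
        if cfg.labels_surface:
            lmesh, lfields = read_vtk_surface(cfg.labels_surface)
            labels = next((f for f in lfields if isinstance(f, LabelField)), None)
        else:
            labels = next((f for f in fields if isinstance(f, LabelField)), None)

        if cfg.do_volumes and cfg.segmented_volume and cfg.region_labels_volume:
            stage = "volumes"
            t0 = time.perf_counter()
            seg = read_volume(cfg.segmented_volume)
            reg = read_volume(cfg.region_labels_volume)
            write_shape_table(
                volumetric_shapes.volume_per_region(reg), out / "tables" / "volume_per_region.csv"
            )
            write_shape_table(
                volumetric_shapes.thickinthehead(seg, reg, cfg.thickin),
                out / "tables" / "thickinthehead.csv",
            )
            manifest["stage_seconds"][stage] = time.perf_counter() - t0

        if not cfg.do_surfaces:
            return _finish()

        stage = "vertex_shapes"
        t0 = time.perf_counter()
        area = voronoi_area(mesh, graph)
        meanc = vertex_shapes.mean_curvature(mesh, graph, cfg.curvature)
        gaussc = vertex_shapes.gaussian_curvature(mesh, graph, cfg.curvature)
        wrapper = vertex_shapes.make_wrapper_surface(mesh, cfg.depth)
        gdepth = vertex_shapes.geodesic_depth(mesh, graph, wrapper, cfg.depth)
        tdepth = vertex_shapes.travel_depth(mesh, graph, wrapper, cfg.depth)
        write_vtk_surface(
            mesh, [area, meanc, gaussc, gdepth, tdepth], out / "shapes" / "vertex_shapes.vtk"
        )
        manifest["stage_seconds"][stage] = time.perf_counter() - t0

        stage = "features"
        t0 = time.perf_counter()
        if mesh.n_vertices >= cfg.min_depth_values:
            threshold = surface_features.find_depth_threshold(tdepth)
        else:
            threshold = float(np.median(tdepth.values))
        folds = surface_features.extract_folds(mesh, graph, tdepth, threshold, cfg.fundus)
        write_vtk_surface(
            mesh, [LabelField(folds.fold_ids, name="fold_ids")], out / "features" / "folds.vtk"
        )
        fundi = None
        if cfg.do_fundi:
            fundi = surface_features.extract_fundi(mesh, graph, folds, tdepth, meanc, cfg.fundus)
            write_vtk_surface(mesh, [fundi], out / "features" / "fundi.vtk")
        sulci = None
        if labels is not None:
            proto = protocol or default_protocol()
            sulci = surface_features.extract_sulci(mesh, graph, folds, labels, proto)
            write_vtk_surface(mesh, [sulci], out / "features" / "sulci.vtk")
            if fundi is not None:
                sf = surface_features.segment_by_region(fundi, sulci)
                write_vtk_surface(mesh, [sf], out / "features" / "sulcal_fundi.vtk")
        manifest["stage_seconds"][stage] = time.perf_counter() - t0

        stage = "whole_shapes"
        t0 = time.perf_counter()
        feature_sets = {}
        if sulci is not None:
            for sid in sorted(set(sulci.labels[sulci.labels >= 0])):
                feature_sets[int(sid)] = np.flatnonzero(sulci.labels == sid)
        else:
            for k in range(folds.n_folds):
                feature_sets[k] = folds.vertices(k)
        if cfg.do_spectra and feature_sets:
            rows = []
            for fid, verts in feature_sets.items():
                try:
                    spec = laplace_beltrami_spectrum(
                        mesh, cfg.n_spectrum, normalize=True, vertices=verts
                    )
                except (ValueError, RuntimeError) as exc:
                    logger.warning("spectrum skipped for feature %d: %s", fid, exc)
                    continue
                row = {"region_id": fid}
                row.update(
                    {f"eig_{i + 1}": v for i, v in enumerate(spec.eigenvalues)}
                )
                rows.append(row)
            if rows:
                write_shape_table(
                    ShapeTable(pd.DataFrame(rows)), out / "shapes" / "spectra.csv"
                )
        if cfg.do_zernike and feature_sets:
            rows = []
            for fid, verts in feature_sets.items():
                try:
                    z = zernike_moments(submesh(mesh, verts), cfg.zernike_order)
                except ValueError as exc:
                    logger.warning("zernike skipped for feature %d: %s", fid, exc)
                    continue
                row = {"region_id": fid}
                row.update({f"z_{i + 1}": v for i, v in enumerate(z.values)})
                rows.append(row)
            if rows:
                write_shape_table(
                    ShapeTable(pd.DataFrame(rows)), out / "shapes" / "zernike.csv"
                )
        manifest["stage_seconds"][stage] = time.perf_counter() - t0

        stage = "tables"
        t0 = time.perf_counter()
        measure_fields = [area, meanc, gaussc, gdepth, tdepth]
        for feature_name, feature_labels in (
            ("fold", LabelField(folds.fold_ids, name="fold_ids")),
            ("sulcus", sulci),
            ("fundus", fundi),
        ):
            if feature_labels is None:
                continue
            parts = [
                label_stats.stats_per_label(f, feature_labels, areas=area)
                for f in measure_fields
            ]
            df = pd.concat([p.data for p in parts], ignore_index=True)
            write_shape_table(
                ShapeTable(df), out / "tables" / f"{feature_name}_shapes.csv"
            )
        if labels is not None:
            parts = [
                label_stats.stats_per_label(f, labels, areas=area)
                for f in measure_fields
            ]
            df = pd.concat([p.data for p in parts], ignore_index=True)
            write_shape_table(ShapeTable(df), out / "tables" / "label_shapes.csv")
        manifest["stage_seconds"][stage] = time.perf_counter() - t0
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        logger.error("pipeline failed in stage %s: %s", stage, exc)
        _finish()
        raise
    return _finish()
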
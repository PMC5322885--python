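"""Shared fixtures.  The wrapper-surface/depth computations are the expensive
pieces, so they are computed once per session on each reference fixture and
reused by the unit and acceptance tests."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from foldscape.io_formats import ScalarField, TriangleMesh
from foldscape.mesh_graph import MeshGraph, build_graph
from foldscape.synthetic_fixtures import (
    SheetInfo,
    analytic_depth,
    flask_cavity,
    gyrified_sheet,
    icosphere,
    v_groove_sheet,
)
from foldscape.vertex_shapes import (
    DepthConfig,
    WrapperSurface,
    geodesic_depth,
    make_wrapper_surface,
    travel_depth,
)


@dataclass
class DepthBundle:
    mesh: TriangleMesh
    graph: MeshGraph
    wrapper: WrapperSurface
    geodesic: ScalarField
    travel: ScalarField
    config: DepthConfig
    info: object = None


def _bundle(mesh: TriangleMesh, cfg: DepthConfig, info=None) -> DepthBundle:
    graph = build_graph(mesh)
    wrapper = make_wrapper_surface(mesh, cfg)
    return DepthBundle(
        mesh=mesh,
        graph=graph,
        wrapper=wrapper,
        geodesic=geodesic_depth(mesh, graph, wrapper, cfg),
        travel=travel_depth(mesh, graph, wrapper, cfg),
        config=cfg,
        info=info,
    )


@pytest.fixture(scope="session")
def sphere_mesh() -> TriangleMesh:
    return icosphere(10.0, 3)


@pytest.fixture(scope="session")
def sphere_graph(sphere_mesh) -> MeshGraph:
    return build_graph(sphere_mesh)


@pytest.fixture(scope="session")
def sphere_depths(sphere_mesh) -> DepthBundle:
    return _bundle(sphere_mesh, DepthConfig())


@pytest.fixture(scope="session")
def valley_sheet() -> SheetInfo:
    return gyrified_sheet(nx=40, ny=30, amplitude=10.0, wavelength=6.0, n_valleys=1)


@pytest.fixture(scope="session")
def valley_depths(valley_sheet) -> DepthBundle:
    return _bundle(valley_sheet.mesh, DepthConfig(), info=valley_sheet)


@pytest.fixture(scope="session")
def vgroove_depths() -> DepthBundle:
    info = v_groove_sheet()
    return _bundle(info.mesh, DepthConfig(), info=info)


@pytest.fixture(scope="session")
def flask_depths() -> DepthBundle:
    mesh, info = flask_cavity()
    return _bundle(mesh, DepthConfig(), info=info)


@pytest.fixture(scope="session")
def analytic_valley():
    """Elongated single-valley sheet with an analytic depth field (-z of the
    top surface): fast substrate for fold/fundus/sulcus tests."""
    info = gyrified_sheet(
        nx=44, ny=36, amplitude=10.0, wavelength=8.0, n_valleys=1, valley_len=24.0
    )
    return info, build_graph(info.mesh), analytic_depth(info)
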
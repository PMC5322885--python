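"""Per-vertex surface shape measures: curvature, geodesic depth, travel depth.

Depth is measured against a *wrapper surface*: the morphological closing of
the voxelized mesh interior with a ball probe (default 5 mm), replacing the
convex hull so gyral crowns inside global concavities still get zero depth.
Geodesic depth is the shortest on-surface path to the wrapper-contact set;
travel depth may additionally hop straight through exterior space between
mutually visible points, so travel depth <= geodesic depth everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from skimage import measure as _skmeasure

from ._geometry import MeshDistance, segments_intersect_mesh, voxelize_solid
from .io_formats import ScalarField, TriangleMesh, VolumeImage
from .mesh_graph import MeshGraph, geodesic_disks, vertex_normals, voronoi_area

logger = logging.getLogger(__name__)


@dataclass
class DepthConfig:
    """Wrapper/depth parameters: ball probe radius, voxel grid step, and the
    distance below which a vertex counts as touching the wrapper (all mm)."""

    probe_radius: float = 5.0
    voxel_spacing: float = 1.0
    contact_tolerance: float = 0.1
    max_shortcut_distance: float = 30.0
    max_shortcut_pairs: int = 200_000

    def __post_init__(self) -> None:
        if min(self.probe_radius, self.voxel_spacing, self.contact_tolerance) <= 0:
            raise ValueError("all depth parameters must be positive")


@dataclass
class CurvatureConfig:
    method: str = "normal_directions"
    disk_radius: float = 2.0

    def __post_init__(self) -> None:
        if self.disk_radius <= 0:
            raise ValueError("disk_radius must be positive")
        if self.method not in {"normal_directions", "area_ratio", "laplacian_filter"}:
            raise ValueError(f"unknown curvature method {self.method!r}")


@dataclass
class WrapperSurface:
    """Closed zero-depth reference surface plus the probe radius that built it."""

    mesh: TriangleMesh
    probe_radius: float


# ---------------------------------------------------------------------------
# curvature


def mean_curvature(
    mesh: TriangleMesh, graph: MeshGraph, cfg: CurvatureConfig | None = None
) -> ScalarField:
    """Mean curvature (1/mm) from normal directions in a geodesic disk.

    For each disk member u of vertex v the normal curvature along (u - v) is
    2 * n(v).(u - v) / |u - v|^2 -- exactly 1/R in magnitude on a sphere of
    radius R for every chord.  Averaging over the disk averages the normal
    curvatures over directions, which is the mean curvature.  Sign: positive
    where the surface bends toward the outward normal (concave fold
    interiors), negative on convex crowns.
    """
    cfg = cfg or CurvatureConfig()
    if cfg.method == "laplacian_filter":
        return _laplacian_mean_curvature(mesh, graph)
    if cfg.method == "area_ratio":
        return _area_ratio_mean_curvature(mesh, graph, cfg)
    normals = vertex_normals(mesh)
    disks = geodesic_disks(graph, mesh, cfg.disk_radius)
    h = np.zeros(mesh.n_vertices)
    for v in range(mesh.n_vertices):
        members = disks[v][disks[v] != v]
        if len(members) == 0:
            logger.warning("vertex %d has an empty geodesic disk; curvature 0", v)
            continue
        d = mesh.coordinates[members] - mesh.coordinates[v]
        l2 = (d * d).sum(axis=1)
        h[v] = np.mean(2.0 * (d @ normals[v]) / l2)
    return ScalarField(h, name="mean_curvature", units="1/mm")


def _laplacian_mean_curvature(mesh: TriangleMesh, graph: MeshGraph) -> ScalarField:
    """Mean curvature from the displacement of one umbrella-Laplacian
    smoothing step projected on the normal (saturates for sharp bends)."""
    normals = vertex_normals(mesh)
    h = np.zeros(mesh.n_vertices)
    for v in range(mesh.n_vertices):
        nbrs = graph.neighbors[v]
        if len(nbrs) == 0:
            continue
        disp = mesh.coordinates[nbrs].mean(axis=0) - mesh.coordinates[v]
        l2 = ((mesh.coordinates[nbrs] - mesh.coordinates[v]) ** 2).sum(1).mean()
        h[v] = 2.0 * (disp @ normals[v]) / l2
    return ScalarField(h, name="mean_curvature", units="1/mm")


def _area_ratio_mean_curvature(
    mesh: TriangleMesh, graph: MeshGraph, cfg: CurvatureConfig
) -> ScalarField:
    """Curvature magnitude from the area ratio between a smoothed surface and
    the original, signed by the normal displacement (fast, approximate)."""
    normals = vertex_normals(mesh)
    smoothed = mesh.coordinates.copy()
    for v in range(mesh.n_vertices):
        nbrs = graph.neighbors[v]
        if len(nbrs):
            smoothed[v] = 0.5 * mesh.coordinates[v] + 0.5 * mesh.coordinates[nbrs].mean(axis=0)
    a0 = voronoi_area(mesh).values
    a1 = voronoi_area(TriangleMesh(smoothed, mesh.faces)).values
    with np.errstate(divide="ignore", invalid="ignore"):
        mag = np.where(a0 > 0, np.abs(1.0 - np.sqrt(a1 / np.maximum(a0, 1e-300))), 0.0)
    sign = np.sign(((smoothed - mesh.coordinates) * normals).sum(axis=1))
    l_rms = np.array([
        np.sqrt(np.mean(((mesh.coordinates[graph.neighbors[v]] - mesh.coordinates[v]) ** 2).sum(1)))
        if len(graph.neighbors[v]) else 1.0 for v in range(mesh.n_vertices)
    ])
    # one half-step of smoothing shrinks lengths by ~ (l H)^2 / 4, so the
    # area-ratio magnitude ~ (l H / 2)^2
    return ScalarField(2.0 * sign * np.sqrt(mag) / np.maximum(l_rms, 1e-300),
                       name="mean_curvature", units="1/mm")


def gaussian_curvature(
    mesh: TriangleMesh, graph: MeshGraph, cfg: CurvatureConfig | None = None
) -> ScalarField:
    """Gaussian curvature (1/mm^2) by angle defect over the mixed Voronoi
    area, so the discrete Gauss-Bonnet sum is exact on closed meshes."""
    defect = np.full(mesh.n_vertices, 2.0 * np.pi)
    p = mesh.coordinates[mesh.faces]
    for i in range(3):
        a = p[:, (i + 1) % 3] - p[:, i]
        b = p[:, (i + 2) % 3] - p[:, i]
        na = np.linalg.norm(a, axis=1)
        nb = np.linalg.norm(b, axis=1)
        ok = (na > 1e-14) & (nb > 1e-14)
        cosang = np.ones(len(a))
        cosang[ok] = np.clip((a[ok] * b[ok]).sum(1) / (na[ok] * nb[ok]), -1, 1)
        np.add.at(defect, mesh.faces[:, i], -np.arccos(cosang))
    # boundary vertices have an open link; their defect against pi, not 2 pi
    boundary = _boundary_vertices(mesh)
    defect[boundary] -= np.pi
    area = voronoi_area(mesh).values
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.where(area > 0, defect / np.maximum(area, 1e-300), 0.0)
    return ScalarField(k, name="gaussian_curvature", units="1/mm^2")


def _boundary_vertices(mesh: TriangleMesh) -> np.ndarray:
    e = np.vstack([mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]], mesh.faces[:, [2, 0]]])
    e.sort(axis=1)
    uniq, counts = np.unique(e, axis=0, return_counts=True)
    return np.unique(uniq[counts == 1])


# ---------------------------------------------------------------------------
# wrapper surface


def voxelize_interior(mesh: TriangleMesh, spacing: float = 1.0) -> VolumeImage:
    """Binary image of the closed mesh interior (voxel centers strictly inside)."""
    if not mesh.is_closed():
        raise ValueError("mesh is open; close it (fixtures provide closed solids)")
    return voxelize_solid(mesh, spacing)


def make_wrapper_surface(mesh: TriangleMesh, cfg: DepthConfig | None = None) -> WrapperSurface:
    """Morphological closing of the mesh interior with a ball probe.

    Implemented with Euclidean distance-field level sets for sub-voxel
    accuracy: dilation is the level set {dist(x, solid) = r} of the exact
    point-to-mesh distance, erosion the level set {dist(x, dilation
    complement) = r} of the distance to the marching-cubes dilation surface.
    """
    cfg = cfg or DepthConfig()
    if cfg.probe_radius < cfg.voxel_spacing:
        raise ValueError("probe radius must be at least the voxel spacing")
    if not mesh.is_closed():
        raise ValueError("mesh is open; the wrapper needs a watertight surface")
    s = cfg.voxel_spacing
    r = cfg.probe_radius
    occ = voxelize_solid(mesh, s, pad=r + 3 * s)
    origin = occ.affine[:3, 3]
    shape = occ.data.shape
    centers = _grid_centers(shape, origin, s)
    md = MeshDistance(mesh, max_tri_radius=s)
    d_ap, _ = md.query_approx(centers)
    band = 2.0 * md.tri_radius + 2.0 * s
    d0, _ = md.query(centers, refine_mask=np.abs(d_ap - r) <= band)
    d_solid = np.where(occ.data.ravel() > 0, 0.0, d0).reshape(shape)

    verts, faces, _, _ = _skmeasure.marching_cubes(d_solid, level=r, spacing=(s, s, s))
    dilation = TriangleMesh(verts + origin, faces[:, ::-1].astype(np.int64))

    md1 = MeshDistance(dilation, max_tri_radius=s)
    d1_ap, _ = md1.query_approx(centers)
    band1 = 2.0 * md1.tri_radius + 2.0 * s
    d1, _ = md1.query(centers, refine_mask=np.abs(d1_ap - r) <= band1)
    inside_dilation = (d_solid.ravel() <= r)
    f = np.where(inside_dilation, d1, -d1).reshape(shape)
    verts2, faces2, _, _ = _skmeasure.marching_cubes(f, level=r, spacing=(s, s, s))
    # marching_cubes orients normals toward increasing field values; f grows
    # inward, so flip the winding to get outward normals.
    wrapper = TriangleMesh(verts2 + origin, faces2[:, ::-1].astype(np.int64))
    return WrapperSurface(wrapper, probe_radius=r)


def _grid_centers(shape, origin, spacing: float) -> np.ndarray:
    ii, jj, kk = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]), indexing="ij"
    )
    pts = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3).astype(np.float64)
    return pts * spacing + origin


# ---------------------------------------------------------------------------
# depth


def _contact_and_wrapper_distance(
    mesh: TriangleMesh, wrapper: WrapperSurface, cfg: DepthConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    md = MeshDistance(wrapper.mesh)
    dist, closest = md.query(mesh.coordinates)
    contact = dist < cfg.contact_tolerance
    if not contact.any():
        raise ValueError(
            "no vertex touches the wrapper; the wrapper is too loose "
            "(check probe radius and voxel spacing)"
        )
    return contact, dist, closest


def geodesic_depth(
    mesh: TriangleMesh,
    graph: MeshGraph,
    wrapper: WrapperSurface,
    cfg: DepthConfig | None = None,
) -> ScalarField:
    """Shortest along-surface distance (mm) to the wrapper-contact set."""
    cfg = cfg or DepthConfig()
    contact, _, _ = _contact_and_wrapper_distance(mesh, wrapper, cfg)
    d = dijkstra(graph.weighted, indices=np.flatnonzero(contact), min_only=True)
    d[contact] = 0.0
    d[~np.isfinite(d)] = -1.0  # disconnected from any contact vertex
    return ScalarField(d, name="geodesic_depth", units="mm")


def travel_depth(
    mesh: TriangleMesh,
    graph: MeshGraph,
    wrapper: WrapperSurface,
    cfg: DepthConfig | None = None,
) -> ScalarField:
    """Hybrid depth (mm): on-surface paths plus straight exterior hops.

    The augmented shortest-path graph contains every mesh edge, straight
    "shortcut" edges between mutually visible vertex pairs (segment clears the
    mesh), and a terminal hop from each vertex to its nearest visible wrapper
    point.  Depth is the distance to the wrapper-contact set in this graph,
    so travel depth can never exceed geodesic depth.
    """
    cfg = cfg or DepthConfig()
    contact, dw, closest = _contact_and_wrapper_distance(mesh, wrapper, cfg)
    n = mesh.n_vertices
    occ = voxelize_solid(mesh, cfg.voxel_spacing)
    mesh_dist = MeshDistance(mesh, max_tri_radius=cfg.voxel_spacing)

    # terminal hops: vertex -> nearest wrapper point, if the segment is clear;
    # a segment can tunnel through the solid and exit only at its endpoints
    # (which the face test excuses), so interior samples are checked first
    tunnel = _samples_inside(mesh.coordinates, closest, occ, mesh_dist)
    exclude = [graph.vertex_faces[v] for v in range(n)]
    vis_wrap = ~tunnel & ~segments_intersect_mesh(
        mesh.coordinates, closest, mesh, exclude_faces=exclude
    )
    term = np.where(contact, 0.0, np.where(vis_wrap, dw, np.inf))

    rows, cols, vals = [], [], []
    # vertex-vertex shortcuts, pruned to pairs a straight hop can actually help
    pairs = _shortcut_candidates(mesh, graph, cfg)
    if len(pairs):
        # terminal hops already give visible vertices their straight distance
        # to the wrapper, so a shortcut only matters when it could undercut
        # the provisional depth at one endpoint (or reach a hidden vertex)
        gdep = dijkstra(graph.weighted, indices=np.flatnonzero(contact), min_only=True)
        prov = np.minimum(gdep, term)
        e = np.linalg.norm(
            mesh.coordinates[pairs[:, 0]] - mesh.coordinates[pairs[:, 1]], axis=1
        )
        p_lo = np.minimum(prov[pairs[:, 0]], prov[pairs[:, 1]])
        p_hi = np.maximum(prov[pairs[:, 0]], prov[pairs[:, 1]])
        useful = (p_lo + e < p_hi - 1e-9) | ~np.isfinite(p_hi)
        pairs, e = pairs[useful], e[useful]
    if len(pairs):
        keep = ~_samples_inside(
            mesh.coordinates[pairs[:, 0]], mesh.coordinates[pairs[:, 1]], occ, mesh_dist
        )
        pairs, e = pairs[keep], e[keep]
    if len(pairs) > cfg.max_shortcut_pairs:
        prov_pairs = np.minimum(prov[pairs[:, 0]], prov[pairs[:, 1]])
        gain = np.where(np.isfinite(prov_pairs), np.abs(
            prov[pairs[:, 0]] - prov[pairs[:, 1]]) - e, np.inf)
        order = np.lexsort((pairs[:, 1], pairs[:, 0], -gain))[: cfg.max_shortcut_pairs]
        pairs = pairs[np.sort(order)]
    if len(pairs):
        p, q = pairs[:, 0], pairs[:, 1]
        ex = [np.concatenate([graph.vertex_faces[a], graph.vertex_faces[b]]) for a, b in pairs]
        clear = ~segments_intersect_mesh(
            mesh.coordinates[p], mesh.coordinates[q], mesh, exclude_faces=ex
        )
        keep = pairs[clear]
        if len(keep):
            w = np.linalg.norm(
                mesh.coordinates[keep[:, 0]] - mesh.coordinates[keep[:, 1]], axis=1
            )
            rows += [keep[:, 0], keep[:, 1]]
            cols += [keep[:, 1], keep[:, 0]]
            vals += [w, w]

    # virtual source node n wired to contact (0) and visible-to-wrapper hops
    finite = np.flatnonzero(np.isfinite(term))
    rows += [np.full(len(finite), n), finite]
    cols += [finite, np.full(len(finite), n)]
    vals += [term[finite], term[finite]]

    base = graph.weighted.tocoo()
    rows = np.concatenate([base.row] + [np.asarray(r) for r in rows])
    cols = np.concatenate([base.col] + [np.asarray(c) for c in cols])
    vals = np.concatenate([base.data] + [np.asarray(v, dtype=np.float64) for v in vals])
    aug = csr_matrix((vals, (rows, cols)), shape=(n + 1, n + 1))
    d = dijkstra(aug, indices=n, min_only=True)[:n]
    d[contact] = 0.0
    d[~np.isfinite(d)] = -1.0
    return ScalarField(d, name="travel_depth", units="mm")


def _samples_inside(
    a: np.ndarray, b: np.ndarray, occ: VolumeImage, mesh_dist: MeshDistance
) -> np.ndarray:
    """True per segment when an interior sample lies clearly inside the solid.

    A sample counts only when its voxel is occupied *and* it sits more than
    half a voxel diagonal from the surface, so grazing exterior segments are
    never blocked by occupancy quantization (the face-intersection test
    handles those).
    """
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    spacing = float(occ.voxel_sizes[0])
    margin = 0.87 * spacing
    origin = occ.affine[:3, 3]
    shape = np.array(occ.data.shape)
    inside = np.zeros(len(a), dtype=bool)
    for t in (0.25, 0.5, 0.75):
        p = a + t * (b - a)
        idx = np.round((p - origin) / spacing).astype(np.int64)
        ok = ((idx >= 0) & (idx < shape)).all(axis=1)
        hit = np.zeros(len(a), dtype=bool)
        hit[ok] = occ.data[idx[ok, 0], idx[ok, 1], idx[ok, 2]] > 0
        cand = np.flatnonzero(hit & ~inside)
        if len(cand):
            d, _ = mesh_dist.query_approx(p[cand])
            # query_approx is an upper bound, so d > margin is conservative
            # only up to the bound's slack; refine exactly where it matters
            near = d <= margin + 2.0 * mesh_dist.tri_radius
            if near.any():
                d[near], _ = mesh_dist.query(p[cand][near])
            inside[cand[d > margin]] = True
    return inside


def _shortcut_candidates(
    mesh: TriangleMesh, graph: MeshGraph, cfg: DepthConfig
) -> np.ndarray:
    """Vertex pairs whose straight-line distance beats the on-surface path
    (within the shortcut range); further pruning happens in travel_depth."""
    n = mesh.n_vertices
    gd = dijkstra(graph.weighted)
    from scipy.spatial.distance import cdist

    euclid = cdist(mesh.coordinates, mesh.coordinates)
    iu, ju = np.triu_indices(n, k=1)
    e = euclid[iu, ju]
    g = gd[iu, ju]
    mask = (e <= cfg.max_shortcut_distance) & ((g - e > 1e-9) | np.isinf(g))
    iu, ju = iu[mask], ju[mask]
    return np.stack([iu, ju], axis=1) if len(iu) else np.zeros((0, 2), dtype=np.int64)
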
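"""Low-level geometric primitives: exact point-to-mesh distance, segment
visibility tests, and a scan-column parity voxelizer.

These back the wrapper-surface and travel-depth computations.  Point-triangle
projection is delegated to trimesh; the candidate-triangle prefilter and the
segment-triangle (Moller-Trumbore) test are local because they need bounded
segments and deterministic behavior.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.spatial import cKDTree
from trimesh.triangles import closest_point as _trimesh_closest_point


def _tri_closest_point(triangles, points):
    # trimesh emits spurious divide warnings for degenerate barycentric cases
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.asarray(_trimesh_closest_point(triangles, points))

from .io_formats import TriangleMesh, VolumeImage

logger = logging.getLogger(__name__)


class MeshDistance:
    """Unsigned distance (and closest point) from query points to a mesh.

    ``query_approx`` projects each point onto its nearest-centroid triangle:
    an upper bound whose error is at most two triangle circumradii.
    ``query`` refines by exact point-triangle projection over the ``k``
    nearest centroids, which recovers the true nearest triangle on locally
    uniform triangulations (triangles can be pre-split with
    ``max_tri_radius`` to enforce uniformity) with bounded memory.
    """

    def __init__(self, mesh: TriangleMesh, max_tri_radius: float | None = None):
        tris = np.ascontiguousarray(mesh.coordinates[mesh.faces])
        # zero-area triangles produce NaN projections and add no surface
        area2 = np.linalg.norm(
            np.cross(tris[:, 1] - tris[:, 0], tris[:, 2] - tris[:, 0]), axis=1
        )
        tris = tris[area2 > 1e-14]
        if len(tris) == 0:
            raise ValueError("mesh has no non-degenerate triangles")
        if max_tri_radius is not None:
            # splitting a triangle at its longest edge leaves the union
            # surface unchanged but shrinks the centroid-based error bound
            tris = _subdivide_triangles(tris, max_tri_radius)
        self.triangles = tris
        self.centroids = self.triangles.mean(axis=1)
        # circumradius bound: max distance centroid -> corner
        self.tri_radius = float(
            np.linalg.norm(self.triangles - self.centroids[:, None, :], axis=2).max()
        )
        self.tree = cKDTree(self.centroids)

    def query_approx(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        _, idx = self.tree.query(points)
        closest = _tri_closest_point(self.triangles[idx], points)
        return np.linalg.norm(closest - points, axis=1), closest

    def query(
        self, points: np.ndarray, refine_mask: np.ndarray | None = None,
        k: int = 12, chunk: int = 20_000,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Return (distances, closest_points) for an (Q, 3) array.

        With ``refine_mask`` only the flagged queries are refined; the rest
        keep the (upper bound) nearest-centroid approximation.
        """
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        dist, cp = self.query_approx(points)
        todo = np.flatnonzero(refine_mask) if refine_mask is not None else np.arange(len(points))
        if len(todo) == 0:
            return dist, cp
        k = min(k, len(self.centroids))
        for lo in range(0, len(todo), chunk):
            sel = todo[lo : lo + chunk]
            pts = points[sel]
            _, idx = self.tree.query(pts, k=k)
            idx = np.atleast_2d(idx)
            rep = np.repeat(pts, idx.shape[1], axis=0)
            closest = _tri_closest_point(self.triangles[idx.ravel()], rep)
            d = np.linalg.norm(closest - rep, axis=1).reshape(len(sel), -1)
            best = d.argmin(axis=1)
            rows = np.arange(len(sel))
            dist[sel] = d[rows, best]
            cp[sel] = closest.reshape(len(sel), -1, 3)[rows, best]
        return dist, cp


def _subdivide_triangles(tris: np.ndarray, max_radius: float) -> np.ndarray:
    """Bisect triangles at their longest edge until every circumradius bound
    (max centroid-to-corner distance) is at most ``max_radius``."""
    out = [np.zeros((0, 3, 3))]
    work = tris
    while len(work):
        cent = work.mean(axis=1, keepdims=True)
        radius = np.linalg.norm(work - cent, axis=2).max(axis=1)
        done = (radius <= max_radius) | ~np.isfinite(radius)
        out.append(work[done & np.isfinite(radius)])
        work = work[~done]
        if not len(work):
            break
        edges = np.stack(
            [work[:, 1] - work[:, 0], work[:, 2] - work[:, 1], work[:, 0] - work[:, 2]]
        )
        longest = np.linalg.norm(edges, axis=2).argmax(axis=0)
        a = work[np.arange(len(work)), longest]
        b = work[np.arange(len(work)), (longest + 1) % 3]
        c = work[np.arange(len(work)), (longest + 2) % 3]
        mid = 0.5 * (a + b)
        work = np.concatenate(
            [np.stack([a, mid, c], axis=1), np.stack([mid, b, c], axis=1)]
        )
    return np.concatenate(out)


def segments_intersect_mesh(
    starts: np.ndarray,
    ends: np.ndarray,
    mesh: TriangleMesh,
    exclude_faces: list | None = None,
    eps: float = 1e-6,
    chunk: int = 512,
) -> np.ndarray:
    """Boolean per segment: does the open segment hit any mesh face?

    ``exclude_faces[i]`` lists face indices ignored for segment i (faces
    incident to the segment's endpoints).  The segment is shrunk by ``eps``
    (relative) at both ends so grazing contact at the endpoints never counts.
    """
    starts = np.atleast_2d(starts).astype(np.float64)
    ends = np.atleast_2d(ends).astype(np.float64)
    tri = mesh.coordinates[mesh.faces]  # (F, 3, 3)
    v0, e1, e2 = tri[:, 0], tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]
    tri_lo = tri.min(axis=1)
    tri_hi = tri.max(axis=1)
    out = np.zeros(len(starts), dtype=bool)
    for lo in range(0, len(starts), chunk):
        hi = min(lo + chunk, len(starts))
        s, t = starts[lo:hi], ends[lo:hi]
        # broad phase: segment AABB vs triangle AABB, then narrow-phase
        # Moller-Trumbore only on the overlapping (segment, face) pairs
        seg_lo = np.minimum(s, t)[:, None, :]
        seg_hi = np.maximum(s, t)[:, None, :]
        overlap = (
            (seg_lo <= tri_hi[None, :, :] + 1e-9)
            & (seg_hi >= tri_lo[None, :, :] - 1e-9)
        ).all(axis=2)  # (c, F)
        if exclude_faces is not None:
            for i in range(lo, hi):
                ex = exclude_faces[i]
                if ex is not None and len(ex):
                    overlap[i - lo, np.asarray(ex, dtype=np.int64)] = False
        si, fi = np.nonzero(overlap)
        if len(si) == 0:
            continue
        d = (t - s)[si]
        ss = s[si]
        pvec = np.cross(d, e2[fi])
        det = (e1[fi] * pvec).sum(1)
        good = np.abs(det) > 1e-14
        inv = np.where(good, 1.0 / np.where(det == 0, 1.0, det), 0.0)
        tvec = ss - v0[fi]
        u = (tvec * pvec).sum(1) * inv
        qvec = np.cross(tvec, e1[fi])
        v = (d * qvec).sum(1) * inv
        tt = (e2[fi] * qvec).sum(1) * inv
        hit = (
            good
            & (u >= -1e-12)
            & (v >= -1e-12)
            & (u + v <= 1.0 + 1e-12)
            & (tt > eps)
            & (tt < 1.0 - eps)
        )
        np.logical_or.at(out, si + lo, hit)
    return out


def voxelize_solid(
    mesh: TriangleMesh, spacing: float, pad: float = 1.0
) -> VolumeImage:
    """Binary interior image of a closed mesh by z-column crossing parity.

    The grid is aligned to multiples of ``spacing`` so translating the mesh by
    whole voxels leaves the voxel count unchanged.  Voxel centers strictly
    inside the surface are 1.
    """
    if not mesh.is_closed():
        raise ValueError(
            "mesh is not closed; voxelization needs a watertight surface"
        )
    lo = np.floor((mesh.coordinates.min(axis=0) - pad) / spacing) * spacing
    hi = np.ceil((mesh.coordinates.max(axis=0) + pad) / spacing) * spacing
    shape = np.maximum(np.round((hi - lo) / spacing).astype(int), 1)
    # deterministic sub-voxel shear of column centers avoids edge/vertex hits
    jx, jy = 0.5 + 1.31e-4, 0.5 + 2.47e-4
    xs = lo[0] + (np.arange(shape[0]) + jx) * spacing
    ys = lo[1] + (np.arange(shape[1]) + jy) * spacing

    tri = mesh.coordinates[mesh.faces]
    cross_col: list[np.ndarray] = []
    cross_z: list[np.ndarray] = []
    for f in range(len(tri)):
        a, b, c = tri[f]
        xlo, xhi = min(a[0], b[0], c[0]), max(a[0], b[0], c[0])
        ylo, yhi = min(a[1], b[1], c[1]), max(a[1], b[1], c[1])
        i0 = np.searchsorted(xs, xlo)
        i1 = np.searchsorted(xs, xhi, side="right")
        j0 = np.searchsorted(ys, ylo)
        j1 = np.searchsorted(ys, yhi, side="right")
        if i0 >= i1 or j0 >= j1:
            continue
        gx, gy = np.meshgrid(xs[i0:i1], ys[j0:j1], indexing="ij")
        px = gx.ravel() - a[0]
        py = gy.ravel() - a[1]
        d1 = (b[0] - a[0], b[1] - a[1])
        d2 = (c[0] - a[0], c[1] - a[1])
        det = d1[0] * d2[1] - d1[1] * d2[0]
        if abs(det) < 1e-14:
            continue
        u = (px * d2[1] - py * d2[0]) / det
        v = (-px * d1[1] + py * d1[0]) / det
        inside = (u >= 0.0) & (v >= 0.0) & (u + v <= 1.0)
        if not inside.any():
            continue
        z = a[2] + u[inside] * (b[2] - a[2]) + v[inside] * (c[2] - a[2])
        ii, jj = np.meshgrid(
            np.arange(i0, i1), np.arange(j0, j1), indexing="ij"
        )
        cols = (ii.ravel() * shape[1] + jj.ravel())[inside]
        cross_col.append(cols)
        cross_z.append(z)
    data = np.zeros(shape, dtype=np.uint8)
    if cross_col:
        cols = np.concatenate(cross_col)
        zs = np.concatenate(cross_z)
        order = np.lexsort((zs, cols))
        cols, zs = cols[order], zs[order]
        starts = np.searchsorted(cols, np.arange(shape[0] * shape[1]))
        ends = np.searchsorted(cols, np.arange(shape[0] * shape[1]), side="right")
        z_centers = lo[2] + (np.arange(shape[2]) + 0.5) * spacing
        flat = data.reshape(-1, shape[2])
        odd_cols = 0
        for col in range(shape[0] * shape[1]):
            zc = zs[starts[col] : ends[col]]
            if len(zc) == 0:
                continue
            if len(zc) % 2:
                odd_cols += 1
                continue
            counts = np.searchsorted(zc, z_centers)
            flat[col] = counts % 2
        if odd_cols:
            logger.warning(
                "%d voxel columns had odd crossing parity (near-degenerate geometry)",
                odd_cols,
            )
    if data.sum() == 0:
        logger.warning("voxelization produced an empty volume")
    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = affine[2, 2] = spacing
    affine[:3, 3] = lo + spacing / 2.0
    return VolumeImage(data, affine)
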
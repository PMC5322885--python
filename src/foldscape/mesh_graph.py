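"""Mesh topology utilities shared by every surface algorithm.

Everything here is deterministic: neighbor lists are sorted ascending and all
tie-breaks resolve to the lowest vertex index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse import csgraph

from .io_formats import ScalarField, TriangleMesh

logger = logging.getLogger(__name__)

UNREACHED = -1


@dataclass
class MeshGraph:
    """Vertex adjacency of a triangle mesh.

    ``neighbors[v]`` is the sorted array of vertices sharing an edge with v;
    ``vertex_faces[v]`` the sorted array of faces incident to v.  ``adjacency``
    is the unweighted CSR matrix, ``weighted`` carries Euclidean edge lengths.
    """

    neighbors: list
    vertex_faces: list
    adjacency: sparse.csr_matrix
    weighted: sparse.csr_matrix

    @property
    def n_vertices(self) -> int:
        return self.adjacency.shape[0]


def build_graph(mesh: TriangleMesh) -> MeshGraph:
    n = mesh.n_vertices
    e = np.vstack([mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]], mesh.faces[:, [2, 0]]])
    e.sort(axis=1)
    e = np.unique(e, axis=0)
    rows = np.concatenate([e[:, 0], e[:, 1]])
    cols = np.concatenate([e[:, 1], e[:, 0]])
    ones = np.ones(len(rows), dtype=np.int8)
    adj = sparse.csr_matrix((ones, (rows, cols)), shape=(n, n))
    lengths = np.linalg.norm(
        mesh.coordinates[e[:, 0]] - mesh.coordinates[e[:, 1]], axis=1
    )
    wts = np.concatenate([lengths, lengths])
    weighted = sparse.csr_matrix((wts, (rows, cols)), shape=(n, n))

    neighbors = np.split(adj.indices, adj.indptr[1:-1])
    fidx = np.repeat(np.arange(mesh.n_faces), 3)
    vidx = mesh.faces.ravel()
    order = np.lexsort((fidx, vidx))
    vf_sorted, f_sorted = vidx[order], fidx[order]
    starts = np.searchsorted(vf_sorted, np.arange(n))
    ends = np.searchsorted(vf_sorted, np.arange(n), side="right")
    vertex_faces = [f_sorted[s:t] for s, t in zip(starts, ends)]
    return MeshGraph(list(neighbors), vertex_faces, adj, weighted)


def connected_components(graph: MeshGraph, subset) -> list[np.ndarray]:
    """Connected components of the subgraph induced by ``subset``.

    Returned largest first; ties broken by the smallest contained vertex index.
    """
    subset = np.asarray(sorted(set(int(v) for v in subset)), dtype=np.int64)
    if len(subset) == 0:
        return []
    sub = graph.adjacency[subset][:, subset]
    ncomp, lab = csgraph.connected_components(sub, directed=False)
    comps = [subset[lab == i] for i in range(ncomp)]
    comps.sort(key=lambda c: (-len(c), int(c.min())))
    return comps


def hop_distance(graph: MeshGraph, source: int, cutoff: int) -> np.ndarray:
    """Breadth-first edge counts from ``source``; UNREACHED beyond ``cutoff``."""
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    n = graph.n_vertices
    dist = np.full(n, UNREACHED, dtype=np.int64)
    dist[source] = 0
    frontier = [int(source)]
    for d in range(1, cutoff + 1):
        nxt = []
        for v in frontier:
            for u in graph.neighbors[v]:
                if dist[u] == UNREACHED:
                    dist[u] = d
                    nxt.append(int(u))
        if not nxt:
            break
        frontier = nxt
    return dist


def hop_distance_from_set(
    graph: MeshGraph, sources, cutoff: int | None = None, within=None
) -> np.ndarray:
    """Multi-source BFS hop distance, optionally restricted to ``within`` vertices."""
    n = graph.n_vertices
    dist = np.full(n, UNREACHED, dtype=np.int64)
    allowed = None
    if within is not None:
        allowed = np.zeros(n, dtype=bool)
        allowed[np.asarray(list(within), dtype=np.int64)] = True
    frontier = sorted(set(int(v) for v in sources))
    for v in frontier:
        dist[v] = 0
    d = 0
    while frontier and (cutoff is None or d < cutoff):
        d += 1
        nxt = []
        for v in frontier:
            for u in graph.neighbors[v]:
                if dist[u] == UNREACHED and (allowed is None or allowed[u]):
                    dist[u] = d
                    nxt.append(int(u))
        frontier = nxt
    return dist


def voronoi_area(mesh: TriangleMesh, graph: MeshGraph | None = None) -> ScalarField:
    """Per-vertex surface area (mm^2): mixed Voronoi rule.

    Non-obtuse triangles distribute area by the cotangent Voronoi formula;
    obtuse triangles give 1/2 to the obtuse corner and 1/4 to the others, so
    the per-vertex areas always sum exactly to the total mesh area.
    """
    n = mesh.n_vertices
    area = np.zeros(n)
    p = mesh.coordinates[mesh.faces]  # (M, 3, 3)
    tri_area = mesh.face_areas()
    degenerate = tri_area <= 1e-14
    if degenerate.any():
        logger.warning("%d degenerate faces contribute zero area", int(degenerate.sum()))
    # edge vectors opposite each corner
    e0 = p[:, 2] - p[:, 1]
    e1 = p[:, 0] - p[:, 2]
    e2 = p[:, 1] - p[:, 0]
    l0 = (e0 ** 2).sum(1)
    l1 = (e1 ** 2).sum(1)
    l2 = (e2 ** 2).sum(1)
    with np.errstate(divide="ignore", invalid="ignore"):
        # cot at corner i = (dot of the two edges leaving i) / (2 * area)
        cot0 = (l1 + l2 - l0) / (4.0 * tri_area)
        cot1 = (l2 + l0 - l1) / (4.0 * tri_area)
        cot2 = (l0 + l1 - l2) / (4.0 * tri_area)
    cots = np.stack([cot0, cot1, cot2], axis=1)
    lens = np.stack([l0, l1, l2], axis=1)
    obtuse_corner = np.argmin(cots, axis=1)
    is_obtuse = cots.min(axis=1) < 0.0

    # Voronoi area at corner i = (|e_j|^2 cot_j + |e_k|^2 cot_k) / 8
    for i in range(3):
        j, k = (i + 1) % 3, (i + 2) % 3
        contrib = np.where(
            degenerate,
            0.0,
            np.where(
                is_obtuse,
                np.where(obtuse_corner == i, tri_area / 2.0, tri_area / 4.0),
                (lens[:, j] * cots[:, j] + lens[:, k] * cots[:, k]) / 8.0,
            ),
        )
        np.add.at(area, mesh.faces[:, i], contrib)
    return ScalarField(area, name="area", units="mm^2")


def vertex_normals(mesh: TriangleMesh) -> np.ndarray:
    """Angle-weighted per-vertex unit normals (outward for consistent winding)."""
    p = mesh.coordinates[mesh.faces]
    fn = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    norms = np.linalg.norm(fn, axis=1, keepdims=True)
    fn_unit = np.divide(fn, norms, out=np.zeros_like(fn), where=norms > 1e-14)
    out = np.zeros_like(mesh.coordinates)
    for i in range(3):
        a = p[:, (i + 1) % 3] - p[:, i]
        b = p[:, (i + 2) % 3] - p[:, i]
        na = np.linalg.norm(a, axis=1)
        nb = np.linalg.norm(b, axis=1)
        ok = (na > 1e-14) & (nb > 1e-14)
        cosang = np.zeros(len(a))
        cosang[ok] = np.clip(
            (a[ok] * b[ok]).sum(1) / (na[ok] * nb[ok]), -1.0, 1.0
        )
        ang = np.where(ok, np.arccos(cosang), 0.0)
        np.add.at(out, mesh.faces[:, i], fn_unit * ang[:, None])
    lens = np.linalg.norm(out, axis=1, keepdims=True)
    isolated = lens[:, 0] <= 1e-14
    if isolated.any():
        logger.warning("%d isolated vertices get zero normals", int(isolated.sum()))
    return np.divide(out, lens, out=np.zeros_like(out), where=~isolated[:, None])


def geodesic_disk(
    graph: MeshGraph, mesh: TriangleMesh, center: int, radius: float
) -> np.ndarray:
    """Vertices within graph-geodesic distance ``radius`` (Euclidean edge weights)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    d = csgraph.dijkstra(graph.weighted, indices=center, limit=radius)
    out = np.flatnonzero(np.isfinite(d))
    return out.astype(np.int64)


def geodesic_disks(
    graph: MeshGraph, mesh: TriangleMesh, radius: float
) -> list[np.ndarray]:
    """All per-vertex geodesic disks at once (dense Dijkstra with a limit)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    d = csgraph.dijkstra(graph.weighted, limit=radius)
    return [np.flatnonzero(np.isfinite(row)).astype(np.int64) for row in d]


def is_simple_point(graph: MeshGraph, object_set, v: int) -> bool:
    """True when removing ``v`` from the object keeps the object's topology.

    Criterion: the object members of v's link must form exactly one nonempty
    connected arc among v's neighbors -- and not the entire closed link ring
    (removing an interior vertex of a filled patch would open a hole).
    """
    obj = object_set if isinstance(object_set, (set, frozenset)) else set(
        int(x) for x in object_set
    )
    if v not in obj:
        raise ValueError("v must belong to the object")
    nbrs = graph.neighbors[v]
    members = [int(u) for u in nbrs if int(u) in obj]
    if len(members) <= 1:
        # an isolated vertex or a curve endpoint: not a *simple* point (the
        # erosion treats 1-neighbor endpoints by its own removal rule)
        return False
    member_set = set(members)
    # connectivity among the member neighbors via mesh edges
    comp = 0
    seen: set[int] = set()
    for s in members:
        if s in seen:
            continue
        comp += 1
        if comp > 1:
            return False
        stack = [s]
        seen.add(s)
        while stack:
            x = stack.pop()
            for y in graph.neighbors[x]:
                y = int(y)
                if y in member_set and y not in seen:
                    seen.add(y)
                    stack.append(y)
    if comp != 1:
        return False
    if len(members) == len(nbrs):
        # the full link is in the object; v is interior to a filled patch and
        # its removal would open a hole -- unless the link is an open fan at a
        # mesh boundary, in which case the single-arc test above suffices.
        link_edges = _link_edge_count(graph, v)
        if link_edges == len(nbrs):  # closed ring
            return False
    return True


def _link_edge_count(graph: MeshGraph, v: int) -> int:
    """Number of mesh edges between neighbors of v (link edges)."""
    nbrs = set(int(u) for u in graph.neighbors[v])
    cnt = 0
    for u in nbrs:
        for w in graph.neighbors[u]:
            if int(w) in nbrs and int(w) > u:
                cnt += 1
    return cnt


def submesh(mesh: TriangleMesh, vertices) -> TriangleMesh:
    """Mesh restricted to ``vertices``: faces with all three corners inside.

    Vertices not used by any kept face are dropped; original order preserved.
    """
    vset = np.zeros(mesh.n_vertices, dtype=bool)
    vset[np.asarray(sorted(set(int(v) for v in vertices)), dtype=np.int64)] = True
    keep = vset[mesh.faces].all(axis=1)
    faces = mesh.faces[keep]
    if len(faces) == 0:
        raise ValueError("vertex set induces no complete face")
    used = np.unique(faces)
    remap = np.full(mesh.n_vertices, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return TriangleMesh(mesh.coordinates[used], remap[faces])
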
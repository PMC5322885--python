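"""Graph/topology utilities checked against brute-force oracles."""

import numpy as np
import pytest

from foldscape.io_formats import TriangleMesh
from foldscape.mesh_graph import (
    build_graph,
    connected_components,
    geodesic_disk,
    hop_distance,
    is_simple_point,
    submesh,
    vertex_normals,
    voronoi_area,
)
from foldscape.synthetic_fixtures import gyrified_sheet, icosphere


def _two_triangles():
    coords = np.array([
        [0, 0, 0], [1, 0, 0], [0, 1, 0],
        [5, 0, 0], [6, 0, 0], [5, 1, 0],
    ], dtype=float)
    faces = np.array([[0, 1, 2], [3, 4, 5]])
    return TriangleMesh(coords, faces)


def _flat_grid(n=8, spacing=1.0):
    return gyrified_sheet(nx=n, ny=n, amplitude=0.0, wavelength=1.0,
                          n_valleys=1, spacing=spacing)


class TestBuildGraph:
    def test_single_triangle_degrees(self):
        mesh = TriangleMesh(np.eye(3), np.array([[0, 1, 2]]))
        g = build_graph(mesh)
        assert [len(g.neighbors[v]) for v in range(3)] == [2, 2, 2]

    def test_icosahedron_every_vertex_degree_5(self):
        g = build_graph(icosphere(1.0, 0))
        assert all(len(nb) == 5 for nb in g.neighbors)

    def test_disjoint_triangles(self):
        g = build_graph(_two_triangles())
        assert g.n_vertices == 6
        assert all(len(nb) == 2 for nb in g.neighbors)

    def test_adjacency_symmetric_and_sorted(self):
        g = build_graph(icosphere(1.0, 1))
        for v, nbrs in enumerate(g.neighbors):
            assert list(nbrs) == sorted(nbrs)
            assert all(v in g.neighbors[u] for u in nbrs)


class TestConnectedComponents:
    def test_whole_connected_mesh_single_component(self):
        g = build_graph(icosphere(1.0, 1))
        comps = connected_components(g, range(g.n_vertices))
        assert len(comps) == 1

    def test_two_disjoint_triangles(self):
        g = build_graph(_two_triangles())
        comps = connected_components(g, range(6))
        assert [sorted(c) for c in comps] == [[0, 1, 2], [3, 4, 5]]

    def test_random_subset_matches_union_find_oracle(self):
        info = _flat_grid(8)
        g = build_graph(info.mesh)
        rng = np.random.default_rng(42)
        subset = rng.choice(g.n_vertices, size=50, replace=False)

        # union-find oracle over the induced subgraph
        parent = {int(v): int(v) for v in subset}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        sub = set(int(v) for v in subset)
        for v in sub:
            for u in g.neighbors[v]:
                if int(u) in sub:
                    parent[find(int(u))] = find(v)
        oracle = {}
        for v in sub:
            oracle.setdefault(find(v), set()).add(v)
        got = {frozenset(int(x) for x in c) for c in connected_components(g, subset)}
        assert got == {frozenset(c) for c in oracle.values()}

    def test_order_largest_first_tie_by_min_index(self):
        g = build_graph(_two_triangles())
        comps = connected_components(g, [3, 4, 5, 0, 1, 2])
        assert sorted(comps[0]) == [0, 1, 2]


class TestHopDistance:
    def test_source_is_zero(self):
        g = build_graph(icosphere(1.0, 1))
        assert hop_distance(g, 7, 3)[7] == 0

    def test_cutoff_marks_unreached(self):
        mesh = TriangleMesh(
            np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0], [1.5, 1, 0]], dtype=float),
            np.array([[0, 1, 4], [1, 2, 4], [2, 3, 4]]),
        )
        g = build_graph(mesh)
        d = hop_distance(g, 0, 1)
        assert d[0] == 0 and d[1] == 1 and d[4] == 1
        assert d[2] == -1 and d[3] == -1

    def test_matches_bfs_oracle_on_icosphere(self):
        g = build_graph(icosphere(1.0, 2))
        from collections import deque

        def bfs(src):
            dist = {src: 0}
            q = deque([src])
            while q:
                v = q.popleft()
                for u in g.neighbors[v]:
                    if int(u) not in dist:
                        dist[int(u)] = dist[v] + 1
                        q.append(int(u))
            return dist

        for src in (0, 17, 101):
            oracle = bfs(src)
            got = hop_distance(g, src, cutoff=100)
            for v in range(g.n_vertices):
                assert got[v] == oracle[v]


class TestVoronoiArea:
    def test_equilateral_triangle_split_three_ways(self):
        side = 1.0
        mesh = TriangleMesh(
            np.array([[0, 0, 0], [side, 0, 0], [side / 2, side * np.sqrt(3) / 2, 0]]),
            np.array([[0, 1, 2]]),
        )
        a = voronoi_area(mesh).values
        assert np.allclose(a, (np.sqrt(3) / 4) / 3)

    @pytest.mark.parametrize("fixture", ["sphere", "sheet"])
    def test_total_area_conserved(self, fixture):
        mesh = icosphere(3.0, 3) if fixture == "sphere" else _flat_grid(10).mesh
        a = voronoi_area(mesh).values
        assert a.sum() == pytest.approx(mesh.face_areas().sum(), rel=1e-9)
        assert (a[np.unique(mesh.faces)] > 0).all()

    def test_uniform_grid_interior_equal_areas(self):
        info = _flat_grid(9)
        nx, ny = info.grid_shape
        interior = [i * ny + j for i in range(2, nx - 2) for j in range(2, ny - 2)]
        a = voronoi_area(info.mesh).values[interior]
        assert np.allclose(a, a[0], rtol=1e-9)

    def test_obtuse_triangle_mixed_rule_conserves(self):
        mesh = TriangleMesh(
            np.array([[0, 0, 0], [4, 0, 0], [2, 0.3, 0]]), np.array([[0, 1, 2]])
        )
        a = voronoi_area(mesh).values
        assert a.sum() == pytest.approx(mesh.face_areas().sum(), rel=1e-12)
        assert a[2] == pytest.approx(mesh.face_areas().sum() / 2)


class TestVertexNormals:
    def test_icosphere_normals_radial(self):
        mesh = icosphere(1.0, 3)
        n = vertex_normals(mesh)
        dots = (n * mesh.coordinates).sum(axis=1)
        assert (dots > 0.99).all()

    def test_flat_sheet_normals_vertical(self):
        info = _flat_grid(6)
        n = vertex_normals(info.mesh)
        nx, ny = info.grid_shape
        interior = [i * ny + j for i in range(1, nx - 1) for j in range(1, ny - 1)]
        assert np.allclose(n[interior], [0, 0, 1], atol=1e-9)
        bottom_interior = [nx * ny + v for v in interior]
        assert np.allclose(n[bottom_interior], [0, 0, -1], atol=1e-9)

    def test_flipping_winding_flips_normals(self):
        mesh = icosphere(1.0, 2)
        flipped = TriangleMesh(mesh.coordinates.copy(), mesh.faces[:, ::-1].copy())
        assert np.allclose(vertex_normals(mesh), -vertex_normals(flipped), atol=1e-12)

    def test_unit_norm(self):
        mesh = icosphere(2.0, 2)
        n = vertex_normals(mesh)
        assert np.allclose(np.linalg.norm(n, axis=1), 1.0, atol=1e-9)


class TestGeodesicDisk:
    def test_tiny_radius_is_center_only(self):
        mesh = icosphere(10.0, 2)
        g = build_graph(mesh)
        assert list(geodesic_disk(g, mesh, 5, 1e-6)) == [5]

    def test_unit_grid_radius_one_is_four_neighborhood(self):
        info = _flat_grid(7)
        g = build_graph(info.mesh)
        nx, ny = info.grid_shape
        center = 3 * ny + 3
        disk = set(geodesic_disk(g, info.mesh, center, 1.0))
        expected = {center, center - 1, center + 1, center - ny, center + ny}
        # grid diagonals have length sqrt(2) > 1, so exactly the 4-neighborhood
        assert disk == expected

    def test_monotone_in_radius(self):
        mesh = icosphere(5.0, 2)
        g = build_graph(mesh)
        d1 = set(geodesic_disk(g, mesh, 0, 2.0))
        d2 = set(geodesic_disk(g, mesh, 0, 4.0))
        assert d1 <= d2

    def test_matches_dijkstra_oracle(self):
        mesh = icosphere(5.0, 2)
        g = build_graph(mesh)
        import heapq

        def dijkstra_oracle(src, radius):
            dist = {src: 0.0}
            heap = [(0.0, src)]
            while heap:
                d, v = heapq.heappop(heap)
                if d > dist[v]:
                    continue
                for u in g.neighbors[v]:
                    nd = d + np.linalg.norm(mesh.coordinates[v] - mesh.coordinates[u])
                    if nd <= radius and nd < dist.get(int(u), np.inf):
                        dist[int(u)] = nd
                        heapq.heappush(heap, (nd, int(u)))
            return set(dist)

        assert set(geodesic_disk(g, mesh, 11, 3.0)) == dijkstra_oracle(11, 3.0)


def _euler_characteristic(mesh, obj):
    obj = set(int(v) for v in obj)
    v = len(obj)
    e = sum(1 for a, b in mesh.edges() if a in obj and b in obj)
    f = sum(1 for tri in mesh.faces if all(int(x) in obj for x in tri))
    return v - e + f


def _component_count(graph, obj):
    return len(connected_components(graph, obj))


class TestSimplePoint:
    def test_path_endpoint_not_simple_by_link_test(self):
        info = _flat_grid(6)
        g = build_graph(info.mesh)
        ny = info.grid_shape[1]
        path = [0, ny, 2 * ny]  # straight 1-thick column path
        assert not is_simple_point(g, set(path), 0)

    def test_interior_of_filled_disk_not_simple(self, sphere_mesh, sphere_graph):
        g = sphere_graph
        center = 0
        patch = {0} | {int(u) for u in g.neighbors[0]}
        for u in list(patch):
            patch |= {int(w) for w in g.neighbors[u]}
        assert not is_simple_point(g, patch, center)

    def test_boundary_of_filled_disk_simple(self, sphere_mesh, sphere_graph):
        g = sphere_graph
        patch = {0} | {int(u) for u in g.neighbors[0]}
        boundary_vertex = int(g.neighbors[0][0])
        assert is_simple_point(g, patch, boundary_vertex)

    def test_approved_removals_preserve_topology_exhaustively(self):
        """On a small patch, removing any approved vertex never changes the
        component count or the Euler characteristic."""
        info = _flat_grid(7)
        mesh, g = info.mesh, build_graph(info.mesh)
        rng = np.random.default_rng(3)
        ny = info.grid_shape[1]
        top = [i * ny + j for i in range(7) for j in range(7)]
        for trial in range(8):
            obj = set(int(v) for v in rng.choice(top, size=30, replace=False))
            for v in sorted(obj):
                if not is_simple_point(g, obj, v):
                    continue
                before = (_component_count(g, obj), _euler_characteristic(mesh, obj))
                removed = obj - {v}
                after = (_component_count(g, removed), _euler_characteristic(mesh, removed))
                assert before == after, f"vertex {v} approved but changed topology"


class TestSubmesh:
    def test_submesh_keeps_complete_faces_only(self):
        mesh = icosphere(1.0, 1)
        g = build_graph(mesh)
        verts = {0} | {int(u) for u in g.neighbors[0]}
        sub = submesh(mesh, verts)
        assert sub.n_faces == len(g.neighbors[0])
        assert sub.n_vertices == len(verts)
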
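"""Deterministic synthetic substrates for every stage of the pipeline.

The generators emulate, at desk scale, the geometry the surface and volume
algorithms meet on real brains: an icosphere stands in for a convex cortical
hull, a "gyrified" sheet with Gaussian-profile grooves for folded cortex with
analytically known valley floors, label-painted valleys for gyral label pairs
bounding a sulcus, spherical-shell volumes for a cortex/white-matter
segmentation, and a noisy segmentation pair for two tissue classifiers that
make different kinds of mistakes.  Identical parameters (and seed) always
reproduce the fixture bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import LabelField, TriangleMesh, VolumeImage


# ---------------------------------------------------------------------------
# icosphere

_ICO_T = (1.0 + np.sqrt(5.0)) / 2.0
_ICO_VERTS = np.array(
    [
        [-1, _ICO_T, 0], [1, _ICO_T, 0], [-1, -_ICO_T, 0], [1, -_ICO_T, 0],
        [0, -1, _ICO_T], [0, 1, _ICO_T], [0, -1, -_ICO_T], [0, 1, -_ICO_T],
        [_ICO_T, 0, -1], [_ICO_T, 0, 1], [-_ICO_T, 0, -1], [-_ICO_T, 0, 1],
    ],
    dtype=np.float64,
)
_ICO_FACES = np.array(
    [
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ],
    dtype=np.int64,
)


def icosphere(radius: float = 1.0, subdivisions: int = 2) -> TriangleMesh:
    """Closed, outward-oriented sphere mesh: icosahedron + Loop-style midpoint
    subdivision, every vertex projected to the requested radius."""
    if subdivisions > 6:
        raise ValueError("subdivisions > 6 would be needlessly large")
    verts = _ICO_VERTS.copy()
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = _ICO_FACES.copy()
    for _ in range(subdivisions):
        cache: dict[tuple[int, int], int] = {}
        new_faces = []
        verts_list = list(verts)

        def midpoint(i: int, j: int) -> int:
            key = (min(i, j), max(i, j))
            if key not in cache:
                m = verts_list[i] + verts_list[j]
                m /= np.linalg.norm(m)
                cache[key] = len(verts_list)
                verts_list.append(m)
            return cache[key]

        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        verts = np.array(verts_list)
        faces = np.array(new_faces, dtype=np.int64)
    return TriangleMesh(verts * radius, faces)


# ---------------------------------------------------------------------------
# gyrified sheet


@dataclass
class SheetInfo:
    """A folded sheet plus its analytic ground truth."""

    mesh: TriangleMesh
    top_vertices: np.ndarray          # indices of the folded top surface
    valley_floor_lines: list = field(default_factory=list)  # one index array per valley
    valley_centers_x: np.ndarray = field(default_factory=lambda: np.zeros(0))
    grid_shape: tuple = (0, 0)
    spacing: float = 1.0
    amplitude: float = 0.0


def _groove_profile(x: np.ndarray, centers: np.ndarray, amplitude: float, wavelength: float) -> np.ndarray:
    """Sum of C1 Gaussian grooves; each floor is a unique line (no plateau)."""
    sigma = wavelength / 4.0
    z = np.zeros_like(x)
    for c in centers:
        z -= amplitude * np.exp(-((x - c) ** 2) / (2.0 * sigma ** 2))
    return z


def _sheet_from_heights(xs: np.ndarray, ys: np.ndarray, gz: np.ndarray, wall: float) -> TriangleMesh:
    """Watertight slab: folded top grid, flat bottom grid, stitched side walls."""
    nx, ny = len(xs), len(ys)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    zmin = gz.min() - wall
    top = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    bot = np.stack([gx.ravel(), gy.ravel(), np.full(nx * ny, zmin)], axis=1)
    verts = np.vstack([top, bot])
    nvert_top = nx * ny

    def vid(i: int, j: int, layer: int) -> int:
        return layer * nvert_top + i * ny + j

    faces: list[list[int]] = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a, b = vid(i, j, 0), vid(i + 1, j, 0)
            c, d = vid(i + 1, j + 1, 0), vid(i, j + 1, 0)
            faces += [[a, b, c], [a, c, d]]              # top, normal +z
            a, b = vid(i, j, 1), vid(i + 1, j, 1)
            c, d = vid(i + 1, j + 1, 1), vid(i, j + 1, 1)
            faces += [[a, c, b], [a, d, c]]              # bottom, normal -z
    # side walls (outward normals)
    for i in range(nx - 1):
        faces += [[vid(i, 0, 0), vid(i, 0, 1), vid(i + 1, 0, 1)],
                  [vid(i, 0, 0), vid(i + 1, 0, 1), vid(i + 1, 0, 0)]]
        j = ny - 1
        faces += [[vid(i, j, 0), vid(i + 1, j, 0), vid(i + 1, j, 1)],
                  [vid(i, j, 0), vid(i + 1, j, 1), vid(i, j, 1)]]
    for j in range(ny - 1):
        faces += [[vid(0, j, 0), vid(0, j + 1, 1), vid(0, j, 1)],
                  [vid(0, j, 0), vid(0, j + 1, 0), vid(0, j + 1, 1)]]
        i = nx - 1
        faces += [[vid(i, j, 0), vid(i, j, 1), vid(i, j + 1, 1)],
                  [vid(i, j, 0), vid(i, j + 1, 1), vid(i, j + 1, 0)]]
    return TriangleMesh(verts, np.array(faces, dtype=np.int64))


def gyrified_sheet(
    nx: int = 40,
    ny: int = 30,
    amplitude: float = 10.0,
    wavelength: float = 6.0,
    n_valleys: int = 1,
    spacing: float = 1.0,
    wall: float = 3.0,
    valley_len: float | None = None,
) -> SheetInfo:
    """Closed slab whose top surface carries ``n_valleys`` parallel grooves.

    Valleys run along y; groove centers are spaced evenly in x and must not
    overlap (center spacing > 2 * wavelength).  With ``valley_len`` the
    grooves are windowed in y into elongated elliptical pits of roughly that
    length centered in the sheet.
    """
    if amplitude < 0 or wavelength <= 0:
        raise ValueError("amplitude must be >= 0 and wavelength > 0")
    lx = (nx - 1) * spacing
    centers = (np.arange(n_valleys) + 1.0) * lx / (n_valleys + 1.0)
    if n_valleys > 1 and np.diff(centers).min() <= 2.0 * wavelength:
        raise ValueError("valleys overlap; increase nx or reduce wavelength/n_valleys")
    xs = np.arange(nx) * spacing
    ys = np.arange(ny) * spacing
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    gz = _groove_profile(gx, centers, amplitude, wavelength)
    if valley_len is not None:
        cy = ys[-1] / 2.0
        sigma_y = valley_len / 4.0
        gz *= np.exp(-((gy - cy) ** 2) / (2.0 * sigma_y ** 2))
    mesh = _sheet_from_heights(xs, ys, gz, wall)

    ny_ = len(ys)
    floor_lines = []
    for c in centers:
        i_floor = int(np.argmin(np.abs(xs - c)))
        js = np.arange(ny_)
        if valley_len is not None:
            cy = ys[-1] / 2.0
            js = js[np.abs(ys - cy) <= valley_len / 2.0]
        floor_lines.append((i_floor * ny_ + js).astype(np.int64))
    return SheetInfo(
        mesh=mesh,
        top_vertices=np.arange(nx * ny_, dtype=np.int64),
        valley_floor_lines=floor_lines,
        valley_centers_x=centers,
        grid_shape=(nx, ny_),
        spacing=spacing,
        amplitude=amplitude,
    )


def v_groove_sheet(
    depth: float = 10.0,
    half_width: float = 1.5,
    margin: float = 10.0,
    plateau: float = 6.0,
    taper: float = 5.0,
    y_margin: float = 5.0,
    spacing: float = 1.0,
    fine: float = 0.25,
    wall: float = 3.0,
) -> SheetInfo:
    """Slab with one narrow straight-walled V-groove along y.

    The groove profile z = -depth * (1 - |x - c| / half_width) is carved at
    full depth over a ``plateau`` stretch of y and tapers linearly to zero
    over ``taper`` so the floor cannot escape to zero depth along the groove;
    the x grid is refined to ``fine`` inside the groove so the sharp profile
    is represented faithfully.  The groove is so narrow that exterior hops
    barely beat on-surface paths (travel depth ~ geodesic depth).  The floor
    line metadata covers only the full-depth plateau.
    """
    c = margin + half_width
    xs = np.unique(np.concatenate([
        np.arange(0.0, margin, spacing),
        np.arange(margin, margin + 2 * half_width + fine / 2, fine),
        np.arange(margin + 2 * half_width, 2 * c + spacing / 2, spacing),
    ]))
    ly = plateau + 2 * taper + 2 * y_margin
    ys = np.arange(0.0, ly + spacing / 2, spacing)
    cy = ly / 2.0
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    cross = np.maximum(0.0, 1.0 - np.abs(gx - c) / half_width)
    window = np.clip((plateau / 2.0 + taper - np.abs(gy - cy)) / taper, 0.0, 1.0)
    gz = -depth * cross * window
    mesh = _sheet_from_heights(xs, ys, gz, wall)
    i_floor = int(np.argmin(np.abs(xs - c)))
    js = np.flatnonzero(np.abs(ys - cy) <= plateau / 2.0)
    floor = (i_floor * len(ys) + js).astype(np.int64)
    return SheetInfo(
        mesh=mesh,
        top_vertices=np.arange(len(xs) * len(ys), dtype=np.int64),
        valley_floor_lines=[floor],
        valley_centers_x=np.array([c]),
        grid_shape=(len(xs), len(ys)),
        spacing=spacing,
        amplitude=depth,
    )


def labeled_valley(
    nx: int = 40,
    ny: int = 30,
    amplitude: float = 10.0,
    wavelength: float = 6.0,
    spacing: float = 1.0,
    scheme: str = "two_banks",
) -> tuple[SheetInfo, LabelField, dict]:
    """Single-valley sheet with region labels painted across the valley.

    ``two_banks``: labels 1|2 split at the valley midline (boundary on the
    floor); protocol {(1,2): 0}.  ``three_bands``: labels 1|2|3 in three x
    bands with two boundaries; protocol {(1,2): 0, (2,3): 1}.
    """
    info = gyrified_sheet(nx, ny, amplitude, wavelength, n_valleys=1, spacing=spacing)
    x = info.mesh.coordinates[:, 0]
    c = info.valley_centers_x[0]
    labels = np.zeros(info.mesh.n_vertices, dtype=np.int64)
    if scheme == "two_banks":
        labels[:] = np.where(x < c, 1, 2)
        protocol = {frozenset({1, 2}): 0}
    elif scheme == "three_bands":
        sigma = wavelength / 4.0
        labels[:] = np.where(x < c - sigma, 1, np.where(x <= c + sigma, 2, 3))
        protocol = {frozenset({1, 2}): 0, frozenset({2, 3}): 1}
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return info, LabelField(labels, name="labels"), protocol


def analytic_depth(info: SheetInfo):
    """Ground-truth depth field of a sheet fixture: -z on the folded top
    surface (the pial-like side), zero on the bottom and walls."""
    from .io_formats import ScalarField

    depth = np.zeros(info.mesh.n_vertices)
    top = info.top_vertices
    depth[top] = np.maximum(-info.mesh.coordinates[top, 2], 0.0)
    return ScalarField(depth, name="depth", units="mm")


# ---------------------------------------------------------------------------
# solid of revolution (overhanging-cavity fixtures)


def solid_of_revolution(
    profile_r: np.ndarray, profile_z: np.ndarray, n_theta: int = 48
) -> TriangleMesh:
    """Revolve an open (r, z) profile about the z axis into a closed mesh.

    The profile must start and end on the axis (r == 0); consecutive profile
    rows are stitched into quad strips, and axis endpoints become fan poles.
    Winding is chosen so normals point away from the enclosed solid when the
    profile runs top-to-bottom around the material on its right.
    """
    r = np.asarray(profile_r, dtype=np.float64)
    z = np.asarray(profile_z, dtype=np.float64)
    if r[0] != 0.0 or r[-1] != 0.0:
        raise ValueError("profile must start and end on the axis (r = 0)")
    # coincident consecutive points would stitch zero-area quads
    keep = np.ones(len(r), dtype=bool)
    keep[1:] = (np.abs(np.diff(r)) > 1e-12) | (np.abs(np.diff(z)) > 1e-12)
    r, z = r[keep], z[keep]
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    verts = [np.array([0.0, 0.0, z[0]])]
    ring_start = []
    for k in range(1, len(r) - 1):
        ring_start.append(len(verts))
        for t in range(n_theta):
            verts.append(np.array([r[k] * cos_t[t], r[k] * sin_t[t], z[k]]))
    bottom_pole = len(verts)
    verts.append(np.array([0.0, 0.0, z[-1]]))
    faces: list[list[int]] = []
    first = ring_start[0]
    for t in range(n_theta):
        faces.append([0, first + t, first + (t + 1) % n_theta])
    for k in range(len(ring_start) - 1):
        a0, b0 = ring_start[k], ring_start[k + 1]
        for t in range(n_theta):
            t2 = (t + 1) % n_theta
            faces += [[a0 + t, b0 + t, b0 + t2], [a0 + t, b0 + t2, a0 + t2]]
    last = ring_start[-1]
    for t in range(n_theta):
        faces.append([bottom_pole, last + (t + 1) % n_theta, last + t])
    return TriangleMesh(np.array(verts), np.array(faces, dtype=np.int64))


def flask_cavity(
    cavity_radius: float = 4.8,
    mouth_radius: float = 1.5,
    block_radius: float = 14.0,
    block_height: float = 14.0,
    n_theta: int = 48,
    n_cap: int = 14,
    profile_step: float = 2.0,
) -> tuple[TriangleMesh, dict]:
    """Cylindrical block with a spherical flask cavity opening through a
    narrow mouth in its top face: the cavity belly overhangs the mouth.

    The default belly diameter (9 mm) is below the default 10 mm closing
    probe, so a wrapper surface bridges the mouth instead of entering the
    cavity.  Straight profile stretches are resampled at ``profile_step`` so
    flat faces carry interior vertices (the wrapper contact set).  Returns
    the closed mesh and a dict with the analytic cavity geometry (mouth ring
    at height 0, sphere center depth, bottom-pole depth).
    """
    R, a = cavity_radius, mouth_radius
    if a >= R:
        raise ValueError("mouth must be narrower than the cavity")
    d = float(np.sqrt(R * R - a * a))        # sphere center depth below the top
    # profile runs from the bottom axis up the outside, across the top to the
    # mouth, then around the cavity sphere to its bottom pole on the axis
    ang = np.linspace(np.arcsin(a / R), np.pi, n_cap)  # polar angle from +z of sphere
    cav_r = R * np.sin(ang)
    cav_r[-1] = 0.0  # exact axis endpoint
    cav_z = -d + R * np.cos(ang)
    corners_r = [0.0, block_radius, block_radius, a]
    corners_z = [-block_height, -block_height, 0.0, 0.0]
    prof_r, prof_z = [], []
    for (r0, z0), (r1, z1) in zip(
        zip(corners_r[:-1], corners_z[:-1]), zip(corners_r[1:], corners_z[1:])
    ):
        steps = max(1, int(np.ceil(np.hypot(r1 - r0, z1 - z0) / profile_step)))
        t = np.arange(steps) / steps
        prof_r.extend(r0 + t * (r1 - r0))
        prof_z.extend(z0 + t * (z1 - z0))
    prof_r = np.concatenate([prof_r, [a], cav_r])
    prof_z = np.concatenate([prof_z, [0.0], cav_z])
    # orient top-to-bottom so outward normals are correct: reverse profile
    mesh = solid_of_revolution(prof_r[::-1], prof_z[::-1], n_theta=n_theta)
    info = {
        "mouth_radius": a,
        "cavity_radius": R,
        "center_depth": d,
        "pole_depth": d + R,
    }
    return mesh, info


# ---------------------------------------------------------------------------
# shell volumes and segmentation pairs

BACKGROUND_CLASS, NONCORTEX_CLASS, CORTEX_CLASS = 0, 1, 2


def shell_volume(
    inner_r: float = 40.0, outer_r: float = 43.0, spacing: float = 1.0, pad: float = 3.0
) -> tuple[VolumeImage, VolumeImage]:
    """Spherical-shell segmentation: cortex (2) shell over a non-cortex (1) ball.

    Returns (segmented, region_labels); the region label 1 covers the shell.
    """
    if outer_r <= inner_r:
        raise ValueError("outer_r must exceed inner_r")
    half = outer_r + pad
    n = int(np.ceil(2 * half / spacing))
    ax = (np.arange(n) + 0.5) * spacing - half
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    rho = np.sqrt(x * x + y * y + z * z)
    seg = np.zeros((n, n, n), dtype=np.int16)
    seg[rho < inner_r] = NONCORTEX_CLASS
    seg[(rho >= inner_r) & (rho < outer_r)] = CORTEX_CLASS
    labels = np.zeros_like(seg)
    labels[seg == CORTEX_CLASS] = 1
    affine = np.diag([spacing, spacing, spacing, 1.0])
    affine[:3, 3] = -half + spacing / 2.0
    return VolumeImage(seg, affine), VolumeImage(labels, affine.copy())


@dataclass
class SegmentationPair:
    """Cortex / non-cortex binaries from two segmentation sources on one grid."""

    cortex_a: VolumeImage
    noncortex_a: VolumeImage
    cortex_b: VolumeImage
    noncortex_b: VolumeImage

    def __post_init__(self) -> None:
        grids = [self.noncortex_a, self.cortex_b, self.noncortex_b]
        if not all(self.cortex_a.same_grid(v) for v in grids):
            raise ValueError("segmentation pair volumes must share one grid")
        for cx, nc in ((self.cortex_a, self.noncortex_a), (self.cortex_b, self.noncortex_b)):
            if np.logical_and(cx.data > 0, nc.data > 0).any():
                raise ValueError("cortex and non-cortex overlap within one source")


def segmentation_pair(
    segmented: VolumeImage, seed: int = 0, flip_rate: float = 0.01
) -> SegmentationPair:
    """Two noisy copies of a ground-truth segmentation with source-specific
    error modes: source A loses peripheral cortex (surface-reconstruction
    overcropping), source B adds exterior gray matter and loses deep
    non-cortex (white matter in gyral folds)."""
    if not 0.0 <= flip_rate < 1.0:
        raise ValueError("flip_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    seg = segmented.data
    cortex = seg == CORTEX_CLASS
    nonc = seg == NONCORTEX_CLASS
    from scipy import ndimage

    outer_shell = cortex & ~ndimage.binary_erosion(cortex | nonc)
    cortex_a = cortex & ~(outer_shell & (rng.random(seg.shape) < flip_rate))
    noncortex_a = nonc.copy()

    exterior_rim = ~(cortex | nonc) & ndimage.binary_dilation(cortex)
    cortex_b = cortex | (exterior_rim & (rng.random(seg.shape) < flip_rate))
    deep = ndimage.binary_erosion(nonc)
    noncortex_b = nonc & ~(deep & (rng.random(seg.shape) < flip_rate))

    aff = segmented.affine
    mk = lambda m: VolumeImage(m.astype(np.uint8), aff.copy())
    return SegmentationPair(mk(cortex_a), mk(noncortex_a), mk(cortex_b), mk(noncortex_b))
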
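"""Intrinsic whole-shape descriptors for vertex collections.

Two families:

* the Laplace-Beltrami spectrum ("Shape-DNA"): ascending eigenvalues of the
  generalized problem  S f = lam M f  with P1 finite elements (cotangent
  stiffness S, consistent mass M) and natural boundary conditions on open
  patches, with optional area/index normalization that removes scale and
  flattens the linear Weyl growth; plus the plain truncated L2 distance and
  the weighted spectral distance (WESD) between spectra;

* 3-D Zernike moment invariants: rotation-invariant norms of the projection
  of the enclosed solid onto the orthogonal Zernike basis on the unit ball,
  computed exactly from per-triangle geometric moments of signed tetrahedra.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from math import factorial

import numpy as np
from scipy import sparse
from scipy.signal import fftconvolve
from scipy.sparse.linalg import eigsh

from .io_formats import TriangleMesh
from .mesh_graph import submesh

logger = logging.getLogger(__name__)

ZERO_EIGENVALUE_RTOL = 1e-8


@dataclass
class Spectrum:
    """Laplace-Beltrami eigenvalues (ascending, 1/mm^2) of one surface patch."""

    eigenvalues: np.ndarray
    area: float
    normalized: bool = False

    def __post_init__(self) -> None:
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=np.float64)
        if not self.normalized and len(self.eigenvalues) and np.any(
            np.diff(self.eigenvalues) < -1e-9 * max(1.0, abs(self.eigenvalues[-1]))
        ):
            # the area/index normalization flattens Weyl growth and need not
            # stay monotone, so only raw spectra are required to be ascending
            raise ValueError("eigenvalues must be ascending")

    def nonzero(self) -> np.ndarray:
        """Eigenvalues with the (near-)zero leading mode(s) dropped."""
        if self.normalized:
            return self.eigenvalues
        if len(self.eigenvalues) == 0:
            return self.eigenvalues
        tol = ZERO_EIGENVALUE_RTOL * max(1.0, float(np.abs(self.eigenvalues).max()))
        return self.eigenvalues[self.eigenvalues > tol]


@dataclass
class WesdParams:
    p: float = 2.0
    N: int = 10

    def __post_init__(self) -> None:
        if self.p < 1 or self.N < 1:
            raise ValueError("p must be >= 1 and N >= 1")


@dataclass
class ZernikeDescriptor:
    order: int
    values: np.ndarray  # one entry per (n, l) pair, n <= order, n - l even

    def __post_init__(self) -> None:
        if len(self.values) != descriptor_count(self.order):
            raise ValueError("descriptor length does not match the order")


# ---------------------------------------------------------------------------
# FEM Laplace-Beltrami


def fem_matrices(
    mesh: TriangleMesh, vertices=None
) -> tuple[sparse.csr_matrix, sparse.csr_matrix]:
    """P1 FEM (stiffness, mass) for a mesh or a vertex-subset patch.

    Stiffness is the cotangent Laplacian (positive semidefinite, constants in
    the kernel); mass is the consistent (non-lumped) P1 matrix whose entries
    sum to the patch area.  Degenerate faces are skipped with a warning.
    """
    patch = mesh if vertices is None else submesh(mesh, vertices)
    n = patch.n_vertices
    p = patch.coordinates[patch.faces]
    areas = patch.face_areas()
    bad = areas <= 1e-14
    if bad.any():
        logger.warning("%d degenerate faces excluded from FEM assembly", int(bad.sum()))
    rows, cols, s_vals, m_vals = [], [], [], []
    for i in range(3):
        j, k = (i + 1) % 3, (i + 2) % 3
        e1 = p[:, j] - p[:, i]
        e2 = p[:, k] - p[:, i]
        cross = np.linalg.norm(np.cross(e1, e2), axis=1)
        cot = np.where(bad, 0.0, (e1 * e2).sum(1) / np.maximum(cross, 1e-300))
        # off-diagonal for edge (j, k): -cot(angle at i)/2
        rows += [patch.faces[:, j], patch.faces[:, k]]
        cols += [patch.faces[:, k], patch.faces[:, j]]
        s_vals += [-cot / 2.0, -cot / 2.0]
        m_off = np.where(bad, 0.0, areas / 12.0)
        m_vals += [m_off, m_off]
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    S = sparse.csr_matrix((np.concatenate(s_vals), (rows, cols)), shape=(n, n))
    S = S - sparse.diags(np.asarray(S.sum(axis=1)).ravel())
    M = sparse.csr_matrix((np.concatenate(m_vals), (rows, cols)), shape=(n, n))
    diag = np.zeros(n)
    np.add.at(diag, patch.faces.ravel(), np.repeat(np.where(bad, 0.0, areas / 6.0), 3))
    M = M + sparse.diags(diag)
    return S.tocsr(), M.tocsr()


def laplace_beltrami_spectrum(
    patch: TriangleMesh,
    n_eigenvalues: int = 10,
    normalize: bool = False,
    vertices=None,
) -> Spectrum:
    """First eigenvalues of the Laplace-Beltrami operator on a patch.

    Closed patches (and Neumann open patches) have a leading ~0 eigenvalue.
    With ``normalize`` the zero mode is dropped and the remaining values are
    mapped to lam_i * area / i (i = 1, 2, ...), which is scale-invariant and
    compensates Weyl's linear growth.
    """
    mesh = patch if vertices is None else submesh(patch, vertices)
    S, M = fem_matrices(mesh)
    n = mesh.n_vertices
    want = n_eigenvalues + (1 if normalize else 0)
    if want > n - 1:
        raise ValueError("n_eigenvalues must be at most vertex count - 1")
    v0 = np.sin(np.arange(n) + 1.0)  # deterministic generic start vector
    try:
        vals = eigsh(S, k=want, M=M, sigma=-0.01, which="LM",
                     v0=v0, return_eigenvectors=False)
    except Exception as exc:  # pragma: no cover - solver diagnostics path
        raise RuntimeError(
            f"eigensolver failed on patch with {n} vertices "
            f"(stiffness nnz={S.nnz}, mass nnz={M.nnz}): {exc}"
        ) from exc
    vals = np.sort(vals)
    vals[np.abs(vals) < ZERO_EIGENVALUE_RTOL * max(1.0, abs(vals[-1]))] = 0.0
    area = float(mesh.face_areas().sum())
    if normalize:
        raw = Spectrum(vals, area).nonzero()[:n_eigenvalues]
        idx = np.arange(1, len(raw) + 1, dtype=np.float64)
        return Spectrum(raw * area / idx, area, normalized=True)
    return Spectrum(vals[:n_eigenvalues], area)


def spectrum_distance(a: Spectrum, b: Spectrum, N: int) -> float:
    """Euclidean (L2) distance of the first N nonzero eigenvalues."""
    va, vb = a.nonzero(), b.nonzero()
    if len(va) < N or len(vb) < N:
        raise ValueError(f"both spectra need at least N={N} nonzero eigenvalues")
    return float(np.linalg.norm(va[:N] - vb[:N]))


def wesd(a: Spectrum, b: Spectrum, params: WesdParams | None = None) -> float:
    """Weighted spectral distance: Lp norm of the reciprocal-eigenvalue gap.

    The term for mode n is |lam_n^A - lam_n^B| / (lam_n^A lam_n^B), i.e. the
    difference of 1/lam vectors, so WESD is a true pseudo-metric (symmetry and
    the triangle inequality hold exactly) and, because 1/lam_n decays like
    1/n on surfaces, the influence of additional modes shrinks with N.
    """
    params = params or WesdParams()
    va, vb = a.nonzero(), b.nonzero()
    if len(va) < params.N or len(vb) < params.N:
        raise ValueError(f"both spectra need at least N={params.N} nonzero eigenvalues")
    w = np.abs(1.0 / va[: params.N] - 1.0 / vb[: params.N])
    return float((w ** params.p).sum() ** (1.0 / params.p))


# ---------------------------------------------------------------------------
# 3-D Zernike moments


def descriptor_count(order: int) -> int:
    """Number of rotation-invariant (n, l) descriptors up to ``order``:
    pairs with 0 <= l <= n <= order and n - l even."""
    if order < 0:
        raise ValueError("order must be >= 0")
    return sum(n // 2 + 1 for n in range(order + 1))


def geometric_moments(mesh: TriangleMesh, order: int, chunk: int = 128) -> np.ndarray:
    """Exact monomial moments m[a, b, c] = int_solid x^a y^b z^c dV, a+b+c <= order.

    The solid is the union of signed tetrahedra (origin, v0, v1, v2) over the
    faces; for closed outward-oriented meshes this is the enclosed volume, for
    open patches the cone solid over the patch.  Per tetrahedron the moment
    reduces to a 3-D convolution of per-vertex monomial tensors weighted by
    trinomial coefficients (exact simplex integration, no quadrature).
    """
    n1 = order + 1
    fact = np.array([float(factorial(i)) for i in range(3 * order + 4)])
    tri = np.zeros((n1, n1, n1))
    for a in range(n1):
        for b in range(n1 - a):
            for c in range(n1 - a - b):
                tri[a, b, c] = fact[a + b + c] / (fact[a] * fact[b] * fact[c])
    abc = np.array([(a, b, c) for a in range(n1) for b in range(n1 - a)
                    for c in range(n1 - a - b)])
    weight = np.zeros((n1, n1, n1))
    for a, b, c in abc:
        weight[a, b, c] = fact[a] * fact[b] * fact[c] / fact[a + b + c + 3]

    verts = mesh.coordinates[mesh.faces]  # (F, 3 corners, 3 xyz)
    det = np.linalg.det(verts)            # 6 * signed tet volume
    powers = verts[:, :, :, None] ** np.arange(n1)  # (F, corner, xyz, power)
    out = np.zeros((n1, n1, n1))
    for lo in range(0, len(verts), chunk):
        hi = min(lo + chunk, len(verts))
        t = []
        for corner in range(3):
            px = powers[lo:hi, corner, 0][:, :, None, None]
            py = powers[lo:hi, corner, 1][:, None, :, None]
            pz = powers[lo:hi, corner, 2][:, None, None, :]
            t.append(tri[None] * px * py * pz)
        conv = fftconvolve(fftconvolve(t[0], t[1], axes=(1, 2, 3)), t[2], axes=(1, 2, 3))
        conv = conv[:, :n1, :n1, :n1]
        out += np.tensordot(det[lo:hi], conv, axes=(0, 0))
    return out * weight


@lru_cache(maxsize=None)
def _radial_coefficients(n: int, l: int) -> tuple:
    """Coefficients c_nu of R_nl(r) = sum_nu c_nu r^(l + 2 nu), orthonormal
    under int_0^1 R R' r^2 dr, built by exact Gram-Schmidt over rationals."""
    k = (n - l) // 2
    basis = [l + 2 * v for v in range(k + 1)]

    def inner(u: list[Fraction], v: list[Fraction]) -> Fraction:
        tot = Fraction(0)
        for a in range(k + 1):
            if u[a] == 0:
                continue
            for b in range(k + 1):
                if v[b]:
                    tot += u[a] * v[b] * Fraction(1, basis[a] + basis[b] + 3)
        return tot

    # classic Gram-Schmidt over exact rationals, unnormalized
    ortho: list[list[Fraction]] = []
    norms2: list[Fraction] = []
    for i in range(k + 1):
        vec = [Fraction(0)] * (k + 1)
        vec[i] = Fraction(1)
        for j in range(i):
            coef = inner(vec, ortho[j]) / norms2[j]
            vec = [vec[b] - coef * ortho[j][b] for b in range(k + 1)]
        ortho.append(vec)
        norms2.append(inner(vec, vec))
    scale = 1.0 / float(norms2[k]) ** 0.5
    return tuple(float(c) * scale for c in ortho[k])


@lru_cache(maxsize=None)
def _solid_harmonic(l: int, m: int) -> np.ndarray:
    """Complex monomial coefficients of the regular solid harmonic
    R_l^m = r^l P_l^m(cos th) e^(i m phi) / (l + m)!  as an (l+1, l+1, l+1)
    array over exponents (a, b, c), homogeneous of degree l.

    Built from the standard recurrences
        R_l^l = -(x + i y) R_(l-1)^(l-1) / (2 l)
        R_l^m = ((2l-1) z R_(l-1)^m - r^2 R_(l-2)^m) / ((l+m)(l-m)).
    """
    if m < 0 or m > l:
        raise ValueError("need 0 <= m <= l")
    size = l + 1
    if l == 0:
        out = np.zeros((1, 1, 1), dtype=complex)
        out[0, 0, 0] = 1.0
        return out
    if m == l:
        prev = _solid_harmonic(l - 1, l - 1)
        out = np.zeros((size,) * 3, dtype=complex)
        out[1:, : size - 1, : size - 1] += prev * (-1.0 / (2 * l))
        out[: size - 1, 1:, : size - 1] += prev * (-1j / (2 * l))
        return out
    out = np.zeros((size,) * 3, dtype=complex)
    prev = _solid_harmonic(l - 1, m)
    out[: l, : l, 1 : l + 1] += (2 * l - 1) * prev
    if l - 2 >= m:
        pp = _solid_harmonic(l - 2, m)
        s = l - 1
        out[2:, : s, : s] -= pp
        out[: s, 2:, : s] -= pp
        out[: s, : s, 2:] -= pp
    return out / ((l + m) * (l - m))


@lru_cache(maxsize=None)
def _zernike_poly(n: int, l: int, m: int) -> np.ndarray:
    """Monomial coefficients of Z_nlm = R_nl(r) Y_lm, shape (n+1, n+1, n+1)."""
    norm = np.sqrt((2 * l + 1) / (4.0 * np.pi) * factorial(l + m) * factorial(l - m))
    harm = _solid_harmonic(l, m) * norm
    radial = _radial_coefficients(n, l)
    size = n + 1
    out = np.zeros((size,) * 3, dtype=complex)
    r2 = np.zeros((3,) * 3)
    r2[2, 0, 0] = r2[0, 2, 0] = r2[0, 0, 2] = 1.0
    mult = np.zeros((1, 1, 1))
    mult[0, 0, 0] = 1.0  # (x^2+y^2+z^2)^nu accumulator
    for nu, c in enumerate(radial):
        if nu > 0:
            mult = _poly_mul(mult, r2)
        if c == 0.0:
            continue
        term = _poly_mul(harm.real, mult) + 1j * _poly_mul(harm.imag, mult)
        deg = term.shape[0]
        out[:deg, :deg, :deg] += c * term
    return out


def _poly_mul(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    sa, sb = a.shape[0], b.shape[0]
    out = np.zeros((sa + sb - 1,) * 3, dtype=np.result_type(a, b))
    idx = np.argwhere(b != 0)
    for i, j, k in idx:
        out[i : i + sa, j : j + sa, k : k + sa] += b[i, j, k] * a
    return out


def zernike_pairs(order: int) -> list[tuple[int, int]]:
    """(n, l) index pairs in canonical order."""
    return [(n, l) for n in range(order + 1) for l in range(n % 2, n + 1, 2)]


def zernike_moments(patch: TriangleMesh, order: int = 10) -> ZernikeDescriptor:
    """Rotation-invariant 3-D Zernike descriptors of the solid enclosed by a patch.

    The patch is translated to its solid centroid and scaled into the unit
    ball, geometric moments are computed exactly from signed tetrahedra, and
    each descriptor is the norm over m of the Zernike coefficients
    Omega_nlm = (3 / 4 pi) <solid, Z_nlm>.  Values are typically <= 1; larger
    values are logged as a numerical-instability warning.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    if patch.n_faces == 0:
        raise ValueError("empty patch")
    m1 = geometric_moments(patch, 1)
    vol = m1[0, 0, 0]
    if abs(vol) < 1e-12:
        raise ValueError("patch encloses (near-)zero volume")
    centroid = np.array([m1[1, 0, 0], m1[0, 1, 0], m1[0, 0, 1]]) / vol
    centered = patch.coordinates - centroid
    scale = np.linalg.norm(centered, axis=1).max()
    mesh = TriangleMesh(centered / scale, patch.faces)
    mom = geometric_moments(mesh, order)

    values = []
    for n, l in zernike_pairs(order):
        total = 0.0
        for m in range(l + 1):
            poly = _zernike_poly(n, l, m)
            om = (3.0 / (4.0 * np.pi)) * np.vdot(poly, mom[: n + 1, : n + 1, : n + 1])
            total += (1.0 if m == 0 else 2.0) * abs(om) ** 2
        values.append(np.sqrt(total))
    values = np.array(values)
    if (values > 1.0 + 1e-9).any():
        logger.warning(
            "%d Zernike descriptors exceed 1 (possible instability at order %d)",
            int((values > 1.0 + 1e-9).sum()), order,
        )
    return ZernikeDescriptor(order=order, values=values)
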
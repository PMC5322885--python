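"""Core data containers and strict readers/writers for the three external formats.

Surfaces travel as legacy ASCII VTK PolyData (the only dialect accepted or
emitted), volumes as NIfTI-1 via nibabel, and per-region shape values as
plain CSV tables with a header row.  All coordinates are world millimetres in
the subject's own space; per-vertex fields use -1 as the missing/background
sentinel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for undefined per-vertex values and background feature ids.
BACKGROUND = -1


class FormatError(ValueError):
    """Raised when an input file violates the documented dialect."""


@dataclass
class TriangleMesh:
    """Triangle surface mesh: ``coordinates`` (N, 3) in mm, ``faces`` (M, 3) vertex indices."""

    coordinates: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.coordinates = np.ascontiguousarray(self.coordinates, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be (N, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (M, 3)")
        n = len(self.coordinates)
        if n < 3:
            raise ValueError("a mesh needs at least 3 vertices")
        if len(self.faces) < 1:
            raise ValueError("a mesh needs at least 1 face")
        if self.faces.min() < 0 or self.faces.max() >= n:
            raise ValueError("face index out of range")
        if (
            (self.faces[:, 0] == self.faces[:, 1])
            | (self.faces[:, 1] == self.faces[:, 2])
            | (self.faces[:, 0] == self.faces[:, 2])
        ).any():
            raise ValueError("a face repeats a vertex")

    @property
    def n_vertices(self) -> int:
        return len(self.coordinates)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def edges(self) -> np.ndarray:
        """Unique undirected edges as a sorted (E, 2) integer array."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def face_areas(self) -> np.ndarray:
        p = self.coordinates[self.faces]
        return 0.5 * np.linalg.norm(
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
        )

    def is_closed(self) -> bool:
        """True when every undirected edge borders exactly two faces."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e.sort(axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool((counts == 2).all())


@dataclass
class ScalarField:
    """Per-vertex real values aligned to a mesh; -1 marks undefined entries."""

    values: np.ndarray
    name: str
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.ascontiguousarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("field values must be a 1-D vector")


@dataclass
class LabelField:
    """Per-vertex integer labels; background is -1."""

    labels: np.ndarray
    name: str = "labels"

    def __post_init__(self) -> None:
        self.labels = np.ascontiguousarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1:
            raise ValueError("labels must be a 1-D vector")
        if self.labels.min(initial=0) < BACKGROUND:
            raise ValueError("labels must be >= -1")


Field = Union[ScalarField, LabelField]


@dataclass
class VolumeImage:
    """3-D voxel grid plus a 4x4 voxel-to-mm affine."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3-D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Voxel edge lengths in mm, read off the affine columns."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3 (determinant of the linear part)."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def same_grid(self, other: "VolumeImage", tol: float = 1e-6) -> bool:
        return self.data.shape == other.data.shape and bool(
            np.allclose(self.affine, other.affine, atol=tol)
        )


@dataclass
class ShapeTable:
    """Per-region shape values: a DataFrame keyed by region_id (and optionally measure)."""

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "region_id" not in self.data.columns:
            raise ValueError("ShapeTable needs a region_id column")
        keys = ["region_id"] + (["measure"] if "measure" in self.data.columns else [])
        if self.data.duplicated(subset=keys).any():
            raise ValueError("duplicate (region_id, measure) keys")

    def sorted(self) -> pd.DataFrame:
        keys = ["region_id"] + (["measure"] if "measure" in self.data.columns else [])
        return self.data.sort_values(keys, kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# VTK legacy ASCII PolyData

_VTK_INT_TYPES = {"int", "long", "short", "vtkidtype", "unsigned_int", "unsigned_long"}
_VTK_FLOAT_TYPES = {"float", "double"}


def write_vtk_surface(
    mesh: TriangleMesh, fields: Sequence[Field], path: Union[str, Path]
) -> Path:
    """Write a mesh and its point-data fields as legacy ASCII VTK PolyData.

    Floats are printed with %.17g so that a write/read cycle is bitwise
    lossless for float64 values.  Field lengths are validated before anything
    touches the filesystem.
    """
    path = Path(path)
    for f in fields:
        vec = f.values if isinstance(f, ScalarField) else f.labels
        if len(vec) != mesh.n_vertices:
            raise ValueError(
                f"field {f.name!r} has length {len(vec)}, mesh has {mesh.n_vertices} vertices"
            )
    lines = [
        "# vtk DataFile Version 4.2",
        "foldscape surface",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {mesh.n_vertices} double",
    ]
    for p in mesh.coordinates:
        lines.append(" ".join("%.17g" % c for c in p))
    lines.append(f"POLYGONS {mesh.n_faces} {4 * mesh.n_faces}")
    for tri in mesh.faces:
        lines.append("3 %d %d %d" % tuple(tri))
    if fields:
        lines.append(f"POINT_DATA {mesh.n_vertices}")
        for f in fields:
            if isinstance(f, LabelField):
                lines.append(f"SCALARS {f.name} int 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend("%d" % v for v in f.labels)
            else:
                lines.append(f"SCALARS {f.name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend("%.17g" % v for v in f.values)
    path.write_text("\n".join(lines) + "\n")
    return path


def read_vtk_surface(path: Union[str, Path]) -> tuple[TriangleMesh, list[Field]]:
    """Read legacy ASCII VTK PolyData with POINTS, triangle POLYGONS and SCALARS arrays."""
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith("<"):
        raise FormatError(
            f"{path}: XML VTK is not supported; convert to legacy ASCII PolyData"
        )
    lines = [ln.strip() for ln in text.splitlines()]
    lines = [ln for ln in lines if ln]
    if len(lines) < 5 or not lines[0].startswith("# vtk DataFile"):
        raise FormatError(f"{path}: missing legacy VTK header")
    if lines[2].upper() != "ASCII":
        raise FormatError(f"{path}: only ASCII files are supported")
    if lines[3].upper() != "DATASET POLYDATA":
        raise FormatError(f"{path}: only DATASET POLYDATA is supported")

    # tokenize everything after the four header lines, keeping section keywords
    tokens: list[str] = []
    for ln in lines[4:]:
        tokens.extend(ln.split())
    pos = 0

    def expect(kw: str) -> None:
        nonlocal pos
        if pos >= len(tokens) or tokens[pos].upper() != kw:
            got = tokens[pos] if pos < len(tokens) else "<eof>"
            raise FormatError(f"{path}: expected {kw}, got {got}")
        pos += 1

    expect("POINTS")
    n = int(tokens[pos]); pos += 1
    pos += 1  # dtype
    coords = np.array(tokens[pos : pos + 3 * n], dtype=np.float64).reshape(n, 3)
    pos += 3 * n

    expect("POLYGONS")
    m = int(tokens[pos]); pos += 1
    total = int(tokens[pos]); pos += 1
    faces = np.empty((m, 3), dtype=np.int64)
    for i in range(m):
        k = int(tokens[pos]); pos += 1
        if k != 3:
            raise FormatError(f"{path}: polygon {i} has {k} vertices; only triangles allowed")
        faces[i] = [int(tokens[pos]), int(tokens[pos + 1]), int(tokens[pos + 2])]
        pos += 3
    if total != 4 * m:
        raise FormatError(f"{path}: POLYGONS size field {total} != {4 * m}")
    if faces.min() < 0 or faces.max() >= n:
        bad = int(np.argmax((faces < 0).any(axis=1) | (faces >= n).any(axis=1)))
        raise FormatError(f"{path}: face {bad} references a vertex outside [0, {n})")
    mesh = TriangleMesh(coords, faces)

    fields: list[Field] = []
    if pos < len(tokens):
        expect("POINT_DATA")
        npd = int(tokens[pos]); pos += 1
        if npd != n:
            raise FormatError(f"{path}: POINT_DATA count {npd} != POINTS count {n}")
        while pos < len(tokens):
            expect("SCALARS")
            name = tokens[pos]; dtype = tokens[pos + 1].lower(); pos += 2
            ncomp = 1
            if pos < len(tokens) and tokens[pos].isdigit():
                ncomp = int(tokens[pos]); pos += 1
            if ncomp != 1:
                raise FormatError(f"{path}: SCALARS {name} has {ncomp} components; only 1 supported")
            if pos < len(tokens) and tokens[pos].upper() == "LOOKUP_TABLE":
                pos += 2
            raw = tokens[pos : pos + n]
            if len(raw) < n:
                raise FormatError(f"{path}: SCALARS {name} truncated")
            pos += n
            if dtype in _VTK_INT_TYPES:
                fields.append(LabelField(np.array(raw, dtype=np.int64), name=name))
            elif dtype in _VTK_FLOAT_TYPES:
                fields.append(ScalarField(np.array(raw, dtype=np.float64), name=name))
            else:
                raise FormatError(f"{path}: unsupported SCALARS type {dtype}")
    return mesh, fields


# ---------------------------------------------------------------------------
# NIfTI volumes


def read_volume(path: Union[str, Path]) -> VolumeImage:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(
            f"{path}: volume is {data.ndim}-D; extract a single 3-D image first"
        )
    return VolumeImage(data, np.asarray(img.affine))


def write_volume(vol: VolumeImage, path: Union[str, Path]) -> Path:
    path = Path(path)
    data = vol.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(data, vol.affine), str(path))
    return path


# ---------------------------------------------------------------------------
# CSV shape tables


def write_shape_table(table: ShapeTable, path: Union[str, Path]) -> Path:
    """Emit a ShapeTable as CSV: header row, rows sorted by region_id then measure."""
    path = Path(path)
    df = table.sorted()
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_shape_table(path: Union[str, Path]) -> ShapeTable:
    return ShapeTable(pd.read_csv(path))
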
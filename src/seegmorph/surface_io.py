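"""File I/O for cortical surfaces, curvature maps and electrode tables.

Supported formats
-----------------
* FreeSurfer binary *triangle* surfaces (big-endian, 3-byte magic
  ``0xff 0xff 0xfe``): vertex coordinates in surface-RAS millimetres,
  0-based triangular faces. Quad and ASCII variants are rejected.
* FreeSurfer curvature files: the "new" format (magic ``0xff 0xff 0xff``,
  three int32 header fields, float32 values) is read and written; the old
  int16 format is read only.
* Electrode tables: UTF-8 TSV with header columns ``name``, ``x``, ``y``,
  ``z`` and an optional ``lead`` column grouping contacts on one trajectory.
  Coordinates are surface-RAS millimetres.
* Mesh export to ASCII PLY or Wavefront OBJ for external 3-D viewers.

All inputs are assumed to share the FreeSurfer surface-RAS frame of the
reconstruction; no affine handling is performed. A bounding-box sanity
warning is emitted when an electrode falls far outside the surface extent.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._exceptions import (
    CorruptFileError,
    FormatError,
    InconsistencyError,
    ValidationError,
)

__all__ = [
    "SurfaceMesh",
    "CurvatureMap",
    "ElectrodeSet",
    "read_freesurfer_surface",
    "write_freesurfer_surface",
    "read_curvature",
    "write_curvature",
    "read_electrodes",
    "write_electrodes",
    "write_mesh",
]

TRIANGLE_MAGIC = b"\xff\xff\xfe"
NEW_CURV_MAGIC = b"\xff\xff\xff"
_CREATOR_COMMENT = b"created by seegmorph\n\n"

HEMISPHERES = ("left", "right", "unknown")


@dataclass(frozen=True)
class SurfaceMesh:
    """One hemisphere surface: vertices (mm, surface-RAS) and triangle faces.

    Parameters
    ----------
    vertices : (N, 3) float array
        Vertex coordinates in millimetres.
    faces : (M, 3) int array
        0-based vertex indices, winding as stored on disk.
    hemisphere : {"left", "right", "unknown"}
    """

    vertices: np.ndarray
    faces: np.ndarray
    hemisphere: str = "unknown"

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=np.float64)
        f = np.asarray(self.faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValidationError(f"vertices must be (N, 3), got {v.shape}")
        if f.ndim != 2 or f.shape[1] != 3:
            raise ValidationError(f"faces must be (M, 3), got {f.shape}")
        if v.shape[0] < 3:
            raise ValidationError(f"need at least 3 vertices, got {v.shape[0]}")
        if f.shape[0] < 1:
            raise ValidationError("need at least 1 face")
        if not np.all(np.isfinite(v)):
            raise ValidationError("vertex coordinates contain NaN or infinity")
        if f.size and (f.min() < 0 or f.max() >= v.shape[0]):
            raise ValidationError(
                f"face indices must lie in [0, {v.shape[0] - 1}]"
            )
        if self.hemisphere not in HEMISPHERES:
            raise ValidationError(
                f"hemisphere must be one of {HEMISPHERES}, got {self.hemisphere!r}"
            )
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]


@dataclass(frozen=True)
class CurvatureMap:
    """Per-vertex curvature, FreeSurfer convention: positive = sulcal."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64).ravel()
        if v.size == 0:
            raise ValidationError("curvature map is empty")
        if np.any(np.isnan(v)):
            raise ValidationError("curvature values contain NaN")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class ElectrodeSet:
    """Named 3-D contact coordinates with optional per-contact lead grouping."""

    names: tuple
    positions: np.ndarray
    lead: tuple | None = field(default=None)

    def __post_init__(self) -> None:
        names = tuple(str(n) for n in self.names)
        pos = np.asarray(self.positions, dtype=np.float64).reshape(-1, 3)
        if len(names) != pos.shape[0]:
            raise ValidationError(
                f"{len(names)} names but {pos.shape[0]} positions"
            )
        if any(n == "" for n in names):
            raise ValidationError("electrode names must be non-empty")
        seen: set = set()
        for n in names:
            if n in seen:
                raise ValidationError(f"duplicate electrode name {n!r}")
            seen.add(n)
        if np.any(np.isnan(pos)):
            raise ValidationError("electrode positions contain NaN")
        lead = self.lead
        if lead is not None:
            lead = tuple(str(x) for x in lead)
            if len(lead) != len(names):
                raise ValidationError(
                    f"{len(lead)} lead labels but {len(names)} contacts"
                )
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "lead", lead)

    def __len__(self) -> int:
        return len(self.names)


def _hemisphere_from_name(path: Path) -> str:
    name = path.name
    if name.startswith("lh."):
        return "left"
    if name.startswith("rh."):
        return "right"
    return "unknown"


def read_freesurfer_surface(path) -> SurfaceMesh:
    """Read a FreeSurfer binary triangle surface.

    The hemisphere tag is inferred from an ``lh.``/``rh.`` filename prefix.

    Raises
    ------
    FormatError
        If the 3-byte magic is not the triangle-file magic ``0xfffffe``.
    CorruptFileError
        If the payload is truncated.
    """
    path = Path(path)
    with open(path, "rb") as f:
        magic = f.read(3)
        if len(magic) < 3:
            raise CorruptFileError(f"{path}: file shorter than magic")
        if magic != TRIANGLE_MAGIC:
            raise FormatError(
                f"{path}: unsupported FreeSurfer magic 0x{magic.hex()}; "
                "only triangle files (magic 0xfffffe) are supported"
            )
        # creator comment: one text line plus a terminating blank line
        f.readline()
        f.readline()
        head = f.read(8)
        if len(head) < 8:
            raise CorruptFileError(f"{path}: truncated header")
        vnum, fnum = struct.unpack(">2i", head)
        if vnum < 0 or fnum < 0:
            raise CorruptFileError(f"{path}: negative counts {vnum}/{fnum}")
        vbytes = f.read(vnum * 12)
        if len(vbytes) < vnum * 12:
            raise CorruptFileError(f"{path}: truncated vertex block")
        fbytes = f.read(fnum * 12)
        if len(fbytes) < fnum * 12:
            raise CorruptFileError(f"{path}: truncated face block")
    vertices = np.frombuffer(vbytes, dtype=">f4").reshape(vnum, 3)
    faces = np.frombuffer(fbytes, dtype=">i4").reshape(fnum, 3)
    return SurfaceMesh(
        vertices.astype(np.float64),
        faces.astype(np.int64),
        hemisphere=_hemisphere_from_name(path),
    )


def write_freesurfer_surface(mesh: SurfaceMesh, path) -> None:
    """Write a mesh as a FreeSurfer binary triangle surface.

    Coordinates are stored as big-endian float32 (the on-disk precision of
    the format); a fixed creator comment is emitted for bit-reproducibility.
    """
    path = Path(path)
    with open(path, "wb") as f:
        f.write(TRIANGLE_MAGIC)
        f.write(_CREATOR_COMMENT)
        f.write(struct.pack(">2i", mesh.n_vertices, mesh.n_faces))
        f.write(mesh.vertices.astype(">f4").tobytes())
        f.write(mesh.faces.astype(">i4").tobytes())


def read_curvature(path, surface: SurfaceMesh | None = None) -> CurvatureMap:
    """Read a FreeSurfer curvature file (new float32 or old int16 format).

    If *surface* is given, the value count must match its vertex count.
    """
    path = Path(path)
    with open(path, "rb") as f:
        magic = f.read(3)
        if len(magic) < 3:
            raise CorruptFileError(f"{path}: file shorter than magic")
        if magic == NEW_CURV_MAGIC:
            head = f.read(12)
            if len(head) < 12:
                raise CorruptFileError(f"{path}: truncated curv header")
            vnum, _fnum, vals_per_vertex = struct.unpack(">3i", head)
            if vals_per_vertex != 1:
                raise FormatError(
                    f"{path}: {vals_per_vertex} values per vertex unsupported"
                )
            data = f.read(vnum * 4)
            if len(data) < vnum * 4:
                raise CorruptFileError(f"{path}: truncated curv values")
            values = np.frombuffer(data, dtype=">f4").astype(np.float64)
        else:
            # old format: 3-byte vertex count, 3-byte face count, int16/100
            vnum = int.from_bytes(magic, "big")
            fmagic = f.read(3)
            if len(fmagic) < 3:
                raise CorruptFileError(f"{path}: truncated old-curv header")
            data = f.read(vnum * 2)
            if len(data) < vnum * 2:
                raise CorruptFileError(f"{path}: truncated old-curv values")
            values = np.frombuffer(data, dtype=">i2").astype(np.float64) / 100.0
    if np.any(np.isnan(values)):
        raise CorruptFileError(f"{path}: curvature contains NaN")
    if surface is not None and values.size != surface.n_vertices:
        raise InconsistencyError(
            f"{path}: {values.size} curvature values for a "
            f"{surface.n_vertices}-vertex surface"
        )
    return CurvatureMap(values)


def write_curvature(curv: CurvatureMap, path, n_faces: int = 0) -> None:
    """Write a curvature map in the FreeSurfer "new" float32 format."""
    path = Path(path)
    with open(path, "wb") as f:
        f.write(NEW_CURV_MAGIC)
        f.write(struct.pack(">3i", len(curv), n_faces, 1))
        f.write(curv.values.astype(">f4").tobytes())


_ELECTRODE_COLUMNS = ("name", "x", "y", "z")


def read_electrodes(path) -> ElectrodeSet:
    """Read an electrode coordinate table (TSV: name, x, y, z[, lead]).

    Row order is preserved; coordinates are parsed as millimetres.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _ELECTRODE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    names = df["name"].tolist()
    seen: set = set()
    for n in names:
        if n in seen:
            raise ValidationError(f"{path}: duplicate electrode name {n!r}")
        seen.add(n)
    coords = np.empty((len(df), 3), dtype=np.float64)
    for ci, col in enumerate(("x", "y", "z")):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(parsed.isna().to_numpy())[0]
        if bad.size:
            # +2: 1-based data rows after the header line
            raise FormatError(
                f"{path}: non-numeric {col} value {df[col].iloc[bad[0]]!r} "
                f"at row {bad[0] + 2}"
            )
        coords[:, ci] = parsed.to_numpy()
    lead = tuple(df["lead"].tolist()) if "lead" in df.columns else None
    return ElectrodeSet(tuple(names), coords, lead)


def write_electrodes(electrodes: ElectrodeSet, path) -> None:
    """Write an electrode set as TSV with full round-trip float precision."""
    path = Path(path)
    cols = ["name", "x", "y", "z"] + (["lead"] if electrodes.lead else [])
    with open(path, "w", encoding="utf-8", newline="\n") as f:
        f.write("\t".join(cols) + "\n")
        for j, name in enumerate(electrodes.names):
            row = [name] + [repr(float(v)) for v in electrodes.positions[j]]
            if electrodes.lead:
                row.append(electrodes.lead[j])
            f.write("\t".join(row) + "\n")


def check_electrodes_in_frame(
    electrodes: ElectrodeSet, mesh: SurfaceMesh, margin_mm: float = 20.0
) -> None:
    """Warn when a contact falls outside the surface bounding box + margin.

    Surfaces and electrodes must already share the surface-RAS frame; a
    contact far outside the surface extent usually means they do not.
    """
    lo = mesh.vertices.min(axis=0) - margin_mm
    hi = mesh.vertices.max(axis=0) + margin_mm
    outside = np.any((electrodes.positions < lo) | (electrodes.positions > hi), axis=1)
    for j in np.nonzero(outside)[0]:
        warnings.warn(
            f"electrode {electrodes.names[j]!r} lies more than {margin_mm} mm "
            "outside the surface bounding box; check the coordinate frame",
            stacklevel=2,
        )


def write_mesh(mesh: SurfaceMesh, path, format: str = "ply") -> None:
    """Export a mesh as ASCII PLY or Wavefront OBJ, preserving vertex order."""
    path = Path(path)
    if format == "ply":
        with open(path, "w", encoding="ascii", newline="\n") as f:
            f.write("ply\nformat ascii 1.0\ncomment created by seegmorph\n")
            f.write(f"element vertex {mesh.n_vertices}\n")
            f.write("property float x\nproperty float y\nproperty float z\n")
            f.write(f"element face {mesh.n_faces}\n")
            f.write("property list uchar int vertex_indices\nend_header\n")
            for v in mesh.vertices:
                f.write(f"{v[0]:.8g} {v[1]:.8g} {v[2]:.8g}\n")
            for a, b, c in mesh.faces:
                f.write(f"3 {a} {b} {c}\n")
    elif format == "obj":
        with open(path, "w", encoding="ascii", newline="\n") as f:
            f.write("# created by seegmorph\n")
            for v in mesh.vertices:
                f.write(f"v {v[0]:.8g} {v[1]:.8g} {v[2]:.8g}\n")
            for a, b, c in mesh.faces:
                f.write(f"f {a + 1} {b + 1} {c + 1}\n")
    else:
        raise ValueError(f"unknown mesh format {format!r}; use 'ply' or 'obj'")
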
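"""Synthetic folded-sheet surfaces with analytically known flattened twins.

Real folded/inflated surface pairs require a full MRI reconstruction, so the
test bed is a corrugated sheet whose "inflation" has a closed-form ground
truth: the folded surface is

    z(x) = A * sin(2 * pi * k * x / L)

over a regular triangulated grid of extent L, and the flattened counterpart
is the same grid with z = 0 and x replaced by the along-x arc length

    s(x) = integral_0^x sqrt(1 + z'(t)^2) dt.

This flattening preserves along-x path length exactly (up to quadrature
precision), mimicking the key property of cortical inflation — on-surface
distances are approximately restored as straight-line distances — while
remaining fully verifiable. Both meshes share faces and vertex order, so
every generated pair satisfies the 1:1 vertex-identity contract.

Straight, equally spaced contact trajectories emulate SEEG depth leads
passing through the folded sheet. Defaults model a cortical patch with
sulci ~10 mm apart and 10 mm peak-to-trough fold depth, and lead contacts
at 3.5 mm pitch.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.integrate import quad

from ._exceptions import ValidationError
from .morph_core import SurfacePair, validate_pair
from .surface_io import (
    CurvatureMap,
    ElectrodeSet,
    SurfaceMesh,
    write_curvature,
    write_electrodes,
    write_freesurfer_surface,
)

__all__ = [
    "SheetSpec",
    "TrajectorySpec",
    "make_folded_pair",
    "make_curvature",
    "make_trajectory",
    "default_trajectory",
    "opposite_bank_contacts",
    "write_fixture_set",
]


@dataclass(frozen=True)
class SheetSpec:
    """Parameters of the synthetic folded sheet.

    nx, ny : grid resolution (vertices per side).
    extent_mm : sheet width/height L.
    amplitude_mm : fold amplitude A (half the peak-to-trough depth).
    n_folds : number of full sine periods k across the sheet.
    seed : RNG seed for the optional vertex jitter.
    jitter_frac : uniform jitter as a fraction of grid pitch (<= 1%),
        used to break exact ties in nearest-vertex queries.
    """

    nx: int = 50
    ny: int = 50
    extent_mm: float = 30.0
    amplitude_mm: float = 5.0
    n_folds: int = 3
    seed: int = 0
    jitter_frac: float = 0.0

    def __post_init__(self) -> None:
        if self.nx < 2 or self.ny < 2:
            raise ValidationError(f"grid must be >= 2x2, got {self.nx}x{self.ny}")
        if self.extent_mm <= 0:
            raise ValidationError(f"extent_mm must be positive, got {self.extent_mm}")
        if self.amplitude_mm < 0:
            raise ValidationError(f"amplitude_mm must be >= 0, got {self.amplitude_mm}")
        if self.n_folds < 0:
            raise ValidationError(f"n_folds must be >= 0, got {self.n_folds}")
        if not 0.0 <= self.jitter_frac <= 0.01:
            raise ValidationError(
                f"jitter_frac must lie in [0, 0.01], got {self.jitter_frac}"
            )

    @property
    def n_vertices(self) -> int:
        return self.nx * self.ny


@dataclass(frozen=True)
class TrajectorySpec:
    """A straight depth-lead trajectory with equally spaced contacts."""

    entry_mm: tuple
    direction: tuple
    n_contacts: int
    spacing_mm: float
    lead: str = "T"

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=np.float64).reshape(3)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ValidationError(
                f"direction must be a unit vector, |d| = {np.linalg.norm(d)}"
            )
        if self.spacing_mm <= 0:
            raise ValidationError(f"spacing_mm must be positive, got {self.spacing_mm}")
        if self.n_contacts < 1:
            raise ValidationError(f"need >= 1 contact, got {self.n_contacts}")


def _grid(spec: SheetSpec):
    """Jittered (X, Y, Z) vertex grids, each of shape (ny, nx)."""
    x = np.linspace(0.0, spec.extent_mm, spec.nx)
    y = np.linspace(0.0, spec.extent_mm, spec.ny)
    X, Y = np.meshgrid(x, y)
    if spec.jitter_frac > 0.0:
        rng = np.random.default_rng(spec.seed)
        pitch = spec.extent_mm / (max(spec.nx, spec.ny) - 1)
        jmax = spec.jitter_frac * pitch
        X = X + rng.uniform(-jmax, jmax, X.shape)
        Y = Y + rng.uniform(-jmax, jmax, Y.shape)
    if spec.amplitude_mm == 0.0:
        Z = np.zeros_like(X)  # avoid -0.0 from 0 * sin()
    else:
        w = 2.0 * np.pi * spec.n_folds / spec.extent_mm
        Z = spec.amplitude_mm * np.sin(w * X)
    return X, Y, Z


def _grid_faces(nx: int, ny: int) -> np.ndarray:
    """Two triangles per grid quad, vertex id = iy * nx + ix."""
    faces = []
    for iy in range(ny - 1):
        for ix in range(nx - 1):
            v00 = iy * nx + ix
            v01 = v00 + 1
            v10 = v00 + nx
            v11 = v10 + 1
            faces.append((v00, v01, v11))
            faces.append((v00, v11, v10))
    return np.asarray(faces, dtype=np.int64)


def arc_length(spec: SheetSpec, x) -> np.ndarray:
    """Along-x arc length s(x) of the folded profile, by adaptive quadrature."""
    x = np.atleast_1d(np.asarray(x, dtype=np.float64))
    if spec.amplitude_mm == 0.0 or spec.n_folds == 0:
        return x.copy()
    w = 2.0 * np.pi * spec.n_folds / spec.extent_mm
    aw = spec.amplitude_mm * w

    def integrand(t):
        return np.sqrt(1.0 + (aw * np.cos(w * t)) ** 2)

    return np.array([quad(integrand, 0.0, xi, limit=200)[0] for xi in x])


def make_folded_pair(spec: SheetSpec) -> SurfacePair:
    """Build the folded sheet and its arc-length-preserving flattened twin."""
    X, Y, Z = _grid(spec)
    faces = _grid_faces(spec.nx, spec.ny)
    folded = SurfaceMesh(
        np.column_stack([X.ravel(), Y.ravel(), Z.ravel()]),
        faces,
        hemisphere="left",
    )
    if spec.amplitude_mm == 0.0 or spec.n_folds == 0:
        Xf = X
    else:
        Xf = arc_length(spec, X.ravel()).reshape(X.shape)
    inflated = SurfaceMesh(
        np.column_stack([Xf.ravel(), Y.ravel(), np.zeros(X.size)]),
        faces,
        hemisphere="left",
    )
    return validate_pair(folded, inflated)


def make_curvature(spec: SheetSpec) -> CurvatureMap:
    """Ground-truth curvature: +1 at trough bottoms (sulcal), -1 at crests."""
    _, _, Z = _grid(spec)
    if spec.amplitude_mm == 0.0:
        return CurvatureMap(np.zeros(Z.size))
    return CurvatureMap((-Z / spec.amplitude_mm).ravel())


def make_trajectory(spec: TrajectorySpec) -> ElectrodeSet:
    """Contacts at entry + n * spacing * direction, named T1..Tn, one lead."""
    entry = np.asarray(spec.entry_mm, dtype=np.float64).reshape(3)
    direction = np.asarray(spec.direction, dtype=np.float64).reshape(3)
    steps = np.arange(spec.n_contacts, dtype=np.float64)[:, None]
    positions = entry[None, :] + steps * spec.spacing_mm * direction[None, :]
    names = tuple(f"{spec.lead}{n + 1}" for n in range(spec.n_contacts))
    return ElectrodeSet(names, positions, (spec.lead,) * spec.n_contacts)


def default_trajectory(sheet: SheetSpec) -> TrajectorySpec:
    """A vertical lead through the sheet centre.

    Entered from below the deepest trough, the lead's distal contacts are
    far from the surface (excluded at a 4 mm criterion) while contacts near
    the sheet are included — mirroring a depth lead crossing white matter
    into cortex.
    """
    c = sheet.extent_mm / 2.0
    n = 10
    spacing = 3.5
    entry_z = -sheet.amplitude_mm - (n - 4) * spacing / 2.0
    return TrajectorySpec(
        entry_mm=(c, c, entry_z),
        direction=(0.0, 0.0, 1.0),
        n_contacts=n,
        spacing_mm=spacing,
    )


def opposite_bank_contacts(spec: SheetSpec, pair: SurfacePair) -> ElectrodeSet:
    """Two contacts on opposite banks of the middle fold, placed exactly on
    folded vertices of the central grid row.

    The contacts sit at the zero crossings flanking one trough: close in
    folded Euclidean space (separated by half a fold wavelength) but far
    apart along the sheet, which must descend into and climb out of the
    trough between them.
    """
    if spec.n_folds < 1:
        raise ValidationError("opposite-bank contacts need at least one fold")
    L, k = spec.extent_mm, spec.n_folds
    m = (k - 1) // 2  # middle trough
    x_trough = L * (3 + 4 * m) / (4 * k)
    x_desc = x_trough - L / (4 * k)
    x_asc = x_trough + L / (4 * k)
    iy = spec.ny // 2
    row = np.arange(iy * spec.nx, iy * spec.nx + spec.nx)
    row_x = pair.folded.vertices[row, 0]
    va = row[int(np.argmin(np.abs(row_x - x_desc)))]
    vb = row[int(np.argmin(np.abs(row_x - x_asc)))]
    return ElectrodeSet(
        ("bankA", "bankB"),
        pair.folded.vertices[[va, vb]].copy(),
        ("bank", "bank"),
    )


def write_fixture_set(
    sheet: SheetSpec, trajectory: TrajectorySpec, outdir
) -> dict[str, Path]:
    """Write the full fixture set (surfaces, curvature, electrodes) to disk.

    Files use the standard naming scheme (``lh.folded``, ``lh.inflated``,
    ``lh.curv``, ``electrodes.tsv``) so readers see hemisphere-prefixed
    names. Returns the mapping of logical names to paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pair = make_folded_pair(sheet)
    curv = make_curvature(sheet)
    electrodes = make_trajectory(trajectory)
    paths = {
        "folded": outdir / "lh.folded",
        "inflated": outdir / "lh.inflated",
        "curv": outdir / "lh.curv",
        "electrodes": outdir / "electrodes.tsv",
    }
    write_freesurfer_surface(pair.folded, paths["folded"])
    write_freesurfer_surface(pair.inflated, paths["inflated"])
    write_curvature(curv, paths["curv"], n_faces=pair.folded.n_faces)
    write_electrodes(electrodes, paths["electrodes"])
    return paths
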
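"""Derived per-contact analyses: sulcus/gyrus class, label lookup, distances.

Sulcal/gyral classification follows the FreeSurfer curvature convention
(positive curvature = sulcal, negative = gyral) evaluated at each contact's
snapped vertex. Label overlays are generic per-vertex integer maps (e.g. an
atlas parcellation sampled onto the surface); the contact simply reports the
label at its snapped vertex.

The distance report quantifies how inter-contact distances distort between
folded and inflated space: two contacts separated by a sulcus are close in
folded Euclidean space but far apart along the cortical sheet, and the
inflated representation approximately restores the along-sheet distance.
On-surface distance is approximated by the graph shortest path along mesh
edges (Dijkstra, edge weights = Euclidean edge lengths), not an exact
polyhedral geodesic.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from ._exceptions import InconsistencyError
from .morph_core import ContactMapping, SurfacePair
from .surface_io import CurvatureMap, ElectrodeSet, SurfaceMesh

__all__ = [
    "LabelMap",
    "DistanceReport",
    "classify_contacts",
    "lookup_labels",
    "mesh_edge_graph",
    "distance_report",
    "write_distance_report",
    "read_label_map",
    "write_label_map",
]

SULCAL = "sulcal"
GYRAL = "gyral"


@dataclass(frozen=True)
class LabelMap:
    """Per-vertex integer labels plus a name for each label value.

    Label values without a name entry resolve to the reserved name
    ``"unknown"``.
    """

    values: np.ndarray
    names: dict

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.int64).ravel()
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "names", dict(self.names))

    def name_of(self, label: int) -> str:
        return self.names.get(int(label), "unknown")

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class DistanceReport:
    """Distances between one pair of included contacts.

    ``euclidean_folded_mm`` is the straight-line distance between original
    contact positions; ``euclidean_inflated_mm`` the straight-line distance
    between their snapped vertices' inflated coordinates; and
    ``geodesic_folded_mm`` the graph shortest path along folded mesh edges
    between the snapped vertices.
    """

    name_a: str
    name_b: str
    euclidean_folded_mm: float
    euclidean_inflated_mm: float
    geodesic_folded_mm: float


def classify_contacts(
    mappings: Sequence[ContactMapping],
    curv: CurvatureMap,
    n_vertices: int | None = None,
) -> list[str]:
    """Classify each contact as sulcal or gyral from curvature sign.

    Curvature > 0 at the snapped vertex means sulcal, < 0 gyral; exactly 0
    is assigned to gyral (flat crown). Output is aligned with *mappings*.
    """
    if n_vertices is not None and len(curv) != n_vertices:
        raise InconsistencyError(
            f"{len(curv)} curvature values for a {n_vertices}-vertex surface"
        )
    out = []
    for m in mappings:
        if m.vertex_index >= len(curv):
            raise InconsistencyError(
                f"snapped vertex {m.vertex_index} outside {len(curv)}-value "
                "curvature map"
            )
        out.append(SULCAL if curv.values[m.vertex_index] > 0 else GYRAL)
    return out


def lookup_labels(
    mappings: Sequence[ContactMapping],
    labels: LabelMap,
    n_vertices: int | None = None,
) -> dict[int, str]:
    """Label name at the snapped vertex of each *included* contact.

    Returns ``{electrode_index: label_name}``; excluded contacts are absent.
    """
    if n_vertices is not None and len(labels) != n_vertices:
        raise InconsistencyError(
            f"{len(labels)} label values for a {n_vertices}-vertex surface"
        )
    out: dict[int, str] = {}
    for m in mappings:
        if not m.included:
            continue
        if m.vertex_index >= len(labels):
            raise InconsistencyError(
                f"snapped vertex {m.vertex_index} outside {len(labels)}-value "
                "label map"
            )
        out[m.electrode_index] = labels.name_of(labels.values[m.vertex_index])
    return out


def mesh_edge_graph(mesh: SurfaceMesh):
    """Sparse symmetric adjacency of mesh edges weighted by edge length (mm)."""
    f = mesh.faces
    edges = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    edges = np.sort(edges, axis=1)
    edges = np.unique(edges, axis=0)
    w = np.linalg.norm(
        mesh.vertices[edges[:, 0]] - mesh.vertices[edges[:, 1]], axis=1
    )
    n = mesh.n_vertices
    g = coo_matrix(
        (
            np.concatenate([w, w]),
            (
                np.concatenate([edges[:, 0], edges[:, 1]]),
                np.concatenate([edges[:, 1], edges[:, 0]]),
            ),
        ),
        shape=(n, n),
    )
    return g.tocsr()


def distance_report(
    pair: SurfacePair,
    mappings: Sequence[ContactMapping],
    electrodes: ElectrodeSet,
) -> list[DistanceReport]:
    """All pairwise folded/inflated/geodesic distances between included
    contacts, in input order; empty when fewer than two contacts pass the
    distance criterion."""
    inc = [m for m in mappings if m.included]
    if len(inc) < 2:
        return []
    graph = mesh_edge_graph(pair.folded)
    sources = sorted({m.vertex_index for m in inc})
    src_row = {v: k for k, v in enumerate(sources)}
    dmat = dijkstra(graph, directed=False, indices=sources)
    out = []
    for ma, mb in combinations(inc, 2):
        pa = electrodes.positions[ma.electrode_index]
        pb = electrodes.positions[mb.electrode_index]
        ia = pair.inflated.vertices[ma.vertex_index]
        ib = pair.inflated.vertices[mb.vertex_index]
        out.append(
            DistanceReport(
                name_a=electrodes.names[ma.electrode_index],
                name_b=electrodes.names[mb.electrode_index],
                euclidean_folded_mm=float(np.linalg.norm(pa - pb)),
                euclidean_inflated_mm=float(np.linalg.norm(ia - ib)),
                geodesic_folded_mm=float(
                    dmat[src_row[ma.vertex_index], mb.vertex_index]
                ),
            )
        )
    return out


def read_label_map(path) -> LabelMap:
    """Read a per-vertex label overlay from TSV.

    Expected columns: ``label`` (one integer per vertex, in vertex order)
    and optionally ``name`` giving that label value's name (repeated rows
    may restate the same name; the first occurrence wins).
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    if "label" not in df.columns:
        raise InconsistencyError(f"{path}: missing required column 'label'")
    values = df["label"].to_numpy(dtype=np.int64)
    names: dict = {}
    if "name" in df.columns:
        for val, name in zip(values, df["name"]):
            if isinstance(name, str) and int(val) not in names:
                names[int(val)] = name
    return LabelMap(values, names)


def write_label_map(labels: LabelMap, path) -> None:
    """Write a per-vertex label overlay as TSV (columns: label, name)."""
    with open(path, "w", encoding="utf-8", newline="\n") as f:
        f.write("label\tname\n")
        for v in labels.values:
            f.write(f"{int(v)}\t{labels.name_of(v)}\n")


def write_distance_report(path, reports: Sequence[DistanceReport]) -> None:
    """Write the pairwise distance report as TSV."""
    with open(path, "w", encoding="utf-8", newline="\n") as f:
        f.write(
            "name_a\tname_b\teuclid_folded_mm\teuclid_inflated_mm\t"
            "geodesic_folded_mm\n"
        )
        for r in reports:
            f.write(
                f"{r.name_a}\t{r.name_b}\t{r.euclidean_folded_mm!r}\t"
                f"{r.euclidean_inflated_mm!r}\t{r.geodesic_folded_mm!r}\n"
            )
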
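# Methods

## Model

The package operates on a *surface pair*: a folded cortical mesh (typically
FreeSurfer's pial surface, though any folded/inflated pair is accepted) and
its inflated counterpart. The central assumption is FreeSurfer's 1:1 vertex
identity — vertex *i* of both meshes names the same cortical location and
both meshes share one face array. Construction of a `SurfacePair` verifies
vertex counts, face arrays and hemisphere tags and refuses anything else;
no resampling or registration is attempted.

Morphing is per-vertex linear interpolation by a parameter σ ∈ [0, 1]:
`p_m = (1−σ)·p_folded + σ·p_inflated`. The same blend moves each selected
electrode contact from its original position toward the inflated coordinate
of its snapped vertex. Linearity means every vertex and contact traces a
straight segment; any frame is the σ-blend of the two endpoint frames.
σ outside [0, 1] is rejected rather than extrapolated.

Electrode selection uses a single distance criterion: a contact is treated
as cortical when the Euclidean distance to its nearest folded vertex is
*strictly* below a threshold, default 4 mm — roughly cortical thickness plus
localization error. Boundary contacts at exactly the threshold are excluded
(pass `threshold + ε` to keep them). Excluded contacts are omitted from
morph output, not frozen in place, but remain in the mapping table with
`included=false`. Snapping is vertex-only (no projection onto triangle
interiors): the snap distance is a cap on the error this introduces, and
vertex identity is what makes the inflated target well defined.

Sulcal/gyral classification is the curvature sign at the snapped vertex in
the FreeSurfer convention (positive = sulcal, negative = gyral). Exact zero
is assigned to *gyral*: a flat vertex behaves like a crown, and the choice
makes the boundary deterministic.

The distance report gives, for every pair of included contacts, the folded
Euclidean distance between original positions, the inflated Euclidean
distance between snapped inflated vertices, and the folded on-surface
distance as the graph shortest path along mesh edges (Dijkstra, weights =
Euclidean edge lengths). Edge-graph distance slightly overestimates the
exact polyhedral geodesic but is independent-oracle-testable
(Bellman–Ford) and sufficient to quantify folding distortion; exact
geodesics are out of scope.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `threshold_mm` | 4.0 | cortical-contact distance criterion (strict `<`) |
| σ | — | morph parameter, 0 = folded, 1 = inflated |
| k-d tree cutover | 10 000 vertices | below: exhaustive scan; above: `cKDTree` with explicit lowest-index tie resolution; both paths give identical results |
| bounding-box margin | 20 mm | contacts outside the surface box + margin trigger a coordinate-frame warning |

All coordinates are FreeSurfer surface-RAS millimetres. Electrodes must
already be co-registered into that frame (as they are after a standard
CT-to-T1 registration); the package performs no affine handling.

## Numerical choices

* Morph endpoints are returned as exact copies of the input arrays, so
  σ = 0 and σ = 1 reproduce folded/inflated geometry and original/snapped
  contact positions bitwise, rather than relying on `(1−σ)·a + σ·b`
  evaluating exactly at the endpoints (it does not for signed zeros).
* Nearest-vertex ties are broken to the lowest vertex index on both code
  paths; the argmin of the squared distance is compared exactly.
* Surfaces and curvature are stored on disk as big-endian float32 (the
  FreeSurfer format's precision); round-trips are exact at that precision.
  Electrode TSVs are written with `repr` floats and round-trip exactly in
  double precision.
* Dijkstra distances are compared to the Bellman–Ford oracle at 1e-9 mm
  absolute: both algorithms sum the same edge weights but may accumulate
  equal-length alternatives in different orders.

## The synthetic test bed

Real folded/inflated pairs require an MRI reconstruction, so tests run on a
corrugated sheet: `z(x) = A·sin(2πkx/L)` over a regular triangulated
`nx × ny` grid, with the "inflated" twin obtained by setting z = 0 and
replacing x by the along-x arc length `s(x) = ∫√(1+z′²)`, computed by
adaptive quadrature. This flattening preserves along-x path length
essentially exactly, so on-surface distances and their straight-line
restoration in flattened space have an analytic ground truth. Defaults —
50×50 vertices, L = 30 mm, A = 5 mm, k = 3 — model a cortical patch with
sulci ~10 mm apart and 10 mm peak-to-trough fold depth, i.e. realistic
human folding geometry at a mesh pitch (~0.6 mm) close to FreeSurfer's.
Optional seeded vertex jitter (≤ 1 % of grid pitch) breaks exact ties for
determinism tests. Straight trajectories with 3.5 mm contact pitch emulate
SEEG leads; the default lead enters below the sheet so that deep contacts
fail the 4 mm criterion and mid-lead contacts pass it.

What the sheet does *not* emulate: closed cortical topology, varying fold
wavelength and depth, FreeSurfer's actual inflation (which minimizes a
folding energy and distorts metric properties anisotropically), bilateral
anatomy, and CT localization noise. Passing tests therefore demonstrate the
correctness of the morphing, selection, snapping, classification and
distance machinery — not fidelity of FreeSurfer's reconstruction, which
this package consumes as input.

The sheet's discretization bounds the flattening property: the along-row
edge-graph path is a chordal approximation of the smooth arc, so row
geodesics match flattened x-distances within ~2 % at the default
resolution (the observed cross-fold disagreement is ≈ 0.4 %).

## Design choices

* **Bilateral data.** The core operates on one surface pair. A wrapper
  assigns each contact to the hemisphere whose folded surface is nearer
  (ties to left), avoiding cross-midline snapping artifacts.
* **Hand-written FreeSurfer I/O.** The triangle and curv readers/writers
  are implemented directly (the format is a few dozen lines) so that
  malformed files produce the package's documented errors — unsupported
  magic named in hex, truncated payloads distinguished from wrong formats.
  nibabel's readers serve as an independent cross-check in the tests.
* **Static export only.** Morph frames are written as PLY/OBJ meshes plus
  electrode TSVs for external viewers; no interactive window or linked
  scatter/text morphing is provided, keeping the tool headless.
* **Label overlays** are generic per-vertex integer maps with a name
  table (unnamed values resolve to "unknown"); atlas fitting is out of
  scope.

## Limitations

* Vertex-only snapping can misassign a contact near a thin sulcal wall to
  the wrong bank when the opposing bank's vertex happens to be nearer; a
  smaller mesh pitch reduces the risk.
* The distance criterion is a global constant, while cortical thickness
  varies; volume-label-based selection would be more specific but requires
  a segmentation that is not an input here.
* Edge-graph geodesics overestimate true surface distance by up to the
  mesh-pitch-dependent chordal error.
* Electrode coordinates are trusted as given; only a bounding-box warning
  guards against frame mismatches.
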
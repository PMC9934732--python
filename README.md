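# seegmorph

Visualize and analyze stereo-EEG (SEEG) electrode positions on the folded
human cortex by morphing between a FreeSurfer cortical surface and its
inflated counterpart.

## The problem

SEEG leads are implanted along straight trajectories, so their equally
spaced contacts pass through gyral crowns, sulcal banks, white matter and
subcortex. On an opaque 3-D rendering most contacts are hidden inside the
folds; on a semi-transparent one, two contacts that look adjacent may in
fact sit on opposite banks of a sulcus, far apart along the cortical sheet.
The inflated surface unfolds the cortex while preserving its topology, and
because FreeSurfer's folded and inflated reconstructions share a 1:1 vertex
identity, surface and electrodes can be blended continuously between the
two views.

## The method

Let `p_c[i]` and `p_i[i]` be the i-th vertex of the folded and inflated
surface. For a morph parameter `σ ∈ [0, 1]` the morphed surface is the
linear blend

    p_m[i] = (1 − σ) · p_c[i] + σ · p_i[i]

Cortical contacts are selected by a distance criterion: electrode `e_j` is
kept iff its distance to the nearest folded vertex is strictly below a
threshold `d` (default 4 mm),

    d_j = min_i ‖e_j − p_c[i]‖ < d

Each kept contact is snapped to that nearest vertex `i_j = argmin_i
‖p_c[i] − e_j‖` and morphs toward the vertex's *inflated* coordinate:

    e_m[j] = (1 − σ) · e_j + σ · p_i[i_j]

So `σ = 0` shows the anatomically accurate scene and `σ = 1` places every
cortical contact on the unfolded sheet. Contacts are classified as sulcal
or gyral from the curvature sign at the snapped vertex (FreeSurfer
convention: positive = sulcal), and pairwise contact distances are reported
in folded Euclidean, inflated Euclidean, and folded on-surface (mesh-edge
Dijkstra) metrics.

No patient data is required to use or test the package: a fixtures module
generates a corrugated-sheet "cortex" whose flattened counterpart has an
analytic ground truth (arc-length-preserving along the fold axis), plus
straight SEEG-like trajectories.

## Worked example

```python
import numpy as np
import seegmorph as sm
from seegmorph import fixtures as fx

spec = fx.SheetSpec()                       # 50x50 sheet, 5 mm folds, 3 sulci
pair = fx.make_folded_pair(spec)
lead = fx.make_trajectory(fx.default_trajectory(spec))
maps = sm.map_contacts(pair, lead, threshold_mm=4.0)
curv = fx.make_curvature(spec)
classes = sm.classify_contacts(maps, curv, pair.n_vertices)

for m, c in zip(maps, classes):
    print(f"{lead.names[m.electrode_index]:>3}  d={m.distance_mm:6.2f} mm  "
          f"included={str(m.included):5}  class={c}")

frame = sm.make_frame(pair, lead, maps, sigma=0.5)
print("morphed contacts at sigma=0.5:")
print(np.round(frame.electrode_positions, 2))

banks = fx.opposite_bank_contacts(spec, pair)
rep, = sm.distance_report(pair, sm.map_contacts(pair, banks, 4.0), banks)
print(f"folded {rep.euclidean_folded_mm:.2f} mm | inflated "
      f"{rep.euclidean_inflated_mm:.2f} mm | geodesic {rep.geodesic_folded_mm:.2f} mm")
```

prints

```
 T1  d= 10.84 mm  included=False  class=sulcal
 T2  d=  7.45 mm  included=False  class=sulcal
 T3  d=  4.22 mm  included=False  class=sulcal
 T4  d=  1.80 mm  included=True   class=sulcal
 T5  d=  0.70 mm  included=True   class=sulcal
 T6  d=  1.13 mm  included=True   class=gyral
 T7  d=  2.10 mm  included=True   class=gyral
 T8  d=  4.66 mm  included=False  class=gyral
 T9  d=  7.93 mm  included=False  class=gyral
T10  d= 11.33 mm  included=False  class=gyral
morphed contacts at sigma=0.5:
[[26.98 14.85 -2.5 ]
 [25.29 14.85 -0.75]
 [24.28 14.85  1.  ]
 [22.6  14.85  2.75]]
folded 5.52 mm | inflated 13.20 mm | geodesic 13.14 mm
```

Four of the ten lead contacts lie within 4 mm of the folded sheet and are
treated as cortical; the deep and superficial contacts are excluded. The
last line shows the distance distortion the inflated view corrects: two
contacts on opposite banks of one fold are only 5.5 mm apart in folded
space but 13.1 mm apart along the cortical sheet, and the inflated
straight-line distance (13.2 mm) recovers that on-surface distance to
within half a percent.

## Command line

```sh
seegmorph fixtures --out fx/                      # synthetic surfaces + lead
seegmorph map --folded fx/lh.folded --inflated fx/lh.inflated \
    --electrodes fx/electrodes.tsv --curv fx/lh.curv --out mapping.tsv
seegmorph frames --folded fx/lh.folded --inflated fx/lh.inflated \
    --electrodes fx/electrodes.tsv --n-frames 5 --out frames/
seegmorph distances --folded fx/lh.folded --inflated fx/lh.inflated \
    --electrodes fx/electrodes.tsv --out distances.tsv
```

`frames` writes one PLY/OBJ mesh plus an electrode TSV per morph step, for
rendering or animation in any external 3-D viewer. A `--config` file of
`key = value` lines can hold common flags; explicit flags override it.

Real data: pass FreeSurfer's `lh.pial`/`lh.inflated` (or white) surfaces,
an `lh.curv` file, and a TSV of electrode coordinates in surface-RAS
millimetres (columns `name`, `x`, `y`, `z`, optional `lead`). Two
`--folded`/`--inflated` pairs enable bilateral runs; contacts are assigned
to the hemisphere whose surface is nearer.

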
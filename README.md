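# urbantree

Fully automatic two-stage urban tree inventories from remote data: airborne
laser scanning (ALS) point clouds, street-level panoramas, and RGB/NIR
orthophotos. Written for urban-forestry and remote-sensing practitioners who
need to locate every street and park tree in a city without field work, and
for method developers who want a testbed in which the ground truth is known
exactly.

## The method

City-scale tree mapping faces a trade-off: detectors tuned to find *every*
tree produce large numbers of false positives (facade edges, poles, street
furniture, branch-level height maxima). The two-stage design embraces this:

**Stage 1 — detect everything.**

* *ALS path:* the normalized point cloud is gridded into a canopy height
  model (CHM) at 0.25 m (per-cell maximum height), smoothed with a 3×3 mean
  filter, and clipped by building footprints. Treetops are variable-window
  local maxima: a cell of height *h* is a treetop iff it is at least 2 m
  tall and no cell within radius *r(h) = 0.12·h + 0.5* m is taller.
* *Street-level path:* per-image stem detections are geolocated by
  trigonometry. The pixel column gives the bearing (heading + in-image
  angle); the stem-base row gives the flat-ground distance
  *d = h_cam / tan δ* from the depression angle δ below the horizon.

**Stage 2 — debug the false positives.**

* *Image consistency:* a candidate survives only if it is detected in each
  of its three nearest panoramas and the three estimated positions agree
  pairwise within 4 m; survivors move to the centroid of the three.
* *Spectral classification:* per-band zonal statistics (mean and standard
  deviation in a 50 cm buffer) over seven ortho bands (RGB ×2 years + NIR)
  feed a TREE / NOT-TREE classifier (random forest by default; neural net
  and linear/radial SVM behind the same interface) trained with repeated
  cross-validation.

After **every** stage, candidates closer than 4 m are merged (buffer-union
connected components → centroid). Inventories are scored against ground
truth by the 5 m matching criteria — a candidate is a true positive iff its
nearest truth point is within 5 m and no other candidate is closer to that
truth point — and summarized as

    r = TP/(TP+FN),   p = TP/(TP+FP),   F1 = 2pr/(p+r).

A seeded scene simulator generates the full input suite (tree layouts along
streets and in parks, point clouds at 14 returns/m², seven-band ortho
stacks with separable class spectra, panorama stations every 15 m with
invertible detections, injected clutter), so all six method combinations
(`GSV`, `ALS`, `GSV+GSV`, `GSV+ML`, `ALS+GSV`, `ALS+ML`) run end-to-end with
exact truth.

## Worked example

A 120 m × 60 m district with one street of 13 trees, a building block,
three pole-like clutter objects and one spurious image detection per
panorama on average — save as `district.yaml`:

```yaml
method: ALS+ML
eval_zone: street
scene:
  area_width: 120
  area_height: 60
  street_axes: [[[0, 30], [120, 30]]]
  street_tree_spacing: 10
  building_rects: [[10, 5, 40, 20]]
  pole_count: 3
  false_detection_rate: 1.0
  n_training_points: 600
  seed: 2
```

```bash
$ urbantree run --config district.yaml --method ALS
{
 "method": "ALS",
 "counts": {"stage1": 64, "stage1_merged": 16, "final": 16, "truth": 13}
}
p=81.25% r=100.00% F1=89.66%
```

Stage 1 finds 64 raw height maxima (branch-level duplicates), merging
collapses them to 16 candidates: all 13 trees (recall 100%) plus the 3
poles, hence precision 81.25%. Adding the spectral filter:

```bash
$ urbantree run --config district.yaml   # method: ALS+ML from the YAML
{
 "method": "ALS+ML",
 "counts": {"stage1": 64, "stage1_merged": 16, "stage2": 13, "final": 13, "truth": 13}
}
p=100.00% r=100.00% F1=100.00%
```

The poles are tall in the point cloud but spectrally NOT-TREE, so stage 2
removes exactly the three false positives.

Other subcommands: `urbantree simulate` (write a scene's cloud/orthos/
stations/detections/truth to disk), `urbantree evaluate` (score a candidate
GeoJSON against a truth GeoJSON), `urbantree report` (summarize run
reports). The same functionality is available as a library
(`urbantree.run_pipeline`, and per-stage functions in `chm`, `itd`,
`street_geoloc`, `merge`, `spectral`, `evaluate`).

## Documentation

`docs/methods.md` describes the models, parameter choices, numerical
conventions, what the simulator does and does not emulate, and known
limitations.
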
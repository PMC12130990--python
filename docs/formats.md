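# File formats

All files are UTF-8; numbers are plain JSON floats. Coordinates are
0-based pixels in image-array convention (`x` = column, `y` = row), at the
prediction resolution (default 0.263 µm/px at 40×).

## Prediction file (per model, per slide)

A JSON object mapping nucleus id → record:

```json
{
  "0": {
    "centroid": [10.0, 20.0],
    "contour": [[9.0, 19.0], [11.0, 19.0], [10.0, 21.0]],
    "box": [[9.0, 19.0], [11.0, 21.0]],
    "prob": 0.9,
    "type": "epithelial"
  }
}
```

* `centroid` — `[x, y]` nucleus centre.
* `contour` — ≥ 3 ordered polygon vertices.
* `box` — `[[min_x, min_y], [max_x, max_y]]`, must contain the centroid.
* `prob` — classification probability in `[0, 1]`.
* `type` — a raw label from the model's vocabulary.

A top-level JSON **list** of records is also accepted; ids are then the
insertion index rendered as a string (`"0"`, `"1"`, …). Native pickle-based
prediction dumps of segmentation toolkits are not read; convert them to
this dialect first.

## Merged output file

A single JSON document:

```json
{
  "format": "nucmerge-merged",
  "version": 1,
  "models": {"m1": "monusac", "m2": "pannuke"},
  "nuclei": {
    "k0": {
      "centroid": [11.0, 10.0],
      "contour": [...], "box": [...],
      "prob": 0.9,
      "category": "non-neoplastic epithelial",
      "provenance": "merged",
      "source_ids": {"monusac": "a1", "pannuke": "b7"},
      "source_labels": {"monusac": "epithelial",
                         "pannuke": "non-neoplastic epithelial"},
      "equivocal": false,
      "distance": 2.0
    }
  },
  "equivocal": [...],
  "match_flags": {"m1": {"a1": true}, "m2": {"b7": true}},
  "dropped_m2": []
}
```

`provenance` is one of `merged`, `conflict_m1`, `conflict_m2`,
`unmatched_m1`, `unmatched_m2`. `category` is a harmonized schema node,
not a raw model label. `distance` is the matched-pair distance in pixels
(`null` for unmatched nuclei).

## Schema config (YAML or JSON)

```yaml
tree:
  cell:
    epithelial:
      neoplastic epithelial: {}
      non-neoplastic epithelial: {}
    inflammatory:
      lymphocyte: {}
      neutrophil: {}
      macrophage: {}
    connective: {}
    dead: {}
match_level: {}          # optional overrides; default = depth-1 ancestor
models:
  monusac:
    vocabulary: [epithelial, lymphocyte, macrophage, neutrophil]
    labels:
      epithelial: epithelial
      lymphocyte: lymphocyte
      neutrophil: neutrophil
      macrophage: macrophage
  pannuke:
    vocabulary: [connective, dead, inflammatory,
                 neoplastic epithelial, non-neoplastic epithelial]
    labels:
      neoplastic epithelial: neoplastic epithelial
      non-neoplastic epithelial: non-neoplastic epithelial
      connective: connective
      inflammatory: inflammatory
      dead: dead
```

Every label of a declared `vocabulary` must be mapped; `match_level`
entries must name an ancestor of the node. More than two models may be
declared; a merge run is pairwise, and chains are formed by merging the
merged output (exported back to the prediction dialect) with a third set.

## CSV reports

Comma-separated, UTF-8, one header row, minimal quoting.

* `merge_report.csv` — `row_type=detail` rows (one per output nucleus:
  id, provenance, category, centroid, source ids/labels, prob, distance,
  equivocal flag) followed by `row_type=summary` rows (per category:
  merged / conflict / unmatched counts).
* `equivocal_report.csv` — one row per equivocal pair: both centroids,
  both labels, both probabilities, winner, distance.
* `proportions.csv` — `category,count,proportion` (9 decimal places;
  `--percent` rescales to 0–100) with a trailing `TOTAL` row.

## GeoJSON export

`--geojson` writes the merged contours as a `FeatureCollection` of closed
polygons with `id`, `category`, `prob`, `provenance`, `equivocal`
properties, for overlay in slide viewers. Pixel coordinates; not intended
for lossless round-tripping.
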
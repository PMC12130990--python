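"""Reading and writing nuclei prediction files.

The on-disk dialect is JSON (UTF-8). A *prediction file* is a top-level map
of nucleus id to record::

    {
      "0": {"centroid": [10.0, 20.0],
             "contour": [[9.0, 19.0], [11.0, 19.0], [10.0, 21.0]],
             "box": [[9.0, 19.0], [11.0, 21.0]],
             "prob": 0.9,
             "type": "epithelial"},
      ...
    }

A top-level JSON *list* of records is also accepted; ids are then
synthesized deterministically as the record's insertion index rendered as a
string. Coordinates are 0-based pixels, ``x`` = column, ``y`` = row.

The *merged* output file is a single JSON document carrying the merged
nuclei (with provenance and source bookkeeping), the equivocal records, the
match flags of the merging loop, and ids of any dropped M2 nuclei, so a
merge result round-trips losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

from .errors import FormatError, ValidationError
from .model import (
    EquivocalRecord,
    MergedNucleus,
    MergeResult,
    Nucleus,
    PredictionSet,
)

_REQUIRED_KEYS = ("centroid", "contour", "box", "prob", "type")


def _pair(v: Any, what: str, rid: str) -> tuple[float, float]:
    if not isinstance(v, (list, tuple)) or len(v) != 2:
        raise FormatError(f"record {rid!r}: {what} must be a pair, got {v!r}")
    return (float(v[0]), float(v[1]))


def _nucleus_from_record(rid: str, rec: Any) -> Nucleus:
    if not isinstance(rec, dict):
        raise FormatError(f"record {rid!r}: expected an object, got {type(rec).__name__}")
    for key in _REQUIRED_KEYS:
        if key not in rec:
            raise FormatError(f"record {rid!r}: missing key {key!r}")
    contour = [_pair(v, "contour vertex", rid) for v in rec["contour"]]
    box = rec["box"]
    if not isinstance(box, (list, tuple)) or len(box) != 2:
        raise FormatError(f"record {rid!r}: box must hold two corner pairs")
    n = Nucleus(
        id=rid,
        centroid=_pair(rec["centroid"], "centroid", rid),
        contour=contour,
        bbox=(_pair(box[0], "box min", rid), _pair(box[1], "box max", rid)),
        type_label=str(rec["type"]),
        prob=float(rec["prob"]),
    )
    n.validate()
    return n


def read_prediction_set(
    path: str | Path,
    model_id: str,
    vocabulary: set[str] | None = None,
    pixel_scale_um: float = 0.263,
) -> PredictionSet:
    """Read one model's per-slide prediction file.

    When ``vocabulary`` is given, any record whose type label falls outside
    it raises :class:`~nucmerge.errors.ValidationError`; otherwise the
    vocabulary is taken as the set of labels observed in the file.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON ({exc})") from exc
    if isinstance(doc, dict):
        items = [(str(k), v) for k, v in doc.items()]
    elif isinstance(doc, list):
        items = [(str(i), v) for i, v in enumerate(doc)]
    else:
        raise FormatError(f"{path}: top level must be an object or a list")
    nuclei = [_nucleus_from_record(rid, rec) for rid, rec in items]
    vocab = set(vocabulary) if vocabulary is not None else {
        n.type_label for n in nuclei
    }
    pset = PredictionSet(
        model_id=model_id,
        vocabulary=vocab,
        nuclei=nuclei,
        pixel_scale_um=pixel_scale_um,
    )
    pset.validate()
    return pset


def _nucleus_to_record(n: Nucleus) -> dict[str, Any]:
    return {
        "centroid": list(n.centroid),
        "contour": [list(v) for v in n.contour],
        "box": [list(n.bbox[0]), list(n.bbox[1])],
        "prob": n.prob,
        "type": n.type_label,
    }


def write_prediction_set(pset: PredictionSet, path: str | Path) -> dict[str, Any]:
    """Serialize a prediction set; returns a small file manifest."""
    pset.validate()
    path = Path(path)
    doc = {n.id: _nucleus_to_record(n) for n in pset.nuclei}
    path.write_text(json.dumps(doc, indent=1), encoding="utf-8")
    return {"path": str(path), "records": len(pset.nuclei)}


# -- merged output ---------------------------------------------------------

def _merged_to_record(rec: MergedNucleus) -> dict[str, Any]:
    return {
        "centroid": list(rec.centroid),
        "contour": [list(v) for v in rec.contour],
        "box": [list(rec.bbox[0]), list(rec.bbox[1])],
        "prob": rec.prob,
        "category": rec.category,
        "provenance": rec.provenance,
        "source_ids": dict(rec.source_ids),
        "source_labels": dict(rec.source_labels),
        "equivocal": rec.equivocal,
        "distance": rec.distance,
    }


def write_merged_set(result: MergeResult, path: str | Path) -> dict[str, Any]:
    """Serialize a merge result, provenance and bookkeeping included."""
    result.validate()
    path = Path(path)
    doc = {
        "format": "nucmerge-merged",
        "version": 1,
        "models": {"m1": result.model1_id, "m2": result.model2_id},
        "nuclei": {rec.id: _merged_to_record(rec) for rec in result.merged},
        "equivocal": [vars(e) | {
            "m1_centroid": list(e.m1_centroid),
            "m2_centroid": list(e.m2_centroid),
        } for e in result.equivocal],
        "match_flags": {
            "m1": result.m1_matched,
            "m2": result.m2_matched,
        },
        "dropped_m2": list(result.dropped_m2),
    }
    path.write_text(json.dumps(doc, indent=1), encoding="utf-8")
    return {"path": str(path), "records": len(result.merged)}


def read_merged_set(path: str | Path) -> MergeResult:
    path = Path(path)
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(doc, dict) or doc.get("format") != "nucmerge-merged":
        raise FormatError(f"{path}: not a merged-output document")
    merged = []
    for rid, rec in doc["nuclei"].items():
        m = MergedNucleus(
            id=str(rid),
            centroid=(float(rec["centroid"][0]), float(rec["centroid"][1])),
            contour=[(float(x), float(y)) for x, y in rec["contour"]],
            bbox=(
                (float(rec["box"][0][0]), float(rec["box"][0][1])),
                (float(rec["box"][1][0]), float(rec["box"][1][1])),
            ),
            category=str(rec["category"]),
            prob=float(rec["prob"]),
            provenance=str(rec["provenance"]),
            source_ids=dict(rec["source_ids"]),
            source_labels=dict(rec["source_labels"]),
            equivocal=bool(rec["equivocal"]),
            distance=None if rec["distance"] is None else float(rec["distance"]),
        )
        m.validate()
        merged.append(m)
    equivocal = [
        EquivocalRecord(
            m1_id=e["m1_id"],
            m2_id=e["m2_id"],
            m1_centroid=(float(e["m1_centroid"][0]), float(e["m1_centroid"][1])),
            m2_centroid=(float(e["m2_centroid"][0]), float(e["m2_centroid"][1])),
            m1_label=e["m1_label"],
            m2_label=e["m2_label"],
            m1_prob=float(e["m1_prob"]),
            m2_prob=float(e["m2_prob"]),
            winner=e["winner"],
            distance=float(e["distance"]),
        )
        for e in doc.get("equivocal", [])
    ]
    result = MergeResult(
        model1_id=doc["models"]["m1"],
        model2_id=doc["models"]["m2"],
        merged=merged,
        m1_matched={k: bool(v) for k, v in doc["match_flags"]["m1"].items()},
        m2_matched={k: bool(v) for k, v in doc["match_flags"]["m2"].items()},
        equivocal=equivocal,
        dropped_m2=[str(x) for x in doc.get("dropped_m2", [])],
    )
    result.validate()
    return result


def write_geojson(result: MergeResult, path: str | Path) -> dict[str, Any]:
    """Export merged nuclei as a GeoJSON FeatureCollection of polygons.

    Intended for overlay in slide viewers (e.g. QuPath); coordinates stay in
    pixel units and exact round-tripping is not a goal of this format.
    """
    features = []
    for rec in result.merged:
        ring = [list(v) for v in rec.contour]
        if ring and ring[0] != ring[-1]:
            ring = ring + [ring[0]]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {
                    "id": rec.id,
                    "category": rec.category,
                    "prob": rec.prob,
                    "provenance": rec.provenance,
                    "equivocal": rec.equivocal,
                },
            }
        )
    doc = {"type": "FeatureCollection", "features": features}
    path = Path(path)
    path.write_text(json.dumps(doc), encoding="utf-8")
    return {"path": str(path), "records": len(features)}
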
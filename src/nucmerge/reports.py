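"""Counts, proportions and CSV reports over a merge result.

Three comma-separated reports are produced per slide:

* a **merge report** — one detail row per output nucleus (provenance,
  category, source ids, pair distance) followed by per-category summary
  rows of merged/unmerged counts per source model;
* an **equivocal report** — one row per overlapping type-disagreeing pair
  where both model probabilities exceed the equivocal threshold, with the
  centroid positions, both labels and probabilities and the winner;
* a **proportions table** — ``category,count,proportion`` with proportion
  = count / total over all output nuclei.

All CSVs are UTF-8 with a header row; proportions are written with 9
decimal places.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from .errors import ValidationError
from .model import MergeResult
from .schema import TypeSchema


@dataclass
class ProportionTable:
    """Per-category counts and proportions of a merged slide.

    When ``total`` is 0 the proportions are undefined; ``proportions`` is
    then ``None`` rather than a table of NaNs.
    """

    counts: dict[str, int]
    total: int
    proportions: dict[str, float] | None = field(default=None)

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.total:
            raise ValidationError("proportion table counts do not sum to total")
        if self.total > 0 and self.proportions is None:
            self.proportions = {
                c: n / self.total for c, n in self.counts.items()
            }


def compute_proportions(result: MergeResult, schema: TypeSchema) -> ProportionTable:
    """Count output categories and normalize to proportions.

    Every schema category is present in the table, zero-count ones
    included, in deterministic tree preorder.
    """
    counts = {c: 0 for c in schema.categories()}
    for rec in result.merged:
        counts[rec.category] = counts.get(rec.category, 0) + 1
    return ProportionTable(counts=counts, total=len(result.merged))


def project_to_match_level(
    counts: dict[str, int], schema: TypeSchema
) -> dict[str, int]:
    """Aggregate per-node counts up to each node's match-level ancestor."""
    out: dict[str, int] = {}
    for node, n in counts.items():
        lvl = schema.match_level[node]
        out[lvl] = out.get(lvl, 0) + n
    return out


def prediction_set_counts(pset, schema: TypeSchema) -> dict[str, int]:
    """Per-category counts of a single model's predictions (own nodes)."""
    counts: dict[str, int] = {}
    for n in pset.nuclei:
        node = schema.node_of(pset.model_id, n.type_label)
        counts[node] = counts.get(node, 0) + 1
    return counts


def total_variation(p: dict[str, float], q: dict[str, float]) -> float:
    """Total variation distance between two category distributions."""
    keys = set(p) | set(q)
    return 0.5 * sum(abs(p.get(k, 0.0) - q.get(k, 0.0)) for k in keys)


# -- CSV reports -----------------------------------------------------------

_MERGE_COLUMNS = [
    "row_type", "id", "provenance", "category", "x", "y",
    "m1_source_id", "m2_source_id", "m1_label", "m2_label",
    "prob", "distance", "equivocal",
    "merged_count", "conflict_m1_count", "conflict_m2_count",
    "unmatched_m1_count", "unmatched_m2_count",
]


def write_merge_report(result: MergeResult, path: str | Path) -> dict[str, Any]:
    """Detail rows for every output nucleus plus a per-category summary."""
    path = Path(path)
    summary: dict[str, dict[str, int]] = {}
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.DictWriter(fh, fieldnames=_MERGE_COLUMNS)
        w.writeheader()
        for rec in result.merged:
            w.writerow(
                {
                    "row_type": "detail",
                    "id": rec.id,
                    "provenance": rec.provenance,
                    "category": rec.category,
                    "x": repr(rec.centroid[0]),
                    "y": repr(rec.centroid[1]),
                    "m1_source_id": rec.source_ids.get(result.model1_id, ""),
                    "m2_source_id": rec.source_ids.get(result.model2_id, ""),
                    "m1_label": rec.source_labels.get(result.model1_id, ""),
                    "m2_label": rec.source_labels.get(result.model2_id, ""),
                    "prob": repr(rec.prob),
                    "distance": "" if rec.distance is None else repr(rec.distance),
                    "equivocal": str(rec.equivocal).lower(),
                }
            )
            cat = summary.setdefault(
                rec.category,
                {t: 0 for t in (
                    "merged", "conflict_m1", "conflict_m2",
                    "unmatched_m1", "unmatched_m2",
                )},
            )
            cat[rec.provenance] += 1
        for category in sorted(summary):
            cat = summary[category]
            w.writerow(
                {
                    "row_type": "summary",
                    "category": category,
                    "merged_count": cat["merged"],
                    "conflict_m1_count": cat["conflict_m1"],
                    "conflict_m2_count": cat["conflict_m2"],
                    "unmatched_m1_count": cat["unmatched_m1"],
                    "unmatched_m2_count": cat["unmatched_m2"],
                }
            )
    return {"path": str(path), "detail_rows": len(result.merged),
            "summary_rows": len(summary)}


_EQUIVOCAL_COLUMNS = [
    "m1_id", "m2_id", "m1_x", "m1_y", "m2_x", "m2_y",
    "m1_label", "m2_label", "m1_prob", "m2_prob", "winner", "distance",
]


def write_equivocal_report(result: MergeResult, path: str | Path) -> dict[str, Any]:
    """One row per equivocal overlap (both probabilities above threshold)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.DictWriter(fh, fieldnames=_EQUIVOCAL_COLUMNS)
        w.writeheader()
        for e in result.equivocal:
            w.writerow(
                {
                    "m1_id": e.m1_id,
                    "m2_id": e.m2_id,
                    "m1_x": repr(e.m1_centroid[0]),
                    "m1_y": repr(e.m1_centroid[1]),
                    "m2_x": repr(e.m2_centroid[0]),
                    "m2_y": repr(e.m2_centroid[1]),
                    "m1_label": e.m1_label,
                    "m2_label": e.m2_label,
                    "m1_prob": repr(e.m1_prob),
                    "m2_prob": repr(e.m2_prob),
                    "winner": e.winner,
                    "distance": repr(e.distance),
                }
            )
    return {"path": str(path), "rows": len(result.equivocal)}


def write_proportions_csv(
    table: ProportionTable, path: str | Path, percent: bool = False
) -> dict[str, Any]:
    """``category,count,proportion`` rows plus a TOTAL row.

    With ``percent=True`` proportions are scaled to 0-100.
    """
    path = Path(path)
    scale = 100.0 if percent else 1.0
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["category", "count", "percent" if percent else "proportion"])
        for category, count in table.counts.items():
            if table.proportions is None:
                prop = ""
            else:
                prop = f"{table.proportions[category] * scale:.9f}"
            w.writerow([category, count, prop])
        w.writerow(["TOTAL", table.total, "" if table.total == 0 else
                    f"{1.0 * scale:.9f}"])
    return {"path": str(path), "rows": len(table.counts)}


def read_proportions_csv(path: str | Path) -> ProportionTable:
    """Parse a proportions CSV back into a table (fraction or percent)."""
    path = Path(path)
    counts: dict[str, int] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        next(reader)  # header
        for row in reader:
            if row[0] == "TOTAL":
                continue
            counts[row[0]] = int(row[1])
    return ProportionTable(counts=counts, total=sum(counts.values()))
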
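"""Core domain containers for nuclei predictions and merge results.

Coordinates are 0-based pixels in image-array convention: ``x`` is the
column and ``y`` the row. The default physical scale is 0.263 micrometres
per pixel (40x magnification); the merge distance itself is computed in
pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import ValidationError

Point = tuple[float, float]

#: Provenance tags carried by every merged-output nucleus.
PROVENANCE_TAGS = (
    "merged",        # spatial match with agreeing harmonized type
    "conflict_m1",   # spatial match, disagreeing types, M1 nucleus won
    "conflict_m2",   # spatial match, disagreeing types, M2 nucleus won
    "unmatched_m1",  # M1 nucleus with no consuming match
    "unmatched_m2",  # M2 nucleus with no neighbor within the threshold
)


@dataclass
class Nucleus:
    """One segmented nucleus from a single model.

    Parameters
    ----------
    id
        Opaque identifier, unique within its owning prediction set.
    centroid
        ``(x, y)`` pixel centre of the nucleus.
    contour
        Ordered polygon vertices (>= 3) outlining the nucleus, in pixels.
    bbox
        ``((min_x, min_y), (max_x, max_y))`` axis-aligned bounding box.
    type_label
        Cell-type label from the owning model's vocabulary.
    prob
        Classification probability in ``[0, 1]``.
    """

    id: str
    centroid: Point
    contour: list[Point]
    bbox: tuple[Point, Point]
    type_label: str
    prob: float

    def validate(self) -> None:
        if not (0.0 <= self.prob <= 1.0):
            raise ValidationError(
                f"nucleus {self.id!r}: prob {self.prob} outside [0, 1]"
            )
        if len(self.contour) < 3:
            raise ValidationError(
                f"nucleus {self.id!r}: contour has {len(self.contour)} "
                "vertices, need >= 3"
            )
        (x0, y0), (x1, y1) = self.bbox
        if x0 > x1 or y0 > y1:
            raise ValidationError(
                f"nucleus {self.id!r}: bbox min exceeds max"
            )
        cx, cy = self.centroid
        if not (x0 <= cx <= x1 and y0 <= cy <= y1):
            raise ValidationError(
                f"nucleus {self.id!r}: centroid {self.centroid} outside bbox"
            )
        for v in (cx, cy):
            if not math.isfinite(v):
                raise ValidationError(
                    f"nucleus {self.id!r}: non-finite centroid"
                )


@dataclass
class PredictionSet:
    """All nuclei predicted by one model on one slide."""

    model_id: str
    vocabulary: set[str]
    nuclei: list[Nucleus] = field(default_factory=list)
    pixel_scale_um: float = 0.263

    def validate(self) -> None:
        seen: set[str] = set()
        for n in self.nuclei:
            n.validate()
            if n.id in seen:
                raise ValidationError(
                    f"{self.model_id}: duplicate nucleus id {n.id!r}"
                )
            seen.add(n.id)
            if n.type_label not in self.vocabulary:
                raise ValidationError(
                    f"{self.model_id}: nucleus {n.id!r} has label "
                    f"{n.type_label!r} outside the declared vocabulary"
                )

    def __len__(self) -> int:
        return len(self.nuclei)


@dataclass
class MergedNucleus:
    """A nucleus in the merged output, with full provenance.

    ``category`` is the harmonized output-category node (not a raw model
    label). ``source_ids`` / ``source_labels`` map contributing model ids to
    the source nucleus id and its raw label. ``distance`` is the pixel
    distance of the matched pair (``None`` for unmatched provenance).
    """

    id: str
    centroid: Point
    contour: list[Point]
    bbox: tuple[Point, Point]
    category: str
    prob: float
    provenance: str
    source_ids: dict[str, str]
    source_labels: dict[str, str]
    equivocal: bool = False
    distance: float | None = None

    def validate(self) -> None:
        if self.provenance not in PROVENANCE_TAGS:
            raise ValidationError(f"unknown provenance {self.provenance!r}")
        if self.provenance == "merged" and len(self.source_ids) != 2:
            raise ValidationError(
                f"merged nucleus {self.id!r} must carry two source ids"
            )


@dataclass
class EquivocalRecord:
    """A spatially-overlapping, type-disagreeing pair where both model
    probabilities exceed the equivocal threshold; kept for manual review."""

    m1_id: str
    m2_id: str
    m1_centroid: Point
    m2_centroid: Point
    m1_label: str
    m2_label: str
    m1_prob: float
    m2_prob: float
    winner: str        # "m1" | "m2"
    distance: float


@dataclass
class MergeResult:
    """Outcome of merging two prediction sets.

    ``m1_matched`` / ``m2_matched`` are the per-input match flags of the
    merging loop. ``dropped_m2`` lists M2 nuclei that lost a conflict whose
    M1 winner was already present in the output (so re-inserting it would
    have duplicated an M1 source).
    """

    model1_id: str
    model2_id: str
    merged: list[MergedNucleus] = field(default_factory=list)
    m1_matched: dict[str, bool] = field(default_factory=dict)
    m2_matched: dict[str, bool] = field(default_factory=dict)
    equivocal: list[EquivocalRecord] = field(default_factory=list)
    dropped_m2: list[str] = field(default_factory=list)

    def validate(self) -> None:
        seen_m1: set[str] = set()
        for rec in self.merged:
            rec.validate()
            sid = rec.source_ids.get(self.model1_id)
            if sid is not None:
                if sid in seen_m1:
                    raise ValidationError(
                        f"M1 source {sid!r} appears in more than one "
                        "output record"
                    )
                seen_m1.add(sid)

    def counts_by_provenance(self) -> dict[str, int]:
        out = {tag: 0 for tag in PROVENANCE_TAGS}
        for rec in self.merged:
            out[rec.provenance] += 1
        return out
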
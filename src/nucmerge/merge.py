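"""Nearest-neighbor merging of two nuclei prediction sets.

The merge walks every nucleus of the second set (M2), finds its nearest
neighbor among the first set's (M1) centroids, and applies three rules with
Euclidean distance threshold ``D`` (default 10 px):

* ``d <= D`` and the harmonized types match — the pair is **merged**:
  centroid is the componentwise midpoint, probability the maximum of the
  two, contour and bounding box are taken from the M2 member, and the type
  is the most specific output category of the pair.
* ``d <= D`` but the types disagree — a **conflict**: the nucleus with the
  higher probability is kept (ties keep the M2 nucleus). When both
  probabilities exceed the equivocal threshold (strictly above 0.75 by
  default) the pair is additionally recorded as *equivocal* for manual
  review; the winner still enters the output.
* ``d > D`` — the M2 nucleus is retained as is.

Afterwards every M1 nucleus that was never matched is retained as is, so
the output is a union of both models' detections with overlaps collapsed.

Two matching strategies are provided. ``literal`` follows the printed
procedure one query at a time, with a first-wins guard so an M1 nucleus
already consumed is never inserted twice: a later same-type match against a
consumed neighbor falls through to the ``d > D`` branch, and a conflict
whose M1 winner is already in the output drops the losing M2 nucleus
(recorded in ``dropped_m2``). ``one_to_one`` instead re-queries for the
nearest *unconsumed* M1 neighbor, so no guard is ever needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, ContractError
from .index import ExactIndex, RPTreeIndex
from .model import (
    EquivocalRecord,
    MergedNucleus,
    MergeResult,
    Nucleus,
    PredictionSet,
)
from .schema import TypeSchema


@dataclass
class MergeConfig:
    """Tunable parameters of the merging algorithm.

    ``distance_threshold`` is in pixels at the prediction resolution.
    ``equivocal_prob_threshold`` is strict: a conflict is equivocal only
    when *both* probabilities are strictly above it.
    """

    distance_threshold: float = 10.0
    equivocal_prob_threshold: float = 0.75
    index_backend: str = "exact"          # "exact" | "approximate"
    n_trees: int = 100
    search_k: int = -1
    matching_strategy: str = "literal"    # "literal" | "one_to_one"
    random_seed: int = 0                  # approximate backend only

    def validate(self) -> None:
        if not (self.distance_threshold > 0):
            raise ConfigError(
                f"distance_threshold must be > 0, got {self.distance_threshold}"
            )
        if not (0.0 < self.equivocal_prob_threshold < 1.0):
            raise ConfigError(
                "equivocal_prob_threshold must lie in (0, 1), got "
                f"{self.equivocal_prob_threshold}"
            )
        if self.index_backend not in ("exact", "approximate"):
            raise ConfigError(f"unknown index backend {self.index_backend!r}")
        if self.matching_strategy not in ("literal", "one_to_one"):
            raise ConfigError(
                f"unknown matching strategy {self.matching_strategy!r}"
            )


def build_index(points: np.ndarray, config: MergeConfig):
    """Build the configured spatial index over centroid positions."""
    if config.index_backend == "approximate":
        return RPTreeIndex(
            points,
            n_trees=config.n_trees,
            search_k=config.search_k,
            seed=config.random_seed,
        )
    return ExactIndex(points)


def merge_pair(
    n1: Nucleus,
    n2: Nucleus,
    schema: TypeSchema,
    model1_id: str,
    model2_id: str,
    merged_id: str,
    distance: float | None = None,
) -> MergedNucleus:
    """Combine a same-type pair into one output nucleus.

    Centroid is the midpoint, probability the max; contour and bounding box
    come from the M2 member, whose segmentation the procedure trusts for
    geometry.
    """
    if not schema.types_match(n1.type_label, model1_id, n2.type_label, model2_id):
        raise ContractError(
            f"merge_pair called on non-matching types {n1.type_label!r} vs "
            f"{n2.type_label!r}; route conflicts to resolve_conflict"
        )
    category = schema.output_category(
        n1.type_label, model1_id, n2.type_label, model2_id
    )
    return MergedNucleus(
        id=merged_id,
        centroid=(
            (n1.centroid[0] + n2.centroid[0]) / 2.0,
            (n1.centroid[1] + n2.centroid[1]) / 2.0,
        ),
        contour=list(n2.contour),
        bbox=n2.bbox,
        category=category,
        prob=max(n1.prob, n2.prob),
        provenance="merged",
        source_ids={model1_id: n1.id, model2_id: n2.id},
        source_labels={model1_id: n1.type_label, model2_id: n2.type_label},
        distance=distance,
    )


def resolve_conflict(
    n1: Nucleus, n2: Nucleus, config: MergeConfig
) -> tuple[Nucleus, bool]:
    """Pick the winner of a type-disagreeing overlap.

    Returns ``(winner, equivocal)``: the M2 nucleus wins on probability ties,
    and the pair is equivocal when both probabilities are strictly above the
    configured threshold.
    """
    winner = n2 if n2.prob >= n1.prob else n1
    thr = config.equivocal_prob_threshold
    return winner, (n1.prob > thr and n2.prob > thr)


def _single_source(
    n: Nucleus,
    schema: TypeSchema,
    model_id: str,
    provenance: str,
    merged_id: str,
    distance: float | None = None,
    equivocal: bool = False,
) -> MergedNucleus:
    return MergedNucleus(
        id=merged_id,
        centroid=n.centroid,
        contour=list(n.contour),
        bbox=n.bbox,
        category=schema.node_of(model_id, n.type_label),
        prob=n.prob,
        provenance=provenance,
        source_ids={model_id: n.id},
        source_labels={model_id: n.type_label},
        equivocal=equivocal,
        distance=distance,
    )


def _run_merge(
    m1: PredictionSet,
    m2: PredictionSet,
    schema: TypeSchema,
    config: MergeConfig,
    query_nearest,
) -> MergeResult:
    """Shared decision loop; ``query_nearest(n2, consumed)`` supplies the
    neighbor search so exact, approximate and brute-force variants differ
    only in how neighbors are found."""
    config.validate()
    m1.validate()
    m2.validate()
    for pset in (m1, m2):
        for label in pset.vocabulary:
            schema.node_of(pset.model_id, label)  # raises if unmapped

    D = config.distance_threshold
    one_to_one = config.matching_strategy == "one_to_one"
    result = MergeResult(
        model1_id=m1.model_id,
        model2_id=m2.model_id,
        m1_matched={n.id: False for n in m1.nuclei},
        m2_matched={n.id: False for n in m2.nuclei},
    )
    consumed: set[int] = set()   # M1 indices already placed in the output
    seq = 0

    def next_id() -> str:
        nonlocal seq
        mid = f"k{seq}"
        seq += 1
        return mid

    for n2 in m2.nuclei:
        i, d = query_nearest(n2, consumed if one_to_one else None)
        if i is not None:
            # canonical distance, independent of the index backend's metric
            c1 = m1.nuclei[i].centroid
            d = math.hypot(c1[0] - n2.centroid[0], c1[1] - n2.centroid[1])
        if i is None or d > D:
            result.merged.append(
                _single_source(n2, schema, m2.model_id, "unmatched_m2", next_id())
            )
            result.m2_matched[n2.id] = True
            continue
        n1 = m1.nuclei[i]
        if schema.types_match(
            n1.type_label, m1.model_id, n2.type_label, m2.model_id
        ):
            if i in consumed:
                # first consumption wins; treat as if no neighbor in range
                result.merged.append(
                    _single_source(
                        n2, schema, m2.model_id, "unmatched_m2", next_id()
                    )
                )
                result.m2_matched[n2.id] = True
                continue
            result.merged.append(
                merge_pair(
                    n1, n2, schema, m1.model_id, m2.model_id, next_id(),
                    distance=d,
                )
            )
            consumed.add(i)
            result.m1_matched[n1.id] = True
            result.m2_matched[n2.id] = True
        else:
            winner, equivocal = resolve_conflict(n1, n2, config)
            if equivocal:
                result.equivocal.append(
                    EquivocalRecord(
                        m1_id=n1.id,
                        m2_id=n2.id,
                        m1_centroid=n1.centroid,
                        m2_centroid=n2.centroid,
                        m1_label=n1.type_label,
                        m2_label=n2.type_label,
                        m1_prob=n1.prob,
                        m2_prob=n2.prob,
                        winner="m2" if winner is n2 else "m1",
                        distance=d,
                    )
                )
            if winner is n2:
                result.merged.append(
                    _single_source(
                        n2, schema, m2.model_id, "conflict_m2", next_id(),
                        distance=d, equivocal=equivocal,
                    )
                )
                result.m2_matched[n2.id] = True
            else:
                if i in consumed:
                    # M1 winner already in the output: the losing M2
                    # nucleus is dropped rather than duplicating M1
                    result.dropped_m2.append(n2.id)
                    continue
                result.merged.append(
                    _single_source(
                        n1, schema, m1.model_id, "conflict_m1", next_id(),
                        distance=d, equivocal=equivocal,
                    )
                )
                consumed.add(i)
                result.m1_matched[n1.id] = True

    for n1 in m1.nuclei:
        if not result.m1_matched[n1.id]:
            result.merged.append(
                _single_source(n1, schema, m1.model_id, "unmatched_m1", next_id())
            )

    result.validate()
    return result


def merge_predictions(
    m1: PredictionSet,
    m2: PredictionSet,
    schema: TypeSchema,
    config: MergeConfig | None = None,
) -> MergeResult:
    """Merge two prediction sets using the configured spatial index."""
    config = config or MergeConfig()
    config.validate()
    points = np.array([n.centroid for n in m1.nuclei], dtype=float).reshape(-1, 2)
    index = build_index(points, config)

    def query(n2: Nucleus, exclude: set[int] | None):
        return index.query(n2.centroid, exclude=exclude)

    return _run_merge(m1, m2, schema, config, query)


def brute_force_merge(
    m1: PredictionSet,
    m2: PredictionSet,
    schema: TypeSchema,
    config: MergeConfig | None = None,
) -> MergeResult:
    """Reference merge finding neighbors by exhaustive all-pairs scan.

    Same contract as :func:`merge_predictions`; used as an independent
    oracle in the test suite.
    """
    config = config or MergeConfig()
    config.validate()
    p1 = np.array([n.centroid for n in m1.nuclei], dtype=float).reshape(-1, 2)

    def query(n2: Nucleus, exclude: set[int] | None):
        if len(p1) == 0:
            return None, math.inf
        d = np.hypot(p1[:, 0] - n2.centroid[0], p1[:, 1] - n2.centroid[1])
        if exclude:
            if len(exclude) >= len(p1):
                return None, math.inf
            d = d.copy()
            d[list(exclude)] = math.inf
        i = int(np.argmin(d))   # argmin takes the smallest index on ties
        return i, float(d[i])

    return _run_merge(m1, m2, schema, config, query)
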
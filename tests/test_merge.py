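import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucmerge import (
    ConfigError,
    ContractError,
    MergeConfig,
    PredictionSet,
    brute_force_merge,
    merge_pair,
    merge_predictions,
    resolve_conflict,
)

from conftest import make_nucleus, random_prediction_set, results_equal


# ---------------------------------------------------------------------------
# merge_pair / resolve_conflict unit behavior
# ---------------------------------------------------------------------------

def test_merge_pair_midpoint_maxprob_m2_geometry(schema):
    n1 = make_nucleus("a", (10, 10), "epithelial", 0.6)
    n2 = make_nucleus("b", (12, 10), "non-neoplastic epithelial", 0.9)
    m = merge_pair(n1, n2, schema, "monusac", "pannuke", "k0", distance=2.0)
    assert m.centroid == (11.0, 10.0)
    assert m.prob == 0.9
    assert m.contour == n2.contour
    assert m.bbox == n2.bbox
    assert m.category == "non-neoplastic epithelial"
    assert m.provenance == "merged"
    assert m.source_ids == {"monusac": "a", "pannuke": "b"}


def test_merge_pair_identical_nuclei_is_idempotent(schema):
    n1 = make_nucleus("a", (5, 5), "epithelial", 0.5)
    n2 = make_nucleus("b", (5, 5), "non-neoplastic epithelial", 0.5)
    m = merge_pair(n1, n2, schema, "monusac", "pannuke", "k0")
    assert m.centroid == (5.0, 5.0)
    assert m.prob == 0.5


def test_merge_pair_takes_max_probability(schema):
    n1 = make_nucleus("a", (0, 0), "lymphocyte", 0.99)
    n2 = make_nucleus("b", (0, 0), "inflammatory", 0.10)
    assert merge_pair(n1, n2, schema, "monusac", "pannuke", "k0").prob == 0.99


def test_merge_pair_refuses_non_matching_types(schema):
    n1 = make_nucleus("a", (0, 0), "epithelial", 0.9)
    n2 = make_nucleus("b", (0, 0), "connective", 0.9)
    with pytest.raises(ContractError):
        merge_pair(n1, n2, schema, "monusac", "pannuke", "k0")


@pytest.mark.parametrize(
    "p1, p2, winner_is_m2, equivocal",
    [
        (0.8, 0.8, True, True),     # tie keeps the M2 nucleus; both high
        (0.9, 0.5, False, False),
        (0.75, 0.76, True, False),  # threshold is strict: 0.75 is not high
        (0.76, 0.75, False, False),
        (0.751, 0.76, True, True),
    ],
)
def test_resolve_conflict_tie_and_equivocal_rules(p1, p2, winner_is_m2, equivocal):
    n1 = make_nucleus("a", (0, 0), "inflammatory", p1)
    n2 = make_nucleus("b", (1, 0), "epithelial", p2)
    winner, eq = resolve_conflict(n1, n2, MergeConfig())
    assert (winner is n2) is winner_is_m2
    assert eq is equivocal


# ---------------------------------------------------------------------------
# merge_predictions behavior
# ---------------------------------------------------------------------------

def _pset(model_id, nuclei, vocab):
    p = PredictionSet(model_id, set(vocab), nuclei)
    p.validate()
    return p


def test_empty_m2_retains_all_m1(schema):
    rng = np.random.default_rng(0)
    m1 = random_prediction_set(rng, "monusac", 10)
    m2 = _pset("pannuke", [], ["connective"])
    res = merge_predictions(m1, m2, schema)
    assert len(res.merged) == 10
    assert all(r.provenance == "unmatched_m1" for r in res.merged)


def test_empty_m1_retains_all_m2(schema):
    rng = np.random.default_rng(0)
    m2 = random_prediction_set(rng, "pannuke", 10)
    m1 = _pset("monusac", [], ["epithelial"])
    res = merge_predictions(m1, m2, schema)
    assert len(res.merged) == 10
    assert all(r.provenance == "unmatched_m2" for r in res.merged)


def test_distance_threshold_is_inclusive_at_exactly_ten(schema):
    m1 = _pset("monusac", [make_nucleus("a", (0, 0), "epithelial", 0.6)],
               ["epithelial"])
    m2 = _pset("pannuke",
               [make_nucleus("b", (6, 8), "non-neoplastic epithelial", 0.7)],
               ["non-neoplastic epithelial"])
    res = merge_predictions(m1, m2, schema)
    assert len(res.merged) == 1
    rec = res.merged[0]
    assert rec.provenance == "merged"
    assert rec.centroid == (3.0, 4.0)
    assert rec.distance == 10.0


def test_pair_just_beyond_threshold_stays_unmerged(schema):
    m1 = _pset("monusac", [make_nucleus("a", (0, 0), "epithelial", 0.6)],
               ["epithelial"])
    m2 = _pset("pannuke",
               [make_nucleus("b", (10.0 + 1e-9, 0), "non-neoplastic epithelial", 0.7)],
               ["non-neoplastic epithelial"])
    res = merge_predictions(m1, m2, schema)
    assert len(res.merged) == 2
    assert {r.provenance for r in res.merged} == {"unmatched_m1", "unmatched_m2"}


def test_conflict_outputs_and_equivocal_flag(schema):
    m1 = _pset("monusac", [make_nucleus("a", (0, 0), "lymphocyte", 0.8)],
               ["lymphocyte"])
    m2 = _pset("pannuke", [make_nucleus("b", (1, 0), "connective", 0.8)],
               ["connective"])
    res = merge_predictions(m1, m2, schema)
    # tie keeps M2; the losing M1 is retained afterwards as unmatched
    provs = sorted(r.provenance for r in res.merged)
    assert provs == ["conflict_m2", "unmatched_m1"]
    assert len(res.equivocal) == 1
    e = res.equivocal[0]
    assert e.winner == "m2"
    assert e.m1_label == "lymphocyte" and e.m2_label == "connective"


def test_literal_guard_same_type_second_match_falls_through(schema):
    # two M2 nuclei share the same nearest M1; first consumes it
    m1 = _pset("monusac", [make_nucleus("a", (0, 0), "epithelial", 0.5)],
               ["epithelial"])
    m2 = _pset(
        "pannuke",
        [
            make_nucleus("b1", (1, 0), "non-neoplastic epithelial", 0.6),
            make_nucleus("b2", (0, 1), "non-neoplastic epithelial", 0.7),
        ],
        ["non-neoplastic epithelial"],
    )
    res = merge_predictions(m1, m2, schema)
    provs = sorted(r.provenance for r in res.merged)
    assert provs == ["merged", "unmatched_m2"]
    merged = next(r for r in res.merged if r.provenance == "merged")
    assert merged.source_ids["pannuke"] == "b1"  # first consumption wins


def test_literal_guard_drops_m2_losing_conflict_to_consumed_m1(schema):
    # b1 merges with a; b2 then loses a conflict against the consumed a
    m1 = _pset("monusac", [make_nucleus("a", (0, 0), "epithelial", 0.9)],
               ["epithelial"])
    m2 = _pset(
        "pannuke",
        [
            make_nucleus("b1", (1, 0), "non-neoplastic epithelial", 0.6),
            make_nucleus("b2", (0, 1), "connective", 0.3),
        ],
        ["non-neoplastic epithelial", "connective"],
    )
    res = merge_predictions(m1, m2, schema)
    assert [r.provenance for r in res.merged] == ["merged"]
    assert res.dropped_m2 == ["b2"]


def test_one_to_one_requeries_unconsumed_neighbor(schema):
    # both M2 nuclei nearest the same M1 'a'; one_to_one lets the second
    # take the farther unconsumed 'c'
    m1 = _pset(
        "monusac",
        [
            make_nucleus("a", (0, 0), "epithelial", 0.5),
            make_nucleus("c", (5, 0), "epithelial", 0.5),
        ],
        ["epithelial"],
    )
    m2 = _pset(
        "pannuke",
        [
            make_nucleus("b1", (1, 0), "non-neoplastic epithelial", 0.6),
            make_nucleus("b2", (2, 0), "non-neoplastic epithelial", 0.7),
        ],
        ["non-neoplastic epithelial"],
    )
    res = merge_predictions(
        m1, m2, schema, MergeConfig(matching_strategy="one_to_one")
    )
    assert sorted(r.provenance for r in res.merged) == ["merged", "merged"]
    pairs = {r.source_ids["monusac"]: r.source_ids["pannuke"]
             for r in res.merged}
    assert pairs == {"a": "b1", "c": "b2"}


@pytest.mark.parametrize(
    "kwargs",
    [
        {"distance_threshold": 0.0},
        {"distance_threshold": -3.0},
        {"equivocal_prob_threshold": 0.0},
        {"equivocal_prob_threshold": 1.0},
        {"index_backend": "kdtree"},
        {"matching_strategy": "greedy"},
    ],
)
def test_invalid_config_rejected(schema, kwargs):
    rng = np.random.default_rng(0)
    m1 = random_prediction_set(rng, "monusac", 2)
    m2 = random_prediction_set(rng, "pannuke", 2)
    with pytest.raises(ConfigError):
        merge_predictions(m1, m2, schema, MergeConfig(**kwargs))


# ---------------------------------------------------------------------------
# an independent miniature reference (plain dict/loop implementation)
# ---------------------------------------------------------------------------

def mini_reference(m1, m2, schema, D=10.0):
    """Literal merging loop written independently of the package internals;
    returns comparable (provenance, sources, category) summaries."""
    out = []
    matched1 = set()
    for n2 in m2.nuclei:
        best_i, best_d = None, math.inf
        for i, n1 in enumerate(m1.nuclei):
            d = math.hypot(n1.centroid[0] - n2.centroid[0],
                           n1.centroid[1] - n2.centroid[1])
            if d < best_d:
                best_i, best_d = i, d
        if best_i is None or best_d > D:
            out.append(("unmatched_m2", (None, n2.id),
                        schema.node_of(m2.model_id, n2.type_label)))
            continue
        n1 = m1.nuclei[best_i]
        if schema.types_match(n1.type_label, m1.model_id,
                              n2.type_label, m2.model_id):
            if best_i in matched1:
                out.append(("unmatched_m2", (None, n2.id),
                            schema.node_of(m2.model_id, n2.type_label)))
            else:
                matched1.add(best_i)
                out.append(("merged", (n1.id, n2.id),
                            schema.output_category(
                                n1.type_label, m1.model_id,
                                n2.type_label, m2.model_id)))
        elif n2.prob >= n1.prob:
            out.append(("conflict_m2", (None, n2.id),
                        schema.node_of(m2.model_id, n2.type_label)))
        elif best_i not in matched1:
            matched1.add(best_i)
            out.append(("conflict_m1", (n1.id, None),
                        schema.node_of(m1.model_id, n1.type_label)))
    for i, n1 in enumerate(m1.nuclei):
        if i not in matched1:
            out.append(("unmatched_m1", (n1.id, None),
                        schema.node_of(m1.model_id, n1.type_label)))
    return sorted(out, key=repr)


def summarize(result):
    out = [
        (
            r.provenance,
            (r.source_ids.get(result.model1_id),
             r.source_ids.get(result.model2_id)),
            r.category,
        )
        for r in result.merged
    ]
    return sorted(out, key=repr)


@pytest.mark.parametrize("seed", range(10))
def test_merge_matches_independent_reference(schema, seed):
    rng = np.random.default_rng(seed)
    m1 = random_prediction_set(rng, "monusac", int(rng.integers(0, 60)), span=60)
    m2 = random_prediction_set(rng, "pannuke", int(rng.integers(0, 60)), span=60)
    res = merge_predictions(m1, m2, schema)
    assert summarize(res) == mini_reference(m1, m2, schema)


# ---------------------------------------------------------------------------
# oracle equivalence and invariants
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("strategy", ["literal", "one_to_one"])
@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_exact_backend_equals_brute_force(schema, strategy, seed):
    rng = np.random.default_rng(seed)
    n1, n2 = int(rng.integers(0, 200)), int(rng.integers(0, 200))
    m1 = random_prediction_set(rng, "monusac", n1, span=120)
    m2 = random_prediction_set(rng, "pannuke", n2, span=120)
    cfg = MergeConfig(matching_strategy=strategy)
    assert results_equal(
        merge_predictions(m1, m2, schema, cfg),
        brute_force_merge(m1, m2, schema, cfg),
    )


def check_conservation(res, n1, n2):
    counts = res.counts_by_provenance()
    assert len(res.merged) <= n1 + n2
    assert (
        counts["merged"] + counts["conflict_m1"] + counts["conflict_m2"]
        + counts["unmatched_m2"]
        == n2 - len(res.dropped_m2)
    )
    matched_m1 = sum(res.m1_matched.values())
    assert counts["unmatched_m1"] == n1 - matched_m1
    m1_sources = [
        r.source_ids[res.model1_id]
        for r in res.merged
        if res.model1_id in r.source_ids
    ]
    assert len(m1_sources) == len(set(m1_sources))


@given(seed=st.integers(0, 10_000), strategy=st.sampled_from(["literal", "one_to_one"]))
@settings(max_examples=40)
def test_conservation_invariants_hold_on_random_instances(schema, seed, strategy):
    rng = np.random.default_rng(seed)
    n1, n2 = int(rng.integers(0, 120)), int(rng.integers(0, 120))
    m1 = random_prediction_set(rng, "monusac", n1, span=80)
    m2 = random_prediction_set(rng, "pannuke", n2, span=80)
    res = merge_predictions(m1, m2, schema,
                            MergeConfig(matching_strategy=strategy))
    check_conservation(res, n1, n2)


def test_exact_backend_is_deterministic(schema):
    rng = np.random.default_rng(77)
    m1 = random_prediction_set(rng, "monusac", 150, span=100)
    m2 = random_prediction_set(rng, "pannuke", 150, span=100)
    assert results_equal(
        merge_predictions(m1, m2, schema),
        merge_predictions(m1, m2, schema),
    )


def test_merged_pairs_grow_with_threshold_without_contention(schema):
    """Raising the distance threshold can only add merged pairs when no two
    sites compete for the same neighbor. (Under contention the greedy
    one-to-one matching is order-dependent and genuinely non-monotone: an
    earlier query reaching farther can consume the partner a later query
    used at the smaller threshold.)"""
    rng = np.random.default_rng(13)
    # isolated sites, one nucleus per model per site, far enough apart that
    # no query can ever cross between sites
    sites = rng.uniform(0, 2000, size=(60, 2))
    keep = [
        i for i, s in enumerate(sites)
        if all(np.hypot(*(s - t)) > 80 for t in sites[:i])
    ]
    nuclei1, nuclei2 = [], []
    for k, i in enumerate(keep):
        x, y = sites[i]
        offset = rng.uniform(2, 18)
        nuclei1.append(make_nucleus(f"m{k}", (x, y), "epithelial", 0.5))
        nuclei2.append(make_nucleus(
            f"p{k}", (x + offset, y), "non-neoplastic epithelial", 0.5))
    m1 = _pset("monusac", nuclei1, ["epithelial"])
    m2 = _pset("pannuke", nuclei2, ["non-neoplastic epithelial"])

    def merged_pairs(D):
        res = merge_predictions(
            m1, m2, schema,
            MergeConfig(distance_threshold=D, matching_strategy="one_to_one"),
        )
        return {
            (r.source_ids[m1.model_id], r.source_ids[m2.model_id])
            for r in res.merged
            if r.provenance == "merged"
        }

    small, medium, large = merged_pairs(5.0), merged_pairs(12.0), merged_pairs(18.0)
    assert small < large  # some pairs only merge at the wider threshold
    assert small <= medium <= large


def test_approximate_backend_runs_and_mostly_agrees(schema):
    rng = np.random.default_rng(21)
    m1 = random_prediction_set(rng, "monusac", 400, span=400)
    m2 = random_prediction_set(rng, "pannuke", 400, span=400)
    exact = merge_predictions(m1, m2, schema)
    approx = merge_predictions(
        m1, m2, schema, MergeConfig(index_backend="approximate", random_seed=4)
    )
    # approximate is allowed to differ on a small fraction of decisions
    same = len(set(summarize(exact)) & set(summarize(approx)))
    assert same / len(exact.merged) >= 0.98
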
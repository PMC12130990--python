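# Methods

## Model and scope

`nucmerge` treats nuclei integration as a point-set matching problem.
Each model's prediction set is reduced to its centroids for matching;
contours and boxes are carried through but never influence a decision.
Matching is one directional pass over the second set (M₂) against a fixed
spatial index on the first set's (M₁) centroids, with three outcomes per
query (merge / conflict resolution / retain), followed by retention of
never-matched M₁ nuclei. This is deliberately not a globally optimal
assignment: it reproduces a simple, fast, streaming procedure whose
behavior is easy to audit per nucleus. Contour-overlap (IoU) matching and
simultaneous merging of more than two models are out of scope; chains are
formed pairwise.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `distance_threshold` (D) | 10 | px | centroid distance below which two detections are considered the same nucleus; at 0.263 µm/px this is ~2.6 µm, well under a nucleus diameter. Comparison is inclusive (`d ≤ D`). |
| `equivocal_prob_threshold` | 0.75 | — | both probabilities must be **strictly** above this for a disagreeing overlap to be reported for manual review; the winner still enters the output. |
| `index_backend` | `exact` | — | exact k-d tree; `approximate` selects the random-projection forest. |
| `n_trees`, `search_k` | 100, −1 | — | forest size and candidate budget of the approximate backend; `search_k = −1` means one leaf's worth of candidates per tree. |
| `matching_strategy` | `literal` | — | see below. |
| `pixel_scale_um` | 0.263 | µm/px | carried as metadata; all distances are computed in pixels. |

## Matching strategies and the duplicate-consumption guard

The streaming procedure as printed has no guard against two M₂ nuclei
matching the same M₁ nucleus. `literal` keeps the stream order and adds
the minimal guard that preserves the no-duplicate-output invariant:

* a same-type match whose M₁ neighbor is already consumed is handled as
  if no neighbor were in range (the M₂ nucleus is retained unmatched);
* a conflict resolved in favor of an already-consumed M₁ nucleus adds
  nothing (the losing M₂ nucleus is dropped and recorded in
  `dropped_m2`), since re-inserting the winner would duplicate it.

`one_to_one` instead re-queries for the nearest *unconsumed* neighbor, so
every decision is against an available partner and nothing is ever
dropped. Bookkeeping identities asserted on every run: each M₂ nucleus
yields exactly one output record or one `dropped_m2` entry; unmatched M₁
count equals |M₁| minus distinct matched M₁; no M₁ source id appears
twice; output size ≤ |M₁| + |M₂|.

A consequence of greedy in-order matching worth knowing: the merged-pair
set is **not monotone** in D under contention. Raising D can let an
earlier M₂ query reach and consume the M₁ nucleus that a later query had
merged with at the smaller threshold. Monotonicity holds only in
contention-free geometry (at most one candidate per site), which is what
the property test asserts.

## Merged-record semantics

For a same-type pair the merged record takes the centroid midpoint, the
maximum probability, and the contour/box of the M₂ member (whose
segmentation this procedure trusts for geometry). The output type is the
**most specific** harmonized node of the two labels along their shared
lineage — e.g. a `lymphocyte` call merged with an `inflammatory` call is
reported as `lymphocyte`. This (rather than copying the M₂ label verbatim)
is what lets the merged output report categories only one model can name;
for sibling nodes under the same match level the deeper node wins, ties
preferring the M₂ side. Conflict ties on probability keep the M₂ nucleus.

## Type schema

The harmonization schema is a rooted tree in which children refine
parents. Each model maps its raw labels to nodes; equality for merging is
evaluated at each node's *match level* (default: its depth-1 ancestor).
The shipped default encodes the PanNuke/MoNuSAC pairing with
`epithelial`, `inflammatory`, `connective`, `dead` as match-level nodes.
Both the tree and the match levels are user-overridable; validation
rejects unmapped labels, unknown nodes, non-ancestor match levels, cycles
and duplicate nodes.

## Spatial index

The exact backend wraps a k-d tree and breaks exact distance ties by the
smallest point index, so runs are bit-reproducible (distances of matched
pairs are recomputed canonically with `hypot`, making results identical
across backends when the neighbor agrees). The approximate backend builds
`n_trees` random-projection trees (recursive perpendicular-bisector
splits of two sampled points, leaves ≤ 16 items; degenerate point clouds
fall back to balanced random splits) and searches them with a shared
priority queue ordered by the smallest hyperplane margin along the path,
scanning `search_k` candidates exactly. It is seeded and deterministic
for a fixed seed, but its tie-breaking is only guaranteed within the
candidate set. Measured agreement with the exact backend at 10,000
uniform points and 100 trees is ≥ 99% of queries (the suite asserts this
bound; observed agreement is typically 100%).

## Statistics

`lin_ccc` implements the concordance correlation coefficient with biased
(1/n) moments, ρ̂_c = 2s_xy/(s_x²+s_y²+(x̄−ȳ)²), and the standard
asymptotic confidence interval on the Fisher z-scale (variance per Lin's
corrected formula with the scale-shift term u = (ȳ−x̄)/(s_x s_y)^{1/2}),
back-transformed with `tanh`. Degenerate inputs collapse the interval to
the point estimate (|ρ̂_c| = 1 or zero covariance); two constant vectors
with equal means are rejected as undefined rather than returned as NaN.
Reference values (deciles from a manual review) enter as plain numeric
percentages; no ordinal model is fitted. `two_sample_t` defers to the
standard Welch/pooled t-test, with the double-degenerate case (both
samples constant) defined as t = 0, p = 1 on equal means and an infinite
statistic otherwise.

## Synthetic data

The generator emulates paired model views of one slide. Ground truth is a
hard-core point process (grid-accelerated dart throwing, minimum centre
separation 20 px) over a 4096² px field with exact per-category counts;
nuclei carry circular 12-gon contours of radius 8 px — a stand-in shape,
carried but never used by the merge math. Default composition (2,000
nuclei: 52.5% epithelial, 43% connective, 2.1% lymphocyte, 0.5%
neutrophil, 0.4% macrophage, 1.5% dead) reflects benign prostate tissue,
where connective cells average ~43% of nuclei and lymphocytes ≤ 2%.

Model profiles default to the asymmetry that motivates integration: the
MoNuSAC-style profile detects epithelial and the inflammatory subtypes at
0.95 but connective/dead at 0 (it cannot segment them); the PanNuke-style
profile detects epithelial/connective at 0.95, dead at 0.90, and the
inflammatory categories at only 0.25, collapsed into one `inflammatory`
label. Both jitter centroids with σ = 1 px and draw probability scores
from Beta(8, 2) (mean 0.8 — confident but not saturated calls). All
randomness flows from explicit seeds (seeds derived through
`SeedSequence`); identical seeds give identical fields, views and files.

What the generator does **not** emulate: real nucleus shapes and contour
overlap, spatially correlated detection failures (e.g. tissue folds),
probability scores correlated with correctness, under/over-segmentation
(one nucleus split into two detections), and staining/scanner variation.
Passing the recovery tests therefore shows the *algorithm* integrates
complementary detector profiles correctly under spatial noise — it is not
evidence about any particular real slide cohort.

## Numerical and degenerate-input choices

* Distances in pixels, `float64`; matched-pair distances recomputed with
  `hypot` for cross-backend identity.
* Equidistant neighbors: smallest index wins (exact backend guarantee).
* Empty inputs are legal everywhere: empty prediction sets merge to the
  other set's retained nuclei; an empty index answers with a no-neighbor
  sentinel; an empty merge result yields a proportion table with total 0
  and explicitly undefined (`None`) proportions.
* Coincident centroids within one set are legal; the algorithm never
  deduplicates within a model's own predictions.
* CSV floats are written with `repr` (shortest round-trip) and
  proportions with 9 decimals, so re-running a merge writes byte-identical
  reports.

## Known limitations

* Greedy, order-dependent matching (see non-monotonicity above); the
  one-to-one strategy removes duplicate-consumption artifacts but is still
  not a globally optimal assignment.
* Centroid-only matching cannot distinguish a true overlap from two
  adjacent small nuclei closer than D; D = 10 px presumes ≥ 40×-resolution
  coordinates, and coordinates in microns or at other magnifications need
  a rescaled threshold.
* The approximate backend's recall contract is statistical, not per-query.
* The confidence interval of the concordance coefficient is asymptotic;
  at very small n it is wide and approximate.
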
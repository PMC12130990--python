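"""Synthetic paired model predictions over a known ground truth.

A *truth field* is a set of non-overlapping nuclei (centroid, true
category, circular contour) scattered over a rectangular pixel field by
grid-accelerated dart throwing with a minimum centre separation. Each model
*views* the truth through its own profile: per-category detection dropout,
Gaussian centroid jitter, a label-confusion matrix over the model's
vocabulary, and Beta-distributed classification probabilities.

The default profiles emulate the asymmetries of two real pretrained
nuclei-classification models: model ``monusac`` never detects connective or
dead cells but names individual inflammatory subtypes (lymphocyte,
neutrophil, macrophage); model ``pannuke`` detects connective and dead
cells but lumps inflammatory cells into one class and under-detects them.
Default truth composition is dominated by epithelial (~52%) and connective
(~43%) cells with ~2% lymphocytes, the regime of benign prostate tissue.

Because the truth is known, expected merge statistics come for free: in
the noiseless limit the merged output has exactly one nucleus per truth
nucleus detected by either model, and its category proportions equal the
truth proportions over detectable categories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError, GenerationError
from .model import Nucleus, PredictionSet
from .schema import TypeSchema

#: Truth categories are leaf nodes of the default schema.
DEFAULT_TRUTH_COUNTS = {
    "epithelial": 1050,
    "connective": 860,
    "lymphocyte": 42,
    "neutrophil": 10,
    "macrophage": 8,
    "dead": 30,
}


@dataclass
class ModelProfile:
    """How one model degrades the truth.

    ``label_map`` sends truth categories into the model's vocabulary;
    ``detection_prob`` gives per-truth-category detection probability
    (categories absent from ``label_map`` are implicitly undetectable);
    ``confusion`` is an optional row-stochastic matrix over the model's
    vocabulary applied after mapping; probability scores are drawn from
    ``Beta(prob_beta[0], prob_beta[1])``.
    """

    model_id: str
    label_map: dict[str, str]
    detection_prob: dict[str, float]
    jitter_sd: float = 1.0
    confusion: dict[str, dict[str, float]] = field(default_factory=dict)
    prob_beta: tuple[float, float] = (8.0, 2.0)

    def vocabulary(self) -> set[str]:
        vocab = set(self.label_map.values())
        for row in self.confusion.values():
            vocab |= set(row)
        return vocab

    def validate(self) -> None:
        for cat, p in self.detection_prob.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigError(
                    f"{self.model_id}: detection prob for {cat!r} is {p}"
                )
            if p > 0 and cat not in self.label_map:
                raise ConfigError(
                    f"{self.model_id}: detectable category {cat!r} has no label"
                )
        for src, row in self.confusion.items():
            if abs(sum(row.values()) - 1.0) > 1e-9:
                raise ConfigError(
                    f"{self.model_id}: confusion row {src!r} does not sum to 1"
                )
        if self.jitter_sd < 0:
            raise ConfigError(f"{self.model_id}: negative jitter sd")


def monusac_profile(**overrides) -> ModelProfile:
    """Default profile of the MoNuSAC-trained model: no connective/dead."""
    prof = ModelProfile(
        model_id="monusac",
        label_map={
            "epithelial": "epithelial",
            "lymphocyte": "lymphocyte",
            "neutrophil": "neutrophil",
            "macrophage": "macrophage",
        },
        detection_prob={
            "epithelial": 0.95,
            "lymphocyte": 0.95,
            "neutrophil": 0.95,
            "macrophage": 0.95,
            "connective": 0.0,
            "dead": 0.0,
        },
    )
    return replace(prof, **overrides) if overrides else prof


def pannuke_profile(**overrides) -> ModelProfile:
    """Default profile of the PanNuke-trained model: one inflammatory
    class, under-detected; connective and dead detected."""
    prof = ModelProfile(
        model_id="pannuke",
        label_map={
            "epithelial": "non-neoplastic epithelial",
            "lymphocyte": "inflammatory",
            "neutrophil": "inflammatory",
            "macrophage": "inflammatory",
            "connective": "connective",
            "dead": "dead",
        },
        detection_prob={
            "epithelial": 0.95,
            "lymphocyte": 0.25,
            "neutrophil": 0.25,
            "macrophage": 0.25,
            "connective": 0.95,
            "dead": 0.90,
        },
    )
    return replace(prof, **overrides) if overrides else prof


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic slide."""

    field_size: tuple[float, float] = (4096.0, 4096.0)
    truth_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_TRUTH_COUNTS)
    )
    min_separation: float = 20.0
    nucleus_radius: float = 8.0
    profile_m1: ModelProfile = field(default_factory=monusac_profile)
    profile_m2: ModelProfile = field(default_factory=pannuke_profile)
    random_seed: int = 0

    def validate(self) -> None:
        if any(n < 0 for n in self.truth_counts.values()):
            raise ConfigError("negative truth count")
        if self.min_separation <= 0 or self.nucleus_radius <= 0:
            raise ConfigError("separation and radius must be positive")
        self.profile_m1.validate()
        self.profile_m2.validate()


@dataclass
class TruthNucleus:
    id: str
    centroid: tuple[float, float]
    category: str


@dataclass
class TruthField:
    nuclei: list[TruthNucleus]
    field_size: tuple[float, float]
    radius: float

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for n in self.nuclei:
            out[n.category] = out.get(n.category, 0) + 1
        return out

    def __len__(self) -> int:
        return len(self.nuclei)


def _dart_throw(
    rng: np.random.Generator,
    n: int,
    size: tuple[float, float],
    min_sep: float,
    max_attempts_per_point: int = 200,
) -> np.ndarray:
    """Sample n points with pairwise distance >= min_sep (grid-accelerated)."""
    cell = min_sep
    grid: dict[tuple[int, int], list[int]] = {}
    pts = np.empty((n, 2))
    placed = 0
    attempts_left = n * max_attempts_per_point
    while placed < n:
        if attempts_left <= 0:
            raise GenerationError(
                f"could not place {n} points with separation {min_sep} "
                f"in a {size[0]}x{size[1]} field"
            )
        attempts_left -= 1
        p = rng.uniform((0.0, 0.0), size)
        gx, gy = int(p[0] // cell), int(p[1] // cell)
        ok = True
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for j in grid.get((gx + dx, gy + dy), ()):
                    if np.hypot(*(pts[j] - p)) < min_sep:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            pts[placed] = p
            grid.setdefault((gx, gy), []).append(placed)
            placed += 1
    return pts


def generate_truth(
    config: SyntheticConfig, seed: int | None = None
) -> TruthField:
    """Place the configured per-category counts of nuclei in the field."""
    config.validate()
    rng = np.random.default_rng(
        config.random_seed if seed is None else seed
    )
    total = sum(config.truth_counts.values())
    pts = _dart_throw(rng, total, config.field_size, config.min_separation)
    categories = [
        cat for cat, cnt in config.truth_counts.items() for _ in range(cnt)
    ]
    rng.shuffle(categories)
    nuclei = [
        TruthNucleus(id=str(i), centroid=(float(x), float(y)), category=cat)
        for i, ((x, y), cat) in enumerate(zip(pts, categories))
    ]
    return TruthField(
        nuclei=nuclei, field_size=config.field_size,
        radius=config.nucleus_radius,
    )


def _circle(cx: float, cy: float, r: float, k: int = 12) -> list[tuple[float, float]]:
    ang = np.linspace(0.0, 2.0 * math.pi, k, endpoint=False)
    return [(float(cx + r * math.cos(a)), float(cy + r * math.sin(a))) for a in ang]


def degrade_to_model_view(
    truth: TruthField, profile: ModelProfile, seed: int
) -> PredictionSet:
    """One model's noisy view of the truth field.

    Each truth nucleus is independently detected with its category's
    detection probability; detected nuclei get a jittered centroid, a
    (possibly confused) label and a Beta-distributed probability score.
    Output nucleus ids equal the source truth ids, so correspondence is
    traceable.
    """
    profile.validate()
    rng = np.random.default_rng(seed)
    nuclei: list[Nucleus] = []
    r = truth.radius
    for t in truth.nuclei:
        p_det = profile.detection_prob.get(t.category, 0.0)
        if rng.random() >= p_det:
            continue
        label = profile.label_map[t.category]
        row = profile.confusion.get(label)
        if row:
            labels = sorted(row)
            label = rng.choice(labels, p=[row[l] for l in labels])
        cx = t.centroid[0] + rng.normal(0.0, profile.jitter_sd)
        cy = t.centroid[1] + rng.normal(0.0, profile.jitter_sd)
        prob = float(rng.beta(*profile.prob_beta))
        nuclei.append(
            Nucleus(
                id=t.id,
                centroid=(float(cx), float(cy)),
                contour=_circle(cx, cy, r),
                bbox=((float(cx - r), float(cy - r)), (float(cx + r), float(cy + r))),
                type_label=str(label),
                prob=prob,
            )
        )
    pset = PredictionSet(
        model_id=profile.model_id,
        vocabulary=profile.vocabulary(),
        nuclei=nuclei,
    )
    pset.validate()
    return pset


def generate_pair(
    config: SyntheticConfig,
) -> tuple[TruthField, PredictionSet, PredictionSet, dict]:
    """Generate a truth field and both model views, with expected statistics.

    The expected statistics are computed by construction from the realized
    detections: which truth nuclei each model saw, how many were seen by
    both with agreeing post-confusion labels (the merged count in the
    small-jitter limit), and the truth category proportions.
    """
    config.validate()
    ss = np.random.SeedSequence(config.random_seed)
    s_truth, s1, s2 = [int(s) for s in ss.generate_state(3) >> np.uint32(1)]
    truth = generate_truth(config, seed=s_truth)
    m1 = degrade_to_model_view(truth, config.profile_m1, seed=s1)
    m2 = degrade_to_model_view(truth, config.profile_m2, seed=s2)

    schema = TypeSchema.default()
    ids1 = {n.id: n for n in m1.nuclei}
    ids2 = {n.id: n for n in m2.nuclei}
    both = set(ids1) & set(ids2)
    matching = sum(
        1
        for tid in both
        if schema.types_match(
            ids1[tid].type_label, m1.model_id,
            ids2[tid].type_label, m2.model_id,
        )
    )
    total = len(truth)
    expected = {
        "n_truth": total,
        "n_detected_m1": len(m1),
        "n_detected_m2": len(m2),
        "n_detected_both": len(both),
        "n_detected_either": len(set(ids1) | set(ids2)),
        "expected_merged_small_jitter": matching,
        "truth_counts": truth.counts(),
        "truth_proportions": {
            c: n / total for c, n in truth.counts().items()
        } if total else {},
    }
    return truth, m1, m2, expected
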
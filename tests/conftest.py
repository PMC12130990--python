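import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nucmerge import Nucleus, PredictionSet, TypeSchema
from nucmerge.schema import MONUSAC_LABELS, PANNUKE_LABELS

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def schema() -> TypeSchema:
    return TypeSchema.default()


def make_nucleus(
    nid: str,
    centroid: tuple[float, float],
    type_label: str,
    prob: float,
    radius: float = 3.0,
) -> Nucleus:
    """A minimal valid nucleus: triangle contour around the centroid."""
    x, y = centroid
    contour = [(x - radius, y - radius), (x + radius, y - radius), (x, y + radius)]
    return Nucleus(
        id=nid,
        centroid=(float(x), float(y)),
        contour=contour,
        bbox=((x - radius, y - radius), (x + radius, y + radius)),
        type_label=type_label,
        prob=float(prob),
    )


def random_prediction_set(
    rng: np.random.Generator,
    model_id: str,
    n: int,
    span: float = 300.0,
) -> PredictionSet:
    """Random but valid prediction set in the default vocabularies."""
    labels = sorted(MONUSAC_LABELS if model_id == "monusac" else PANNUKE_LABELS)
    nuclei = [
        make_nucleus(
            f"{model_id[0]}{i}",
            (float(rng.uniform(0, span)), float(rng.uniform(0, span))),
            labels[int(rng.integers(len(labels)))],
            float(rng.uniform(0, 1)),
        )
        for i in range(n)
    ]
    pset = PredictionSet(model_id=model_id, vocabulary=set(labels), nuclei=nuclei)
    pset.validate()
    return pset


def results_equal(a, b) -> bool:
    """Field-for-field equality of two merge results."""
    return (
        a.model1_id == b.model1_id
        and a.model2_id == b.model2_id
        and a.merged == b.merged
        and a.m1_matched == b.m1_matched
        and a.m2_matched == b.m2_matched
        and a.equivocal == b.equivocal
        and a.dropped_m2 == b.dropped_m2
    )
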
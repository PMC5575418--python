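import pytest

from prolight.instruments import QuestionnaireRecord, default_scales
from prolight.norms import load_default_norms, load_thresholds
from prolight.report import load_narratives


@pytest.fixture(scope="session")
def scales():
    return default_scales()


@pytest.fixture(scope="session")
def norms():
    return load_default_norms()


@pytest.fixture(scope="session")
def thresholds():
    return load_thresholds()


@pytest.fixture(scope="session")
def narratives():
    return load_narratives()


def make_record(scale, values, patient_id="p1"):
    """Record answering one scale's items with `values` (None = missing)."""
    return QuestionnaireRecord(
        patient_id, dict(zip(scale.item_ids, values)))


@pytest.fixture(scope="session")
def favorable_record(scales):
    """Full battery answered at the favorable extreme of every scale."""
    responses = {}
    for scale in scales.values():
        if scale.instrument == "HADS":
            best = scale.response_min
        elif scale.transform == "eortc_functioning":
            best = scale.response_min  # 1 = no trouble
        elif scale.transform == "eortc_global":
            best = scale.response_max  # 7 = excellent health
        else:
            best = scale.response_min  # symptom: 1 = not at all
        for item in scale.items:
            responses[item.item_id] = best
    return QuestionnaireRecord("best", responses)
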
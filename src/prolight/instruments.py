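"""Questionnaire instruments and scale scoring.

Defines the EORTC QLQ-C30 scales fed back to patients (physical, emotional,
cognitive and social functioning, global health status/QoL, fatigue) plus a
single-item neuropathy symptom (tingling in hands or feet), and the two HADS
subscales (anxiety, depression).

Scoring follows the instruments' published conventions:

* EORTC scales: raw score = mean of the answered items (scored if at least
  half the items are answered — the "half rule"), then a linear transform to
  0-100.  Functioning scales and the global scale are oriented so that higher
  means better functioning; symptom scales so that higher means more symptoms.
* HADS subscales: sum of the 7 items (0-3 each), range 0-21, higher = more
  anxiety/depressive symptoms.  If exactly one item is missing the sum is
  prorated to 7 items; with more than one missing the score is not computed.

Item coding is explicit in the scale registry (EORTC items 1-4, global items
1-7, HADS items 0-3) so alternative renderings of the response categories can
be configured.  Note that questionnaires are sometimes described with verbal
anchors "0 (not at all) to 4 (very much)"; the 0-100 transform below assumes
the published 1-4 coding, and the registry is the single source of truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

import yaml

__all__ = [
    "ItemDefinition",
    "ScaleDefinition",
    "QuestionnaireRecord",
    "ScaleScore",
    "ScoringError",
    "ResponseRangeError",
    "UnknownItemError",
    "load_scale_registry",
    "default_scales",
    "raw_score",
    "transform_score",
    "score_hads",
    "score_scale",
    "score_all",
]

EORTC = "EORTC"
HADS = "HADS"

HIGHER_IS_BETTER = "higher_is_better"
HIGHER_IS_WORSE = "higher_is_worse"

TRANSFORMS = ("eortc_functioning", "eortc_symptom", "eortc_global", "hads_sum")


class ScoringError(ValueError):
    """Base class for scoring configuration/validation errors."""


class ResponseRangeError(ScoringError):
    """A response value lies outside its item's permitted range."""

    def __init__(self, patient_id: str, item_id: str, value: float,
                 lo: int, hi: int):
        self.patient_id = patient_id
        self.item_id = item_id
        self.value = value
        super().__init__(
            f"patient {patient_id!r}: response {value!r} for item {item_id!r} "
            f"outside permitted range [{lo}, {hi}]"
        )


class UnknownItemError(ScoringError):
    """A scale references an item that the record does not define."""


@dataclass(frozen=True)
class ItemDefinition:
    item_id: str
    response_min: int
    response_max: int

    def __post_init__(self):
        if self.response_min >= self.response_max:
            raise ScoringError(
                f"item {self.item_id!r}: response_min must be < response_max"
            )


@dataclass(frozen=True)
class ScaleDefinition:
    """One scored scale: its items, orientation and transform.

    ``score_min``/``score_max`` give the reporting range (0-100 for EORTC,
    0-21 for HADS).  ``min_answered_fraction`` implements the EORTC half
    rule; ``hads_max_missing`` the HADS proration rule.  Both are exposed so
    a deployment can tighten or relax the missing-data policy.
    """

    scale_id: str
    instrument: str
    items: tuple[ItemDefinition, ...]
    polarity: str
    transform: str
    score_min: float
    score_max: float
    min_answered_fraction: float = 0.5
    hads_max_missing: int = 1

    def __post_init__(self):
        if self.instrument not in (EORTC, HADS):
            raise ScoringError(f"unknown instrument {self.instrument!r}")
        if self.polarity not in (HIGHER_IS_BETTER, HIGHER_IS_WORSE):
            raise ScoringError(f"unknown polarity {self.polarity!r}")
        if self.transform not in TRANSFORMS:
            raise ScoringError(f"unknown transform {self.transform!r}")
        if not self.items:
            raise ScoringError(f"scale {self.scale_id!r} has no items")
        mins = {it.response_min for it in self.items}
        maxs = {it.response_max for it in self.items}
        if len(mins) != 1 or len(maxs) != 1:
            raise ScoringError(
                f"scale {self.scale_id!r}: items must share one response range"
            )
        if self.instrument == HADS and len(self.items) != 7:
            raise ScoringError(
                f"HADS subscale {self.scale_id!r} must have exactly 7 items"
            )

    @property
    def response_min(self) -> int:
        return self.items[0].response_min

    @property
    def response_max(self) -> int:
        return self.items[0].response_max

    @property
    def response_range(self) -> int:
        return self.response_max - self.response_min

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for it in self.items)


@dataclass(frozen=True)
class QuestionnaireRecord:
    """One patient's item-level answers; ``None`` marks a missing response."""

    patient_id: str
    responses: Mapping[str, Optional[int]]


@dataclass(frozen=True)
class ScaleScore:
    patient_id: str
    scale_id: str
    value: Optional[float]
    n_items_total: int
    n_items_answered: int


def _answered(record: QuestionnaireRecord,
              scale: ScaleDefinition) -> list[float]:
    """Collect the non-missing responses for ``scale``, validating ranges."""
    out = []
    for item in scale.items:
        if item.item_id not in record.responses:
            raise UnknownItemError(
                f"patient {record.patient_id!r}: record has no entry for item "
                f"{item.item_id!r} of scale {scale.scale_id!r}"
            )
        v = record.responses[item.item_id]
        if v is None or (isinstance(v, float) and math.isnan(v)):
            continue
        if not (item.response_min <= v <= item.response_max):
            raise ResponseRangeError(record.patient_id, item.item_id, v,
                                     item.response_min, item.response_max)
        out.append(float(v))
    return out


def raw_score(record: QuestionnaireRecord,
              scale: ScaleDefinition) -> Optional[float]:
    """Mean of the answered items, or ``None`` if the completeness rule fails.

    EORTC: at least ``min_answered_fraction`` (default half) of the items
    must be answered.  HADS: at most ``hads_max_missing`` (default 1) of the
    7 items may be missing.
    """
    answered = _answered(record, scale)
    n_total = len(scale.items)
    n_ans = len(answered)
    if scale.instrument == HADS:
        if n_total - n_ans > scale.hads_max_missing:
            return None
    else:
        if n_ans < scale.min_answered_fraction * n_total:
            return None
    if n_ans == 0:
        return None
    return sum(answered) / n_ans


def transform_score(raw: float, scale: ScaleDefinition) -> float:
    """Linear 0-100 transform of an EORTC raw (mean-item) score.

    Functioning scales: S = (1 - (raw - min)/range) * 100, so the favorable
    extreme maps to 100.  Symptom scales and the global scale:
    S = ((raw - min)/range) * 100; for the global scale the item range is 6
    (items coded 1-7).
    """
    if scale.transform == "hads_sum":
        raise ScoringError("transform_score applies to EORTC scales only")
    lo, rng = scale.response_min, scale.response_range
    if not (lo <= raw <= scale.response_max):
        raise ScoringError(
            f"raw score {raw} outside item range [{lo}, {scale.response_max}] "
            f"for scale {scale.scale_id!r}"
        )
    frac = (raw - lo) / rng
    if scale.transform == "eortc_functioning":
        return (1.0 - frac) * 100.0
    # eortc_symptom and eortc_global share the same orientation
    return frac * 100.0


def score_hads(record: QuestionnaireRecord,
               scale: ScaleDefinition) -> ScaleScore:
    """Sum the 7 HADS items (prorating a single missing item) into 0-21."""
    if scale.instrument != HADS:
        raise ScoringError(f"scale {scale.scale_id!r} is not a HADS subscale")
    answered = _answered(record, scale)
    mean = raw_score(record, scale)
    value = None if mean is None else mean * len(scale.items)
    return ScaleScore(record.patient_id, scale.scale_id, value,
                      len(scale.items), len(answered))


def score_scale(record: QuestionnaireRecord,
                scale: ScaleDefinition) -> ScaleScore:
    """Score one scale, dispatching on its transform."""
    if scale.instrument == HADS:
        return score_hads(record, scale)
    answered = _answered(record, scale)
    raw = raw_score(record, scale)
    value = None if raw is None else transform_score(raw, scale)
    return ScaleScore(record.patient_id, scale.scale_id, value,
                      len(scale.items), len(answered))


def score_all(record: QuestionnaireRecord,
              scales: Sequence[ScaleDefinition]) -> list[ScaleScore]:
    """Score every scale in ``scales`` for one record (deterministic order)."""
    return [score_scale(record, scale) for scale in scales]


def _parse_scale(entry: dict) -> ScaleDefinition:
    lo, hi = int(entry["response_min"]), int(entry["response_max"])
    items = tuple(ItemDefinition(str(i), lo, hi) for i in entry["items"])
    return ScaleDefinition(
        scale_id=entry["scale_id"],
        instrument=entry["instrument"],
        items=items,
        polarity=entry["polarity"],
        transform=entry["transform"],
        score_min=float(entry["score_min"]),
        score_max=float(entry["score_max"]),
        min_answered_fraction=float(entry.get("min_answered_fraction", 0.5)),
        hads_max_missing=int(entry.get("hads_max_missing", 1)),
    )


def load_scale_registry(path: Optional[str] = None) -> dict[str, ScaleDefinition]:
    """Load scale definitions from YAML; packaged registry when no path given.

    The registry is user-extensible: any file with the same layout can add
    scales (for example the remaining QLQ-C30 symptom scales).
    """
    if path is None:
        text = (resources.files("prolight.data") / "scales.yaml").read_text()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    scales = {}
    for entry in doc["scales"]:
        scale = _parse_scale(entry)
        if scale.scale_id in scales:
            raise ScoringError(f"duplicate scale id {scale.scale_id!r}")
        scales[scale.scale_id] = scale
    return scales


def default_scales() -> dict[str, ScaleDefinition]:
    """The packaged scale battery (cached per call; cheap to reload)."""
    return load_scale_registry()
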
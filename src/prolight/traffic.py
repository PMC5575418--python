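"""Traffic-light classification of scale scores.

A score is compared with an age- and sex-matched reference mean ``m`` using
the minimal medium clinically relevant difference ``d`` as band half-width:

* within ``d`` of the mean (|score - m| < d): average -> amber;
* at least ``d`` better than the mean: above average -> green;
* at least ``d`` worse than the mean: below average -> red.

Scores exactly at ``m +/- d`` take the extreme color ("as much as or more
than"); the amber band is open at both ends.  "Better" follows the scale's
polarity: higher scores are better on functioning/global scales and worse on
symptom scales.

HADS anxiety/depression scores are instead classified on the published
absolute cutoffs: 0-7 no or mild symptoms (green), 8-10 moderate (amber),
>= 11 severe (red), independent of any comparator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

from .instruments import HIGHER_IS_BETTER, HIGHER_IS_WORSE, HADS, ScaleDefinition

__all__ = [
    "GREEN", "AMBER", "RED", "COLORS",
    "Segment", "TrafficLightResult",
    "classify_vs_norm", "classify_hads",
    "gp_advice_flag", "color_counts", "result_to_json",
]

GREEN = "green"
AMBER = "amber"
RED = "red"
COLORS = (RED, AMBER, GREEN)

HADS_CUTOFFS = ((0, 7, GREEN), (8, 10, AMBER), (11, 21, RED))


@dataclass(frozen=True)
class Segment:
    """One colored interval of the score axis.

    ``open_lo``/``open_hi`` record whether the endpoint is excluded; the
    amber band is open where it meets ``m +/- d`` (those boundary scores take
    the extreme color) and closed where clipped by the scale range.
    """

    lo: float
    hi: float
    color: str
    open_lo: bool = False
    open_hi: bool = False

    def contains(self, x: float) -> bool:
        if x < self.lo or x > self.hi:
            return False
        if x == self.lo and self.open_lo:
            return False
        if x == self.hi and self.open_hi:
            return False
        return True


@dataclass(frozen=True)
class TrafficLightResult:
    """Color category for one score vs one comparator, plus chart geometry.

    ``boundaries`` lists the colored segments in axis order; together they
    tile the scale's score range (each score belongs to exactly one segment),
    and segments the scale range clips away entirely are dropped.
    """

    color: str
    comparator: Optional[str]
    boundaries: tuple[Segment, ...]
    patient_value: float
    gp_advice: bool = False


def classify_vs_norm(score: float, norm_mean: float, d: float,
                     polarity: str,
                     score_range: tuple[float, float] = (0.0, 100.0),
                     comparator: Optional[str] = None) -> TrafficLightResult:
    """Classify ``score`` against a reference mean with band half-width ``d``."""
    if d <= 0:
        raise ValueError(f"clinically relevant difference d must be > 0, got {d}")
    if polarity not in (HIGHER_IS_BETTER, HIGHER_IS_WORSE):
        raise ValueError(f"unknown polarity {polarity!r}")
    smin, smax = score_range
    if not (smin <= score <= smax):
        raise ValueError(f"score {score} outside scale range [{smin}, {smax}]")

    diff = score - norm_mean
    if abs(diff) < d:
        color = AMBER
    elif (diff > 0) == (polarity == HIGHER_IS_BETTER):
        color = GREEN
    else:
        color = RED

    low_color, high_color = (
        (RED, GREEN) if polarity == HIGHER_IS_BETTER else (GREEN, RED)
    )
    lo_cut, hi_cut = norm_mean - d, norm_mean + d
    segments = []
    # conceptual partition of the axis: (-inf, m-d] / (m-d, m+d) / [m+d, inf),
    # intersected with the scale range [smin, smax]
    if lo_cut >= smin:
        segments.append(Segment(smin, min(lo_cut, smax), low_color))
    if lo_cut < smax and hi_cut > smin:
        a_lo, a_hi = max(lo_cut, smin), min(hi_cut, smax)
        segments.append(Segment(a_lo, a_hi, AMBER,
                                open_lo=lo_cut >= smin,
                                open_hi=hi_cut <= smax))
    if hi_cut <= smax:
        segments.append(Segment(max(hi_cut, smin), smax, high_color))
    return TrafficLightResult(color=color, comparator=comparator,
                              boundaries=tuple(segments),
                              patient_value=float(score))


def classify_hads(score: float) -> TrafficLightResult:
    """Classify a HADS subscale score (0-21) on the absolute cutoffs."""
    if score != int(score) or not (0 <= score <= 21):
        raise ValueError(f"HADS score must be an integer in [0, 21], got {score}")
    score = int(score)
    color = next(col for lo, hi, col in HADS_CUTOFFS if lo <= score <= hi)
    segments = tuple(Segment(float(lo), float(hi), col)
                     for lo, hi, col in HADS_CUTOFFS)
    return TrafficLightResult(color=color, comparator=None,
                              boundaries=segments, patient_value=float(score))


def gp_advice_flag(result: TrafficLightResult, scale: ScaleDefinition,
                   advise_functioning: bool = False) -> bool:
    """Whether to advise contacting the general practitioner.

    Default policy: only a red *symptom* score (EORTC symptom scales and the
    HADS subscales) triggers the advice.  ``advise_functioning=True`` extends
    it to red functioning/global scores as well.
    """
    if result.color != RED:
        return False
    symptomatic = scale.polarity == HIGHER_IS_WORSE or scale.instrument == HADS
    return symptomatic or advise_functioning


def color_counts(results: Sequence[TrafficLightResult]) -> dict:
    """Tabulate colors as counts and percentages (red/amber/green rows)."""
    n = len(results)
    counts = {c: 0 for c in COLORS}
    for r in results:
        counts[r.color] += 1
    pct = {c: (100.0 * counts[c] / n if n else 0.0) for c in COLORS}
    return {"n": n, "counts": counts, "percent": pct}


def result_to_json(result: TrafficLightResult) -> str:
    """Serialize one classification (consumed by the report module)."""
    return json.dumps(asdict(result), sort_keys=True)
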
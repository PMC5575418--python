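"""Per-patient feedback reports: selection flow, bar charts, narrative text.

The feedback flow mirrors the study procedure: the patient first opts in or
out; an opted-in patient picks topics (overall quality of life, four
functioning scales, fatigue, tingling, anxiety, depressive symptoms, or all)
and how to compare (own scores only, versus a lymphoma reference cohort,
versus a general-population normative cohort, or both cohorts).  Feedback is
then generated automatically: no opt-in, no report.

Each topic section shows a horizontal bar chart per comparator — the score
axis painted in traffic-light segments with a dotted line at the patient's
score — plus narrative text: a plain-language scale description, one
interpretation sentence per comparator keyed by the traffic-light color, a
contextual paragraph, and, for red symptom scores, advice to contact the
general practitioner.  When a comparator has no reference norm for a topic
(the packaged table has no general-population tingling norm) the section
degrades to an own-score chart with an explanatory note.

Charts are emitted as self-contained SVG and the whole report as a single
HTML document; a JSON sidecar carries every number for downstream systems.
All rendering is deterministic: identical inputs give byte-identical output.
"""

from __future__ import annotations

import dataclasses
import html
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

import yaml

from . import traffic
from .instruments import HADS, ScaleDefinition, ScaleScore
from .norms import (LYMPHOMA_COHORT, NORMATIVE_POPULATION, NormTable,
                    NormUnavailableError, ThresholdTable, lookup_norm)
from .traffic import (AMBER, GREEN, RED, Segment, TrafficLightResult,
                      classify_hads, classify_vs_norm, gp_advice_flag)

__all__ = [
    "TOPICS", "TOPIC_SCALES", "OWN_ONLY",
    "FeedbackSelection", "ComparatorBlock", "ReportSection", "FeedbackReport",
    "load_narratives", "build_report",
    "render_chart", "render_own_chart", "render_document",
    "report_to_dict", "report_to_json",
]

OWN_ONLY = "own_only"
CHART_COMPARATORS = (LYMPHOMA_COHORT, NORMATIVE_POPULATION)

TOPIC_SCALES = {
    "general_qol": "global_qol",
    "physical": "physical_functioning",
    "emotional": "emotional_functioning",
    "cognitive": "cognitive_functioning",
    "social": "social_functioning",
    "fatigue": "fatigue",
    "tingling": "tingling",
    "anxiety": "hads_anxiety",
    "depressive": "hads_depression",
}
TOPICS = tuple(TOPIC_SCALES)

DEFAULT_STYLE = {
    "colors": {GREEN: "#2ca02c", AMBER: "#ffcc00", RED: "#d62728"},
    "own_bar": "#d9d9d9",
    "patient_line": "#7b2d8b",  # purple, dotted, per the adopted design
    "width": 420,
    "bar_height": 46,
}


class SelectionError(ValueError):
    """Invalid feedback selection (unknown topic, inconsistent comparators)."""


@dataclass(frozen=True)
class FeedbackSelection:
    """What one patient asked for: opt-in, topics, comparators."""

    patient_id: str
    wants_feedback: bool
    topics: tuple[str, ...] = ()
    comparators: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.wants_feedback:
            if self.topics or self.comparators:
                raise SelectionError(
                    "a patient who declines feedback selects no topics "
                    "or comparators"
                )
            return
        topics = self.topics
        if topics == ("all",) or topics == "all":
            object.__setattr__(self, "topics", TOPICS)
            topics = TOPICS
        unknown = set(topics) - set(TOPICS)
        if unknown:
            raise SelectionError(f"unknown topic(s): {sorted(unknown)}")
        allowed = {OWN_ONLY, *CHART_COMPARATORS}
        unknown = set(self.comparators) - allowed
        if unknown:
            raise SelectionError(f"unknown comparator(s): {sorted(unknown)}")
        if OWN_ONLY in self.comparators and len(self.comparators) > 1:
            raise SelectionError("own_only excludes cohort comparators")


@dataclass(frozen=True)
class ComparatorBlock:
    comparator: Optional[str]
    result: Optional[TrafficLightResult]
    note: Optional[str] = None  # set when the comparison is unavailable


@dataclass(frozen=True)
class ReportSection:
    topic: str
    scale_id: str
    score: Optional[float]
    comparisons: tuple[ComparatorBlock, ...]
    own_chart: bool
    narrative: tuple[str, ...]
    gp_advice: bool


@dataclass(frozen=True)
class FeedbackReport:
    patient_id: str
    generated: bool
    sections: tuple[ReportSection, ...] = ()


def load_narratives(path: Optional[str] = None) -> dict:
    """Narrative text registry (packaged English strings; localizable)."""
    if path is None:
        text = (resources.files("prolight.data") / "narratives.yaml").read_text()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    return yaml.safe_load(text)


def _interpretation(texts: dict, scale: ScaleDefinition, comparator: str,
                    color: str) -> str:
    """Interpretation sentence: a pure function of (scale, comparator, color)."""
    family = "hads" if scale.instrument == HADS else scale.polarity
    template = texts["interpretation"][family][color]
    return template.format(comparator=texts["comparator_names"][comparator])


def build_report(scores: Sequence[ScaleScore], selection: FeedbackSelection,
                 norms: NormTable, thresholds: ThresholdTable,
                 scales: Mapping[str, ScaleDefinition], *,
                 sex: str = "pooled", age: float = 18.0,
                 texts: Optional[dict] = None,
                 advise_functioning: bool = False) -> FeedbackReport:
    """Assemble the feedback document for one patient.

    ``sex``/``age`` locate the patient's reference cell.  Selected topics
    whose score could not be computed (missing-data rule) get a section with
    an explanatory note.  HADS topics are classified on the absolute
    cutoffs, one chart regardless of the chosen cohorts.
    """
    if not selection.wants_feedback:
        return FeedbackReport(selection.patient_id, generated=False)
    texts = texts if texts is not None else load_narratives()
    by_scale = {s.scale_id: s for s in scores}

    sections = []
    for topic in selection.topics:
        scale = scales[TOPIC_SCALES[topic]]
        entry = by_scale.get(scale.scale_id)
        value = entry.value if entry is not None else None
        scale_texts = texts["scales"][topic]
        narrative = [scale_texts["description"]]
        comparisons: list[ComparatorBlock] = []
        own_chart = OWN_ONLY in selection.comparators
        gp = False

        if value is None:
            narrative.append(texts["messages"]["not_computable"])
            sections.append(ReportSection(topic, scale.scale_id, None, (),
                                          own_chart=False,
                                          narrative=tuple(narrative),
                                          gp_advice=False))
            continue

        if scale.instrument == HADS and not own_chart:
            result = classify_hads(value)
            result = dataclasses.replace(
                result, gp_advice=gp_advice_flag(result, scale,
                                                 advise_functioning))
            gp = result.gp_advice
            comparisons.append(ComparatorBlock(None, result))
            narrative.append(
                texts["interpretation"]["hads"][result.color].format(
                    comparator=texts["comparator_names"]["absolute"]))
        elif not own_chart:
            for comparator in CHART_COMPARATORS:
                if comparator not in selection.comparators:
                    continue
                try:
                    cell = lookup_norm(norms, comparator, scale.scale_id,
                                       sex, age)
                except NormUnavailableError:
                    comparisons.append(ComparatorBlock(
                        comparator, None,
                        note=texts["messages"]["unavailable"].format(
                            comparator=texts["comparator_names"][comparator])))
                    narrative.append(
                        texts["messages"]["unavailable"].format(
                            comparator=texts["comparator_names"][comparator]))
                    continue
                result = classify_vs_norm(
                    value, cell.mean, thresholds.d(scale.scale_id),
                    scale.polarity, (scale.score_min, scale.score_max),
                    comparator=comparator)
                result = dataclasses.replace(
                    result, gp_advice=gp_advice_flag(result, scale,
                                                     advise_functioning))
                gp = gp or result.gp_advice
                comparisons.append(ComparatorBlock(comparator, result))
                narrative.append(_interpretation(texts, scale, comparator,
                                                 result.color))
            if comparisons and all(b.result is None for b in comparisons):
                own_chart = True  # every comparison unavailable: own chart

        narrative.append(scale_texts["context"])
        if gp:
            narrative.append(texts["messages"]["gp_advice"])
        sections.append(ReportSection(topic, scale.scale_id, float(value),
                                      tuple(comparisons), own_chart,
                                      tuple(narrative), gp))
    return FeedbackReport(selection.patient_id, generated=True,
                          sections=tuple(sections))


# ---------------------------------------------------------------------------
# rendering

def _fmt(x: float) -> str:
    return f"{x:.2f}".rstrip("0").rstrip(".")


def _svg_header(width: int, height: int) -> str:
    return (f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
            f'height="{height}" viewBox="0 0 {width} {height}">')


def _draw_bar(segments: Sequence[tuple[float, float, str]],
              lo: float, hi: float, patient: Optional[float],
              style: dict) -> str:
    """Shared bar renderer: colored rectangles plus the dotted score line."""
    width, bh = style["width"], style["bar_height"]
    pad, top = 10, 8
    span = hi - lo

    def x(v: float) -> float:
        return pad + (v - lo) / span * (width - 2 * pad)

    parts = [_svg_header(width, bh + top + 26)]
    for seg_lo, seg_hi, color in segments:
        parts.append(
            f'<rect x="{_fmt(x(seg_lo))}" y="{top}" '
            f'width="{_fmt(x(seg_hi) - x(seg_lo))}" height="{bh}" '
            f'fill="{color}" stroke="none"/>'
        )
    if patient is not None:
        px = _fmt(x(patient))
        parts.append(
            f'<line x1="{px}" y1="2" x2="{px}" y2="{bh + top + 4}" '
            f'stroke="{style["patient_line"]}" stroke-width="3" '
            f'stroke-dasharray="4,3"/>'
        )
    parts.append(f'<text x="{pad}" y="{bh + top + 20}" font-size="12">'
                 f'{_fmt(lo)}</text>')
    parts.append(f'<text x="{width - pad}" y="{bh + top + 20}" '
                 f'font-size="12" text-anchor="end">{_fmt(hi)}</text>')
    parts.append("</svg>")
    return "".join(parts)


def render_chart(result: TrafficLightResult,
                 style: Optional[dict] = None) -> str:
    """Traffic-light bar chart for one classification, as an SVG string.

    Colored rectangles follow ``result.boundaries`` in order and extent on
    the score axis; the patient's score is a dotted vertical line.  Adjacent
    integer bands (the HADS 0-7/8-10/>=11 cutoffs) are drawn meeting at the
    half-integer between them so the bar has no gaps.
    """
    style = {**DEFAULT_STYLE, **(style or {})}
    segs = result.boundaries
    lo, hi = segs[0].lo, segs[-1].hi
    drawn = []
    for i, seg in enumerate(segs):
        start = seg.lo if i == 0 else drawn[-1][1]
        end = seg.hi if i == len(segs) - 1 else (seg.hi + segs[i + 1].lo) / 2.0
        drawn.append((start, end, style["colors"][seg.color]))
    return _draw_bar(drawn, lo, hi, result.patient_value, style)


def render_own_chart(score: float, score_range: tuple[float, float],
                     style: Optional[dict] = None) -> str:
    """Uncolored own-score bar: neutral axis plus the dotted score line."""
    style = {**DEFAULT_STYLE, **(style or {})}
    lo, hi = score_range
    return _draw_bar([(lo, hi, style["own_bar"])], lo, hi, score, style)


def render_document(report: FeedbackReport, scales: Mapping[str, ScaleDefinition],
                    style: Optional[dict] = None,
                    texts: Optional[dict] = None) -> str:
    """Self-contained HTML document for a generated report."""
    if not report.generated:
        raise ValueError("cannot render a report that was not generated")
    texts = texts if texts is not None else load_narratives()
    style = {**DEFAULT_STYLE, **(style or {})}
    out = ['<!DOCTYPE html><html><head><meta charset="utf-8">',
           f'<title>{texts["document"]["title"]} — '
           f'{html.escape(report.patient_id)}</title></head><body>',
           f'<h1>{texts["document"]["title"]}</h1>',
           f'<p>{texts["document"]["intro"]}</p>']
    for sec in report.sections:
        scale = scales[sec.scale_id]
        title = texts["scales"][sec.topic]["name"]
        out.append(f'<h2>{html.escape(title)}</h2>')
        if sec.score is not None:
            out.append(f'<p>{texts["document"]["your_score"]} '
                       f'<b>{sec.score:.1f}</b> '
                       f'({_fmt(scale.score_min)}&ndash;{_fmt(scale.score_max)})'
                       f'</p>')
        for block in sec.comparisons:
            if block.result is not None:
                if block.comparator is not None:
                    cname = texts["comparator_names"][block.comparator]
                    out.append(f'<h3>{html.escape(cname)}</h3>')
                out.append(render_chart(block.result, style))
            elif block.note:
                out.append(f'<p><i>{html.escape(block.note)}</i></p>')
        if sec.own_chart and sec.score is not None:
            out.append(render_own_chart(
                sec.score, (scale.score_min, scale.score_max), style))
        for para in sec.narrative:
            out.append(f'<p>{html.escape(para)}</p>')
        if sec.gp_advice:
            out.append(f'<p class="gp-advice"><b>'
                       f'{html.escape(texts["messages"]["gp_advice"])}</b></p>')
    out.append("</body></html>")
    return "".join(out)


def report_to_dict(report: FeedbackReport) -> dict:
    """All numeric report content as plain data (JSON sidecar)."""
    return dataclasses.asdict(report)


def report_to_json(report: FeedbackReport) -> str:
    return json.dumps(report_to_dict(report), sort_keys=True, indent=1)
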
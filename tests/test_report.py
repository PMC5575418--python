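"""Feedback flow, narrative selection, chart and document rendering."""

import pytest

from prolight.instruments import ScaleScore
from prolight.report import (TOPIC_SCALES, TOPICS, ComparatorBlock,
                             FeedbackSelection, SelectionError, build_report,
                             render_chart, render_document, render_own_chart,
                             report_to_json)
from prolight.traffic import AMBER, GREEN, RED, classify_hads, classify_vs_norm


def scores_for(scales, patient="p1", **values):
    return [ScaleScore(patient, sid, v, len(scales[sid].items),
                       len(scales[sid].items)) for sid, v in values.items()]


class TestSelection:
    def test_decline_means_empty_selection(self):
        sel = FeedbackSelection("p1", wants_feedback=False)
        assert sel.topics == () and sel.comparators == ()

    def test_decline_with_topics_is_invalid(self):
        with pytest.raises(SelectionError):
            FeedbackSelection("p1", False, topics=("fatigue",))

    def test_all_expands_to_every_topic(self):
        sel = FeedbackSelection("p1", True, topics=("all",),
                                comparators=("lymphoma_cohort",))
        assert sel.topics == TOPICS

    def test_own_only_excludes_cohorts(self):
        with pytest.raises(SelectionError):
            FeedbackSelection("p1", True, topics=("fatigue",),
                              comparators=("own_only", "lymphoma_cohort"))

    def test_unknown_topic_rejected(self):
        with pytest.raises(SelectionError):
            FeedbackSelection("p1", True, topics=("sleep",),
                              comparators=("lymphoma_cohort",))


class TestBuildReport:
    def test_no_optin_no_report(self, scales, norms, thresholds):
        sel = FeedbackSelection("p1", wants_feedback=False)
        rep = build_report([], sel, norms, thresholds, scales)
        assert rep.generated is False and rep.sections == ()

    def test_cognitive_amber_vs_cohort_red_vs_population(self, scales, norms,
                                                         thresholds):
        # score 75: within d=10 of the lymphoma mean 82.4 (amber) but more
        # than 10 below the population mean 92.5 (red)
        sel = FeedbackSelection("p1", True, topics=("cognitive",),
                                comparators=("lymphoma_cohort",
                                             "normative_population"))
        rep = build_report(
            scores_for(scales, cognitive_functioning=75.0), sel, norms,
            thresholds, scales, sex="female", age=40)
        (section,) = rep.sections
        colors = [b.result.color for b in section.comparisons]
        assert colors == [AMBER, RED]
        text = " ".join(section.narrative)
        assert "similar to that of other people with lymphoma" in text
        assert ("lower than the average score of people from the general "
                "population") in text

    def test_all_topics_yield_nine_sections(self, scales, norms, thresholds):
        sel = FeedbackSelection("p1", True, topics=("all",),
                                comparators=("lymphoma_cohort",))
        values = {sid: 50.0 if scales[sid].score_max == 100 else 5.0
                  for sid in TOPIC_SCALES.values()}
        rep = build_report(scores_for(scales, **values), sel, norms,
                           thresholds, scales, sex="male", age=60)
        assert len(rep.sections) == 9

    def test_charts_per_section_one_or_two(self, scales, norms, thresholds):
        sel = FeedbackSelection("p1", True, topics=("all",),
                                comparators=("lymphoma_cohort",
                                             "normative_population"))
        values = {sid: 50.0 if scales[sid].score_max == 100 else 5.0
                  for sid in TOPIC_SCALES.values()}
        rep = build_report(scores_for(scales, **values), sel, norms,
                           thresholds, scales, sex="male", age=60)
        for sec in rep.sections:
            n_charts = sum(1 for b in sec.comparisons if b.result is not None)
            n_charts += 1 if sec.own_chart else 0
            assert 1 <= n_charts <= 2, sec.topic

    def test_own_only_yields_single_uncolored_chart(self, scales, norms,
                                                    thresholds):
        sel = FeedbackSelection("p1", True, topics=("fatigue",),
                                comparators=("own_only",))
        rep = build_report(scores_for(scales, fatigue=40.0), sel, norms,
                           thresholds, scales, sex="male", age=60)
        (section,) = rep.sections
        assert section.own_chart is True and section.comparisons == ()

    def test_tingling_vs_population_degrades_with_note(self, scales, norms,
                                                       thresholds):
        sel = FeedbackSelection("p1", True, topics=("tingling",),
                                comparators=("normative_population",))
        rep = build_report(scores_for(scales, tingling=30.0), sel, norms,
                           thresholds, scales, sex="male", age=60)
        (section,) = rep.sections
        assert section.own_chart is True  # every comparison unavailable
        (block,) = section.comparisons
        assert block.result is None and "not available" in block.note

    def test_hads_topic_uses_absolute_cutoffs_one_chart(self, scales, norms,
                                                        thresholds):
        sel = FeedbackSelection("p1", True, topics=("anxiety",),
                                comparators=("lymphoma_cohort",
                                             "normative_population"))
        rep = build_report(scores_for(scales, hads_anxiety=12.0), sel, norms,
                           thresholds, scales, sex="female", age=50)
        (section,) = rep.sections
        (block,) = section.comparisons
        assert block.result.color == RED and block.comparator is None
        assert section.gp_advice is True

    def test_missing_score_gets_explanatory_section(self, scales, norms,
                                                    thresholds):
        sel = FeedbackSelection("p1", True, topics=("fatigue",),
                                comparators=("lymphoma_cohort",))
        scores = [ScaleScore("p1", "fatigue", None, 3, 1)]
        rep = build_report(scores, sel, norms, thresholds, scales,
                           sex="male", age=60)
        (section,) = rep.sections
        assert section.score is None and section.comparisons == ()
        assert any("unanswered" in p for p in section.narrative)

    def test_narrative_agrees_with_color_and_names_comparator(
            self, scales, norms, thresholds, narratives):
        # interpretation sentence is a pure function of (scale, comparator,
        # color): spot-check all colors against the registry strings
        for score, color, keyword in ((95.0, GREEN, "green"),
                                      (80.0, AMBER, "yellow"),
                                      (60.0, RED, "red")):
            sel = FeedbackSelection("p1", True, topics=("cognitive",),
                                    comparators=("lymphoma_cohort",))
            rep = build_report(
                scores_for(scales, cognitive_functioning=score), sel, norms,
                thresholds, scales, sex="male", age=60)
            (section,) = rep.sections
            assert section.comparisons[0].result.color == color
            sentence = section.narrative[1]
            assert keyword in sentence and "lymphoma" in sentence


class TestRendering:
    def test_three_segments_three_rects_one_dotted_line(self):
        r = classify_vs_norm(50.0, 60.0, 8.0, "higher_is_better")
        svg = render_chart(r)
        assert svg.count("<rect") == 3
        assert svg.count("stroke-dasharray") == 1

    def test_clipped_segment_renders_two_rects(self):
        r = classify_vs_norm(80.0, 95.0, 10.0, "higher_is_better")
        svg = render_chart(r)
        assert svg.count("<rect") == 2

    def test_rendering_is_deterministic(self):
        r = classify_hads(9)
        assert render_chart(r) == render_chart(r)
        assert render_own_chart(42.0, (0, 100)) == render_own_chart(42.0, (0, 100))

    def test_hads_bands_meet_at_half_integers(self):
        svg = render_chart(classify_hads(9))
        assert svg.count("<rect") == 3  # contiguous bar, no gaps

    def test_document_requires_generated_report(self, scales):
        from prolight.report import FeedbackReport
        with pytest.raises(ValueError):
            render_document(FeedbackReport("p1", generated=False), scales)

    def test_document_contains_gp_callout_for_red_fatigue(self, scales, norms,
                                                          thresholds):
        sel = FeedbackSelection("p1", True, topics=("fatigue",),
                                comparators=("lymphoma_cohort",))
        rep = build_report(scores_for(scales, fatigue=80.0), sel, norms,
                           thresholds, scales, sex="male", age=60)
        html = render_document(rep, scales)
        assert "general practitioner" in html
        assert html.count("<h2>") == 1

    def test_document_renders_unavailable_note_with_own_chart(
            self, scales, norms, thresholds):
        sel = FeedbackSelection("p1", True, topics=("tingling",),
                                comparators=("normative_population",))
        rep = build_report(scores_for(scales, tingling=30.0), sel, norms,
                           thresholds, scales, sex="male", age=60)
        html = render_document(rep, scales)
        assert "not available" in html and "<svg" in html

    def test_json_sidecar_round_trips_numbers(self, scales, norms, thresholds):
        import json
        sel = FeedbackSelection("p1", True, topics=("cognitive",),
                                comparators=("lymphoma_cohort",))
        rep = build_report(scores_for(scales, cognitive_functioning=75.0),
                           sel, norms, thresholds, scales, sex="male", age=60)
        doc = json.loads(report_to_json(rep))
        assert doc["sections"][0]["score"] == 75.0
        assert doc["sections"][0]["comparisons"][0]["result"]["color"] == AMBER
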
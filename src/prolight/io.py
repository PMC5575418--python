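"""Readers, writers and run configuration for the pipeline.

Conventions: comma-separated UTF-8 CSV with a header row; a missing value is
an empty cell; decimal point (never comma).  Malformed rows are reported
with their 1-based file line number; the partial-failure policy is
configurable (abort, the default, or skip-and-log).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd
import yaml

from .instruments import QuestionnaireRecord, ScaleScore
from .norms import AgeBandScheme, NormTable, read_norms_csv, read_norms_json
from .report import (FeedbackReport, FeedbackSelection, load_narratives,
                     render_chart, render_own_chart, render_document,
                     report_to_json)

logger = logging.getLogger("prolight")

__all__ = [
    "ParseError", "RunConfig", "load_config",
    "read_items_csv", "read_items_wide", "write_items_csv",
    "read_demographics", "write_demographics",
    "read_selections", "write_selections",
    "read_scores", "write_scores", "write_report",
]


class ParseError(ValueError):
    """A file violated its documented schema (carries the line number)."""


def _na(v) -> bool:
    return v is None or (isinstance(v, float) and pd.isna(v)) or v == ""


# ---------------------------------------------------------------------------
# item responses

def read_items_csv(path, *, on_error: str = "abort") -> list[QuestionnaireRecord]:
    """Long-format item responses: columns patient_id, item_id, response."""
    df = pd.read_csv(path, dtype={"patient_id": str, "item_id": str})
    required = {"patient_id", "item_id", "response"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(required)}")
    if len(df) == 0:
        logger.warning("%s: empty items file", path)
    responses: dict[str, dict] = {}
    for idx, row in df.iterrows():
        line = idx + 2
        try:
            pid, item = row["patient_id"], row["item_id"]
            if _na(pid) or _na(item):
                raise ParseError(f"{path} line {line}: empty patient or item id")
            v = row["response"]
            value = None if _na(v) else int(v)
            bucket = responses.setdefault(pid, {})
            if item in bucket:
                raise ParseError(
                    f"{path} line {line}: duplicate response for "
                    f"({pid!r}, {item!r})")
            bucket[item] = value
        except (ParseError, ValueError, TypeError) as exc:
            msg = exc if isinstance(exc, ParseError) else \
                f"{path} line {line}: {exc}"
            if on_error == "skip":
                logger.warning("skipping row: %s", msg)
                continue
            raise ParseError(str(msg)) from None
    return [QuestionnaireRecord(pid, items)
            for pid, items in responses.items()]


def read_items_wide(path) -> list[QuestionnaireRecord]:
    """Wide-format responses: a patient_id column plus one column per item."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    if "patient_id" not in df.columns:
        raise ParseError(f"{path}: missing patient_id column")
    item_cols = [c for c in df.columns if c != "patient_id"]
    records = []
    for idx, row in df.iterrows():
        resp = {}
        for c in item_cols:
            v = row[c]
            try:
                resp[c] = None if _na(v) else int(v)
            except (ValueError, TypeError):
                raise ParseError(
                    f"{path} line {idx + 2}: non-integer response "
                    f"{v!r} for item {c!r}") from None
        records.append(QuestionnaireRecord(row["patient_id"], resp))
    return records


def write_items_csv(records: Sequence[QuestionnaireRecord], path) -> None:
    rows = [{"patient_id": r.patient_id, "item_id": item,
             "response": "" if v is None else v}
            for r in records for item, v in r.responses.items()]
    pd.DataFrame(rows, columns=["patient_id", "item_id", "response"]
                 ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# demographics, selections, scores

def read_demographics(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    required = {"patient_id", "sex", "age"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(required)}")
    bad = df[~df["sex"].isin(["male", "female"])]
    if len(bad):
        raise ParseError(
            f"{path} line {bad.index[0] + 2}: sex must be 'male' or 'female'")
    return df


def write_demographics(patients: pd.DataFrame, path) -> None:
    patients.to_csv(path, index=False)


def read_selections(path) -> list[FeedbackSelection]:
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    return [FeedbackSelection(patient_id=e["patient_id"],
                              wants_feedback=bool(e["wants_feedback"]),
                              topics=tuple(e.get("topics", ())),
                              comparators=tuple(e.get("comparators", ())))
            for e in doc]


def write_selections(selections: Sequence[FeedbackSelection], path) -> None:
    doc = [dataclasses.asdict(s) for s in selections]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)


def read_scores(path) -> list[ScaleScore]:
    df = pd.read_csv(path, dtype={"patient_id": str, "scale_id": str},
                     float_precision="round_trip")
    return [ScaleScore(row.patient_id, row.scale_id,
                       None if pd.isna(row.value) else float(row.value),
                       int(row.n_items_total), int(row.n_items_answered))
            for row in df.itertuples()]


def write_scores(scores: Sequence[ScaleScore], path) -> None:
    rows = [{"patient_id": s.patient_id, "scale_id": s.scale_id,
             "value": "" if s.value is None else repr(float(s.value)),
             "n_items_total": s.n_items_total,
             "n_items_answered": s.n_items_answered} for s in scores]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# report output

def write_report(report: FeedbackReport, out_dir, scales, *,
                 style: Optional[dict] = None,
                 texts: Optional[dict] = None) -> list[str]:
    """Write one patient's HTML document, JSON sidecar and per-chart SVGs.

    Returns the paths written.  A non-generated report produces only the
    JSON sidecar recording that fact.
    """
    os.makedirs(out_dir, exist_ok=True)
    pid = report.patient_id
    written = []
    sidecar = os.path.join(out_dir, f"{pid}.json")
    with open(sidecar, "w", encoding="utf-8") as fh:
        fh.write(report_to_json(report))
    written.append(sidecar)
    if not report.generated:
        return written
    texts = texts if texts is not None else load_narratives()
    html_path = os.path.join(out_dir, f"{pid}.html")
    with open(html_path, "w", encoding="utf-8") as fh:
        fh.write(render_document(report, scales, style=style, texts=texts))
    written.append(html_path)
    for sec in report.sections:
        scale = scales[sec.scale_id]
        for block in sec.comparisons:
            if block.result is None:
                continue
            tag = block.comparator or "cutoffs"
            svg_path = os.path.join(out_dir, f"{pid}_{sec.topic}_{tag}.svg")
            with open(svg_path, "w", encoding="utf-8") as fh:
                fh.write(render_chart(block.result, style))
            written.append(svg_path)
        if sec.own_chart and sec.score is not None:
            svg_path = os.path.join(out_dir, f"{pid}_{sec.topic}_own.svg")
            with open(svg_path, "w", encoding="utf-8") as fh:
                fh.write(render_own_chart(
                    sec.score, (scale.score_min, scale.score_max), style))
            written.append(svg_path)
    return written


# ---------------------------------------------------------------------------
# run configuration

_CONFIG_KEYS = {
    "items", "demographics", "selections", "norms", "thresholds",
    "narratives", "scales", "out_dir", "age_bands", "t_variant",
    "advise_functioning", "decimals", "seed", "strict", "log_level",
}


@dataclass(frozen=True)
class RunConfig:
    """Paths and options for a pipeline run (YAML-loadable)."""

    items: Optional[str] = None
    demographics: Optional[str] = None
    selections: Optional[str] = None
    norms: Optional[str] = None
    thresholds: Optional[str] = None
    narratives: Optional[str] = None
    scales: Optional[str] = None
    out_dir: str = "."
    age_bands: Optional[tuple[tuple[int, Optional[int]], ...]] = None
    t_variant: str = "pooled"
    advise_functioning: bool = False
    decimals: int = 1
    seed: int = 0
    strict: bool = False
    log_level: str = "INFO"

    def age_scheme(self) -> AgeBandScheme:
        if self.age_bands is None:
            return AgeBandScheme()
        return AgeBandScheme(tuple((lo, hi) for lo, hi in self.age_bands))


def load_config(path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    unknown = set(doc) - _CONFIG_KEYS
    if unknown:
        raise ParseError(f"{path}: unknown config key(s) {sorted(unknown)}")
    if "age_bands" in doc and doc["age_bands"] is not None:
        doc["age_bands"] = tuple((int(lo), None if hi is None else int(hi))
                                 for lo, hi in doc["age_bands"])
    cfg = RunConfig(**doc)
    for key in ("items", "demographics", "selections", "norms",
                "thresholds", "narratives", "scales"):
        p = getattr(cfg, key)
        if p is not None and not os.path.exists(p):
            raise ParseError(f"{path}: configured {key} file {p!r} not found")
    return cfg


def read_norms(path, scheme: Optional[AgeBandScheme] = None) -> NormTable:
    """Read a norm table from CSV or JSON, by extension."""
    if str(path).endswith(".json"):
        return read_norms_json(path)
    return read_norms_csv(path, scheme if scheme is not None else AgeBandScheme())
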
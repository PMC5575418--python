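"""Reference norms and clinically-relevant-difference thresholds.

A patient's scale score is interpreted against the mean of a reference cell
matched on sex and age band, for one of two comparators: a lymphoma
reference cohort ("peers") or a general-population normative cohort.  This
module holds those stratified means/SDs (:class:`NormTable`), the age-band
scheme that maps an age in years to a band, and the per-scale
clinically-relevant-difference thresholds (:class:`ThresholdTable`) that set
the traffic-light band half-width.

The packaged fixture table carries published pooled cohort summaries
replicated via a pooled-sex fallback; real deployments supply fully
stratified tables through the same CSV/JSON interface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional

import pandas as pd
import yaml

__all__ = [
    "LYMPHOMA_COHORT",
    "NORMATIVE_POPULATION",
    "AgeBandScheme",
    "NormCell",
    "NormTable",
    "ThresholdTable",
    "NormUnavailableError",
    "NormTableError",
    "assign_age_band",
    "lookup_norm",
    "read_norms_csv",
    "write_norms_csv",
    "read_norms_json",
    "write_norms_json",
    "load_default_norms",
    "load_thresholds",
]

LYMPHOMA_COHORT = "lymphoma_cohort"
NORMATIVE_POPULATION = "normative_population"
COMPARATORS = (LYMPHOMA_COHORT, NORMATIVE_POPULATION)

SEXES = ("male", "female", "pooled")


class NormTableError(ValueError):
    """Invalid norm-table structure (duplicate keys, bad values)."""


class NormUnavailableError(LookupError):
    """No reference cell for the requested key.

    This is defined behavior, not a bug: e.g. the packaged table has no
    general-population norm for the tingling symptom.
    """

    def __init__(self, comparator, scale_id, sex, band):
        self.key = (comparator, scale_id, sex, band)
        super().__init__(
            f"no reference norm for comparator={comparator!r}, "
            f"scale={scale_id!r}, sex={sex!r}, age_band={band!r}"
        )


@dataclass(frozen=True)
class AgeBandScheme:
    """Ordered, contiguous age bands covering adults from 18 up.

    Bands are stored as ``(lower, upper)`` with inclusive integer bounds and
    ``None`` for the open-ended last band.  Non-integer ages between two
    bands' edges (e.g. 30.5) fall in the lower band: membership is evaluated
    as ``lower <= age < next_lower``.
    """

    bands: tuple[tuple[int, Optional[int]], ...] = (
        (18, 30), (31, 45), (46, 60), (61, 75), (76, None),
    )

    def __post_init__(self):
        prev_hi = None
        for i, (lo, hi) in enumerate(self.bands):
            last = i == len(self.bands) - 1
            if prev_hi is not None and lo != prev_hi + 1:
                raise NormTableError("age bands must be contiguous")
            if not last and (hi is None or hi < lo):
                raise NormTableError("only the last band may be open-ended")
            if last and hi is not None:
                raise NormTableError("last band must be open-ended")
            prev_hi = hi
        if self.bands[0][0] != 18:
            raise NormTableError("age bands must start at 18")

    def label(self, index: int) -> str:
        lo, hi = self.bands[index]
        return f"{lo}-{hi}" if hi is not None else f">{lo - 1}"


def assign_age_band(age: float, scheme: AgeBandScheme = AgeBandScheme()) -> int:
    """Index of the band containing ``age``; ages below 18 are a domain error."""
    if age < scheme.bands[0][0]:
        raise ValueError(f"age {age} below the lowest band "
                         f"({scheme.bands[0][0]} years)")
    for i, (lo, hi) in enumerate(scheme.bands):
        nxt = scheme.bands[i + 1][0] if hi is not None else None
        if nxt is None or age < nxt:
            return i
    raise AssertionError("unreachable: last band is open-ended")


@dataclass(frozen=True)
class NormCell:
    comparator: str
    scale_id: str
    sex: str
    age_band: int  # band index; -1 marks an all-ages (pooled-age) cell
    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.comparator not in COMPARATORS:
            raise NormTableError(f"unknown comparator {self.comparator!r}")
        if self.sex not in SEXES:
            raise NormTableError(f"unknown sex {self.sex!r}")
        if self.sd < 0:
            raise NormTableError("sd must be >= 0")
        if self.n < 1:
            raise NormTableError("n must be >= 1")


POOLED_AGE = -1  # sentinel band index: cell applies to every age band


@dataclass
class NormTable:
    """Set of reference cells, keyed (comparator, scale, sex, band)."""

    age_scheme: AgeBandScheme = field(default_factory=AgeBandScheme)
    _cells: dict = field(default_factory=dict)

    def add(self, cell: NormCell) -> None:
        key = (cell.comparator, cell.scale_id, cell.sex, cell.age_band)
        if key in self._cells:
            raise NormTableError(f"duplicate norm cell for key {key}")
        self._cells[key] = cell

    @property
    def cells(self) -> list[NormCell]:
        return list(self._cells.values())

    def get(self, comparator, scale_id, sex, band) -> Optional[NormCell]:
        return self._cells.get((comparator, scale_id, sex, band))


def lookup_norm(table: NormTable, comparator: str, scale_id: str,
                sex: str, age: float, *,
                sex_fallback: bool = True) -> NormCell:
    """Resolve the reference cell for a patient.

    Resolution order: exact (sex, band) cell; then, with ``sex_fallback``,
    the pooled-sex cell for the band; then the corresponding all-ages cells.
    Raises :class:`NormUnavailableError` when nothing matches — callers must
    handle that explicitly (there is no silent default).
    """
    band = assign_age_band(age, table.age_scheme)
    candidates = [(sex, band)]
    if sex_fallback and sex != "pooled":
        candidates.append(("pooled", band))
    candidates.append((sex, POOLED_AGE))
    if sex_fallback and sex != "pooled":
        candidates.append(("pooled", POOLED_AGE))
    for s, b in candidates:
        cell = table.get(comparator, scale_id, s, b)
        if cell is not None:
            return cell
    raise NormUnavailableError(comparator, scale_id, sex, band)


# ---------------------------------------------------------------------------
# serialization

_CSV_COLUMNS = ["comparator", "scale_id", "sex", "age_lo", "age_hi",
                "mean", "sd", "n"]


def _cell_to_row(cell: NormCell, scheme: AgeBandScheme) -> dict:
    if cell.age_band == POOLED_AGE:
        lo, hi = "", ""
    else:
        lo, hi = scheme.bands[cell.age_band]
        hi = "" if hi is None else hi
    return {"comparator": cell.comparator, "scale_id": cell.scale_id,
            "sex": cell.sex, "age_lo": lo, "age_hi": hi,
            "mean": cell.mean, "sd": cell.sd, "n": cell.n}


def _row_to_cell(row: dict, scheme: AgeBandScheme) -> NormCell:
    lo = row.get("age_lo")
    if lo in ("", None) or (isinstance(lo, float) and pd.isna(lo)):
        band = POOLED_AGE
    else:
        band = assign_age_band(float(lo), scheme)
        blo, bhi = scheme.bands[band]
        hi = row.get("age_hi")
        hi_empty = hi in ("", None) or (isinstance(hi, float) and pd.isna(hi))
        if float(lo) != blo or ((bhi is None) != hi_empty) or \
                (not hi_empty and float(hi) != bhi):
            raise NormTableError(
                f"age interval [{lo}, {hi}] does not match a scheme band"
            )
    return NormCell(comparator=str(row["comparator"]),
                    scale_id=str(row["scale_id"]), sex=str(row["sex"]),
                    age_band=band, mean=float(row["mean"]),
                    sd=float(row["sd"]), n=int(row["n"]))


def read_norms_csv(path, scheme: AgeBandScheme = AgeBandScheme()) -> NormTable:
    """Read a norm table from CSV (columns comparator, scale_id, sex,
    age_lo, age_hi, mean, sd, n; empty age columns = all ages)."""
    df = pd.read_csv(path, dtype={"age_lo": "object", "age_hi": "object"},
                     float_precision="round_trip")
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise NormTableError(f"norms CSV missing columns: {sorted(missing)}")
    table = NormTable(age_scheme=scheme)
    for idx, row in df.iterrows():
        try:
            table.add(_row_to_cell(row.to_dict(), scheme))
        except NormTableError as exc:
            raise NormTableError(f"norms CSV row {idx + 2}: {exc}") from exc
    return table


def write_norms_csv(table: NormTable, path) -> None:
    rows = [_cell_to_row(c, table.age_scheme) for c in table.cells]
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def write_norms_json(table: NormTable, path) -> None:
    doc = {
        "age_bands": [[lo, hi] for lo, hi in table.age_scheme.bands],
        "cells": [
            {"comparator": c.comparator, "scale_id": c.scale_id,
             "sex": c.sex, "age_band": c.age_band,
             "mean": c.mean, "sd": c.sd, "n": c.n}
            for c in table.cells
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)


def read_norms_json(path) -> NormTable:
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    scheme = AgeBandScheme(tuple((lo, hi) for lo, hi in doc["age_bands"]))
    table = NormTable(age_scheme=scheme)
    for c in doc["cells"]:
        table.add(NormCell(**c))
    return table


def load_default_norms(scheme: AgeBandScheme = AgeBandScheme()) -> NormTable:
    """The packaged demonstration norm table.

    It holds the published pooled cohort means/SDs for a lymphoma reference
    cohort (n=876) and a general-population normative cohort (n=1852) as
    pooled-sex, all-ages cells; sex/age lookups resolve through the fallback
    chain.  It demonstrates the pipeline — stratified production tables are
    supplied by the user in the same format.  The normative population has
    no tingling norm; that lookup raises :class:`NormUnavailableError`.
    """
    with resources.as_file(resources.files("prolight.data")
                           / "norms_reference.csv") as p:
        return read_norms_csv(p, scheme)


@dataclass(frozen=True)
class ThresholdTable:
    """Per-scale clinically-relevant-difference configuration.

    ``d_medium`` is the minimal medium clinically relevant difference for
    the scale: the half-width of the amber band around the reference mean.
    ``size_class_bounds`` are ordered |difference| cutoffs separating the
    labels no / trivial / small / medium / large used when reporting group
    mean differences.
    """

    d_medium: dict[str, float]
    size_class_bounds: dict[str, tuple[float, ...]] = field(default_factory=dict)

    def __post_init__(self):
        for sid, d in self.d_medium.items():
            if d <= 0:
                raise NormTableError(f"d_medium for {sid!r} must be > 0")
        for sid, bounds in self.size_class_bounds.items():
            if list(bounds) != sorted(bounds) or len(set(bounds)) != len(bounds):
                raise NormTableError(
                    f"size_class_bounds for {sid!r} must be strictly increasing"
                )

    def d(self, scale_id: str) -> float:
        try:
            return self.d_medium[scale_id]
        except KeyError:
            raise NormTableError(
                f"no d_medium configured for scale {scale_id!r}"
            ) from None

    def bounds(self, scale_id: str) -> tuple[float, ...]:
        try:
            return tuple(self.size_class_bounds[scale_id])
        except KeyError:
            raise NormTableError(
                f"no size_class_bounds configured for scale {scale_id!r}"
            ) from None


def load_thresholds(path: Optional[str] = None) -> ThresholdTable:
    """Load a threshold table from YAML (packaged defaults when no path)."""
    if path is None:
        text = (resources.files("prolight.data") / "thresholds.yaml").read_text()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    d_medium = {k: float(v["d_medium"]) for k, v in doc["scales"].items()}
    bounds = {k: tuple(float(x) for x in v["size_class_bounds"])
              for k, v in doc["scales"].items() if "size_class_bounds" in v}
    return ThresholdTable(d_medium=d_medium, size_class_bounds=bounds)
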
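"""Synthetic cohorts: item-level patients, selections, reference microdata.

Every downstream module is testable end to end without patient data.  The
generator draws, per patient and scale, a latent score from a normal
distribution with the configured target mean/SD truncated to the scale's
score range, then constructs item responses whose scored value is the
nearest score the items can realize (the remaining sub-item granularity is
distributed over items by randomized rounding).  Scale-level summary targets
are therefore met by construction, which is exactly what published cohort
tables specify.

Defaults emulate the study conditions: a cohort that is 58% male with mean
age 60.7 (SD 13.6) years, scale targets equal to the published lymphoma
reference cohort summaries, an 80% feedback opt-in rate, per-topic viewing
probabilities from the published topic-uptake table, and comparator-set
probabilities own-only 2/36, lymphoma-only 11/36, both cohorts 23/36.

A single root seed drives independent per-purpose streams (demographics,
scores, selections, missingness), so each piece regenerates identically on
its own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import brentq

from .instruments import (HADS, QuestionnaireRecord, ScaleDefinition,
                          default_scales)
from .norms import LYMPHOMA_COHORT, NORMATIVE_POPULATION
from .report import OWN_ONLY, TOPIC_SCALES, TOPICS, FeedbackSelection

__all__ = ["CohortSpec", "simulate_cohort", "simulate_norm_microdata",
           "DEFAULT_SCALE_TARGETS", "DEFAULT_TOPIC_PROBS",
           "DEFAULT_COMPARATOR_PROBS"]

#: published lymphoma reference cohort summaries (mean, sd) per scale
DEFAULT_SCALE_TARGETS: dict[str, tuple[float, float]] = {
    "physical_functioning": (79.4, 21.0),
    "emotional_functioning": (82.8, 21.0),
    "cognitive_functioning": (82.4, 23.0),
    "social_functioning": (84.4, 24.0),
    "global_qol": (74.0, 20.0),
    "fatigue": (28.9, 27.0),
    "tingling": (17.0, 29.0),
    "hads_anxiety": (4.4, 3.8),
    "hads_depression": (4.7, 3.8),
}

#: published topic-uptake fractions among patients receiving feedback
DEFAULT_TOPIC_PROBS: dict[str, float] = {
    "general_qol": 1.00,
    "physical": 0.92,
    "emotional": 0.89,
    "social": 0.92,
    "cognitive": 0.86,
    "fatigue": 0.86,
    "tingling": 0.81,
    "anxiety": 0.83,
    "depressive": 0.83,
}

#: comparator-set probabilities among patients receiving feedback
DEFAULT_COMPARATOR_PROBS: dict[tuple[str, ...], float] = {
    (OWN_ONLY,): 2 / 36,
    (LYMPHOMA_COHORT,): 11 / 36,
    (LYMPHOMA_COHORT, NORMATIVE_POPULATION): 23 / 36,
}


@dataclass(frozen=True)
class CohortSpec:
    """Statistical structure of a synthetic cohort."""

    n: int = 45
    sex_ratio: float = 0.58  # fraction male
    age_mean: float = 60.7
    age_sd: float = 13.6
    age_min: float = 18.0
    age_max: float = 95.0
    scale_targets: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SCALE_TARGETS))
    optin_probability: float = 0.80
    topic_probabilities: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TOPIC_PROBS))
    comparator_probabilities: Mapping[tuple[str, ...], float] = field(
        default_factory=lambda: dict(DEFAULT_COMPARATOR_PROBS))
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n < 0:
            raise ValueError("n must be >= 0")
        probs = [self.sex_ratio, self.optin_probability, self.missing_rate,
                 *self.topic_probabilities.values(),
                 *self.comparator_probabilities.values()]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.age_min < 18 or self.age_max <= self.age_min:
            raise ValueError("age range must satisfy 18 <= min < max")
        total = sum(self.comparator_probabilities.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError("comparator-set probabilities must sum to 1")


def _streams(seed: int) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    names = ("demographics", "scores", "selections", "missing")
    return {name: np.random.default_rng(child)
            for name, child in zip(names, root.spawn(len(names)))}


def _truncated_normal(mean, sd, lo, hi, size, rng) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                             random_state=rng)


def _score_grid(scale: ScaleDefinition) -> np.ndarray:
    """The scores a fully answered scale can realize, in ascending order."""
    k = len(scale.items)
    totals = np.arange(k * scale.response_min, k * scale.response_max + 1)
    if scale.transform == "hads_sum":
        return totals.astype(float)
    raw = totals / k
    frac = (raw - scale.response_min) / scale.response_range
    if scale.transform == "eortc_functioning":
        return np.sort((1.0 - frac) * 100.0)
    return frac * 100.0


def _calibrate_mu(target_mean: float, sd: float,
                  scale: ScaleDefinition) -> float:
    """Latent location whose *scored* expectation equals the target mean.

    The latent score is normal(mu, sd) truncated to the score range and then
    rounded to the nearest achievable score, which both pull the realized
    mean toward the middle of the range (published summary means sit close
    to the ceiling on several scales).  The expectation of the rounded,
    truncated draw has a closed form over the achievable-score grid, so mu
    can be root-solved to hit the target exactly.
    """
    smin, smax = scale.score_min, scale.score_max
    if target_mean == smin or target_mean == smax:
        return target_mean  # degenerate: every draw rounds to the extreme
    grid = _score_grid(scale)
    cuts = (grid[:-1] + grid[1:]) / 2.0  # bin edges between grid points

    def scored_mean(mu: float) -> float:
        a, b = (smin - mu) / sd, (smax - mu) / sd
        cdf = sps.truncnorm.cdf(cuts, a, b, loc=mu, scale=sd)
        probs = np.diff(np.concatenate(([0.0], cdf, [1.0])))
        return float(grid @ probs)

    lo, hi = smin - 12 * sd, smax + 12 * sd
    return brentq(lambda m: scored_mean(m) - target_mean, lo, hi, xtol=1e-10)


def _target_total(latent: float, scale: ScaleDefinition) -> int:
    """Item-sum total whose scored value is nearest the latent score."""
    k = len(scale.items)
    lo, rng_ = scale.response_min, scale.response_range
    if scale.transform == "hads_sum":
        raw_sum = latent  # latent already on the 0-21 sum scale
    elif scale.transform == "eortc_functioning":
        raw_sum = (lo + rng_ * (1.0 - latent / 100.0)) * k
    else:  # eortc_symptom, eortc_global
        raw_sum = (lo + rng_ * latent / 100.0) * k
    total = int(round(raw_sum))
    return int(np.clip(total, k * lo, k * scale.response_max))


def _distribute(total: int, scale: ScaleDefinition,
                rng: np.random.Generator) -> list[int]:
    """Randomized rounding: split an item-sum total over the scale's items."""
    k = len(scale.items)
    lo, hi = scale.response_min, scale.response_max
    values = [lo] * k
    extra = total - k * lo
    base, rem = divmod(extra, k)
    values = [v + base for v in values]
    bump = rng.permutation(k)[:rem]
    for j in bump:
        values[j] += 1
    # base/rem splitting keeps every item within [lo, hi] because total <= k*hi
    assert all(lo <= v <= hi for v in values) and sum(values) == total
    return values


def simulate_cohort(spec: CohortSpec,
                    scales: Optional[Mapping[str, ScaleDefinition]] = None,
                    return_latents: bool = False
                    ) -> tuple[pd.DataFrame, list[QuestionnaireRecord],
                               list[FeedbackSelection]]:
    """Generate demographics, item-level records and feedback selections.

    Returns ``(patients, records, selections)`` where ``patients`` has
    columns patient_id, sex, age; with ``return_latents`` a fourth element
    maps scale_id -> per-patient latent scores (before item rounding).
    Fully reproducible from ``spec.seed``.
    """
    scales = scales if scales is not None else default_scales()
    for sid, (mean, _sd) in spec.scale_targets.items():
        scale = scales[sid]
        if not (scale.score_min <= mean <= scale.score_max):
            raise ValueError(
                f"target mean {mean} for {sid!r} outside score range "
                f"[{scale.score_min}, {scale.score_max}]")
    streams = _streams(spec.seed)
    n = spec.n
    ids = [f"P{i + 1:05d}" for i in range(n)]

    rng = streams["demographics"]
    sex = np.where(rng.random(n) < spec.sex_ratio, "male", "female")
    age = _truncated_normal(spec.age_mean, spec.age_sd, spec.age_min,
                            spec.age_max, n, rng)
    patients = pd.DataFrame({"patient_id": ids, "sex": sex,
                             "age": np.round(age, 1)})

    rng = streams["scores"]
    latents = {}
    for sid, (mean, sd) in spec.scale_targets.items():
        scale = scales[sid]
        mu = _calibrate_mu(mean, sd, scale)
        if mean in (scale.score_min, scale.score_max):
            latents[sid] = np.full(n, float(mean))
        else:
            latents[sid] = _truncated_normal(mu, sd, scale.score_min,
                                             scale.score_max, n, rng)
    miss_rng = streams["missing"]
    records = []
    for i, pid in enumerate(ids):
        responses: dict[str, Optional[int]] = {}
        for sid in spec.scale_targets:
            scale = scales[sid]
            total = _target_total(latents[sid][i], scale)
            values = _distribute(total, scale, rng)
            for item, v in zip(scale.items, values):
                responses[item.item_id] = int(v)
        if spec.missing_rate > 0:
            for item_id in list(responses):
                if miss_rng.random() < spec.missing_rate:
                    responses[item_id] = None
        records.append(QuestionnaireRecord(pid, responses))

    rng = streams["selections"]
    comparator_sets = list(spec.comparator_probabilities)
    set_probs = np.array([spec.comparator_probabilities[c]
                          for c in comparator_sets])
    selections = []
    for pid in ids:
        if rng.random() >= spec.optin_probability:
            selections.append(FeedbackSelection(pid, wants_feedback=False))
            continue
        topics = tuple(t for t in TOPICS
                       if rng.random() < spec.topic_probabilities.get(t, 0.0))
        comparators = comparator_sets[rng.choice(len(comparator_sets),
                                                 p=set_probs)]
        selections.append(FeedbackSelection(pid, wants_feedback=True,
                                            topics=topics,
                                            comparators=tuple(comparators)))
    if return_latents:
        return patients, records, selections, latents
    return patients, records, selections


def simulate_norm_microdata(n_per_group: int = 200, *,
                            baseline: float = 70.0,
                            group_effect: float = 0.0,
                            age_effect: float = 0.0,
                            sex_effect: float = 0.0,
                            residual_sd: float = 20.0,
                            age_mean: float = 60.0, age_sd: float = 13.0,
                            age_min: float = 18.0, age_max: float = 95.0,
                            group1_age_shift: float = 0.0,
                            sex_ratio: float = 0.5,
                            seed: int = 0) -> pd.DataFrame:
    """Subject-level scores with injected group/age/sex effects.

    score = baseline + group_effect*group + age_effect*(age - age_mean)
            + sex_effect*sex + N(0, residual_sd).

    ``group1_age_shift`` moves group 1's age distribution to create
    age-confounded designs for covariate-adjustment tests.  Columns:
    score, group (0/1), age, sex (0/1).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    n = 2 * n_per_group
    group = np.repeat([0, 1], n_per_group)
    shift = group * group1_age_shift
    age = _truncated_normal(age_mean, age_sd, age_min, age_max, n, rng) + shift
    sex = (rng.random(n) < sex_ratio).astype(int)
    noise = rng.normal(0.0, residual_sd, n)
    score = (baseline + group_effect * group + age_effect * (age - age_mean)
             + sex_effect * sex + noise)
    return pd.DataFrame({"score": score, "group": group,
                         "age": age, "sex": sex})
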
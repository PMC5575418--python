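"""Group-comparison statistics for cohort descriptions.

Implements the analysis toolkit used to compare respondents with
nonrespondents and patients with reference cohorts:

* Fisher's exact test for 2x2 tables and its Freeman-Halton generalization
  to r x c tables, by complete enumeration of all tables with the observed
  margins.  The two-sided p-value uses probability-mass ordering: the sum of
  the probabilities of every margin-fixed table whose probability does not
  exceed the observed table's (with a small relative tolerance so exactly
  tied tables are never lost to floating-point rounding).
* Two-sample t tests (pooled/Student by default, Welch by flag), entered
  either with raw samples or with summary statistics (mean, sd, n).
* ANCOVA: ordinary least squares of the score on a binary group indicator
  with age (years) and sex (0/1) as covariates; the group effect is the
  adjusted mean difference, with adjusted group means evaluated at the
  overall covariate means.
* Mapping of a group mean difference to a clinical-relevance size label
  (no / trivial / small / medium / large) through configured per-scale
  cutoffs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln
import statsmodels.api as sm

from .norms import ThresholdTable

__all__ = [
    "ContingencyTable", "TestResult", "AncovaResult",
    "EnumerationCapError",
    "fisher_exact", "enumerate_tables", "table_log_prob",
    "t_test", "ancova_group_effect", "clinical_relevance_label",
    "RELEVANCE_LABELS",
]

RELEVANCE_LABELS = ("no", "trivial", "small", "medium", "large")

#: relative tolerance when comparing a table's probability with the observed
#: table's, so tables with mathematically equal probability are included even
#: when floating-point evaluation differs in the last bits
TIE_RTOL = 1e-7


class EnumerationCapError(RuntimeError):
    """Complete enumeration would exceed the configured cap.

    Use ``method='montecarlo'`` for large tables.
    """


@dataclass(frozen=True)
class ContingencyTable:
    counts: tuple[tuple[int, ...], ...]
    row_labels: Optional[tuple[str, ...]] = None
    col_labels: Optional[tuple[str, ...]] = None

    def __post_init__(self):
        a = np.asarray(self.counts)
        if a.ndim != 2 or a.shape[0] < 2 or a.shape[1] < 2:
            raise ValueError("contingency table must be at least 2x2")
        if (a < 0).any() or not np.issubdtype(a.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        if a.sum() == 0:
            raise ValueError("table total must be positive")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)


@dataclass(frozen=True)
class TestResult:
    method: str
    p_value: float
    statistic: Optional[float] = None
    df: Optional[float] = None


@dataclass(frozen=True)
class AncovaResult:
    group_effect: float
    p_value: float
    se: float
    adjusted_means: dict[str, float]
    covariates: tuple[str, ...] = ("age", "sex")
    n: int = 0


# ---------------------------------------------------------------------------
# exact contingency-table tests

def table_log_prob(table: np.ndarray, log_margin_const: Optional[float] = None
                   ) -> float:
    """Log hypergeometric probability of ``table`` given its margins.

    P(T) = (prod_i r_i!)(prod_j c_j!) / (N! prod_ij n_ij!).
    """
    t = np.asarray(table, dtype=np.int64)
    if log_margin_const is None:
        log_margin_const = (gammaln(t.sum(1) + 1).sum()
                            + gammaln(t.sum(0) + 1).sum()
                            - gammaln(t.sum() + 1))
    return float(log_margin_const - gammaln(t + 1).sum())


def enumerate_tables(row_sums: Sequence[int], col_sums: Sequence[int],
                     cap: int = 2_000_000):
    """Yield every non-negative integer table with the given margins.

    Tables are produced row by row (depth-first over bounded compositions of
    each row sum).  Raises :class:`EnumerationCapError` after ``cap`` tables.
    """
    rows = list(int(r) for r in row_sums)
    cols = list(int(c) for c in col_sums)
    if sum(rows) != sum(cols):
        raise ValueError("row and column sums disagree")
    r, c = len(rows), len(cols)
    count = 0

    def compositions(total, bounds):
        # all ways to split `total` over len(bounds) cells with cell j <= bounds[j]
        if len(bounds) == 1:
            if 0 <= total <= bounds[0]:
                yield (total,)
            return
        tail_room = sum(bounds[1:])
        for v in range(max(0, total - tail_room), min(total, bounds[0]) + 1):
            for rest in compositions(total - v, bounds[1:]):
                yield (v,) + rest

    def rec(i, remaining, acc):
        nonlocal count
        if i == r - 1:
            if all(v >= 0 for v in remaining):
                count += 1
                if count > cap:
                    raise EnumerationCapError(
                        f"more than {cap} tables with these margins; "
                        "use method='montecarlo'"
                    )
                yield acc + (tuple(remaining),)
            return
        for comp in compositions(rows[i], remaining):
            rem = [rc - v for rc, v in zip(remaining, comp)]
            yield from rec(i + 1, rem, acc + (comp,))

    yield from rec(0, cols, ())


def _fisher_enumerate(a: np.ndarray, cap: int) -> float:
    rows, cols = a.sum(1), a.sum(0)
    const = (gammaln(rows + 1).sum() + gammaln(cols + 1).sum()
             - gammaln(a.sum() + 1))
    log_obs = table_log_prob(a, const)
    # include tables with P <= P_obs * (1 + TIE_RTOL)
    log_cut = log_obs + math.log1p(TIE_RTOL)
    p = 0.0
    for t in enumerate_tables(rows, cols, cap=cap):
        lp = const - gammaln(np.asarray(t) + 1).sum()
        if lp <= log_cut:
            p += math.exp(lp)
    return min(p, 1.0)


def _fisher_montecarlo(a: np.ndarray, n_resamples: int,
                       rng: np.random.Generator) -> float:
    rows, cols = a.sum(1), a.sum(0)
    const = (gammaln(rows + 1).sum() + gammaln(cols + 1).sum()
             - gammaln(a.sum() + 1))
    log_obs = table_log_prob(a, const)
    log_cut = log_obs + math.log1p(TIE_RTOL)
    dist = sps.random_table(rows, cols)
    sims = dist.rvs(n_resamples, method="patefield", random_state=rng)
    lps = const - gammaln(sims + 1).sum(axis=(1, 2))
    hits = int((lps <= log_cut).sum())
    # add-one estimator keeps the Monte-Carlo p-value in (0, 1]
    return (hits + 1) / (n_resamples + 1)


def fisher_exact(table: ContingencyTable | Sequence[Sequence[int]], *,
                 cap: int = 2_000_000, method: str = "exact",
                 n_resamples: int = 10_000,
                 rng: Optional[np.random.Generator] = None) -> TestResult:
    """Two-sided exact test of independence for an r x c table.

    For 2x2 tables this is Fisher's exact test; for larger tables the
    Freeman-Halton generalization.  Both run through the same complete
    enumeration with probability-mass ordering.  ``method='montecarlo'``
    estimates the same p-value by sampling margin-fixed tables (Patefield's
    algorithm) when enumeration is too large.
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(tuple(tuple(int(v) for v in row)
                                       for row in table))
    a = table.array
    if (a.sum(0) == 0).any() or (a.sum(1) == 0).any():
        raise ValueError("every row and column margin must be positive")
    if method == "exact":
        p = _fisher_enumerate(a, cap)
        name = "fisher_exact" if a.shape == (2, 2) else "freeman_halton_exact"
        return TestResult(method=name, p_value=p)
    if method == "montecarlo":
        p = _fisher_montecarlo(a, n_resamples,
                               rng if rng is not None else np.random.default_rng())
        return TestResult(method="fisher_montecarlo", p_value=p)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# t tests

def t_test(sample_a: Optional[Sequence[float]] = None,
           sample_b: Optional[Sequence[float]] = None, *,
           summary_a: Optional[tuple[float, float, int]] = None,
           summary_b: Optional[tuple[float, float, int]] = None,
           variant: str = "pooled") -> TestResult:
    """Two-sided two-sample t test from raw samples or (mean, sd, n) summaries.

    The raw-data and summary-statistic entry points agree exactly on matching
    data.  Degenerate input with zero variance in both groups returns p = 1
    when the means are equal and is a domain error otherwise.
    """
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    equal_var = variant == "pooled"
    if summary_a is not None or summary_b is not None:
        if sample_a is not None or sample_b is not None:
            raise ValueError("pass either raw samples or summaries, not both")
        (m1, s1, n1), (m2, s2, n2) = summary_a, summary_b
    else:
        x1 = np.asarray(sample_a, dtype=float)
        x2 = np.asarray(sample_b, dtype=float)
        if len(x1) < 2 or len(x2) < 2:
            raise ValueError("each group needs n >= 2")
        m1, s1, n1 = x1.mean(), x1.std(ddof=1), len(x1)
        m2, s2, n2 = x2.mean(), x2.std(ddof=1), len(x2)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if s1 == 0 and s2 == 0:
        if m1 == m2:
            df = n1 + n2 - 2 if equal_var else float("nan")
            return TestResult(method=f"t_{variant}", p_value=1.0,
                              statistic=0.0, df=df)
        raise ValueError("zero variance in both groups with unequal means")
    stat, p = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2,
                                       equal_var=equal_var)
    if equal_var:
        df = float(n1 + n2 - 2)
    else:
        v1, v2 = s1 ** 2 / n1, s2 ** 2 / n2
        df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    return TestResult(method=f"t_{variant}", p_value=float(p),
                      statistic=float(stat), df=float(df))


# ---------------------------------------------------------------------------
# ANCOVA

def ancova_group_effect(scores: Sequence[float], group: Sequence[int],
                        age: Sequence[float], sex: Sequence[int]
                        ) -> AncovaResult:
    """Adjusted group mean difference from OLS of score on group + age + sex.

    ``group`` and ``sex`` are 0/1 indicators; ``age`` is in years,
    untransformed.  Adjusted means are the model predictions for each group
    at the overall mean age and sex composition, so they differ exactly by
    the group coefficient.
    """
    y = np.asarray(scores, dtype=float)
    g = np.asarray(group, dtype=float)
    a = np.asarray(age, dtype=float)
    s = np.asarray(sex, dtype=float)
    if not (len(y) == len(g) == len(a) == len(s)):
        raise ValueError("scores, group, age and sex must have equal length")
    for name, arr in (("group", g), ("sex", s)):
        if not np.isin(arr, (0.0, 1.0)).all():
            raise ValueError(f"{name} must be coded 0/1")
    if min((g == 0).sum(), (g == 1).sum()) < 2:
        raise ValueError("each group needs at least 2 subjects")

    X = np.column_stack([np.ones_like(y), g, a, s])
    names = ["intercept", "group", "age", "sex"]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = [names[j] for j in range(1, X.shape[1])
               if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank]
        raise ValueError(f"singular design: collinear column(s) {bad}")

    fit = sm.OLS(y, X).fit()
    effect = float(fit.params[1])
    base = float(fit.params[0] + fit.params[2] * a.mean()
                 + fit.params[3] * s.mean())
    return AncovaResult(
        group_effect=effect,
        p_value=float(fit.pvalues[1]),
        se=float(fit.bse[1]),
        adjusted_means={"group0": base, "group1": base + effect},
        n=len(y),
    )


# ---------------------------------------------------------------------------
# clinical relevance

def clinical_relevance_label(difference: float, scale_id: str,
                             thresholds: ThresholdTable) -> str:
    """Map |difference| to no / trivial / small / medium / large.

    The configured bounds ``(b0, b1, b2, b3)`` delimit the labels:
    |d| < b0 -> no, [b0, b1) -> trivial, [b1, b2) -> small,
    [b2, b3) -> medium, >= b3 -> large.  Symmetric in the sign of the
    difference.
    """
    bounds = thresholds.bounds(scale_id)
    if len(bounds) != len(RELEVANCE_LABELS) - 1:
        raise ValueError(
            f"scale {scale_id!r} needs {len(RELEVANCE_LABELS) - 1} bounds, "
            f"got {len(bounds)}"
        )
    mag = abs(difference)
    for bound, label in zip(bounds, RELEVANCE_LABELS):
        if mag < bound:
            return label
    return RELEVANCE_LABELS[-1]
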
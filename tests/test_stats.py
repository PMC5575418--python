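"""Exact tests, t tests, ANCOVA — checked against independent oracles."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats as sps

from prolight.norms import ThresholdTable
from prolight.stats import (ContingencyTable, EnumerationCapError,
                            ancova_group_effect, clinical_relevance_label,
                            enumerate_tables, fisher_exact, t_test,
                            table_log_prob)


# --------------------------------------------------------------------------
# independent brute-force oracle: iterate the full cell product space and
# keep tables with the right margins, with exact rational probabilities
def oracle_fisher_p(table):
    a = np.asarray(table)
    rows, cols = a.sum(1), a.sum(0)

    def prob(t):
        num = 1
        for m in (*rows, *cols):
            num *= math.factorial(int(m))
        den = math.factorial(int(a.sum()))
        for v in t:
            den *= math.factorial(int(v))
        return Fraction(num, den)

    ranges = [range(min(rows[i], cols[j]) + 1)
              for i in range(a.shape[0]) for j in range(a.shape[1])]
    p_obs = prob(a.ravel())
    total = Fraction(0)
    for cells in itertools.product(*ranges):
        t = np.asarray(cells).reshape(a.shape)
        if (t.sum(1) == rows).all() and (t.sum(0) == cols).all():
            p = prob(cells)
            if p <= p_obs:
                total += p
    return float(total)


class TestFisherExact:
    def test_equal_proportions_give_p_one(self):
        assert fisher_exact([[5, 5], [5, 5]]).p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("table", [
        [[8, 1], [37, 18]],
        [[26, 14], [19, 5]],
        [[3, 7], [9, 2]],
        [[1, 9], [8, 2]],
        [[10, 0], [0, 10]],
    ])
    def test_two_by_two_matches_scipy(self, table):
        ours = fisher_exact(table).p_value
        ref = sps.fisher_exact(table).pvalue
        assert ours == pytest.approx(ref, rel=1e-9)

    @pytest.mark.parametrize("table", [
        [[3, 2], [1, 4], [5, 1]],
        [[2, 0], [3, 4], [1, 6]],
        [[4, 4], [4, 4], [4, 4]],
        [[1, 2], [3, 1], [0, 5]],
    ])
    def test_rxc_matches_enumeration_oracle(self, table):
        # oracle enumerates the raw cell product space with exact rationals
        assert fisher_exact(table).p_value == pytest.approx(
            oracle_fisher_p(table), rel=1e-9)

    def test_2x2_is_rxc_restricted(self):
        # embedding a 2x2 in the general code path changes nothing
        t = [[7, 3], [2, 9]]
        assert fisher_exact(t).method == "fisher_exact"
        assert fisher_exact(t).p_value == pytest.approx(oracle_fisher_p(t),
                                                        rel=1e-9)

    def test_probabilities_sum_to_one(self):
        a = np.array([[8, 4], [10, 2], [5, 4], [13, 4]])
        rows, cols = a.sum(1), a.sum(0)
        total = sum(math.exp(table_log_prob(np.asarray(t)))
                    for t in enumerate_tables(rows, cols))
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[0, 0], [3, 4]])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(((1, -1), (2, 3)))

    def test_enumeration_cap_suggests_montecarlo(self):
        big = (np.ones((6, 6), dtype=int) * 12).tolist()
        with pytest.raises(EnumerationCapError, match="montecarlo"):
            fisher_exact(big, cap=1000)

    def test_montecarlo_mode_approximates_exact(self):
        table = [[3, 2], [1, 4], [5, 1]]
        exact = fisher_exact(table).p_value
        mc = fisher_exact(table, method="montecarlo", n_resamples=20000,
                          rng=np.random.default_rng(5)).p_value
        assert abs(mc - exact) < 0.02

    def test_exact_pvalues_are_valid_under_the_null(self):
        # weight every margin-fixed table by its null probability: the
        # rejection mass at level alpha can never exceed alpha
        a = np.array([[6, 3], [2, 7], [4, 5]])
        rows, cols = a.sum(1), a.sum(0)
        pairs = [(math.exp(table_log_prob(np.asarray(t))),
                  fisher_exact([list(r) for r in t]).p_value)
                 for t in enumerate_tables(rows, cols)]
        for alpha in (0.01, 0.05, 0.1):
            mass = sum(pr for pr, p in pairs if p <= alpha)
            assert mass <= alpha + 1e-9


class TestTTest:
    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = t_test(x, x)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_pooled_from_summary_statistics(self):
        # two groups: means 60.7/63.8, sd 13.6/14.7, n 45/19
        res = t_test(summary_a=(60.7, 13.6, 45), summary_b=(63.8, 14.7, 19),
                     variant="pooled")
        assert res.statistic == pytest.approx(-0.81, abs=0.005)
        assert res.df == 62

    def test_raw_and_summary_entry_points_agree(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 20), rng.normal(0.5, 1.2, 15)
        for variant in ("pooled", "welch"):
            raw = t_test(x, y, variant=variant)
            summ = t_test(summary_a=(x.mean(), x.std(ddof=1), 20),
                          summary_b=(y.mean(), y.std(ddof=1), 15),
                          variant=variant)
            assert raw.p_value == pytest.approx(summ.p_value, rel=1e-12)
            assert raw.statistic == pytest.approx(summ.statistic, rel=1e-12)

    def test_welch_matches_scipy(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(0, 1, 12), rng.normal(1, 3, 30)
        res = t_test(x, y, variant="welch")
        ref = sps.ttest_ind(x, y, equal_var=False)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-12)

    def test_degenerate_zero_variance(self):
        assert t_test([2.0, 2.0], [2.0, 2.0]).p_value == 1.0
        with pytest.raises(ValueError):
            t_test([2.0, 2.0], [3.0, 3.0])

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            t_test([1.0], [2.0, 3.0])


class TestAncova:
    def test_six_subject_normal_equations_oracle(self):
        # coefficients must equal the closed-form least-squares solution
        y = np.array([70.0, 64.0, 81.0, 59.0, 88.0, 75.0])
        g = np.array([0, 0, 0, 1, 1, 1])
        age = np.array([55.0, 62.0, 44.0, 70.0, 38.0, 51.0])
        sex = np.array([1, 0, 1, 0, 0, 1])
        X = np.column_stack([np.ones(6), g, age, sex])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        s2 = resid @ resid / (6 - 4)
        se = math.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        p = 2 * sps.t.sf(abs(beta[1] / se), 6 - 4)
        res = ancova_group_effect(y, g, age, sex)
        assert res.group_effect == pytest.approx(beta[1], rel=1e-10)
        assert res.se == pytest.approx(se, rel=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-10)

    def test_adjusted_means_differ_by_group_effect(self):
        rng = np.random.default_rng(0)
        y = rng.normal(70, 10, 40)
        g = np.repeat([0, 1], 20)
        res = ancova_group_effect(y, g, rng.uniform(20, 80, 40),
                                  rng.integers(0, 2, 40))
        diff = res.adjusted_means["group1"] - res.adjusted_means["group0"]
        assert diff == pytest.approx(res.group_effect, rel=1e-12)

    def test_reduces_to_pooled_t_on_balanced_null_covariates(self):
        # constant-effect-free covariates balanced across groups: the
        # adjusted difference equals the raw mean difference
        rng = np.random.default_rng(1)
        y = rng.normal(50, 8, 60)
        g = np.repeat([0, 1], 30)
        age = np.tile(rng.uniform(20, 80, 30), 2)   # identical across groups
        sex = np.tile(rng.integers(0, 2, 30), 2)
        res = ancova_group_effect(y, g, age, sex)
        raw_diff = y[g == 1].mean() - y[g == 0].mean()
        assert res.group_effect == pytest.approx(raw_diff, rel=1e-9)

    def test_singular_design_names_collinear_column(self):
        y = np.arange(8.0)
        g = np.repeat([0, 1], 4)
        with pytest.raises(ValueError, match="sex"):
            ancova_group_effect(y, g, np.ones(8) * 50, g)  # sex == group

    def test_group_must_be_binary(self):
        with pytest.raises(ValueError):
            ancova_group_effect([1.0, 2, 3, 4], [0, 1, 2, 1],
                                [30, 40, 50, 60], [0, 1, 0, 1])


class TestClinicalRelevance:
    @pytest.fixture()
    def table(self):
        return ThresholdTable(d_medium={"s": 10.0},
                              size_class_bounds={"s": (2, 5, 10, 15)})

    @pytest.mark.parametrize("diff,label", [
        (0.0, "no"), (1.9, "no"), (2.0, "trivial"), (4.9, "trivial"),
        (7.0, "small"), (10.0, "medium"), (14.9, "medium"), (15.0, "large"),
        (40.0, "large"),
    ])
    def test_interval_membership(self, table, diff, label):
        assert clinical_relevance_label(diff, "s", table) == label

    def test_symmetric_in_sign(self, table):
        for d in (0.5, 3.0, 7.0, 12.0, 20.0):
            assert (clinical_relevance_label(d, "s", table)
                    == clinical_relevance_label(-d, "s", table))

    def test_missing_bounds_is_configuration_error(self, table):
        from prolight.norms import NormTableError
        with pytest.raises(NormTableError):
            clinical_relevance_label(3.0, "unknown", table)
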
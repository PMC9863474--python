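"""Group summaries, between-group tests, and contingency-table analysis."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from papvrscore import (
    ScoredPatient,
    SurgicalProcedure,
    association_test,
    compare_groups,
    group_vs_rest,
    summarize,
)


def scored(values_by_label):
    out = []
    i = 0
    for label, values in values_by_label.items():
        for v in values:
            out.append(ScoredPatient(f"p{i}", v, actual_procedure=label))
            i += 1
    return out


def fisher_p_enumerated(table):
    """Two-sided Fisher p by enumerating all 2x2 tables with fixed margins."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


class TestSummarize:
    def test_two_point_group(self):
        s = summarize(scored({SurgicalProcedure.WARDEN: [0.4, 0.6],
                              SurgicalProcedure.SINGLE_PATCH: [0.5]}))
        g = s.group("WARDEN")
        assert g.n == 2
        assert g.mean_ratio == pytest.approx(0.5)
        assert g.sd_ratio == pytest.approx(np.std([0.4, 0.6], ddof=1))

    def test_singleton_group_sd_undefined(self):
        s = summarize(scored({SurgicalProcedure.SINGLE_PATCH: [0.42]}))
        g = s.group("SINGLE_PATCH")
        assert g.n == 1 and g.mean_ratio == pytest.approx(0.42)
        assert g.sd_ratio is None

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            summarize([])

    def test_permutation_invariance(self):
        base = scored({SurgicalProcedure.WARDEN: [0.8, 0.9, 0.7],
                       SurgicalProcedure.DOUBLE_PATCH: [0.6, 0.5]})
        summaries = {summarize(list(perm)).as_dict().__repr__()
                     for perm in itertools.permutations(base)}
        assert len(summaries) == 1


class TestCompareGroups:
    def test_well_separated_groups_highly_significant(self):
        rng = np.random.default_rng(3)
        sc = scored({
            SurgicalProcedure.WARDEN: np.clip(rng.normal(0.85, 0.1, 15), 0, 1),
            SurgicalProcedure.SINGLE_PATCH: np.clip(rng.normal(0.55, 0.1, 15), 0, 1),
        })
        res = compare_groups(sc, mode="auto")
        assert res.p_value < 1e-3
        # cross-check against the reference implementation directly
        ref = stats.ttest_ind(
            [p.ratio for p in sc if p.actual_procedure is SurgicalProcedure.WARDEN],
            [p.ratio for p in sc if p.actual_procedure is SurgicalProcedure.SINGLE_PATCH],
            equal_var=False,
        )
        if res.test == "welch_t":
            assert res.p_value == pytest.approx(ref.pvalue)

    def test_identical_samples_null(self):
        sc = scored({SurgicalProcedure.WARDEN: [0.5, 0.5, 0.5],
                     SurgicalProcedure.SINGLE_PATCH: [0.5, 0.5, 0.5]})
        res = compare_groups(sc, mode="kruskal_wallis")
        assert res.p_value == pytest.approx(1.0)
        assert res.statistic == pytest.approx(0.0)

    def test_three_groups_select_kruskal_wallis(self):
        rng = np.random.default_rng(5)
        sc = scored({
            SurgicalProcedure.SINGLE_PATCH: rng.uniform(0.3, 0.6, 7),
            SurgicalProcedure.DOUBLE_PATCH: rng.uniform(0.4, 0.8, 8),
            SurgicalProcedure.WARDEN: rng.uniform(0.6, 1.0, 15),
        })
        res = compare_groups(sc, mode="auto")
        assert res.test == "kruskal_wallis"
        assert res.df == 2.0

    def test_binary_pooling(self):
        rng = np.random.default_rng(9)
        sc = scored({
            SurgicalProcedure.SINGLE_PATCH: rng.normal(0.5, 0.05, 7),
            SurgicalProcedure.DOUBLE_PATCH: rng.normal(0.6, 0.05, 8),
            SurgicalProcedure.WARDEN: np.clip(rng.normal(0.85, 0.05, 15), 0, 1),
        })
        res = compare_groups(sc, mode="kruskal_wallis", binary=True)
        assert res.df == 1.0  # warden vs pooled patch: two groups only

    def test_shift_invariance_of_p_values(self):
        rng = np.random.default_rng(13)
        vals_w = rng.uniform(0.5, 0.9, 10)
        vals_p = rng.uniform(0.1, 0.6, 10)
        for mode in ("t_test", "kruskal_wallis"):
            p0 = compare_groups(
                scored({SurgicalProcedure.WARDEN: vals_w,
                        SurgicalProcedure.SINGLE_PATCH: vals_p}), mode=mode
            ).p_value
            p1 = compare_groups(
                scored({SurgicalProcedure.WARDEN: vals_w + 0.1,
                        SurgicalProcedure.SINGLE_PATCH: vals_p + 0.1}), mode=mode
            ).p_value
            assert p1 == pytest.approx(p0, rel=1e-9)

    def test_insufficient_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups(scored({SurgicalProcedure.WARDEN: [0.8, 0.9]}))
        with pytest.raises(ValueError):
            compare_groups(scored({SurgicalProcedure.WARDEN: [0.8, 0.9],
                                   SurgicalProcedure.SINGLE_PATCH: [0.5]}))

    def test_group_vs_rest_reports_every_group(self):
        rng = np.random.default_rng(21)
        sc = scored({
            SurgicalProcedure.SINGLE_PATCH: rng.normal(0.51, 0.08, 7),
            SurgicalProcedure.DOUBLE_PATCH: rng.normal(0.62, 0.09, 8),
            SurgicalProcedure.WARDEN: np.clip(rng.normal(0.85, 0.10, 15), 0, 1),
        })
        res = group_vs_rest(sc)
        assert set(res) == {"SINGLE_PATCH", "DOUBLE_PATCH", "WARDEN"}
        assert res["WARDEN"].p_value < 0.001


class TestAssociationTest:
    def test_fisher_small_table_matches_enumeration(self):
        res = association_test([[3, 0], [0, 3]])
        assert res.test == "fisher_exact"
        assert res.p_value == pytest.approx(0.1)
        assert res.p_value == pytest.approx(fisher_p_enumerated([[3, 0], [0, 3]]))

    def test_no_association_unit_odds_ratio(self):
        res = association_test([[10, 10], [10, 10]])
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_large_table_chi_square_branch(self):
        res = association_test([[50, 10], [10, 50]])
        assert res.test == "pearson_chi2"
        assert res.p_value < 1e-3
        ref = stats.chi2_contingency([[50, 10], [10, 50]], correction=False)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_odds_ratio_symmetries(self):
        table = np.array([[12, 5], [7, 20]])
        orig = association_test(table).odds_ratio
        assert association_test(table.T).odds_ratio == pytest.approx(orig)
        swapped = association_test(table[::-1]).odds_ratio
        assert swapped == pytest.approx(1.0 / orig)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            association_test([[1, -2], [3, 4]])
        with pytest.raises(ValueError):
            association_test([[1.5, 2], [3, 4]])
        with pytest.raises(ValueError):
            association_test([[1, 2, 3]])
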
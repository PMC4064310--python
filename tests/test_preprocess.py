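"""Univariate screening and comparative-Ct normalization."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from respanel import (
    CtTable,
    DomainError,
    ExpressionMatrix,
    SimulationConfig,
    comparative_ct_normalize,
    differential_genes,
    fold_change,
    low_intensity_filter,
    mann_whitney_u,
    simulate_expression_cohort,
)
from respanel.preprocess import _approx_two_sided_p, _u_statistics

from conftest import matrix_from_rows, two_group_labels


class TestLowIntensityFilter:
    def _ladder(self, n=10):
        return matrix_from_rows({f"g{i:02d}": [float(i + 1)] * 4 for i in range(n)})

    def test_removes_floor_fraction_lowest_means(self):
        filtered = low_intensity_filter(self._ladder(), 0.2)
        assert filtered.n_genes == 8
        assert "g00" not in filtered.gene_ids and "g01" not in filtered.gene_ids

    def test_fraction_zero_is_identity(self):
        m = self._ladder()
        assert low_intensity_filter(m, 0.0).gene_ids == m.gene_ids

    def test_tie_at_cutoff_matches_sort_oracle(self):
        m = matrix_from_rows({"b": [2.0] * 3, "a": [2.0] * 3, "c": [1.0] * 3,
                              "d": [3.0] * 3})
        filtered = low_intensity_filter(m, 0.5)
        # oracle: sort by (mean, gene_id), drop floor(0.5*4)=2 lowest
        means = m.data.mean(axis=1)
        order = sorted(m.gene_ids, key=lambda g: (means[g], g))
        expected = [g for g in m.gene_ids if g not in order[:2]]
        assert filtered.gene_ids == expected  # 'c' and 'a' removed

    def test_empty_matrix_rejected(self):
        with pytest.raises(DomainError):
            low_intensity_filter(ExpressionMatrix(pd.DataFrame(columns=["s1"], dtype=float)), 0.2)

    @given(fracs=st.tuples(st.floats(0, 0.99), st.floats(0, 0.99)),
           seed=st.integers(0, 10))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_monotone_in_fraction(self, fracs, seed):
        """A gene removed at a low fraction stays removed at any higher one."""
        lo, hi = min(fracs), max(fracs)
        m = simulate_expression_cohort(
            SimulationConfig(n_genes=12, n_informative=0, seed=seed)).expression
        kept_hi = set(low_intensity_filter(m, hi).gene_ids)
        kept_lo = set(low_intensity_filter(m, lo).gene_ids)
        assert kept_hi <= kept_lo


class TestFoldChange:
    @pytest.mark.parametrize("resp,nonresp,expected_fc,expected_dir", [
        ([10.0, 10.0], [20.0, 20.0], 2.0, -1),
        ([15.0, 15.0], [15.0, 15.0], 1.0, 0),
        ([30.0, 30.0], [10.0, 10.0], 3.0, 1),
    ])
    def test_ratio_and_direction(self, resp, nonresp, expected_fc, expected_dir):
        m = matrix_from_rows({"g": resp + nonresp})
        fc, direction = fold_change(m, two_group_labels(2, 2), "g")
        assert fc == pytest.approx(expected_fc)
        assert direction == expected_dir

    def test_zero_group_mean_gives_infinite_ratio(self):
        m = matrix_from_rows({"g": [0.0, 0.0, 5.0, 5.0]})
        fc, direction = fold_change(m, two_group_labels(2, 2), "g")
        assert math.isinf(fc) and direction == -1


class TestMannWhitney:
    def test_fully_separated_small_groups(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 of C(6,3)=20 labelings as extreme

    def test_interleaved_matches_enumeration_oracle(self):
        x, y = [1.0, 3.0], [2.0, 4.0]
        u, p = mann_whitney_u(x, y)
        pooled = np.array(x + y)
        u_obs = min(_u_statistics(np.array(x), np.array(y)))
        hits = total = 0
        for idx in combinations(range(4), 2):
            mask = np.zeros(4, dtype=bool)
            mask[list(idx)] = True
            total += 1
            hits += min(_u_statistics(pooled[mask], pooled[~mask])) <= u_obs
        assert u == u_obs
        assert p == pytest.approx(hits / total)

    def test_identical_multisets_not_significant(self):
        _, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert p >= 0.99

    def test_exact_agrees_with_scipy_on_tie_free_data(self, rng):
        for _ in range(20):
            x = rng.normal(size=5)
            y = rng.normal(size=6)
            u, p = mann_whitney_u(x, y)
            ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert p == pytest.approx(ref.pvalue, abs=1e-12)
            assert u == min(ref.statistic, len(x) * len(y) - ref.statistic)

    def test_exact_and_normal_approx_agree_for_6v6(self, rng):
        for _ in range(20):
            x = rng.normal(size=6)
            y = rng.normal(size=6)
            u, p_exact = mann_whitney_u(x, y)
            p_approx = _approx_two_sided_p(x, y, u)
            assert abs(p_exact - p_approx) <= 0.02

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_two_sided_p_symmetric_in_groups(self, seed):
        r = np.random.default_rng(seed)
        x = r.normal(size=r.integers(2, 9))
        y = r.normal(size=r.integers(2, 9))
        assert mann_whitney_u(x, y)[1] == pytest.approx(mann_whitney_u(y, x)[1])

    def test_tiny_group_rejected(self):
        with pytest.raises(DomainError):
            mann_whitney_u([1.0], [2.0, 3.0])


class TestDifferentialGenes:
    def test_pass_requires_both_significance_and_fold_change(self):
        m = matrix_from_rows({
            # strong shift, FC 2: passes
            "hit": [10, 11, 12, 10.5, 11.5, 13, 12.5, 20, 22, 24, 21, 23, 26, 25],
            # strong shift but FC < 1.5: fails on fold change
            "subtle": [100, 101, 102, 100.5, 101.5, 103, 102.5,
                       110, 112, 114, 111, 113, 116, 115],
        })
        labels = two_group_labels(7, 7)
        results = {r.gene_id: r for r in differential_genes(m, labels)}
        assert results["hit"].passed
        assert results["subtle"].p_value < 0.05
        assert results["subtle"].fold_change < 1.5
        assert not results["subtle"].passed

    def test_sorted_by_p_then_fold_change(self):
        cohort = simulate_expression_cohort(
            SimulationConfig(n_genes=20, n_informative=5, seed=6))
        results = differential_genes(cohort.expression, cohort.labels)
        ps = [r.p_value for r in results]
        assert ps == sorted(ps)

    def test_null_matrix_passes_alpha_controlled_fraction(self):
        cohort = simulate_expression_cohort(
            SimulationConfig(n_genes=1000, n_informative=0, effect_size=0.0,
                             n_responders=10, n_nonresponders=10, seed=13))
        results = differential_genes(cohort.expression, cohort.labels,
                                     fc_cutoff=1.0, alpha=0.05)
        frac = np.mean([r.p_value < 0.05 for r in results])
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 1000)

    def test_benjamini_hochberg_is_more_conservative(self):
        cohort = simulate_expression_cohort(
            SimulationConfig(n_genes=100, n_informative=5, seed=21))
        raw = differential_genes(cohort.expression, cohort.labels)
        adj = differential_genes(cohort.expression, cohort.labels,
                                 benjamini_hochberg=True)
        assert sum(r.passed for r in adj) <= sum(r.passed for r in raw)


class TestComparativeCt:
    def _table(self):
        ct = pd.DataFrame({"s1": [22.0, 18.0, 20.0], "s2": [21.0, 19.0, 20.0]},
                          index=["T1", "T2", "PPIA"])
        return CtTable(ct=ct, housekeeping=("PPIA",))

    def test_closed_form_two_to_minus_delta_ct(self):
        rel = comparative_ct_normalize(self._table(), "PPIA")
        assert rel.data.loc["T1", "s1"] == pytest.approx(0.25)   # dCt = +2
        assert rel.data.loc["T2", "s1"] == pytest.approx(4.0)    # dCt = -2
        assert "PPIA" not in rel.gene_ids

    def test_target_with_reference_ct_is_unit(self):
        ct = pd.DataFrame({"s1": [20.0, 20.0], "s2": [23.5, 23.5]},
                          index=["T1", "PPIA"])
        rel = comparative_ct_normalize(CtTable(ct=ct, housekeeping=("PPIA",)), "PPIA")
        assert (rel.data.loc["T1"] == 1.0).all()

    def test_missing_reference_propagates_missing(self):
        ct = pd.DataFrame({"s1": [22.0, 20.0], "s2": [21.0, np.nan]},
                          index=["T1", "PPIA"])
        rel = comparative_ct_normalize(CtTable(ct=ct, housekeeping=("PPIA",)), "PPIA")
        assert np.isnan(rel.data.loc["T1", "s2"])
        assert rel.drop_incomplete_genes().n_genes == 0

    def test_unknown_reference_rejected(self):
        with pytest.raises(DomainError, match="GAPDH"):
            comparative_ct_normalize(self._table(), "GAPDH")

    def test_commutes_with_sample_subsetting(self):
        table = self._table()
        rel_then_subset = comparative_ct_normalize(table, "PPIA").subset_samples(["s2"])
        subset = CtTable(ct=table.ct[["s2"]], housekeeping=("PPIA",))
        subset_then_rel = comparative_ct_normalize(subset, "PPIA")
        pd.testing.assert_frame_equal(rel_then_subset.data, subset_then_rel.data)
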
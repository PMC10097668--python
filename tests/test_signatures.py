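"""Downsampled sum scores, rank-sum testing, BH adjustment."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from hspcflow import (DataError, GeneSet, GeneSetCollection, SimConfig,
                      UmiMatrix, bh_adjust, compare_scores, downsample,
                      exclusive_sets, score_cells, simulate_experiment,
                      wilcoxon_rank_sum)


def single_cell_matrix(counts: dict) -> UmiMatrix:
    genes = list(counts)
    col = np.array([[counts[g]] for g in genes])
    return UmiMatrix(counts=col, genes=genes, barcodes=["cell"])


class TestDownsample:
    def test_totals_are_min_depth_total(self, small_sim):
        _, matrix, _ = small_sim
        before = matrix.cell_totals()
        ds = downsample(matrix, depth=750, seed=0)
        assert np.array_equal(ds.cell_totals(), np.minimum(before, 750))

    def test_below_depth_cell_unchanged_and_flagged(self):
        m = single_cell_matrix({"a": 400, "b": 200})
        ds = downsample(m, depth=750, seed=0)
        assert (ds.counts != m.counts).nnz == 0
        assert bool(ds.cell_meta["below_depth"].iloc[0])

    def test_deterministic_given_seed(self, small_sim):
        _, matrix, _ = small_sim
        a = downsample(matrix, depth=750, seed=3)
        b = downsample(matrix, depth=750, seed=3)
        assert a.equals(b)

    def test_marginal_hypergeometric_mean(self):
        """A gene with 500 of 1000 UMIs downsampled to 750 keeps on
        average 750*500/1000 = 375, within 3 sigma over 200 seeds."""
        m = single_cell_matrix({"a": 500, "b": 300, "c": 150, "d": 50})
        n, depth = 1000, 750
        draws = np.array([
            downsample(m, depth=depth, seed=s).dense().ravel()
            for s in range(200)
        ])
        for j, k in enumerate([500, 300, 150, 50]):
            mean_expected = depth * k / n
            var = depth * (k / n) * (1 - k / n) * (n - depth) / (n - 1)
            sigma_mean = np.sqrt(var / 200)
            assert abs(draws[:, j].mean() - mean_expected) <= 3 * sigma_mean


class TestExclusiveSets:
    def _collection(self):
        return GeneSetCollection([
            GeneSet("S1", ("a", "b", "c")),
            GeneSet("S2", ("b", "c", "d")),
            GeneSet("S3", ("x", "y")),
        ])

    def test_difference_and_suffix(self):
        res = exclusive_sets(self._collection(), "S1", "S2")
        assert res.genes == ("a",)
        assert res.name == "S1_excl"

    def test_disjoint_sets_identity(self):
        res = exclusive_sets(self._collection(), "S1", "S3")
        assert res.genes == ("a", "b", "c")

    def test_empty_result_is_an_error(self):
        col = GeneSetCollection([GeneSet("S1", ("a",)), GeneSet("S2", ("a", "b"))])
        with pytest.raises(DataError):
            exclusive_sets(col, "S1", "S2")

    def test_default_overlap_structure_leaves_25_genes(self):
        from hspcflow import make_gene_sets
        from hspcflow.synthdata import IFNA, IFNG
        sets = make_gene_sets(SimConfig(), seed=0)
        excl = exclusive_sets(sets, IFNA, IFNG)
        assert len(excl) == 25


class TestScoreCells:
    def test_sum_over_set_genes(self):
        m = single_cell_matrix({"a": 3, "b": 2, "c": 5})
        sets = GeneSetCollection([GeneSet("S", ("a", "c"))])
        table = score_cells(m, sets, depth=750)
        assert table.scores.loc["cell", "S"] == 8

    def test_missing_genes_contribute_zero(self):
        m = single_cell_matrix({"a": 0, "b": 2})
        sets = GeneSetCollection([GeneSet("S", ("a", "zzz"))])
        table = score_cells(m, sets, depth=750)
        assert table.scores.loc["cell", "S"] == 0

    def test_set_with_no_present_gene_is_an_error(self):
        m = single_cell_matrix({"a": 1})
        sets = GeneSetCollection([GeneSet("S", ("q", "r"))])
        with pytest.raises(DataError, match="S"):
            score_cells(m, sets, depth=750)

    def test_additive_over_disjoint_sets_and_monotone(self, small_sim):
        _, matrix, _ = small_sim
        ds = downsample(matrix, depth=750, seed=0)
        g = list(ds.genes[:30])
        sets = GeneSetCollection([
            GeneSet("A", tuple(g[:10])),
            GeneSet("B", tuple(g[10:30])),
            GeneSet("AB", tuple(g[:30])),
        ])
        t = score_cells(ds, sets, depth=750)
        assert (t.scores["AB"] == t.scores["A"] + t.scores["B"]).all()
        assert (t.scores["A"] <= t.scores["AB"]).all()
        # scores bounded by depth for at-depth cells
        at_depth = ~t.below_depth
        assert (t.scores.loc[at_depth, "AB"] <= 750).all()


class TestWilcoxonRankSum:
    def test_worked_exact_example(self):
        """x=[1,2] vs y=[3,4]: 2 of the 6 rank splits are as extreme."""
        _, p = wilcoxon_rank_sum([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3)

    def test_identical_groups_p_one(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(DataError):
            wilcoxon_rank_sum([], [1.0])

    def test_exact_matches_brute_force_enumeration(self):
        """DP-based exact p equals direct enumeration of all rank splits
        for a spread of tie-free group sizes."""
        for nx, ny in [(2, 2), (3, 5), (4, 4), (5, 3), (6, 6), (8, 7)]:
            n = nx + ny
            ranks = np.arange(1, n + 1)
            splits = list(itertools.combinations(range(n), nx))
            w_all = np.array([ranks[list(s)].sum() for s in splits])
            mu = nx * (n + 1) / 2.0
            for subset in splits[:: max(1, len(splits) // 20)]:
                x = ranks[list(subset)].astype(float)
                y = np.delete(ranks, list(subset)).astype(float)
                w = x.sum()
                expected = np.mean(np.abs(w_all - mu) >= abs(w - mu) - 1e-9)
                _, p = wilcoxon_rank_sum(x, y)
                assert p == pytest.approx(expected, abs=1e-12)

    def test_large_sample_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(size=40)
            y = rng.normal(0.3, size=55)
            u, p = wilcoxon_rank_sum(x, y)
            ref = scipy.stats.mannwhitneyu(x, y, alternative="two-sided",
                                           method="asymptotic")
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_type_i_error_calibrated(self):
        """Under the null, p < 0.05 happens about 5% of the time."""
        rng = np.random.default_rng(42)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            _, p = wilcoxon_rank_sum(x, y)
            rejections += p < 0.05
        rate = rejections / n_rep
        assert 0.03 <= rate <= 0.07


def bh_oracle(pvals):
    """Literal step-up definition with an explicit double loop."""
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    for pos, i in enumerate(order, start=1):
        q[i] = min(
            min(m * p[j] / (rank + 1)
                for rank, j in enumerate(order) if rank + 1 >= pos),
            1.0,
        )
    return q


class TestBhAdjust:
    def test_worked_example(self):
        q = bh_adjust([0.005, 0.01, 0.03, 0.04])
        assert np.allclose(q, [0.02, 0.02, 0.04, 0.04])

    def test_single_p_and_cap(self):
        assert bh_adjust([0.7])[0] == pytest.approx(0.7)
        assert np.all(bh_adjust([1.0, 1.0, 1.0]) == 1.0)

    def test_invalid_p_rejected(self):
        for bad in ([0.0, 0.5], [0.5, 1.2], [np.nan]):
            with pytest.raises(DataError):
                bh_adjust(bad)

    @given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=50))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_matches_brute_force_definition(self, pvals):
        assert np.allclose(bh_adjust(pvals), bh_oracle(pvals), atol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(3)
        p = rng.uniform(1e-6, 1, size=40)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(bh_adjust(p), ref)


class TestCompareScores:
    def _scored(self, seed=0, **cfg_kwargs):
        from hspcflow import filter_cells, make_gene_sets
        cfg = SimConfig(n_cells_per_condition=300, seed=seed, **cfg_kwargs)
        matrix, _ = simulate_experiment(cfg)
        kept, _ = filter_cells(matrix)
        ds = downsample(kept, depth=750, seed=seed)
        sets = make_gene_sets(cfg, cfg.seed)
        return score_cells(ds, sets, depth=750)

    def test_planted_il6_fold_detected(self):
        from hspcflow.synthdata import IL6
        table = self._scored(seed=1)
        results = compare_scores(table, focal="FBM_Mut")
        il6 = [r for r in results if r.set_name == IL6]
        assert len(il6) == 3
        assert all(r.q < 0.05 for r in il6)
        assert all(r.median_a > r.median_b for r in il6)

    def test_null_modules_mostly_quiet(self):
        """With no planted fold anywhere, nothing should be significant."""
        from hspcflow.synthdata import IL6
        table = self._scored(seed=2, module_fold={})
        results = compare_scores(table, focal="FBM_Mut")
        assert sum(r.q < 0.05 for r in results) == 0

    def test_single_comparison_q_equals_p(self, small_sim):
        table = self._scored(seed=3)
        sub = table.scores[[table.scores.columns[0]]]
        from hspcflow.signatures import ScoreTable
        one = ScoreTable(scores=sub, condition=table.condition,
                         below_depth=table.below_depth, depth=table.depth)
        res = compare_scores(one, comparisons=[("FBM_Mut", "NBM_WT")])
        assert res[0].q == pytest.approx(res[0].p)

    def test_too_few_cells_rejected(self, tiny_matrix):
        sets = GeneSetCollection([GeneSet("S", ("g1",))])
        table = score_cells(tiny_matrix, sets, depth=750)
        with pytest.raises(DataError):
            compare_scores(table, focal="A", include_below_depth=True)
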
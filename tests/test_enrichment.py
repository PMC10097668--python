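"""Fold-change ranking and preranked GSEA against brute-force oracles."""

import numpy as np
import pytest
import scipy.stats

from hspcflow import (DataError, GeneSet, GeneSetCollection, RankedList,
                      enrichment_score, gsea_preranked, rank_by_fold_change)
from hspcflow.matrix import UmiMatrix


def es_oracle(metric, hit_mask, exponent=1.0):
    """Independent running-sum oracle: explicit python loop."""
    n = len(metric)
    n_hits = int(np.sum(hit_mask))
    weights = [abs(m) ** exponent for m in metric]
    denom = sum(w for w, h in zip(weights, hit_mask) if h)
    running, best, cum = [], 0.0, 0.0
    for i in range(n):
        if hit_mask[i]:
            cum += weights[i] / denom
        else:
            cum -= 1.0 / (n - n_hits)
        running.append(cum)
        if abs(cum) > abs(best):
            best = cum
    return best


def ranked_from_metric(metric, prefix="g"):
    order = np.argsort(-np.asarray(metric), kind="stable")
    genes = tuple(f"{prefix}{i}" for i in range(len(metric)))
    return RankedList(genes=tuple(np.asarray(genes)[order]),
                      metric=np.asarray(metric, dtype=float)[order])


class TestRankByFoldChange:
    def _matrix(self):
        counts = np.array([
            [4, 4, 2, 2],   # up in first two cells
            [1, 1, 1, 1],   # flat
            [2, 2, 4, 4],   # down
            [3, 3, 3, 3],   # flat
        ])
        return UmiMatrix(counts=counts, genes=["up", "flatA", "down", "flatB"],
                         barcodes=[f"c{i}" for i in range(4)])

    def test_log_ratio_sign_and_order(self):
        m = self._matrix()
        ranked = rank_by_fold_change(m, [True, True, False, False],
                                     pseudocount=1e-6, center="none")
        assert ranked.genes[0] == "up" and ranked.genes[-1] == "down"
        assert ranked.metric[0] == pytest.approx(1.0, abs=1e-5)
        # flat genes sit at zero, ties broken by name
        assert ranked.genes[1:3] == ("flatA", "flatB")
        assert ranked.metric[1] == pytest.approx(0.0, abs=1e-5)

    def test_swapping_groups_negates_metric(self):
        m = self._matrix()
        fwd = rank_by_fold_change(m, [True, True, False, False], center="none")
        rev = rank_by_fold_change(m, [False, False, True, True], center="none")
        fwd_map = dict(zip(fwd.genes, fwd.metric))
        rev_map = dict(zip(rev.genes, rev.metric))
        for g in fwd_map:
            assert rev_map[g] == pytest.approx(-fwd_map[g])

    def test_median_centering_zeroes_unchanged_genes(self):
        m = self._matrix()
        ranked = rank_by_fold_change(m, [True, True, False, False],
                                     pseudocount=1e-6)
        centered = dict(zip(ranked.genes, ranked.metric))
        assert centered["flatA"] == pytest.approx(0.0, abs=1e-5)

    def test_empty_group_rejected(self):
        with pytest.raises(DataError):
            rank_by_fold_change(self._matrix(), [True] * 4)


class TestEnrichmentScore:
    def test_top_gene_set_scores_plus_one(self):
        ranked = ranked_from_metric([3.0, 2.0, 1.0])
        es, running = enrichment_score(ranked, GeneSet("S", (ranked.genes[0],)))
        assert es == pytest.approx(1.0)
        assert running[0] == pytest.approx(1.0)

    def test_bottom_gene_set_scores_minus_one(self):
        ranked = ranked_from_metric([3.0, 2.0, 1.0])
        es, running = enrichment_score(ranked, GeneSet("S", (ranked.genes[-1],)))
        assert es == pytest.approx(-1.0)
        assert np.allclose(running, [-0.5, -1.0, 0.0])

    def test_es_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(5, 60))
            ranked = ranked_from_metric(rng.normal(size=n))
            size = int(rng.integers(1, n))
            members = tuple(rng.choice(ranked.genes, size=size, replace=False))
            es, _ = enrichment_score(ranked, GeneSet("S", members))
            assert -1.0 <= es <= 1.0

    def test_improper_subset_rejected(self):
        ranked = ranked_from_metric([2.0, 1.0])
        with pytest.raises(DataError):
            enrichment_score(ranked, GeneSet("S", ranked.genes))

    def test_matches_brute_force_oracle(self):
        """500 random (ranking, set) instances agree with the explicit
        python-loop running sum to 1e-9."""
        rng = np.random.default_rng(7)
        for _ in range(500):
            n = int(rng.integers(10, 150))
            ranked = ranked_from_metric(rng.normal(size=n))
            size = int(rng.integers(1, n))
            members = set(rng.choice(ranked.genes, size=size, replace=False))
            hit = [g in members for g in ranked.genes]
            es, _ = enrichment_score(ranked, GeneSet("S", tuple(members)))
            assert es == pytest.approx(es_oracle(ranked.metric, hit), abs=1e-9)

    def test_exponent_zero_reduces_to_ks_statistic(self):
        """With p=0 the |ES| equals the two-sample KS distance between
        hit and miss rank positions."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(20, 100))
            ranked = ranked_from_metric(rng.normal(size=n))
            size = int(rng.integers(2, n - 1))
            members = set(rng.choice(ranked.genes, size=size, replace=False))
            es, _ = enrichment_score(ranked, GeneSet("S", tuple(members)),
                                     exponent=0.0)
            positions = np.arange(n)
            hits = positions[[g in members for g in ranked.genes]]
            misses = positions[[g not in members for g in ranked.genes]]
            ks = scipy.stats.ks_2samp(hits, misses).statistic
            assert abs(es) == pytest.approx(ks, abs=1e-9)


class TestGseaPreranked:
    def _random_collection(self, ranked, n_sets, size, rng):
        sets = []
        for i in range(n_sets):
            members = rng.choice(ranked.genes, size=size, replace=False)
            sets.append(GeneSet(f"set{i}", tuple(members)))
        return GeneSetCollection(sets)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        ranked = ranked_from_metric(rng.normal(size=300))
        col = self._random_collection(ranked, 5, 20, rng)
        a = gsea_preranked(ranked, col, n_perm=200, seed=5)
        b = gsea_preranked(ranked, col, n_perm=200, seed=5)
        assert a.equals(b)

    def test_planted_top_set_detected(self):
        """The set of the top 50 genes of a strong-signal ranking gets a
        positive NES and q < 0.2."""
        rng = np.random.default_rng(1)
        detected = 0
        for seed in range(10):
            metric = np.sort(rng.normal(size=400))[::-1] + 1e-3
            ranked = ranked_from_metric(metric, prefix=f"s{seed}_")
            top = GeneSet("top", ranked.genes[:50])
            decoys = [
                GeneSet(f"d{i}", tuple(rng.choice(ranked.genes[50:], 50,
                                                  replace=False)))
                for i in range(4)
            ]
            res = gsea_preranked(ranked, GeneSetCollection([top] + decoys),
                                 n_perm=500, seed=seed)
            detected += (res.loc["top", "nes"] > 0) and (res.loc["top", "q"] < 0.2)
        assert detected >= 9

    def test_sign_consistency_and_p_floor(self):
        rng = np.random.default_rng(2)
        ranked = ranked_from_metric(rng.normal(size=200))
        col = self._random_collection(ranked, 10, 15, rng)
        res = gsea_preranked(ranked, col, n_perm=100, seed=0)
        assert np.all(np.sign(res["nes"]) == np.sign(res["es"]))
        assert (res["p"] >= 1.0 / (100 + 1)).all()

    def test_small_sets_skipped_with_remaining_results(self):
        rng = np.random.default_rng(3)
        ranked = ranked_from_metric(rng.normal(size=100))
        col = GeneSetCollection([
            GeneSet("tiny", ranked.genes[:2]),
            GeneSet("ok", ranked.genes[5:25]),
        ])
        res = gsea_preranked(ranked, col, n_perm=100, seed=0)
        assert list(res.index) == ["ok"]

    def test_empty_collection_rejected(self):
        ranked = ranked_from_metric([1.0, 0.5, -0.5])
        with pytest.raises(Exception):
            gsea_preranked(ranked, GeneSetCollection([]), n_perm=10, seed=0)
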
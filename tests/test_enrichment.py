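"""Sylamer landscapes, eCDF/K-S shift test and pre-ranked enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from seedtox.alphabet import all_kmers
from seedtox.enrichment import (
    RankedGeneList,
    ecdf_ks,
    preranked_es,
    sylamer_landscape,
)
from seedtox.seedmatch import build_match_index, count_word


def _random_index(rng, n_genes=20, length=120):
    seqs = {
        f"g{i:03d}": "".join(rng.choice(list("ACGU"), size=length))
        for i in range(n_genes)
    }
    return seqs, build_match_index(seqs, words=all_kmers(6))


def _ranked(genes):
    return RankedGeneList(list(genes), np.arange(len(genes), dtype=float))


class TestSylamer:
    def test_full_list_cutoff_is_zero_for_every_word(self):
        rng = np.random.default_rng(1)
        seqs, idx = _random_index(rng, n_genes=12)
        ranked = _ranked(seqs)
        land = sylamer_landscape(ranked, idx, step=len(seqs))
        assert np.allclose(land.values[len(seqs)].to_numpy(), 0.0)

    def test_cells_match_direct_hypergeometric_oracle(self):
        rng = np.random.default_rng(2)
        seqs, idx = _random_index(rng, n_genes=15, length=90)
        ranked = _ranked(seqs)
        land = sylamer_landscape(ranked, idx, step=5)
        genes = ranked.genes
        for t in land.cutoffs:
            lead = genes[:t]
            n = sum(len(seqs[g]) - 5 for g in lead)
            N = sum(len(s) - 5 for s in seqs.values())
            for word in ["GCCCCC", "AAAAAA", "ACGUAC"]:
                x = sum(count_word(seqs[g], word)[0] for g in lead)
                K = sum(count_word(s, word)[0] for s in seqs.values())
                if x >= n * K / N:
                    expected = -np.log10(stats.hypergeom.sf(x - 1, N, K, n))
                else:
                    expected = np.log10(stats.hypergeom.cdf(x, N, K, n))
                if t == len(genes):
                    expected = 0.0
                assert land.values.loc[word, t] == pytest.approx(
                    expected, abs=1e-10
                )

    def test_planted_signal_attains_maximum_above_bonferroni(self):
        rng = np.random.default_rng(3)
        seqs = {}
        for i in range(200):
            s = "".join(rng.choice(list("ACGU"), size=200))
            s = s.replace("GCCCCC", "GCACCC")
            if i < 50:  # most-downregulated genes carry 3 planted matches
                s = "GCCCCC" + s[6:60] + "GCCCCC" + s[66:120] + "GCCCCC" + s[126:]
            seqs[f"g{i:03d}"] = s
        idx = build_match_index(seqs, words=all_kmers(6))
        ranked = _ranked(seqs)
        land = sylamer_landscape(ranked, idx, step=25)
        word, peak = land.max_word()
        assert word == "GCCCCC"
        assert peak > land.bonferroni_threshold

    def test_bonferroni_threshold_value(self):
        rng = np.random.default_rng(4)
        seqs, idx = _random_index(rng, n_genes=8)
        land = sylamer_landscape(_ranked(seqs), idx, step=4)
        assert land.bonferroni_threshold == pytest.approx(-np.log10(0.05 / 4096))

    def test_reversal_antisymmetry(self):
        rng = np.random.default_rng(5)
        seqs, idx = _random_index(rng, n_genes=10, length=100)
        ranked = _ranked(seqs)
        step = 2
        land = sylamer_landscape(ranked, idx, step=step)
        land_rev = sylamer_landscape(ranked.reversed(), idx, step=step)
        n = len(ranked)
        for t in range(step, n, step):
            mirrored = n - t
            if mirrored in land_rev.values.columns and mirrored > 0:
                a = land.values[t].to_numpy()
                b = land_rev.values[mirrored].to_numpy()
                # leading t of the forward list is the complement of the
                # leading n-t of the reversed list: enrichment flips sign
                assert np.allclose(a, -b, atol=1e-9)

    def test_bad_step_rejected(self):
        rng = np.random.default_rng(6)
        seqs, idx = _random_index(rng, n_genes=5)
        with pytest.raises(ValueError):
            sylamer_landscape(_ranked(seqs), idx, step=0)
        with pytest.raises(ValueError):
            sylamer_landscape(_ranked(seqs), idx, step=99)


class TestECDF:
    def test_identical_vectors(self):
        res = ecdf_ks([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.D == 0.0
        assert res.p == 1.0

    def test_complete_separation(self):
        res = ecdf_ks([-3.0, -2.0, -1.0], [1.0, 2.0, 3.0])
        assert res.D == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ecdf_ks([], [1.0])

    def test_p_matches_exhaustive_labeling_enumeration(self):
        # 4-vs-4: p = fraction of C(8,4) relabelings with D+ at least as large
        rng = np.random.default_rng(7)
        for _ in range(10):
            pool = rng.normal(size=8)
            a, b = pool[:4], pool[4:]
            res = ecdf_ks(a, b)
            count = total = 0
            for pick in itertools.combinations(range(8), 4):
                mask = np.zeros(8, bool)
                mask[list(pick)] = True
                d = _dplus_double_loop(pool[mask], pool[~mask])
                count += d >= res.D - 1e-12
                total += 1
            assert res.p == pytest.approx(count / total, abs=1e-12)

    def test_D_matches_double_loop_supremum(self):
        rng = np.random.default_rng(8)
        for n, m in [(10, 15), (50, 50), (100, 37)]:
            a = rng.normal(-0.3, 1, n)
            b = rng.normal(0.0, 1, m)
            res = ecdf_ks(a, b)
            assert res.D == pytest.approx(_dplus_double_loop(a, b), abs=1e-12)


def _dplus_double_loop(a, b):
    """sup_x [ECDF_a(x) - ECDF_b(x)] by brute force over all data points."""
    best = -np.inf
    for x in np.concatenate([a, b]):
        fa = sum(v <= x for v in a) / len(a)
        fb = sum(v <= x for v in b) / len(b)
        best = max(best, fa - fb)
    return best


class TestPrerankedES:
    def test_boundary_closed_form_at_weight_zero(self):
        genes = [f"g{i}" for i in range(50)]
        ranked = RankedGeneList(genes, np.linspace(-3, 3, 50))
        for m in [5, 10, 25]:
            res = preranked_es(ranked, set(genes[:m]), weight_exponent=0.0,
                               n_perm=10, rng_seed=1)
            assert res.ES == pytest.approx(1 - m / 50)

    def test_whole_list_gene_set_rejected(self):
        genes = [f"g{i}" for i in range(10)]
        ranked = RankedGeneList(genes, np.arange(10.0))
        with pytest.raises(ValueError):
            preranked_es(ranked, set(genes))

    def test_disjoint_gene_set_rejected(self):
        ranked = RankedGeneList(["a", "b"], np.array([0.0, 1.0]))
        with pytest.raises(ValueError):
            preranked_es(ranked, {"zz"})

    def test_permutation_p_bounds_and_reproducibility(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(100)]
        ranked = RankedGeneList(genes, rng.normal(size=100))
        gene_set = set(rng.choice(genes, 20, replace=False))
        r1 = preranked_es(ranked, gene_set, n_perm=200, rng_seed=5)
        r2 = preranked_es(ranked, gene_set, n_perm=200, rng_seed=5)
        assert r1.ES == r2.ES and r1.p_perm == r2.p_perm
        assert 1 / 201 <= r1.p_perm <= 1.0
        assert -1.0 <= r1.ES <= 1.0

    def test_invariant_to_gene_relabeling(self):
        rng = np.random.default_rng(10)
        stats_ = rng.normal(size=60)
        genes = [f"g{i}" for i in range(60)]
        ranked = RankedGeneList(genes, stats_)
        members = set(genes[10:25])
        relabel = {g: f"x{g}" for g in genes}
        ranked2 = RankedGeneList([relabel[g] for g in genes], stats_)
        members2 = {relabel[g] for g in members}
        a = preranked_es(ranked, members, n_perm=50, rng_seed=3)
        b = preranked_es(ranked2, members2, n_perm=50, rng_seed=3)
        assert a.ES == b.ES


class TestRankedGeneList:
    def test_stable_tie_break_by_gene_id(self):
        table = pd.DataFrame(
            {"gene": ["b", "a", "c"], "log2FC": [0.0, 0.0, -1.0]}
        )
        ranked = RankedGeneList.from_table(table)
        assert ranked.genes == ["c", "a", "b"]

    def test_duplicate_genes_rejected(self):
        table = pd.DataFrame({"gene": ["a", "a"], "log2FC": [0.0, 1.0]})
        with pytest.raises(ValueError):
            RankedGeneList.from_table(table)
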
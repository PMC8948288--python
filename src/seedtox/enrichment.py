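"""Seed-match enrichment over ranked gene lists.

Three complementary views of miRNA-like target engagement:

* ``sylamer_landscape`` — for a gene list ranked from most down- to most
  up-regulated, slide a cutoff along the list and, at each cutoff, test
  every k-mer for over/under-representation in the leading genes' sequence
  windows with a hypergeometric tail test. A seed-mediated knockdown shows
  up as the seed-match word towering over the Bonferroni line (m = 4^k) at
  early cutoffs.
* ``ecdf_ks`` — compare the log-fold-change ECDFs of genes with vs without
  a seed match in their 3' UTR by a one-sided two-sample Kolmogorov-Smirnov
  test; a leftward shift of the with-group indicates repression.
* ``preranked_es`` — weighted Kolmogorov-Smirnov-style running-sum
  enrichment score of a gene set in a ranked list, with a gene-label
  permutation p-value.

The hypergeometric dialect is occurrence-based with no Markov background
correction and no sequence trimming (configurable via ``dialect``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .seedmatch import SeedMatchIndex


@dataclass
class RankedGeneList:
    """Genes ordered by a ranking statistic (default logFC ascending).

    Most-downregulated first. Ties are broken by (statistic, gene id)
    with a stable sort, so the order is deterministic.
    """

    genes: list[str]
    statistic: np.ndarray

    @classmethod
    def from_table(
        cls,
        table: pd.DataFrame,
        gene_col: str = "gene",
        stat_col: str = "log2FC",
        ascending: bool = True,
    ) -> "RankedGeneList":
        if table[gene_col].duplicated().any():
            dup = table.loc[table[gene_col].duplicated(), gene_col].iloc[0]
            raise ValueError(f"duplicate gene {dup!r} in ranked table")
        t = table.sort_values(
            [stat_col, gene_col], ascending=[ascending, True], kind="mergesort"
        )
        return cls(list(t[gene_col]), t[stat_col].to_numpy(dtype=float))

    def __post_init__(self) -> None:
        self.statistic = np.asarray(self.statistic, dtype=float)
        if len(self.genes) != self.statistic.size:
            raise ValueError("genes and statistic differ in length")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in ranked list")

    def __len__(self) -> int:
        return len(self.genes)

    def reversed(self) -> "RankedGeneList":
        return RankedGeneList(self.genes[::-1], self.statistic[::-1])


@dataclass
class EnrichmentLandscape:
    """Signed -log10 hypergeometric p per word per leading-set cutoff."""

    cutoffs: np.ndarray
    values: pd.DataFrame  # rows = words, columns = cutoffs
    bonferroni_threshold: float
    n_words_tested: int

    def max_word(self) -> tuple[str, float]:
        """Word attaining the landscape maximum and its peak value."""
        peaks = self.values.max(axis=1)
        word = peaks.idxmax()
        return word, float(peaks.loc[word])

    def to_tsv(self, path: str | Path, top: int | None = None) -> None:
        v = self.values
        if top is not None:
            v = v.loc[v.max(axis=1).nlargest(top).index]
        v.rename_axis("word").to_csv(path, sep="\t")


@dataclass
class ECDFResult:
    D: float
    p: float
    n_with: int
    n_without: int


@dataclass
class ESResult:
    ES: float
    p_perm: float
    n_perm: int
    rng_seed: int
    hits: int = 0


def _signed_log10_hypergeom(x: np.ndarray, K: np.ndarray, n: int, N: int) -> np.ndarray:
    """Signed -log10 tail p for draws x of K successes, n draws from N.

    Positive when over-represented (x above expectation, upper tail),
    negative when under-represented (lower tail).
    """
    x = np.asarray(x)
    K = np.asarray(K)
    expected = n * K / N
    over = x >= expected
    # upper tail P(X >= x), lower tail P(X <= x)
    p_over = stats.hypergeom.sf(x - 1, N, K, n)
    p_under = stats.hypergeom.cdf(x, N, K, n)
    with np.errstate(divide="ignore"):
        out = np.where(over, -np.log10(p_over), np.log10(p_under))
    # whole-population (or empty) draws carry no information
    if n == 0 or n == N:
        out = np.zeros_like(out, dtype=float)
    return out


def sylamer_landscape(
    ranked: RankedGeneList,
    index: SeedMatchIndex,
    k: int = 6,
    step: int = 100,
    alpha: float = 0.05,
) -> EnrichmentLandscape:
    """Hypergeometric k-mer enrichment along a ranked gene list.

    At each cutoff t the leading set is the first t genes. For each word w
    the test draws n = total k-windows in the leading genes from a
    population of N windows overall, with K = total occurrences of w
    overall, observing x = occurrences of w in the leading genes. The
    Bonferroni line is -log10(alpha / number of words tested).

    Genes in the ranked list but absent from the index are dropped with a
    warning; the index must have been built over all words of length k for
    window conservation to hold.
    """
    if step <= 0 or step > len(ranked):
        raise ValueError(f"step must be in 1..{len(ranked)}, got {step}")
    if index.k != k:
        raise ValueError(f"index holds {index.k}-mers, requested k={k}")
    in_index = set(index.genes)
    kept = [g for g in ranked.genes if g in in_index]
    if len(kept) < len(ranked):
        import warnings

        warnings.warn(
            f"{len(ranked) - len(kept)} ranked genes lack sequences and were dropped",
            stacklevel=2,
        )
    counts = index.counts_matrix().loc[kept]  # genes x words, ranked order
    windows = index.window_totals().loc[kept].to_numpy()
    n_genes = len(kept)
    cutoffs = np.arange(step, n_genes, step)
    cutoffs = np.append(cutoffs, n_genes)
    cum_counts = np.cumsum(counts.to_numpy(), axis=0)  # genes x words
    cum_windows = np.cumsum(windows)
    K = cum_counts[-1]  # total occurrences per word
    N = int(cum_windows[-1])  # total windows
    m = counts.shape[1]
    values = np.zeros((m, cutoffs.size))
    for j, t in enumerate(cutoffs):
        x = cum_counts[t - 1]
        n = int(cum_windows[t - 1])
        values[:, j] = _signed_log10_hypergeom(x, K, n, N)
    threshold = -np.log10(alpha / m)
    return EnrichmentLandscape(
        cutoffs=cutoffs,
        values=pd.DataFrame(values, index=counts.columns, columns=cutoffs),
        bonferroni_threshold=float(threshold),
        n_words_tested=m,
    )


def ecdf_ks(
    logfc_with: Sequence[float], logfc_without: Sequence[float]
) -> ECDFResult:
    """One-sided two-sample K-S shift test (alternative = "greater").

    Tests whether seed-match-containing genes are shifted toward *lower*
    logFC (more downregulated) than genes without a match: the alternative
    is that the with-group ECDF lies above the without-group ECDF. Exact p
    for small samples, asymptotic otherwise.
    """
    a = np.asarray(logfc_with, dtype=float)
    b = np.asarray(logfc_without, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both gene groups must be non-empty")
    method = "exact" if a.size * b.size <= 10_000 else "asymp"
    res = stats.ks_2samp(a, b, alternative="greater", method=method)
    return ECDFResult(float(res.statistic), float(res.pvalue), a.size, b.size)


def preranked_es(
    ranked: RankedGeneList,
    gene_set: set[str] | Sequence[str],
    weight_exponent: float = 1.0,
    n_perm: int = 1000,
    rng_seed: int = 0,
) -> ESResult:
    """Pre-ranked running-sum enrichment score with a permutation p-value.

    Hits increment the running sum by their normalized weight
    |statistic|^weight_exponent / sum-of-hit-weights while every list
    position decrements uniformly by 1/N, so the running sum is a bridge
    from 0 to 0 and ES (its extreme deviation) lies in [-1, 1]; at weight 0
    this is the classical Kolmogorov-Smirnov statistic of the hit ranks
    against uniform. The p-value permutes gene labels (random sets of the
    same size), counting permutation ES at least as extreme in the same
    direction, with a +1 correction: p in [1/(n_perm+1), 1].
    """
    gene_set = set(gene_set)
    in_set = np.fromiter((g in gene_set for g in ranked.genes), bool, len(ranked))
    n_hits = int(in_set.sum())
    if n_hits == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if n_hits == len(ranked):
        raise ValueError(
            "gene set covers the entire ranked list; enrichment is undefined"
        )
    weights = np.abs(ranked.statistic) ** weight_exponent

    n_total = len(ranked)

    def score(mask: np.ndarray) -> float:
        total = weights[mask].sum()
        if total == 0:  # all-zero statistics: fall back to unweighted
            inc = np.where(mask, 1.0 / mask.sum(), 0.0)
        else:
            inc = np.where(mask, weights / total, 0.0)
        running = np.cumsum(inc) - np.arange(1, n_total + 1) / n_total
        return float(running[np.argmax(np.abs(running))])

    es = score(in_set)
    rng = np.random.default_rng(rng_seed)
    count = 0
    for _ in range(n_perm):
        perm = np.zeros(len(ranked), bool)
        perm[rng.choice(len(ranked), n_hits, replace=False)] = True
        es_p = score(perm)
        if (es >= 0 and es_p >= es) or (es < 0 and es_p <= es):
            count += 1
    p = (count + 1) / (n_perm + 1)
    return ESResult(es, float(p), n_perm, rng_seed, hits=n_hits)
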
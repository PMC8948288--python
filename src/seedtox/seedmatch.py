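"""Guide-strand seeds, seed matches and 6mer occurrence indexing.

A small-RNA guide strand silences through its *seed*, nucleotides 2-7 of the
guide read 5'->3'. The mRNA-side *seed match* is the reverse complement of
the seed, written 5'->3' (seed GGGGGC pairs with the match GCCCCC). This
module extracts seeds from (possibly chemically annotated) guide sequences,
maps seeds to matches, and counts/locates 6mer words in 3' UTR or ORF
sequences with the overlapping-window convention, so that the 4^k word
counts of a sequence always sum to len - k + 1.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .alphabet import (
    encode,
    kmer_window_ids,
    normalize_rna,
    reverse_complement,
    validate_word,
    word_id,
)

SEED_LENGTH = 6

# vendor-style chemical modification markup: r/m prefixes before each base
_MODIFICATION_RE = re.compile(r"[rm](?=[ACGUTacgut])")


@dataclass(frozen=True)
class GuideRNA:
    """A guide (antisense) strand, 5'->3', after modification stripping.

    ``antisense`` is stored in the RNA alphabet; DNA overhang letters (the
    trailing TT/AA of synthetic duplexes) are transcribed and retained —
    they lie outside seed positions 2-7 and are harmless.
    """

    antisense: str
    sense: str | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        raw = strip_modifications(self.antisense)
        if len(raw) < 8:
            raise ValueError(f"guide {self.name or raw!r} too short ({len(raw)} nt)")
        object.__setattr__(self, "antisense", validate_word(raw, name=self.name))
        if self.sense is not None:
            object.__setattr__(
                self, "sense", validate_word(strip_modifications(self.sense))
            )


def strip_modifications(seq: str) -> str:
    """Remove r/m chemistry prefixes from a vendor-format oligo string."""
    return _MODIFICATION_RE.sub("", seq.strip())


def extract_seed(guide: GuideRNA | str) -> str:
    """Seed = guide positions 2-7 (1-based, 5'->3')."""
    seq = guide.antisense if isinstance(guide, GuideRNA) else normalize_rna(
        strip_modifications(guide)
    )
    if len(seq) < 7:
        raise ValueError(f"guide of length {len(seq)} has no complete 2-7 seed")
    return validate_word(seq[1:7], SEED_LENGTH)


def seed_to_match(seed: str) -> str:
    """mRNA-sense seed match: reverse complement of the seed, 5'->3'."""
    return reverse_complement(validate_word(seed, SEED_LENGTH))


def count_word(sequence: str, word: str) -> tuple[int, list[int]]:
    """Count overlapping occurrences of ``word``; 0-based start positions.

    Case-insensitive, T treated as U. Empty/short sequences give (0, []).
    """
    w = validate_word(word)
    seq = normalize_rna(sequence)
    k = len(w)
    if k == 0:
        raise ValueError("empty word")
    if len(seq) < k:
        return 0, []
    positions = []
    start = seq.find(w)
    while start != -1:
        positions.append(start)
        start = seq.find(w, start + 1)
    return len(positions), positions


class SeedMatchIndex:
    """Occurrence counts (and positions) of 6mer words per gene region.

    Holds, per gene: the region label (3UTR/ORF), region length, and a
    genes x words count matrix over the requested word set. Positions are
    recomputed on demand from the stored sequences.
    """

    def __init__(
        self,
        sequences: Mapping[str, str],
        words: Iterable[str],
        region: str = "3UTR",
        k: int = SEED_LENGTH,
    ) -> None:
        self.region = region
        self.k = k
        self.words = [validate_word(w, k) for w in words]
        if len(set(self.words)) != len(self.words):
            raise ValueError("duplicate words requested")
        self._sequences: dict[str, str] = {}
        for gene, seq in sequences.items():
            if gene in self._sequences:
                raise ValueError(f"duplicate gene id {gene!r} after resolution")
            self._sequences[gene] = normalize_rna(seq)
        self.genes = list(self._sequences)
        self._word_col = {w: i for i, w in enumerate(self.words)}
        self._counts = np.zeros((len(self.genes), len(self.words)), dtype=np.int64)
        self._lengths = np.zeros(len(self.genes), dtype=np.int64)
        wanted = {word_id(w): self._word_col[w] for w in self.words}
        for i, gene in enumerate(self.genes):
            codes = encode(self._sequences[gene])
            self._lengths[i] = codes.size
            ids = kmer_window_ids(codes, k)
            if ids.size:
                uniq, cnt = np.unique(ids, return_counts=True)
                for u, c in zip(uniq, cnt):
                    col = wanted.get(int(u))
                    if col is not None:
                        self._counts[i, col] = c
        self._row = {g: i for i, g in enumerate(self.genes)}

    # -- queries -----------------------------------------------------------
    def count(self, gene: str, word: str) -> int:
        return int(self._counts[self._row[gene], self._word_col[validate_word(word, self.k)]])

    def positions(self, gene: str, word: str) -> list[int]:
        return count_word(self._sequences[gene], word)[1]

    def length(self, gene: str) -> int:
        return int(self._lengths[self._row[gene]])

    def sequence(self, gene: str) -> str:
        return self._sequences[gene]

    def counts_matrix(self) -> pd.DataFrame:
        """genes x words occurrence counts."""
        return pd.DataFrame(self._counts, index=self.genes, columns=self.words)

    def window_totals(self) -> pd.Series:
        """Number of k-windows (len - k + 1, floored at 0) per gene."""
        return pd.Series(np.maximum(self._lengths - self.k + 1, 0), index=self.genes)

    def genes_with_match(self, word: str) -> tuple[list[str], list[str]]:
        """Partition genes into (has >=1 occurrence, has none)."""
        col = self._word_col[validate_word(word, self.k)]
        mask = self._counts[:, col] > 0
        has = [g for g, m in zip(self.genes, mask) if m]
        has_not = [g for g, m in zip(self.genes, mask) if not m]
        return has, has_not

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, path: str | Path, *, with_positions: bool = True) -> None:
        rows = []
        for gene in self.genes:
            for w in self.words:
                c = self.count(gene, w)
                if c == 0:
                    continue
                pos = ",".join(map(str, self.positions(gene, w))) if with_positions else ""
                rows.append((gene, self.region, w, c, pos))
        pd.DataFrame(
            rows, columns=["gene", "region", "word", "count", "positions"]
        ).to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (id, sequence) from a (optionally gzipped) multi-line FASTA."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        header: str | None = None
        chunks: list[str] = []
        for line in handle:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    yield header, "".join(chunks)
                header = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
        if header is not None:
            yield header, "".join(chunks)


def resolve_isoforms(records: Iterable[tuple[str, str]]) -> dict[str, str]:
    """One region per gene: the longest sequence wins.

    Gene id = FASTA id up to the first '|' (Ensembl-style gene|transcript
    ids collapse to the gene).
    """
    best: dict[str, str] = {}
    for rid, seq in records:
        gene = rid.split("|")[0]
        if gene not in best or len(seq) > len(best[gene]):
            best[gene] = seq
    return best


def build_match_index(
    sequences: Mapping[str, str] | Iterable[tuple[str, str]] | str | Path,
    words: Iterable[str] | None = None,
    region: str = "3UTR",
    *,
    resolve: bool = False,
) -> SeedMatchIndex:
    """Index occurrence counts of ``words`` over a FASTA/mapping of regions.

    ``sequences`` may be a path to a FASTA file, an iterable of (id, seq)
    records, or a mapping. With ``resolve=True`` isoforms are collapsed to
    the longest sequence per gene; otherwise duplicate ids are an error.
    ``words`` defaults to the single analysis word GCCCCC.
    """
    if isinstance(sequences, (str, Path)):
        records: Iterable[tuple[str, str]] = read_fasta(sequences)
    elif isinstance(sequences, Mapping):
        records = sequences.items()
    else:
        records = sequences
    if resolve:
        seqs: Mapping[str, str] = resolve_isoforms(records)
    else:
        seqs = {}
        for rid, seq in records:
            if rid in seqs:
                raise ValueError(f"duplicate gene id {rid!r} after resolution")
            seqs[rid] = seq
    if words is None:
        words = ["GCCCCC"]
    return SeedMatchIndex(seqs, words, region=region)
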
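"""Target-gene nomination from differential-expression tables.

Filters a DE table (gene, baseMean, log2FC, adjP, joined seed-match
counts) down to highly expressed, significantly deregulated, seed-match
containing candidates; compares match counts between the most and least
downregulated candidates; and picks unchanged, match-free control genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .seedmatch import SeedMatchIndex

DE_COLUMNS = ["gene", "baseMean", "log2FC", "adjP"]


@dataclass
class TargetSet:
    """Filtered candidate genes ordered by log2FC ascending.

    ``provenance`` records each filter step's threshold and the row count
    surviving it (counts are non-increasing along the chain).
    """

    table: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return list(self.table["gene"])

    def __len__(self) -> int:
        return len(self.table)


def join_match_counts(de: pd.DataFrame, index: SeedMatchIndex, word: str) -> pd.DataFrame:
    """Attach a ``match_count`` column (0 for genes absent from the index)."""
    counts = index.counts_matrix()[index.words[0] if word is None else word]
    out = de.copy()
    out["match_count"] = out["gene"].map(counts).fillna(0).astype(int)
    return out


def _require_columns(de: pd.DataFrame, cols: Sequence[str]) -> None:
    for c in cols:
        if c not in de.columns:
            raise ValueError(f"DE table is missing required column {c!r}")


def filter_candidates(
    de: pd.DataFrame,
    min_base_mean: float = 1000.0,
    max_adjp: float = 0.05,
    min_abs_log2fc: float = 1.0,
    min_matches: int = 1,
    direction: str = "down",
) -> TargetSet:
    """Apply the target-nomination filter chain.

    Keeps rows with baseMean >= min_base_mean, adjP strictly < max_adjp,
    |log2FC| strictly > min_abs_log2fc in the requested direction
    (down / up / both) and match_count >= min_matches; the result is sorted
    by log2FC ascending (most downregulated first). Per-step surviving
    counts are recorded in provenance.
    """
    _require_columns(de, DE_COLUMNS + (["match_count"] if min_matches > 0 else []))
    if direction not in ("down", "up", "both"):
        raise ValueError(f"direction must be down/up/both, got {direction!r}")
    prov: dict = {
        "thresholds": {
            "min_base_mean": min_base_mean,
            "max_adjp": max_adjp,
            "min_abs_log2fc": min_abs_log2fc,
            "min_matches": min_matches,
            "direction": direction,
        },
        "counts": {"input": len(de)},
    }
    t = de[de["baseMean"] >= min_base_mean]
    prov["counts"]["base_mean"] = len(t)
    t = t[t["adjP"] < max_adjp]
    prov["counts"]["adjp"] = len(t)
    if direction == "down":
        t = t[t["log2FC"] < -min_abs_log2fc]
    elif direction == "up":
        t = t[t["log2FC"] > min_abs_log2fc]
    else:
        t = t[t["log2FC"].abs() > min_abs_log2fc]
    prov["counts"]["log2fc"] = len(t)
    if min_matches > 0:
        t = t[t["match_count"] >= min_matches]
    prov["counts"]["matches"] = len(t)
    t = t.sort_values(["log2FC", "gene"], kind="mergesort").reset_index(drop=True)
    return TargetSet(t, prov)


def top_bottom(targets: TargetSet | pd.DataFrame, n: int = 10) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Head/tail slices of a log2FC-ordered candidate table.

    Returns the n most downregulated and n least downregulated rows; they
    are disjoint, which requires at least 2n rows.
    """
    table = targets.table if isinstance(targets, TargetSet) else targets
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    if len(table) < 2 * n:
        raise ValueError(
            f"need at least {2 * n} candidates for disjoint top/bottom {n}, "
            f"have {len(table)}"
        )
    return table.head(n).copy(), table.tail(n).copy()


def compare_match_counts(
    top: pd.DataFrame | Sequence[float],
    bottom: pd.DataFrame | Sequence[float],
    equal_var: bool = True,
) -> tuple[float, float]:
    """Two-sample Student's t (Welch with equal_var=False) on match counts."""
    a = np.asarray(
        top["match_count"] if isinstance(top, pd.DataFrame) else top, dtype=float
    )
    b = np.asarray(
        bottom["match_count"] if isinstance(bottom, pd.DataFrame) else bottom,
        dtype=float,
    )
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 members")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def select_control_genes(
    de: pd.DataFrame, n: int = 5, min_norm_reads: float = 1000.0
) -> list[str]:
    """Unchanged control genes: highly expressed, zero seed matches.

    Among genes with baseMean > min_norm_reads and match_count == 0,
    returns the n genes with smallest |log2FC| (ties by gene id).
    """
    _require_columns(de, DE_COLUMNS + ["match_count"])
    eligible = de[(de["baseMean"] > min_norm_reads) & (de["match_count"] == 0)].copy()
    if len(eligible) < n:
        raise ValueError(
            f"only {len(eligible)} eligible control genes, need {n}"
        )
    eligible["abs_fc"] = eligible["log2FC"].abs()
    eligible = eligible.sort_values(["abs_fc", "gene"], kind="mergesort")
    return list(eligible["gene"].head(n))
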
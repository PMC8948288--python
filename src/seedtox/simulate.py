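"""Synthetic inputs with the statistical structure the analyses assume.

Three generators, each a pure function of its parameters and rng_seed:

* ``gen_screen`` — a 4096-seed arrayed viability screen. Expected
  viability of a seed decreases with its position-weighted G content
  (weights decay 5'->3', mimicking the empirical G-at-the-5'-end toxicity
  pattern) through a logistic map into [5%, 110%]. Wells carry
  multiplicative set effects and per-cell-line Gaussian viability noise;
  every set includes non-targeting control wells, so control-based
  normalization must recover the planted viabilities (exactly at zero
  noise).
* ``gen_transcriptome`` — 3' UTR sequences with a planted number of
  non-overlapping seed-match occurrences per gene, and a matching DE
  table where log2FC = -beta_match * match_count + noise; baseMean is
  log-normal and adjusted p-values come from a z-test with
  Benjamini-Hochberg correction.
* ``gen_logo_data`` — long-format positional nucleotide observations for
  two or more seed groups drawn from a multinomial logit with per-seed
  random effects, for mixed-model recovery tests.

All parameter values here are this package's own choices, set so the
planted effects are comfortably detectable at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .alphabet import RNA_ALPHABET, all_kmers, validate_word
from .logo import LOGO_COLUMNS
from .screen import WELL_COLUMNS
from .seedmatch import count_word


# ---------------------------------------------------------------------------
# screen generator
# ---------------------------------------------------------------------------

@dataclass
class ScreenGenerator:
    """Arrayed 6mer-seed screen with planted G-driven toxicity.

    ``position_weights`` score G content (decreasing 5'->3'); the weighted
    G score g(seed) maps through a logistic onto expected percent
    viability in [viability_floor, viability_ceiling]. ``cell_lines`` maps
    line name -> additive viability noise sd (percent). Seeds are split
    round-robin into ``n_sets`` sets per cell line, each with its own
    multiplicative luminescence set effect and ``controls_per_set``
    control wells; every seed is measured in ``n_replicates`` wells.
    """

    n_seeds: int = 4096
    cell_lines: Mapping[str, float] = field(
        default_factory=lambda: {"HLINE1": 4.0, "HLINE2": 4.0, "HLINE3": 4.0}
    )
    position_weights: Sequence[float] = (1.0, 0.9, 0.75, 0.55, 0.35, 0.2)
    logistic_midpoint: float = 1.8
    logistic_scale: float = 0.55
    viability_floor: float = 5.0
    viability_ceiling: float = 110.0
    n_sets: int = 3
    n_replicates: int = 3
    controls_per_set: int = 9
    control_name: str = "siNT1"
    base_luminescence: float = 1.0e6
    set_effect_sd: float = 0.25  # sd of log set effect
    rng_seed: int = 0

    def seeds(self) -> list[str]:
        return all_kmers(6)[: self.n_seeds]

    def g_score(self, seed: str) -> float:
        w = np.asarray(self.position_weights, dtype=float)
        isg = np.array([b == "G" for b in seed], dtype=float)
        return float(w @ isg)

    def expected_viability(self, seed: str) -> float:
        """Planted expected percent viability for a seed."""
        g = self.g_score(validate_word(seed, 6))
        lo, hi = self.viability_floor, self.viability_ceiling
        frac = 1.0 / (1.0 + np.exp((g - self.logistic_midpoint) / self.logistic_scale))
        return float(lo + (hi - lo) * frac)


def gen_screen(gen: ScreenGenerator | None = None) -> pd.DataFrame:
    """Emit raw well records for a synthetic screen (WellRecord columns)."""
    gen = gen or ScreenGenerator()
    rng = np.random.default_rng(gen.rng_seed)
    seeds = gen.seeds()
    expected = np.array([gen.expected_viability(s) for s in seeds])
    rows: list[tuple] = []
    for cell_line, noise_sd in gen.cell_lines.items():
        set_effects = np.exp(rng.normal(0.0, gen.set_effect_sd, gen.n_sets))
        for i, seed in enumerate(seeds):
            set_idx = i % gen.n_sets
            set_id = f"{cell_line}-S{set_idx + 1}"
            for rep in range(1, gen.n_replicates + 1):
                viab = expected[i]
                if noise_sd > 0:
                    viab = max(viab + rng.normal(0.0, noise_sd), 0.0)
                raw = gen.base_luminescence * set_effects[set_idx] * viab / 100.0
                rows.append(
                    (seed, cell_line, set_id, f"{set_id}-P{rep}", rep, raw, False, "")
                )
        for set_idx in range(gen.n_sets):
            set_id = f"{cell_line}-S{set_idx + 1}"
            for w in range(gen.controls_per_set):
                viab = 100.0
                if noise_sd > 0:
                    viab = max(viab + rng.normal(0.0, noise_sd), 0.0)
                raw = gen.base_luminescence * set_effects[set_idx] * viab / 100.0
                rows.append(
                    (
                        f"CTRL{w:02d}",
                        cell_line,
                        set_id,
                        f"{set_id}-P{w % gen.n_replicates + 1}",
                        w % gen.n_replicates + 1,
                        raw,
                        True,
                        gen.control_name,
                    )
                )
    return pd.DataFrame(rows, columns=WELL_COLUMNS)


# ---------------------------------------------------------------------------
# transcriptome generator
# ---------------------------------------------------------------------------

@dataclass
class TranscriptomeGenerator:
    """3' UTRs with planted seed matches and a matching DE table.

    Per gene the planted match count is 0 with probability
    ``p_no_match``, else 1 + Poisson(match_rate). log2FC =
    -beta_match * count + Normal(0, sigma); baseMean ~ LogNormal;
    adjP = BH-adjusted two-sided z-test p of log2FC / sigma.
    """

    n_genes: int = 1000
    word: str = "GCCCCC"
    utr_meanlog: float = float(np.log(500.0))
    utr_sdlog: float = 0.35
    utr_min: int = 60
    utr_max: int = 3000
    p_no_match: float = 0.6
    match_rate: float = 1.0
    beta_match: float = 1.0
    sigma: float = 0.5
    basemean_meanlog: float = float(np.log(800.0))
    basemean_sdlog: float = 1.2
    rng_seed: int = 0


def _plant_word(
    rng: np.random.Generator, length: int, word: str, count: int
) -> str:
    """Random sequence of ``length`` containing exactly ``count`` copies of
    ``word``, planted non-overlapping on a 6-nt block grid."""
    k = len(word)
    n_blocks = length // k
    if count > n_blocks:
        raise ValueError(
            f"UTR of length {length} too short for {count} planted {k}-mers"
        )
    letters = np.array(list(RNA_ALPHABET))
    blocks = rng.choice(n_blocks, size=count, replace=False) * k if count else np.array([], dtype=int)
    planted = set(int(b) for b in blocks)
    for _ in range(100):
        seq = list("".join(rng.choice(letters, size=length)))
        for b in planted:
            seq[b : b + k] = word
        s = "".join(seq)
        n, pos = count_word(s, word)
        extra = [p for p in pos if p not in planted]
        it = 0
        while extra and it < 200:
            it += 1
            for p in extra:
                # flip one letter of the unwanted occurrence that lies
                # outside every planted window
                for off in range(k):
                    idx = p + off
                    if not any(b <= idx < b + k for b in planted):
                        choices = [c for c in RNA_ALPHABET if c != s[idx]]
                        s = s[:idx] + str(rng.choice(choices)) + s[idx + 1 :]
                        break
            _, pos = count_word(s, word)
            extra = [q for q in pos if q not in planted]
        n, pos = count_word(s, word)
        if n == count and set(pos) == planted:
            return s
    raise RuntimeError("failed to plant word occurrences exactly")


def gen_transcriptome(
    gen: TranscriptomeGenerator | None = None,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Return ({gene: 3'UTR sequence}, DE table).

    The DE table has columns gene, baseMean, log2FC, adjP and match_count
    (the planted truth; ``build_match_index`` on the sequences reproduces
    it exactly).
    """
    gen = gen or TranscriptomeGenerator()
    rng = np.random.default_rng(gen.rng_seed)
    word = validate_word(gen.word, 6)
    lengths = np.clip(
        np.round(rng.lognormal(gen.utr_meanlog, gen.utr_sdlog, gen.n_genes)),
        gen.utr_min,
        gen.utr_max,
    ).astype(int)
    has_match = rng.random(gen.n_genes) >= gen.p_no_match
    counts = np.where(has_match, 1 + rng.poisson(gen.match_rate, gen.n_genes), 0)
    sequences: dict[str, str] = {}
    for i in range(gen.n_genes):
        gene = f"GENE{i:05d}"
        sequences[gene] = _plant_word(rng, int(lengths[i]), word, int(counts[i]))
    log2fc = -gen.beta_match * counts + rng.normal(0.0, gen.sigma, gen.n_genes)
    base_mean = rng.lognormal(gen.basemean_meanlog, gen.basemean_sdlog, gen.n_genes)
    z = log2fc / gen.sigma
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    adjp = _benjamini_hochberg(pvals)
    de = pd.DataFrame(
        {
            "gene": list(sequences),
            "baseMean": base_mean,
            "log2FC": log2fc,
            "adjP": adjp,
            "match_count": counts,
        }
    )
    return sequences, de


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# logo generator
# ---------------------------------------------------------------------------

@dataclass
class LogoGenerator:
    """Positional nucleotide draws from a multinomial logit with per-seed
    random effects.

    ``baseline_logits`` are the log-odds of (A, C, U) vs G in the baseline
    group (a 3-vector shared across positions, or a (6, 3) array);
    ``group_logor`` maps non-baseline group names to 3-vectors of
    additional log-odds. ``sigma_true`` is the 3x3 random-effect
    covariance (scalars/1-D arrays are promoted to diagonal).
    """

    baseline_group: str = "human"
    baseline_logits: Sequence[float] = (0.0, 0.0, 0.0)
    group_logor: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: {"mouse": (float(np.log(2.5)), 0.0, 0.0)}
    )
    n_seeds_per_group: int = 100
    sigma_true: float | Sequence[float] | np.ndarray = 0.25
    rng_seed: int = 0

    def sigma_matrix(self) -> np.ndarray:
        s = np.asarray(self.sigma_true, dtype=float)
        if s.ndim == 0:
            s = np.eye(3) * float(s)
        elif s.ndim == 1:
            s = np.diag(s)
        if s.shape != (3, 3):
            raise ValueError("sigma_true must be scalar, length-3 or 3x3")
        # symmetric PSD check
        if not np.allclose(s, s.T) or np.linalg.eigvalsh(s).min() < -1e-10:
            raise ValueError("sigma_true must be symmetric positive semidefinite")
        return s


def gen_logo_data(gen: LogoGenerator | None = None) -> pd.DataFrame:
    """Emit a long-format logo table (seed_id, group, position, nucleotide).

    Non-reference categories are ordered (A, C, U) with G as reference,
    matching the fitting module's convention.
    """
    gen = gen or LogoGenerator()
    rng = np.random.default_rng(gen.rng_seed)
    sigma = gen.sigma_matrix()
    base = np.asarray(gen.baseline_logits, dtype=float)
    if base.ndim == 1:
        base = np.tile(base, (6, 1))
    if base.shape != (6, 3):
        raise ValueError("baseline_logits must be a 3-vector or 6x3")
    cats = ["A", "C", "U"]  # non-reference order; reference G
    groups = [gen.baseline_group] + list(gen.group_logor)
    rows = []
    for group in groups:
        shift = np.zeros(3) if group == gen.baseline_group else np.asarray(
            gen.group_logor[group], dtype=float
        )
        for i in range(gen.n_seeds_per_group):
            sid = f"{group}:{i:05d}"
            b = rng.multivariate_normal(np.zeros(3), sigma) if sigma.any() else np.zeros(3)
            for pos in range(1, 7):
                eta = base[pos - 1] + shift + b
                w = np.exp(np.concatenate([[0.0], eta]))  # G first
                p = w / w.sum()
                draw = rng.choice(4, p=p)
                base_drawn = "G" if draw == 0 else cats[draw - 1]
                rows.append((sid, group, pos, base_drawn))
    return pd.DataFrame(rows, columns=LOGO_COLUMNS)
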
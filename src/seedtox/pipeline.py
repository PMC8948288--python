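"""End-to-end orchestration from a config file.

A run config (flat TOML) points at whichever inputs exist — a well-level
screen CSV, DE tables, a 3' UTR FASTA, gene-set files — plus the analysis
seed word and thresholds. ``run_pipeline`` executes every stage whose
inputs are present (screen -> logo comparison; DE + FASTA -> match index
-> enrichment -> target selection), writes per-stage outputs under the
output directory and returns a JSON-serializable report holding every
headline statistic and full provenance.
"""

from __future__ import annotations

import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .alphabet import all_kmers, validate_word
from .enrichment import RankedGeneList, ecdf_ks, preranked_es, sylamer_landscape
from .logo import GLMMSpec, fit_multinomial_glmm, group_odds_ratios, long_table_from_seeds, test_effect
from .screen import normalize_screen, nucleotide_composition, rank_seeds, read_wells
from .seedmatch import build_match_index, seed_to_match
from .targets import (
    compare_match_counts,
    filter_candidates,
    join_match_counts,
    select_control_genes,
    top_bottom,
)

log = logging.getLogger("seedtox.pipeline")

DEFAULTS: dict[str, Any] = {
    "seed": "GGGGGC",
    "control_name": "siNT1",
    "min_base_mean": 1000.0,
    "max_adjp": 0.05,
    "min_abs_log2fc": 1.0,
    "min_matches": 1,
    "top_n": 10,
    "n_controls": 5,
    "sylamer_step": 100,
    "n_perm": 1000,
    "rng_seed": 0,
    "logo_covariance": "diagonal",
    "top_group_size": 100,
}


class ConfigError(ValueError):
    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    screen_csv: Path | None = None
    de_csv: Path | None = None
    utr_fasta: Path | None = None
    gene_set: Path | None = None
    logo_groups: dict[str, Path] = field(default_factory=dict)
    out_dir: Path = Path("seedtox_out")
    params: dict[str, Any] = field(default_factory=lambda: dict(DEFAULTS))


def validate_config(path_or_dict: str | Path | dict) -> RunConfig:
    """Parse and validate a run config; raises ConfigError listing every
    violation (missing files, out-of-range thresholds)."""
    if isinstance(path_or_dict, dict):
        raw = path_or_dict
    else:
        with open(path_or_dict, "rb") as fh:
            raw = tomllib.load(fh)
    inputs = raw.get("inputs", {})
    analysis = raw.get("analysis", {})
    output = raw.get("output", {})
    errors: list[str] = []

    cfg = RunConfig()
    for key in ("screen_csv", "de_csv", "utr_fasta", "gene_set"):
        val = inputs.get(key)
        if val is not None:
            p = Path(val)
            if not p.exists():
                errors.append(f"inputs.{key}: path {p} does not exist")
            else:
                setattr(cfg, key, p)
    for group, val in inputs.get("logo_groups", {}).items():
        p = Path(val)
        if not p.exists():
            errors.append(f"inputs.logo_groups.{group}: path {p} does not exist")
        else:
            cfg.logo_groups[group] = p

    params = dict(DEFAULTS)
    params.update(analysis)
    ranges = {
        "max_adjp": (0.0, 1.0),
        "min_base_mean": (0.0, np.inf),
        "min_abs_log2fc": (0.0, np.inf),
        "min_matches": (0, np.inf),
        "top_n": (1, np.inf),
        "n_controls": (1, np.inf),
        "sylamer_step": (1, np.inf),
        "n_perm": (1, np.inf),
    }
    for key, (lo, hi) in ranges.items():
        v = params.get(key)
        if not (isinstance(v, (int, float)) and lo <= v <= hi):
            errors.append(f"analysis.{key}: value {v!r} outside [{lo}, {hi}]")
    try:
        params["seed"] = validate_word(str(params["seed"]), 6)
    except ValueError as exc:
        errors.append(f"analysis.seed: {exc}")
    cfg.params = params
    cfg.out_dir = Path(output.get("dir", cfg.out_dir))
    if not (cfg.screen_csv or cfg.de_csv or cfg.logo_groups):
        errors.append("no inputs given: need at least one of inputs.screen_csv, "
                      "inputs.de_csv, inputs.logo_groups")
    if errors:
        raise ConfigError(errors)
    log.info("effective config: %s", cfg)
    return cfg


def _stage_screen(cfg: RunConfig) -> dict:
    wells = read_wells(cfg.screen_csv)
    matrix = normalize_screen(wells, cfg.params["control_name"])
    ranking = rank_seeds(matrix)
    matrix.to_csv(cfg.out_dir / "screen_matrix.csv")
    ranking.to_csv(cfg.out_dir / "seed_ranking.csv")
    n_top = int(cfg.params["top_group_size"])
    comp_top = nucleotide_composition(ranking.seeds[:n_top])
    comp_top.counts.to_csv(cfg.out_dir / "composition_top.csv")
    out = {
        "n_seeds": len(ranking.seeds),
        "cell_lines": matrix.cell_lines,
        "most_toxic_seed": ranking.seeds[0],
        "toxicity_classes": ranking.table["toxicity_class"].value_counts().to_dict(),
    }
    seed = cfg.params["seed"]
    if seed in ranking.table["seed"].values:
        out["analysis_seed_rank"] = ranking.rank_of(seed)
    return out


def _stage_logo(cfg: RunConfig) -> dict:
    groups = {
        g: [line.strip() for line in Path(p).read_text().splitlines() if line.strip()]
        for g, p in cfg.logo_groups.items()
    }
    table = long_table_from_seeds(groups)
    spec = GLMMSpec(covariance=cfg.params["logo_covariance"])
    fit = fit_multinomial_glmm(table, spec)
    fit.coefficients_table().to_csv(cfg.out_dir / "logo_coefficients.csv", index=False)
    names = sorted(groups)
    out: dict[str, Any] = {
        "groups": names,
        "loglik": fit.loglik,
        "converged": fit.converged,
    }
    if len(names) >= 2:
        ors = group_odds_ratios(fit, names[1], names[0])
        out["odds_ratios"] = {
            nt: {k: float(v) for k, v in row.items()} for nt, row in ors.iterrows()
        }
        reduced = fit_multinomial_glmm(
            table, GLMMSpec(covariance=cfg.params["logo_covariance"],
                            include_interaction=False)
        )
        lr, df, p = test_effect(fit, reduced)
        out["interaction_test"] = {"LR": lr, "df": df, "p": p}
    return out


def _stage_targeting(cfg: RunConfig) -> dict:
    de = pd.read_csv(cfg.de_csv)
    seed = cfg.params["seed"]
    match = seed_to_match(seed)
    out: dict[str, Any] = {"seed": seed, "seed_match": match}
    index = build_match_index(cfg.utr_fasta, words=all_kmers(6), resolve=True)
    index_counts = index.counts_matrix()[match]
    de = join_match_counts(de, index, match)

    ranked = RankedGeneList.from_table(de)
    landscape = sylamer_landscape(
        ranked, index, step=int(cfg.params["sylamer_step"])
    )
    landscape.to_tsv(cfg.out_dir / "sylamer_landscape.tsv", top=20)
    word, peak = landscape.max_word()
    out["sylamer"] = {
        "max_word": word,
        "max_value": peak,
        "seed_match_peak": float(landscape.values.loc[match].max()),
        "bonferroni_threshold": landscape.bonferroni_threshold,
    }

    has, has_not = index.genes_with_match(match)
    de_idx = de.set_index("gene")["log2FC"]
    with_fc = de_idx[de_idx.index.isin(has)].to_numpy()
    without_fc = de_idx[de_idx.index.isin(has_not)].to_numpy()
    if with_fc.size and without_fc.size:
        ecdf = ecdf_ks(with_fc, without_fc)
        out["ecdf_ks"] = {
            "D": ecdf.D, "p": ecdf.p,
            "n_with": ecdf.n_with, "n_without": ecdf.n_without,
        }

    if cfg.gene_set is not None:
        genes = {
            line.strip()
            for line in Path(cfg.gene_set).read_text().splitlines()
            if line.strip()
        }
        es = preranked_es(
            ranked, genes,
            n_perm=int(cfg.params["n_perm"]),
            rng_seed=int(cfg.params["rng_seed"]),
        )
        out["preranked_es"] = {"ES": es.ES, "p_perm": es.p_perm, "hits": es.hits}

    targets = filter_candidates(
        de,
        min_base_mean=cfg.params["min_base_mean"],
        max_adjp=cfg.params["max_adjp"],
        min_abs_log2fc=cfg.params["min_abs_log2fc"],
        min_matches=int(cfg.params["min_matches"]),
    )
    targets.table.to_csv(cfg.out_dir / "target_candidates.csv", index=False)
    out["targets"] = {
        "provenance": targets.provenance,
        "n_candidates": len(targets),
    }
    n = int(cfg.params["top_n"])
    if len(targets) >= 2 * n:
        top, bottom = top_bottom(targets, n)
        t, p = compare_match_counts(top, bottom)
        out["targets"]["top_genes"] = list(top["gene"])
        out["targets"]["match_count_t_test"] = {"t": t, "p": p}
    try:
        out["control_genes"] = select_control_genes(
            de, n=int(cfg.params["n_controls"]),
            min_norm_reads=cfg.params["min_base_mean"],
        )
    except ValueError as exc:
        out["control_genes_error"] = str(exc)
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages with available inputs; returns the report dict.

    A stage failure raises ``StageError`` naming the stage; outputs of
    earlier stages are retained on disk.
    """
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "provenance": {
            "seedtox_version": __version__,
            "rng_seed": int(cfg.params["rng_seed"]),
            "thresholds": {
                k: cfg.params[k]
                for k in ("min_base_mean", "max_adjp", "min_abs_log2fc", "min_matches")
            },
            "seed": cfg.params["seed"],
        }
    }
    stages = []
    if cfg.screen_csv is not None:
        stages.append(("screen", _stage_screen))
    else:
        log.info("screen stage skipped: no screen_csv input")
    if cfg.logo_groups:
        stages.append(("logo", _stage_logo))
    else:
        log.info("logo stage skipped: no logo_groups input")
    if cfg.de_csv is not None and cfg.utr_fasta is not None:
        stages.append(("targeting", _stage_targeting))
    else:
        log.info("targeting stage skipped: needs both de_csv and utr_fasta")
    for name, fn in stages:
        log.info("running stage %s", name)
        try:
            report[name] = fn(cfg)
        except Exception as exc:
            raise StageError(name, exc) from exc
    with open(cfg.out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
    return report


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def _json_default(obj):
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
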
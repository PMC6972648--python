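"""End-to-end orchestration: simulate/load -> preprocess -> test -> call -> enrich.

A run starts either from a synthetic experiment (:class:`SimConfig`) or
from on-disk TSV/GMT inputs, executes the stages in a fixed order, writes
every intermediate table under the output directory, and returns a
machine-readable :class:`RunSummary`. A single global seed is fanned out to
per-stage child seeds so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np

from . import __version__
from .catalog import PhosphoCatalog
from .differential import DifferentialConfig, permutation_fdr, pca_scores, volcano_table
from .enrichment import TermAnnotation, deduplicate_hits, fisher_enrichment
from .matrix import IntensityMatrix, read_design, write_design
from .preprocess import (
    filter_valid_values,
    impute_downshifted_normal,
    local_regression_normalize,
    log2_transform,
)
from .proteome_norm import call_regulation_table, match_rows, normalize_against_protein
from .synthetic import SimConfig, generate_experiment, read_gmt, write_gmt

__all__ = ["RunConfig", "RunSummary", "run_pipeline", "percentage_report"]

logger = logging.getLogger(__name__)

# fixed per-stage offsets for fanning the global seed out
_STAGE_SEEDS = {"simulate": 0, "impute": 1, "test_phospho": 2, "test_adjusted": 3}


def _child_seed(seed: int, stage: str) -> int:
    return int(np.random.SeedSequence([seed, _STAGE_SEEDS[stage]]).generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Configuration of one pipeline run (synthetic or file-based)."""

    out_dir: str | Path = "phosdia_run"
    seed: int = 0
    sim: SimConfig | None = None
    phospho_path: str | Path | None = None
    proteome_path: str | Path | None = None
    catalog_path: str | Path | None = None
    design_path: str | Path | None = None
    gmt_path: str | Path | None = None
    differential: DifferentialConfig = field(default_factory=DifferentialConfig)
    min_valid_fraction: float = 0.7
    normalization_span: float = 0.4
    impute: bool = True
    impute_width: float = 0.3
    impute_downshift: float = 1.8
    enrichment_alpha: float = 0.05
    protein_change_threshold: float = 0.3

    def __post_init__(self) -> None:
        paths = [self.phospho_path, self.catalog_path, self.design_path]
        if self.sim is not None and any(p is not None for p in paths):
            raise ValueError("give either a SimConfig or input paths, not both")
        if self.sim is None and any(p is None for p in paths):
            raise ValueError("file-based runs need phospho, catalog and design paths")


@dataclass
class RunSummary:
    rows_in_catalog: int
    rows_quantified: int
    rows_after_filter: int
    rows_testable: int
    n_significant_peptides: int
    n_significant_groups: int
    n_significant_terms: int
    quantified_percent: int
    post_filter_percent: int
    version: str
    config: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def percentage_report(numerator: int, denominator: int) -> int:
    """Round-half-up integer percentage of ``numerator / denominator``."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator > denominator:
        raise ValueError("numerator exceeds denominator")
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return int(pct.quantize(Decimal(1), rounding=ROUND_HALF_UP))


def _config_echo(config: RunConfig) -> dict:
    echo = dataclasses.asdict(config)
    for key, value in echo.items():
        if isinstance(value, Path):
            echo[key] = str(value)
    return echo


def run_pipeline(config: RunConfig) -> RunSummary:
    """Execute all stages, writing artifacts under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- stage 1: obtain inputs ----------------------------------------
    if config.sim is not None:
        sim = dataclasses.replace(config.sim, seed=_child_seed(config.seed, "simulate"))
        exp = generate_experiment(sim)
        catalog, terms = exp.catalog, exp.terms
        phospho_raw, proteome_raw = exp.phospho, exp.proteome
        catalog.to_tsv(out / "catalog.tsv")
        write_gmt(terms, out / "terms.gmt")
        phospho_raw.to_tsv(out / "phospho_raw.tsv")
        proteome_raw.to_tsv(out / "proteome_raw.tsv")
        write_design(phospho_raw.design, out / "design.tsv")
        exp.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    else:
        design = read_design(config.design_path)
        catalog = PhosphoCatalog.from_tsv(config.catalog_path)
        phospho_raw = IntensityMatrix.from_tsv(config.phospho_path, design, "raw")
        proteome_raw = (
            IntensityMatrix.from_tsv(config.proteome_path, design, "raw")
            if config.proteome_path
            else None
        )
        terms = read_gmt(config.gmt_path) if config.gmt_path else {}

    # --- stage 2: preprocess phospho matrix ----------------------------
    try:
        quantified = phospho_raw.values.notna().any(axis=1)
        rows_quantified = int(quantified.sum())
        log2 = log2_transform(phospho_raw)
        log2, norm_report = local_regression_normalize(log2, span=config.normalization_span)
        filtered, n_removed = filter_valid_values(log2, config.min_valid_fraction)
        filtered.to_tsv(out / "phospho_filtered_log2.tsv")
    except Exception as err:  # pragma: no cover - context re-raise
        raise RuntimeError(f"preprocess stage failed: {err}") from err

    # --- stage 3: differential test on observed values -----------------
    try:
        diff_cfg = dataclasses.replace(
            config.differential, seed=_child_seed(config.seed, "test_phospho")
        )
        results = permutation_fdr(filtered, diff_cfg)
        results.to_csv(out / "differential_results.tsv", sep="\t", index=False)
        volcano_table(results).to_csv(out / "volcano.tsv", sep="\t", index=False)
        if config.impute:
            imputed = impute_downshifted_normal(
                filtered,
                config.impute_width,
                config.impute_downshift,
                np.random.default_rng(_child_seed(config.seed, "impute")),
            )
            scores, evr = pca_scores(imputed)
            scores.assign(condition=[imputed.design[s] for s in scores.index]).to_csv(
                out / "pca_scores.tsv", sep="\t"
            )
            np.savetxt(out / "pca_explained_variance.tsv", evr, fmt="%.6f")
    except RuntimeError:
        raise
    except Exception as err:
        raise RuntimeError(f"differential stage failed: {err}") from err

    # --- stage 4: proteome normalization -------------------------------
    calls = None
    if proteome_raw is not None:
        try:
            proteome_log2 = log2_transform(proteome_raw)
            mapping = match_rows(catalog, proteome_log2)
            adjusted, unmatched = normalize_against_protein(filtered, proteome_log2, mapping)
            adj_cfg = dataclasses.replace(
                config.differential, seed=_child_seed(config.seed, "test_adjusted")
            )
            matched_rows = [r for r in adjusted.row_ids if r not in set(unmatched)]
            adjusted_matched = IntensityMatrix(
                adjusted.values.loc[matched_rows], dict(adjusted.design), "log2"
            )
            adj_results = permutation_fdr(adjusted_matched, adj_cfg)
            calls = call_regulation_table(
                results[results["row_id"].isin(matched_rows)],
                adj_results,
                proteome_log2,
                mapping,
                config.protein_change_threshold,
            )
            calls.to_csv(out / "regulation_calls.tsv", sep="\t", index=False)
        except RuntimeError:
            raise
        except Exception as err:
            raise RuntimeError(f"proteome normalization stage failed: {err}") from err

    # --- stage 5: enrichment -------------------------------------------
    significant_peptides = list(results.loc[results["significant"], "row_id"])
    kept = set(filtered.row_ids)
    kept_catalog = PhosphoCatalog([p for p in catalog if p.peptide_id in kept])
    hit_groups = deduplicate_hits(significant_peptides, kept_catalog)
    background = set(kept_catalog.protein_groups())
    n_sig_terms = 0
    if terms:
        try:
            annotations = [
                TermAnnotation(t, t, "pathway", members & background)
                for t, members in sorted(terms.items())
                if members & background
            ]
            enr = fisher_enrichment(
                hit_groups, background, annotations, alpha=config.enrichment_alpha
            )
            enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            n_sig_terms = int(enr["significant"].sum())
        except RuntimeError:
            raise
        except Exception as err:
            raise RuntimeError(f"enrichment stage failed: {err}") from err

    summary = RunSummary(
        rows_in_catalog=len(catalog),
        rows_quantified=rows_quantified,
        rows_after_filter=len(filtered.row_ids),
        rows_testable=int((results["reason"] == "").sum()),
        n_significant_peptides=len(significant_peptides),
        n_significant_groups=len(hit_groups),
        n_significant_terms=n_sig_terms,
        quantified_percent=percentage_report(rows_quantified, len(catalog)),
        post_filter_percent=percentage_report(len(filtered.row_ids), len(catalog)),
        version=__version__,
        config=_config_echo(config),
    )
    summary.to_json(out / "summary.json")
    return summary
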
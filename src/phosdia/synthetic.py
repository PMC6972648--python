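"""Synthetic two-condition DIA phosphoproteome experiments with ground truth.

The generator emulates the statistical shape of a 5-vs-5 replicate
phosphoproteomics quantification: a phosphopeptide catalog over protein
groups, paired phospho/proteome intensity matrices on a log-normal scale,
intensity-dependent (missing-not-at-random) censoring of the phospho
matrix, and a truth table labelling each phosphopeptide row as null,
phospho-driven (the phosphopeptide shifts while its protein does not) or
abundance-driven (peptide and protein shift together).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .catalog import AMINO_ACIDS, PhosphoCatalog, PhosphoPeptide, PhosphoSite
from .matrix import IntensityMatrix

__all__ = [
    "SimConfig",
    "TruthLabel",
    "SyntheticExperiment",
    "censoring_probability",
    "generate_catalog",
    "generate_term_annotation",
    "generate_intensity_matrices",
    "generate_experiment",
    "write_gmt",
    "read_gmt",
]

CONDITIONS = ("aposymbiotic", "symbiotic")


class TruthLabel(str, Enum):
    NULL = "null"
    PHOSPHO_DRIVEN = "phospho_driven"
    ABUNDANCE_DRIVEN = "abundance_driven"


@dataclass
class SimConfig:
    """Parameters of the simulated experiment.

    Defaults mirror the scale of the emulated study: ~1,200 protein groups
    carrying ~3,100 phosphopeptides, five replicates per condition, a
    log-normal intensity distribution, logistic intensity-dependent
    censoring of the phospho matrix, residues drawn at the canonical
    S/T/Y mix and localization probabilities with a ~60% class-I fraction.
    """

    n_protein_groups: int = 1200
    peptides_per_group_mean: float = 2.6
    n_samples_per_condition: int = 5
    n_terms: int = 20
    term_size_range: tuple[int, int] = (10, 40)
    frac_differential: float = 0.1
    frac_abundance_driven: float = 0.3
    effect_size_log2: float = 2.0
    base_log2_mean: float = 20.0
    base_log2_sd: float = 2.0
    noise_sd: float = 0.5
    mnar_midpoint: float = 16.0
    mnar_slope: float = 1.0
    missingness: str = "mnar"  # "mnar" | "mcar" | "none"
    mcar_rate: float = 0.05
    residue_proportions: tuple[float, float, float] = (0.857, 0.135, 0.008)
    frac_high_localization: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_differential", "frac_abundance_driven", "frac_high_localization", "mcar_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_protein_groups", "n_samples_per_condition"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_terms < 0:
            raise ValueError("n_terms must be >= 0")
        if self.peptides_per_group_mean < 1:
            raise ValueError("peptides_per_group_mean must be >= 1")
        for name in ("base_log2_sd", "noise_sd", "mnar_slope", "effect_size_log2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        lo, hi = self.term_size_range
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid term_size_range {self.term_size_range}")
        if abs(sum(self.residue_proportions) - 1.0) > 1e-9:
            raise ValueError(
                f"residue proportions {self.residue_proportions} do not sum to 1"
            )
        if self.missingness not in ("mnar", "mcar", "none"):
            raise ValueError(f"unknown missingness mode {self.missingness!r}")


def censoring_probability(log2_intensity, midpoint: float, slope: float):
    """Probability that a cell of the given log2 intensity is censored.

    Logistic, decreasing in intensity: P = 1 / (1 + exp(slope * (x - m))),
    so low-abundance signals are the ones most often missing.
    """
    from scipy.special import expit

    x = np.asarray(log2_intensity, dtype=float)
    return expit(-slope * (x - midpoint))


def generate_catalog(config: SimConfig, rng: np.random.Generator) -> PhosphoCatalog:
    """Random phosphopeptide catalog with a many-to-one peptide->group map.

    Sequences are uniform over the 20-letter amino-acid alphabet except at
    phosphosites, whose residues follow ``config.residue_proportions``
    (S/T/Y). Localization probabilities come from a two-component mixture:
    with probability ``frac_high_localization`` uniform on (0.75, 1], else
    uniform on [0, 0.75].
    """
    peptides: list[PhosphoPeptide] = []
    aa = np.array(list(AMINO_ACIDS))
    residues = np.array(["S", "T", "Y"])
    props = np.asarray(config.residue_proportions, dtype=float)
    pep_counter = 0
    for g in range(config.n_protein_groups):
        group_id = f"PG{g + 1:05d}"
        n_pep = 1 + rng.poisson(config.peptides_per_group_mean - 1.0)
        for _ in range(n_pep):
            pep_counter += 1
            length = int(rng.integers(8, 31))
            seq = rng.choice(aa, size=length)
            n_sites = 1 + int(rng.random() < 0.1)
            positions = sorted(
                int(p) for p in rng.choice(length, size=min(n_sites, length), replace=False)
            )
            sites = []
            for pos0 in positions:
                res = str(rng.choice(residues, p=props))
                seq[pos0] = res
                if rng.random() < config.frac_high_localization:
                    prob = float(rng.uniform(0.75 + 1e-9, 1.0))
                else:
                    prob = float(rng.uniform(0.0, 0.75))
                sites.append(PhosphoSite(pos0 + 1, res, prob))
            peptides.append(
                PhosphoPeptide(f"pep{pep_counter:06d}", "".join(seq), sites, group_id)
            )
    return PhosphoCatalog(peptides)


def generate_term_annotation(
    catalog: PhosphoCatalog, config: SimConfig, rng: np.random.Generator
) -> dict[str, set[str]]:
    """Random term -> protein-group-set annotation (GMT-ready).

    Each of ``n_terms`` terms draws a size uniformly in ``term_size_range``
    and samples that many distinct protein groups; groups may belong to
    several terms.
    """
    groups = catalog.protein_groups()
    lo, hi = config.term_size_range
    if hi > len(groups):
        raise ValueError(
            f"term_size_range max {hi} exceeds the number of protein groups {len(groups)}"
        )
    terms: dict[str, set[str]] = {}
    for t in range(config.n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(groups), size=size, replace=False)
        terms[f"TERM{t + 1:04d}"] = {groups[i] for i in members}
    return terms


def generate_intensity_matrices(
    catalog: PhosphoCatalog,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[IntensityMatrix, IntensityMatrix, pd.DataFrame]:
    """Paired phospho/proteome raw-intensity matrices plus the truth table.

    Each phosphopeptide row has a latent log2 abundance ~ Normal(base mean,
    base sd); each protein group has its own latent proteome abundance.
    Differential rows receive a +/- ``effect_size_log2`` shift in the second
    condition: phospho-driven rows in the phospho matrix only,
    abundance-driven rows in both their phospho row and their protein
    group's proteome row (abundance-driven rows are drawn from distinct
    groups so a proteome row carries one effect at most). Cell noise is
    Normal(0, noise_sd); phospho cells are then censored with the logistic
    intensity-dependent probability of :func:`censoring_probability` (or
    uniformly for ``missingness="mcar"``). Returned matrices are raw scale
    (2**log2). The truth table records each row's label and signed effect,
    oriented as condition 2 minus condition 1.
    """
    row_ids = [p.peptide_id for p in catalog]
    groups = catalog.protein_groups()
    pep_group = [p.protein_group for p in catalog]
    n_rows = len(row_ids)
    n_per = config.n_samples_per_condition
    sample_ids = [f"{cond[:4]}_{i + 1}" for cond in CONDITIONS for i in range(n_per)]
    design = {
        s: CONDITIONS[0] if i < n_per else CONDITIONS[1] for i, s in enumerate(sample_ids)
    }
    cond2 = np.array([design[s] == CONDITIONS[1] for s in sample_ids])

    latent_pep = rng.normal(config.base_log2_mean, config.base_log2_sd, size=n_rows)
    latent_grp = rng.normal(config.base_log2_mean, config.base_log2_sd, size=len(groups))
    grp_index = {g: i for i, g in enumerate(groups)}

    labels = np.full(n_rows, TruthLabel.NULL.value, dtype=object)
    effects = np.zeros(n_rows)
    n_diff = int(round(config.frac_differential * n_rows))
    if n_diff > 0:
        diff_rows = rng.choice(n_rows, size=n_diff, replace=False)
        n_abund = int(round(config.frac_abundance_driven * n_diff))
        # abundance-driven rows must come from distinct protein groups so
        # that each proteome row carries at most one injected effect
        abund_rows: list[int] = []
        used_groups: set[str] = set()
        for r in diff_rows:
            if len(abund_rows) == n_abund:
                break
            g = pep_group[r]
            if g not in used_groups:
                abund_rows.append(int(r))
                used_groups.add(g)
        abund_set = set(abund_rows)
        signs = rng.choice([-1.0, 1.0], size=n_diff)
        for sign, r in zip(signs, diff_rows):
            effects[r] = sign * config.effect_size_log2
            labels[r] = (
                TruthLabel.ABUNDANCE_DRIVEN.value
                if int(r) in abund_set
                else TruthLabel.PHOSPHO_DRIVEN.value
            )

    grp_effects = np.zeros(len(groups))
    for r in range(n_rows):
        if labels[r] == TruthLabel.ABUNDANCE_DRIVEN.value:
            grp_effects[grp_index[pep_group[r]]] = effects[r]

    n_samples = len(sample_ids)
    phospho_log2 = (
        latent_pep[:, None]
        + np.outer(effects, cond2.astype(float))
        + rng.normal(0.0, config.noise_sd, size=(n_rows, n_samples))
    )
    proteome_log2 = (
        latent_grp[:, None]
        + np.outer(grp_effects, cond2.astype(float))
        + rng.normal(0.0, config.noise_sd, size=(len(groups), n_samples))
    )

    if config.missingness == "mnar":
        p_missing = censoring_probability(phospho_log2, config.mnar_midpoint, config.mnar_slope)
        censored = rng.random(phospho_log2.shape) < p_missing
    elif config.missingness == "mcar":
        censored = rng.random(phospho_log2.shape) < config.mcar_rate
    else:
        censored = np.zeros(phospho_log2.shape, dtype=bool)

    phospho_vals = np.power(2.0, phospho_log2)
    phospho_vals[censored] = np.nan
    proteome_vals = np.power(2.0, proteome_log2)

    phospho = IntensityMatrix(
        pd.DataFrame(phospho_vals, index=row_ids, columns=sample_ids), design, "raw"
    )
    proteome = IntensityMatrix(
        pd.DataFrame(proteome_vals, index=groups, columns=sample_ids), design, "raw"
    )
    truth = pd.DataFrame(
        {"row_id": row_ids, "label": labels, "true_log2_effect": effects}
    )
    return phospho, proteome, truth


@dataclass
class SyntheticExperiment:
    """Bundle of one simulated experiment."""

    catalog: PhosphoCatalog
    terms: dict[str, set[str]]
    phospho: IntensityMatrix
    proteome: IntensityMatrix
    truth: pd.DataFrame
    config: SimConfig = field(repr=False, default=None)


def generate_experiment(config: SimConfig) -> SyntheticExperiment:
    """Generate catalog, annotation, matrices and truth from one seed."""
    rng = np.random.default_rng(config.seed)
    catalog = generate_catalog(config, rng)
    terms = generate_term_annotation(catalog, config, rng)
    phospho, proteome, truth = generate_intensity_matrices(catalog, config, rng)
    return SyntheticExperiment(catalog, terms, phospho, proteome, truth, config)


def write_gmt(terms: dict[str, set[str]], path, descriptions: dict[str, str] | None = None) -> None:
    """Write a term annotation in GMT dialect (term, description, members)."""
    with open(path, "w") as fh:
        for term_id in sorted(terms):
            desc = (descriptions or {}).get(term_id, "na")
            members = "\t".join(sorted(terms[term_id]))
            fh.write(f"{term_id}\t{desc}\t{members}\n" if members else f"{term_id}\t{desc}\n")


def read_gmt(path) -> dict[str, set[str]]:
    terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or not parts[0]:
                continue
            terms[parts[0]] = set(parts[2:])
    return terms
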
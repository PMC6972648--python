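"""Phosphopeptide catalog: sites, localization classes, kinase motifs.

Phosphosite localization probabilities are graded into the conventional
confidence classes: class I sites are confidently localized (probability
strictly above 0.75); sites with probability between 0.25 and 0.75 are
class II when a kinase recognition motif matches the surrounding sequence
and class III otherwise; below 0.25 the assignment is ambiguous and excluded
from class statistics.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum

import pandas as pd
import yaml

__all__ = [
    "PhosphoSite",
    "PhosphoPeptide",
    "PhosphoCatalog",
    "ProteinGroup",
    "PhosphositeClass",
    "KinaseMotif",
    "DEFAULT_MOTIFS",
    "match_motifs",
    "classify_site",
    "residue_composition",
    "summarize_classes",
    "load_motifs",
]

PHOSPHO_RESIDUES = frozenset("STY")
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class PhosphositeClass(str, Enum):
    """Localization confidence class of a phosphosite."""

    I = "I"
    II = "II"
    III = "III"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class PhosphoSite:
    position: int  # 1-based index into the peptide sequence
    residue: str  # S, T or Y
    localization_probability: float


@dataclass
class PhosphoPeptide:
    peptide_id: str
    sequence: str
    sites: list[PhosphoSite]
    protein_group: str

    def __post_init__(self) -> None:
        for site in self.sites:
            if not 1 <= site.position <= len(self.sequence):
                raise ValueError(
                    f"{self.peptide_id}: site position {site.position} outside "
                    f"sequence of length {len(self.sequence)}"
                )
            if self.sequence[site.position - 1] != site.residue:
                raise ValueError(
                    f"{self.peptide_id}: residue {site.residue} at position "
                    f"{site.position} does not match sequence letter "
                    f"{self.sequence[site.position - 1]}"
                )
            if not 0.0 <= site.localization_probability <= 1.0:
                raise ValueError(
                    f"{self.peptide_id}: localization probability "
                    f"{site.localization_probability} outside [0, 1]"
                )


@dataclass
class ProteinGroup:
    group_id: str
    member_proteins: set[str]

    def __post_init__(self) -> None:
        if not self.member_proteins:
            raise ValueError(f"protein group {self.group_id} has no members")


@dataclass
class PhosphoCatalog:
    """Ordered collection of quantified phosphopeptide precursors."""

    peptides: list[PhosphoPeptide] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.peptides)

    def __iter__(self):
        return iter(self.peptides)

    def peptide_to_group(self) -> dict[str, str]:
        return {p.peptide_id: p.protein_group for p in self.peptides}

    def protein_groups(self) -> list[str]:
        seen: list[str] = []
        for p in self.peptides:
            if p.protein_group not in seen:
                seen.append(p.protein_group)
        return seen

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.peptides:
            rows.append(
                {
                    "peptide_id": p.peptide_id,
                    "sequence": p.sequence,
                    "protein_group": p.protein_group,
                    "site_positions": ";".join(str(s.position) for s in p.sites),
                    "site_residues": ";".join(s.residue for s in p.sites),
                    "site_probabilities": ";".join(
                        format(s.localization_probability, ".6g") for s in p.sites
                    ),
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PhosphoCatalog":
        peptides = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                positions = [int(x) for x in row["site_positions"].split(";")]
                residues = row["site_residues"].split(";")
                probs = [float(x) for x in row["site_probabilities"].split(";")]
                sites = [
                    PhosphoSite(pos, res, prob)
                    for pos, res, prob in zip(positions, residues, probs, strict=True)
                ]
                peptides.append(
                    PhosphoPeptide(row["peptide_id"], row["sequence"], sites, row["protein_group"])
                )
        return cls(peptides)


@dataclass(frozen=True)
class KinaseMotif:
    """Positional pattern around a phosphosite.

    ``pattern`` maps a relative offset (0 = the phosphosite itself) to the
    set of residues allowed at that offset. Offset 0 may only allow S/T/Y.
    """

    name: str
    pattern: dict[int, frozenset[str]]

    def __post_init__(self) -> None:
        anchor = self.pattern.get(0)
        if anchor is not None and not anchor <= PHOSPHO_RESIDUES:
            raise ValueError(f"motif {self.name}: offset-0 residues must be within S/T/Y")


def _motif(name: str, pattern: dict[int, str]) -> KinaseMotif:
    return KinaseMotif(name, {k: frozenset(v) for k, v in pattern.items()})


#: Three canonical kinase-motif families, used when no motif set is supplied.
DEFAULT_MOTIFS: list[KinaseMotif] = [
    _motif("proline-directed", {0: "ST", 1: "P"}),
    _motif("basophilic", {-3: "R", 0: "ST"}),
    _motif("acidophilic", {0: "ST", 3: "DE"}),
]


def load_motifs(path) -> list[KinaseMotif]:
    """Load motif definitions from YAML: ``{name: {offset: residues}}``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return [
        _motif(name, {int(off): residues for off, residues in pattern.items()})
        for name, pattern in raw.items()
    ]


def match_motifs(sequence: str, position: int, motifs: list[KinaseMotif]) -> list[str]:
    """Names of the motifs matching ``sequence`` at the 1-based ``position``.

    A motif matches iff, for every offset in its pattern, ``position +
    offset`` lies inside the sequence and the residue there belongs to the
    allowed set. Returned names preserve the input motif order.
    """
    if not 1 <= position <= len(sequence):
        raise ValueError(f"position {position} outside sequence of length {len(sequence)}")
    hits = []
    for motif in motifs:
        ok = True
        for offset, allowed in motif.pattern.items():
            idx = position - 1 + offset
            if not 0 <= idx < len(sequence) or sequence[idx] not in allowed:
                ok = False
                break
        if ok:
            hits.append(motif.name)
    return hits


def classify_site(probability: float, has_matching_motif: bool) -> PhosphositeClass:
    """Grade a phosphosite into localization class I/II/III/ambiguous.

    Class I requires probability strictly above 0.75; probabilities in
    [0.25, 0.75] yield class II with a matching kinase motif and class III
    without; below 0.25 the localization is ambiguous.
    """
    if not 0.0 <= probability <= 1.0:
        raise ValueError(f"probability {probability} outside [0, 1]")
    if probability > 0.75:
        return PhosphositeClass.I
    if probability >= 0.25:
        return PhosphositeClass.II if has_matching_motif else PhosphositeClass.III
    return PhosphositeClass.AMBIGUOUS


def residue_composition(peptides: list[PhosphoPeptide]) -> tuple[float, float, float]:
    """Fractions of phospho-serine, -threonine and -tyrosine over all sites."""
    counts = {"S": 0, "T": 0, "Y": 0}
    for p in peptides:
        for site in p.sites:
            counts[site.residue] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no phosphosites in the input")
    return counts["S"] / total, counts["T"] / total, counts["Y"] / total


def summarize_classes(
    peptides: list[PhosphoPeptide], motifs: list[KinaseMotif] | None = None
) -> pd.DataFrame:
    """Counts and fractions of sites per localization class.

    Motif matching for the class II / III distinction runs against the
    peptide sequence with the supplied motif set (:data:`DEFAULT_MOTIFS`
    when None).
    """
    if motifs is None:
        motifs = DEFAULT_MOTIFS
    counts = {c: 0 for c in PhosphositeClass}
    for p in peptides:
        for site in p.sites:
            has_motif = bool(match_motifs(p.sequence, site.position, motifs))
            counts[classify_site(site.localization_probability, has_motif)] += 1
    total = sum(counts.values())
    return pd.DataFrame(
        {
            "site_class": [c.value for c in PhosphositeClass],
            "count": [counts[c] for c in PhosphositeClass],
            "fraction": [counts[c] / total if total else float("nan") for c in PhosphositeClass],
        }
    )
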
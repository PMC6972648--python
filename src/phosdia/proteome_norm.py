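"""Discriminate PTM-level regulation from protein-abundance changes.

A differentially abundant phosphopeptide may reflect a genuine change in
phosphorylation at its site, or simply a change in the amount of the
carrier protein. Subtracting the matched protein group's log2 proteome
profile from the phosphopeptide's log2 profile yields an adjusted matrix in
which abundance-driven signals cancel while phosphorylation-driven signals
persist; testing the adjusted matrix alongside the raw phospho matrix then
separates the two regimes.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .catalog import PhosphoCatalog
from .matrix import IntensityMatrix

__all__ = [
    "RegulationLabel",
    "RegulationCall",
    "match_rows",
    "normalize_against_protein",
    "call_regulation",
    "call_regulation_table",
]

UNMATCHED = "__unmatched__"


class RegulationLabel(str, Enum):
    PHOSPHO_DRIVEN = "phospho_driven"
    ABUNDANCE_DRIVEN = "abundance_driven"
    MIXED = "mixed"
    UNMATCHED = "unmatched"
    NOT_SIGNIFICANT = "not_significant"


@dataclass
class RegulationCall:
    row_id: str
    call: RegulationLabel
    phospho_diff: float
    protein_diff: float | None
    adjusted_diff: float | None


def match_rows(catalog: PhosphoCatalog, proteome: IntensityMatrix) -> dict[str, str]:
    """Map each phosphopeptide row to its protein group's proteome row.

    Proteome row ids are protein-group ids; peptides whose group has no
    proteome row map to the sentinel ``__unmatched__``.
    """
    proteome_rows = proteome.row_ids
    if len(set(proteome_rows)) != len(proteome_rows):
        dupes = sorted({r for r in proteome_rows if proteome_rows.count(r) > 1})
        raise ValueError(f"duplicate proteome rows for protein groups: {dupes}")
    available = set(proteome_rows)
    mapping = {}
    for pep_id, group in catalog.peptide_to_group().items():
        mapping[pep_id] = group if group in available else UNMATCHED
    return mapping


def normalize_against_protein(
    phospho: IntensityMatrix,
    proteome: IntensityMatrix,
    mapping: dict[str, str],
) -> tuple[IntensityMatrix, list[str]]:
    """Per-sample log2 difference phospho - matched proteome row.

    Cells missing in either input are missing in the output. Unmatched
    phosphopeptide rows are carried through unadjusted and returned in the
    second element so downstream callers can flag them.
    """
    if phospho.scale != "log2" or proteome.scale != "log2":
        raise ValueError("both matrices must be log2-scaled")
    if phospho.sample_ids != proteome.sample_ids:
        only_p = set(phospho.sample_ids) - set(proteome.sample_ids)
        only_q = set(proteome.sample_ids) - set(phospho.sample_ids)
        raise ValueError(
            f"sample sets differ (phospho-only: {sorted(only_p)}, "
            f"proteome-only: {sorted(only_q)}) or are ordered differently"
        )
    adjusted = phospho.values.copy()
    unmatched = []
    for row_id in phospho.row_ids:
        target = mapping.get(row_id, UNMATCHED)
        if target == UNMATCHED:
            unmatched.append(row_id)
            continue
        adjusted.loc[row_id] = phospho.values.loc[row_id] - proteome.values.loc[target]
    return (
        IntensityMatrix(adjusted, dict(phospho.design), "log2"),
        unmatched,
    )


def call_regulation(
    phospho_result: pd.Series,
    adjusted_result: pd.Series,
    protein_diff: float,
    protein_change_threshold: float = 0.3,
) -> RegulationCall:
    """Classify one row given its phospho-level and adjusted-level tests.

    Rule table: phospho significant and adjusted significant -> the signal
    survives protein normalization, hence phospho-driven; phospho
    significant, adjusted not, with |protein difference| above the
    threshold -> explained by protein abundance; phospho significant but
    neither the adjusted test nor a protein change supports a direction ->
    mixed/indeterminate; phospho not significant -> no call.
    """
    if phospho_result["row_id"] != adjusted_result["row_id"]:
        raise ValueError(
            f"row id mismatch: {phospho_result['row_id']} vs {adjusted_result['row_id']}"
        )
    phospho_diff = float(phospho_result["mean_difference"])
    adjusted_diff = float(adjusted_result["mean_difference"])
    if not phospho_result["significant"]:
        call = RegulationLabel.NOT_SIGNIFICANT
    elif adjusted_result["significant"]:
        call = RegulationLabel.PHOSPHO_DRIVEN
    elif np.isfinite(protein_diff) and abs(protein_diff) > protein_change_threshold:
        call = RegulationLabel.ABUNDANCE_DRIVEN
    else:
        call = RegulationLabel.MIXED
    return RegulationCall(
        row_id=str(phospho_result["row_id"]),
        call=call,
        phospho_diff=phospho_diff,
        protein_diff=float(protein_diff),
        adjusted_diff=adjusted_diff,
    )


def call_regulation_table(
    phospho_results: pd.DataFrame,
    adjusted_results: pd.DataFrame,
    proteome: IntensityMatrix,
    mapping: dict[str, str],
    protein_change_threshold: float = 0.3,
) -> pd.DataFrame:
    """Regulation calls for every row of the phospho result table.

    ``protein_diff`` per row is the between-condition mean difference of
    the mapped proteome row (conditions in lexicographic order, matching
    the differential test). Unmatched rows are reported as such.
    """
    conds = sorted({proteome.design[s] for s in proteome.sample_ids})
    sa = [s for s in proteome.sample_ids if proteome.design[s] == conds[0]]
    sb = [s for s in proteome.sample_ids if proteome.design[s] == conds[1]]
    prot_diff = proteome.values[sa].mean(axis=1) - proteome.values[sb].mean(axis=1)

    adj = adjusted_results.set_index("row_id")
    rows = []
    for _, pres in phospho_results.iterrows():
        rid = pres["row_id"]
        target = mapping.get(rid, UNMATCHED)
        if target == UNMATCHED:
            rows.append(
                {
                    "row_id": rid,
                    "call": RegulationLabel.UNMATCHED.value,
                    "phospho_diff": float(pres["mean_difference"]),
                    "protein_diff": np.nan,
                    "adjusted_diff": np.nan,
                }
            )
            continue
        ares = adj.loc[rid]
        ares = pd.concat([pd.Series({"row_id": rid}), ares])
        call = call_regulation(pres, ares, float(prot_diff[target]), protein_change_threshold)
        rows.append(
            {
                "row_id": call.row_id,
                "call": call.call.value,
                "phospho_diff": call.phospho_diff,
                "protein_diff": call.protein_diff,
                "adjusted_diff": call.adjusted_diff,
            }
        )
    return pd.DataFrame(rows)
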
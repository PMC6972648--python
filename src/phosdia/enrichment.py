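"""Fisher's exact pathway enrichment over differential phosphoproteins.

Hits are de-duplicated to protein groups before testing ("relative
enrichment"): a protein carrying several significant phosphopeptides counts
once. Each term is tested with a two-sided Fisher's exact test on the
2x2 table (in-term/out-of-term x hit/non-hit) against the background of all
quantified protein groups, and reported with its enrichment factor

    EF = (k/n) / (K/N)

(hit fraction in the term over background fraction); EF < 1 marks
under-represented terms, which the two-sided test can also flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .catalog import PhosphoCatalog

__all__ = [
    "TermAnnotation",
    "deduplicate_hits",
    "fisher_enrichment",
    "enrichment_scatter_table",
]

logger = logging.getLogger(__name__)


@dataclass
class TermAnnotation:
    term_id: str
    term_name: str
    category: str  # "process" | "pathway"
    members: set[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"term {self.term_id} has an empty member set")
        if self.category not in ("process", "pathway"):
            raise ValueError(f"term {self.term_id}: category must be process or pathway")


def deduplicate_hits(
    significant_peptides: list[str], catalog: PhosphoCatalog
) -> set[str]:
    """Collapse significant phosphopeptides to their protein groups.

    Each group appears at most once no matter how many of its peptides or
    sites are significant.
    """
    pep_to_group = catalog.peptide_to_group()
    groups = set()
    for pep in significant_peptides:
        if pep not in pep_to_group:
            raise ValueError(f"peptide {pep} has no protein group in the catalog")
        groups.add(pep_to_group[pep])
    return groups


def fisher_enrichment(
    hits: set[str],
    background: set[str],
    terms: list[TermAnnotation],
    alpha: float = 0.05,
    correct: str = "none",
) -> pd.DataFrame:
    """Two-sided Fisher's exact test per term.

    Term members outside the background are clipped (logged); hits outside
    the background are an error. ``correct="bh"`` applies a
    Benjamini-Hochberg adjustment across terms before the significance
    call (off by default: raw p < alpha).

    Returns one row per term: ``term_id, term_name, category, k, K, n, N,
    p_value, enrichment_factor, significant``; the factor is NaN when the
    term has no background members or there are no hits.
    """
    stray = hits - background
    if stray:
        raise ValueError(f"hits outside the background universe: {sorted(stray)[:5]}")
    N = len(background)
    n = len(hits)
    rows = []
    for term in terms:
        members = term.members & background
        clipped = len(term.members) - len(members)
        if clipped:
            logger.warning("term %s: %d members outside background clipped", term.term_id, clipped)
        K = len(members)
        k = len(members & hits)
        table = [[k, n - k], [K - k, N - K - (n - k)]]
        _, p = fisher_exact(table, alternative="two-sided")
        factor = (k / n) / (K / N) if n > 0 and K > 0 else np.nan
        rows.append(
            {
                "term_id": term.term_id,
                "term_name": term.term_name,
                "category": term.category,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_value": float(p),
                "enrichment_factor": factor,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        out["significant"] = pd.Series(dtype=bool)
        return out
    if correct == "bh":
        out["significant"] = multipletests(out["p_value"], alpha=alpha, method="fdr_bh")[0]
    elif correct == "none":
        out["significant"] = out["p_value"] < alpha
    else:
        raise ValueError(f"unknown correction {correct!r}")
    return out


def enrichment_scatter_table(results: pd.DataFrame) -> pd.DataFrame:
    """Scatter coordinates (enrichment factor, -log10 p) per defined term.

    Terms with an undefined factor are omitted; rows are sorted by p
    ascending, ties broken by term id.
    """
    if results.empty:
        raise ValueError("no enrichment results supplied")
    defined = results[results["enrichment_factor"].notna()].copy()
    defined["neg_log10_p"] = -np.log10(defined["p_value"])
    defined = defined.sort_values(["p_value", "term_id"], kind="mergesort")
    return defined[
        ["term_id", "category", "enrichment_factor", "neg_log10_p", "significant"]
    ].reset_index(drop=True)
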
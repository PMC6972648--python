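"""Quantification matrix container shared by all pipeline stages.

An :class:`IntensityMatrix` holds a rows x samples abundance grid (rows are
phosphopeptide precursors or protein groups, columns are samples) with
explicit missingness (NaN), a sample -> condition design, and a scale tag so
that a log2 transform cannot be applied twice by accident.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["IntensityMatrix", "read_design", "write_design"]


@dataclass
class IntensityMatrix:
    """Rows x samples abundance table with explicit missingness.

    Parameters
    ----------
    values
        DataFrame with row identifiers as index, sample identifiers as
        columns and float values; missing cells are NaN.
    design
        Mapping from sample id to condition label. Every column of
        ``values`` must appear in the design.
    scale
        ``"raw"`` (linear intensities, strictly positive where observed) or
        ``"log2"``.
    """

    values: pd.DataFrame
    design: dict[str, str] = field(default_factory=dict)
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "log2"):
            raise ValueError(f"scale must be 'raw' or 'log2', got {self.scale!r}")
        self.values = self.values.astype(float)
        missing_design = [s for s in self.values.columns if s not in self.design]
        if missing_design:
            raise ValueError(f"samples without a condition in the design: {missing_design}")
        if self.scale == "raw":
            observed = self.values.to_numpy()
            bad = np.isfinite(observed) & (observed <= 0)
            if bad.any():
                raise ValueError(
                    f"{int(bad.sum())} non-positive observed values in a raw-scale matrix"
                )

    # -- basic accessors -------------------------------------------------
    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def conditions(self) -> list[str]:
        """Condition labels in order of first appearance across samples."""
        seen: list[str] = []
        for s in self.sample_ids:
            c = self.design[s]
            if c not in seen:
                seen.append(c)
        return seen

    def condition_samples(self, condition: str) -> list[str]:
        return [s for s in self.sample_ids if self.design[s] == condition]

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(self.values.copy(), dict(self.design), self.scale)

    # -- serialization ---------------------------------------------------
    def to_tsv(self, path) -> None:
        """Write as TSV: first column ``row_id``, missing cells empty."""
        out = self.values.copy()
        out.index.name = "row_id"
        out.to_csv(path, sep="\t", na_rep="")

    @classmethod
    def from_tsv(cls, path, design: dict[str, str], scale: str = "raw") -> "IntensityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(df, design, scale)


def read_design(path) -> dict[str, str]:
    """Read a two-column ``sample_id<TAB>condition`` table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample_id", "condition"]:
        raise ValueError("design table must have columns 'sample_id' and 'condition'")
    return dict(zip(df["sample_id"], df["condition"]))


def write_design(design: dict[str, str], path) -> None:
    pd.DataFrame(
        {"sample_id": list(design.keys()), "condition": list(design.values())}
    ).to_csv(path, sep="\t", index=False)
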
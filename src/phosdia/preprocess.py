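"""Matrix preprocessing: normalization, log2, valid-value filter, imputation.

The stages follow the standard label-free post-processing chain for a
two-condition DIA quantification matrix:

1. pick the rows eligible for normalization (those passing an upstream
   q-value threshold in at least one sample);
2. local-regression normalization per sample against a stable-background
   reference, assuming most precursors are unregulated;
3. log2 transform;
4. keep rows quantified in at least 70% of samples;
5. impute remaining missing cells from a downshifted, shrunken normal
   distribution per sample, mimicking low-abundance signals — intended for
   ordination/clustering inputs, while the differential test runs on
   observed values only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .matrix import IntensityMatrix

__all__ = [
    "NormalizationReport",
    "select_normalization_rows",
    "local_regression_normalize",
    "log2_transform",
    "filter_valid_values",
    "impute_downshifted_normal",
]

logger = logging.getLogger(__name__)

MIN_NORMALIZATION_ROWS = 8


@dataclass
class NormalizationReport:
    rows_used: int
    span: float
    per_sample: dict[str, dict[str, float]] = field(default_factory=dict)


def select_normalization_rows(matrix: IntensityMatrix, pass_flags: pd.DataFrame) -> list[str]:
    """Rows that passed the identification q-value cutoff in >= 1 sample.

    ``pass_flags`` is a boolean row x sample grid aligned with the matrix.
    """
    if list(pass_flags.index) != matrix.row_ids or list(pass_flags.columns) != matrix.sample_ids:
        raise ValueError("pass_flags shape/labels do not match the matrix")
    mask = pass_flags.to_numpy(dtype=bool).any(axis=1)
    return [r for r, m in zip(matrix.row_ids, mask) if m]


def local_regression_normalize(
    matrix: IntensityMatrix,
    rows: list[str] | None = None,
    span: float = 0.4,
) -> tuple[IntensityMatrix, NormalizationReport]:
    """Remove per-sample intensity-dependent bias by local regression.

    For each sample, the deviation of its observed log2 values from a
    row-wise median reference is smoothed (LOWESS, fraction ``span``) as a
    function of the reference over the selected rows; the fitted bias curve
    is then subtracted from every row of that sample. The observed/missing
    pattern is unchanged. The reference assumes the bulk of precursors are
    an unregulated stable background with no up/down preference.
    """
    if matrix.scale != "log2":
        raise ValueError("normalization expects a log2-scale matrix")
    values = matrix.values.to_numpy(copy=True)
    if rows is None or len(rows) == 0:
        if rows is not None:
            logger.warning(
                "empty normalization-row subset; falling back to all %d rows", values.shape[0]
            )
        row_idx = np.arange(values.shape[0])
    else:
        lookup = {r: i for i, r in enumerate(matrix.row_ids)}
        row_idx = np.array([lookup[r] for r in rows])

    with warnings.catch_warnings():
        # rows with no observed value have an undefined reference; they are
        # excluded from the fit and left untouched below
        warnings.simplefilter("ignore", RuntimeWarning)
        reference_all = np.nanmedian(values, axis=1)
    usable = row_idx[np.isfinite(reference_all[row_idx])]
    if usable.size < MIN_NORMALIZATION_ROWS:
        raise ValueError(
            f"normalization needs at least {MIN_NORMALIZATION_ROWS} usable rows, "
            f"got {usable.size}"
        )

    report = NormalizationReport(rows_used=int(usable.size), span=span)
    for j, sample in enumerate(matrix.sample_ids):
        col = values[:, j]
        sel = usable[np.isfinite(col[usable])]
        if sel.size < MIN_NORMALIZATION_ROWS:
            raise ValueError(
                f"sample {sample}: fewer than {MIN_NORMALIZATION_ROWS} observed "
                "values among the normalization rows"
            )
        x = reference_all[sel]
        y = col[sel] - x
        fitted = lowess(y, x, frac=span, return_sorted=True)
        xs, ys = fitted[:, 0], fitted[:, 1]
        observed = np.isfinite(col)
        bias = np.interp(reference_all, xs, ys)
        # rows with an undefined reference keep their values untouched
        bias[~np.isfinite(reference_all)] = 0.0
        col[observed] = col[observed] - bias[observed]
        report.per_sample[sample] = {
            "median_correction": float(np.median(ys)),
            "n_points": float(sel.size),
        }
    out = IntensityMatrix(
        pd.DataFrame(values, index=matrix.row_ids, columns=matrix.sample_ids),
        dict(matrix.design),
        "log2",
    )
    return out, report


def log2_transform(matrix: IntensityMatrix) -> IntensityMatrix:
    """log2-transform a raw-scale matrix; missing cells stay missing."""
    if matrix.scale == "log2":
        raise ValueError("matrix is already log2-scaled (double-transform guard)")
    values = matrix.values.to_numpy(copy=True)
    bad = np.isfinite(values) & (values <= 0)
    if bad.any():
        logger.warning("%d non-positive values set to missing before log2", int(bad.sum()))
        values[bad] = np.nan
    with np.errstate(invalid="ignore"):
        values = np.log2(values)
    return IntensityMatrix(
        pd.DataFrame(values, index=matrix.row_ids, columns=matrix.sample_ids),
        dict(matrix.design),
        "log2",
    )


def filter_valid_values(
    matrix: IntensityMatrix, min_fraction: float = 0.7
) -> tuple[IntensityMatrix, int]:
    """Keep rows observed in at least ``min_fraction`` of all samples.

    The fraction is computed jointly across samples (with 10 samples and
    the default 0.7, a row needs >= 7 observed values). Row order is
    preserved. Returns the filtered matrix and the number of removed rows.
    """
    if not 0.0 < min_fraction <= 1.0:
        raise ValueError(f"min_fraction must lie in (0, 1], got {min_fraction}")
    observed = matrix.values.notna().to_numpy()
    keep = observed.sum(axis=1) / observed.shape[1] >= min_fraction
    out = IntensityMatrix(matrix.values.loc[keep].copy(), dict(matrix.design), matrix.scale)
    return out, int((~keep).sum())


def impute_downshifted_normal(
    matrix: IntensityMatrix,
    width: float = 0.3,
    downshift: float = 1.8,
    rng: np.random.Generator | None = None,
) -> IntensityMatrix:
    """Fill missing cells from a shrunken, downshifted per-sample normal.

    For each sample with observed mean mu and standard deviation sigma,
    missing cells are drawn i.i.d. from Normal(mu - downshift*sigma,
    (width*sigma)^2), mimicking intensities near the detection limit.
    Observed cells are never altered.
    """
    if matrix.scale != "log2":
        raise ValueError("imputation expects a log2-scale matrix")
    if rng is None:
        rng = np.random.default_rng()
    values = matrix.values.to_numpy(copy=True)
    for j, sample in enumerate(matrix.sample_ids):
        col = values[:, j]
        observed = np.isfinite(col)
        if observed.sum() < 2:
            raise ValueError(f"sample {sample} has fewer than 2 observed values")
        mu = float(col[observed].mean())
        sigma = float(col[observed].std(ddof=1))
        n_miss = int((~observed).sum())
        if n_miss:
            col[~observed] = rng.normal(mu - downshift * sigma, width * sigma, size=n_miss)
    return IntensityMatrix(
        pd.DataFrame(values, index=matrix.row_ids, columns=matrix.sample_ids),
        dict(matrix.design),
        "log2",
    )
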
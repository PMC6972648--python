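"""S0-moderated two-sample testing with permutation-based FDR.

The test statistic is the SAM-style moderated t

    d = (mean_A - mean_B) / (s + s0)

where s is the pooled (equal-variance) standard error of the mean
difference and s0 is a small positive constant ("artificial within-group
variance") that damps the statistic of rows with tiny variance, so that the
mean difference also plays a role in significance. With s0 = 0, d is
exactly the classical two-sample Student t statistic.

Significance is controlled by a permutation FDR: sample condition labels
are randomly relabelled ``n_permutations`` times (unrestricted permutation,
i.e. without grouping preservation), d is recomputed for every row under
each relabeling, and for a symmetric cutoff c the FDR is estimated as the
mean permutation count of |d*| >= c divided by the observed count of
|d| >= c. The significance cutoff is the smallest observed |d| whose
estimated FDR does not exceed the target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from sklearn.decomposition import PCA

from .matrix import IntensityMatrix

__all__ = [
    "DifferentialConfig",
    "sam_statistic",
    "permutation_fdr",
    "pca_scores",
    "pearson_hierarchical_cluster",
    "volcano_table",
]

logger = logging.getLogger(__name__)


@dataclass
class DifferentialConfig:
    """Parameters of the moderated permutation test."""

    s0: float = 0.1
    fdr: float = 0.01
    n_permutations: int = 250
    preserve_grouping: bool = False
    welch: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s0 < 0:
            raise ValueError("s0 must be >= 0")
        if not 0.0 < self.fdr < 1.0:
            raise ValueError("fdr must lie in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.preserve_grouping:
            raise NotImplementedError("grouping-preserving permutation is not implemented")


def sam_statistic(
    values_a, values_b, s0: float = 0.1, welch: bool = False
) -> tuple[float, float]:
    """Moderated t statistic and mean difference for one row.

    Returns ``(d, mean_a - mean_b)`` with d = diff / (s + s0); s is the
    pooled equal-variance standard error of the difference (or the Welch
    form when requested). At s0 = 0 this is the classical t statistic.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observed values per group")
    diff = float(a.mean() - b.mean())
    if welch:
        s = float(np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size))
    else:
        sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
            a.size + b.size - 2
        )
        s = float(np.sqrt(sp2 * (1.0 / a.size + 1.0 / b.size)))
    return diff / (s + s0), diff


def _group_stats(values: np.ndarray, in_group: np.ndarray):
    """Per-row nan-aware count, mean and variance of the masked columns."""
    sub = values[:, in_group]
    obs = np.isfinite(sub)
    n = obs.sum(axis=1)
    z = np.where(obs, sub, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = z.sum(axis=1) / n
        ss = (z * z).sum(axis=1)
        var = (ss - n * mean**2) / (n - 1)
    var = np.clip(var, 0.0, None)  # guard tiny negative round-off
    return n, mean, var


def _d_statistics(values: np.ndarray, mask_a: np.ndarray, s0: float, welch: bool):
    """Vectorized d and mean difference per row; NaN where untestable."""
    na, ma, va = _group_stats(values, mask_a)
    nb, mb, vb = _group_stats(values, ~mask_a)
    testable = (na >= 2) & (nb >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        diff = ma - mb
        if welch:
            s = np.sqrt(va / na + vb / nb)
        else:
            sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
            s = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        d = diff / (s + s0)
    d[~testable] = np.nan
    diff[~testable] = np.nan
    return d, diff, na, nb


def permutation_fdr(
    matrix: IntensityMatrix,
    config: DifferentialConfig | None = None,
    _permutations: list[np.ndarray] | None = None,
) -> pd.DataFrame:
    """Per-row moderated test with permutation-estimated FDR control.

    The mean difference is oriented as first condition minus second
    condition, conditions taken in lexicographic order (so exchanging the
    two condition labels flips every sign without otherwise changing the
    analysis). Rows with
    fewer than two observed values in either group are reported as
    untestable (significant = False, reason set) rather than dropped.

    Returns a DataFrame with columns ``row_id, mean_difference,
    d_statistic, p_value, significant, n_obs_a, n_obs_b, reason``.

    ``_permutations`` (testing hook) supplies explicit boolean group-A
    masks instead of random relabelings.
    """
    if config is None:
        config = DifferentialConfig()
    conditions = sorted(matrix.conditions())
    if len(conditions) != 2:
        raise ValueError(f"exactly two conditions required, got {conditions}")
    cond_a = conditions[0]
    samples = matrix.sample_ids
    mask_a = np.array([matrix.design[s] == cond_a for s in samples])
    values = matrix.values.to_numpy()
    n_samples = len(samples)
    n_a = int(mask_a.sum())

    d_obs, diff_obs, na_obs, nb_obs = _d_statistics(values, mask_a, config.s0, config.welch)
    testable = np.isfinite(d_obs)

    n_distinct = comb(n_samples, n_a)
    if config.n_permutations > n_distinct:
        logger.info(
            "%d randomizations requested but only %d distinct relabelings exist; "
            "sampling with replacement",
            config.n_permutations,
            n_distinct,
        )

    rng = np.random.default_rng(config.seed)
    if _permutations is not None:
        perm_masks = _permutations
    else:
        # Relabelings identical to the observed grouping (or its complement)
        # carry the alternative, not the null: with only comb(10, 5) = 252
        # distinct relabelings they occur often enough to put a hard floor
        # of ~2/252 on the estimated FDR, so they are rejected and redrawn.
        perm_masks = []
        while len(perm_masks) < config.n_permutations:
            idx = rng.permutation(n_samples)[:n_a]
            m = np.zeros(n_samples, dtype=bool)
            m[idx] = True
            if np.array_equal(m, mask_a) or np.array_equal(m, ~mask_a):
                continue
            perm_masks.append(m)

    perm_abs: list[np.ndarray] = []
    for m in perm_masks:
        d_perm, _, _, _ = _d_statistics(values, np.asarray(m, dtype=bool), config.s0, config.welch)
        perm_abs.append(np.abs(d_perm[np.isfinite(d_perm)]))
    pooled = np.sort(np.concatenate(perm_abs)) if perm_abs else np.array([])
    n_perm = len(perm_masks)

    abs_obs = np.abs(d_obs[testable])
    sorted_obs = np.sort(abs_obs)
    candidates = np.unique(abs_obs)

    # counts of |d| >= c via searchsorted on the ascending sorted arrays
    obs_count = sorted_obs.size - np.searchsorted(sorted_obs, candidates, side="left")
    perm_count = (pooled.size - np.searchsorted(pooled, candidates, side="left")) / n_perm
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr_hat = perm_count / obs_count
    passing = candidates[fdr_hat <= config.fdr]
    cutoff = float(passing.min()) if passing.size else np.inf

    # p-values from the pooled permutation distribution of |d*|
    p = np.full(values.shape[0], np.nan)
    if pooled.size:
        ge = pooled.size - np.searchsorted(pooled, np.abs(d_obs[testable]), side="left")
        p[testable] = (ge + 1.0) / (pooled.size + 1.0)
    else:
        p[testable] = 1.0

    significant = np.zeros(values.shape[0], dtype=bool)
    significant[testable] = np.abs(d_obs[testable]) >= cutoff
    reason = np.where(testable, "", "insufficient_observations")

    return pd.DataFrame(
        {
            "row_id": matrix.row_ids,
            "mean_difference": diff_obs,
            "d_statistic": d_obs,
            "p_value": p,
            "significant": significant,
            "n_obs_a": na_obs,
            "n_obs_b": nb_obs,
            "reason": reason,
        }
    )


def pca_scores(matrix: IntensityMatrix) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample-space principal component scores of a complete matrix.

    Rows (features) are centred; samples are the observations. Returns the
    score table (samples x components) and the explained-variance
    fractions, non-increasing.
    """
    values = matrix.values.to_numpy()
    if not np.isfinite(values).all():
        raise ValueError("matrix contains missing values; impute before PCA")
    x = values.T  # samples x rows
    n_comp = min(x.shape[0], x.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(x)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return (
        pd.DataFrame(scores, index=matrix.sample_ids, columns=cols),
        pca.explained_variance_ratio_,
    )


def pearson_hierarchical_cluster(matrix: IntensityMatrix) -> tuple[np.ndarray, list[str]]:
    """Average-linkage clustering of samples at 1 - Pearson correlation.

    Returns the SciPy linkage matrix and the sample order it indexes.
    """
    values = matrix.values.to_numpy()
    if not np.isfinite(values).all():
        raise ValueError("matrix contains missing values; impute before clustering")
    stds = values.std(axis=0)
    for s, sd in zip(matrix.sample_ids, stds):
        if sd == 0:
            raise ValueError(f"sample {s} has a constant profile; correlation undefined")
    corr = np.corrcoef(values.T)
    n = corr.shape[0]
    condensed = np.array([1.0 - corr[i, j] for i in range(n) for j in range(i + 1, n)])
    condensed = np.clip(condensed, 0.0, None)
    return linkage(condensed, method="average"), matrix.sample_ids


def volcano_table(results: pd.DataFrame) -> pd.DataFrame:
    """Volcano coordinates (mean difference, -log10 p) per testable row."""
    if results.empty:
        raise ValueError("no differential results supplied")
    testable = results[results["reason"] == ""]
    return pd.DataFrame(
        {
            "row_id": testable["row_id"].to_numpy(),
            "mean_difference": testable["mean_difference"].to_numpy(),
            "neg_log10_p": -np.log10(testable["p_value"].to_numpy()),
            "significant": testable["significant"].to_numpy(),
        }
    )
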
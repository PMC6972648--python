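import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster

from phosdia.differential import (
    DifferentialConfig,
    pca_scores,
    pearson_hierarchical_cluster,
    permutation_fdr,
    sam_statistic,
    volcano_table,
)
from phosdia.matrix import IntensityMatrix
from phosdia.preprocess import filter_valid_values, log2_transform
from phosdia.synthetic import SimConfig, generate_experiment

from conftest import make_matrix


def pooled_t_oracle(a, b):
    """Textbook pooled-variance two-sample t statistic."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))


class TestSamStatistic:
    def test_identical_groups_give_zero(self):
        d, diff = sam_statistic([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], s0=0.1)
        assert d == 0.0 and diff == 0.0

    def test_s0_zero_reduces_to_student_t(self, rng):
        for _ in range(25):
            a = rng.normal(0, 1, int(rng.integers(3, 8)))
            b = rng.normal(0.5, 2, int(rng.integers(3, 8)))
            d, diff = sam_statistic(a, b, s0=0.0)
            assert d == pytest.approx(pooled_t_oracle(a, b), rel=1e-12)
            assert diff == pytest.approx(a.mean() - b.mean(), rel=1e-12)

    def test_s0_shrinks_statistic_magnitude(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        d0, _ = sam_statistic(a, b, s0=0.0)
        d1, _ = sam_statistic(a, b, s0=0.1)
        assert abs(d1) < abs(d0)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            sam_statistic([1.0], [1.0, 2.0], s0=0.1)


def _synthetic_log2(seed=3, **overrides):
    cfg = SimConfig(
        n_protein_groups=80, peptides_per_group_mean=2.0, n_terms=0,
        term_size_range=(1, 1), seed=seed, **overrides,
    )
    exp = generate_experiment(cfg)
    filtered, _ = filter_valid_values(log2_transform(exp.phospho))
    return filtered, exp.truth


class TestPermutationFdr:
    def test_fixed_seed_fully_reproducible(self):
        m, _ = _synthetic_log2()
        cfg = DifferentialConfig(seed=9, n_permutations=100)
        assert permutation_fdr(m, cfg).equals(permutation_fdr(m, cfg))

    def test_label_exchange_flips_signs_keeps_significance(self):
        m, _ = _synthetic_log2()
        c1, c2 = sorted(set(m.design.values()))
        swapped = IntensityMatrix(
            m.values.copy(),
            {s: (c2 if c == c1 else c1) for s, c in m.design.items()},
            "log2",
        )
        cfg = DifferentialConfig(seed=9, n_permutations=100)
        res = permutation_fdr(m, cfg)
        res_sw = permutation_fdr(swapped, cfg)
        np.testing.assert_allclose(
            res_sw["mean_difference"], -res["mean_difference"], rtol=1e-12
        )
        np.testing.assert_allclose(res_sw["d_statistic"], -res["d_statistic"], rtol=1e-12)
        assert res_sw["significant"].equals(res["significant"])

    def test_significant_set_monotone_in_fdr(self):
        m, _ = _synthetic_log2()
        previous: set[str] = set()
        for fdr in (0.005, 0.01, 0.05, 0.1, 0.3):
            res = permutation_fdr(m, DifferentialConfig(fdr=fdr, seed=4, n_permutations=100))
            current = set(res.loc[res["significant"], "row_id"])
            assert previous <= current
            previous = current

    def test_overwhelming_single_effect_detected(self, rng):
        noise_sd = 0.5
        values = rng.normal(20, noise_sd, (200, 10))
        values[0, 5:] += 10 * noise_sd
        m = make_matrix(values)
        res = permutation_fdr(m, DifferentialConfig(seed=2))
        assert bool(res.loc[res["row_id"] == "r1", "significant"].iloc[0])

    def test_identity_relabeling_gives_no_discoveries_below_max(self, rng):
        """With the observed labeling as the only 'permutation', the FDR
        estimate is 1 everywhere, so only untouchable argmax rows may pass."""
        values = rng.normal(20, 1, (50, 10))
        values[:5, 5:] += 5
        m = make_matrix(values)
        mask_a = np.array([True] * 5 + [False] * 5)
        res = permutation_fdr(
            m,
            DifferentialConfig(n_permutations=1, seed=0),
            _permutations=[mask_a],
        )
        argmax = set(
            res.loc[res["d_statistic"].abs() == res["d_statistic"].abs().max(), "row_id"]
        )
        assert set(res.loc[res["significant"], "row_id"]) <= argmax

    def test_untestable_rows_flagged_not_dropped(self, rng):
        values = rng.normal(20, 1, (10, 10))
        values[0, :4] = np.nan  # one observation left in group a
        m = make_matrix(values)
        res = permutation_fdr(m, DifferentialConfig(seed=1, n_permutations=50))
        row = res[res["row_id"] == "r1"].iloc[0]
        assert row["reason"] == "insufficient_observations"
        assert not row["significant"]
        assert len(res) == 10

    def test_global_null_false_positives_bounded(self):
        """Averaged over 50 null simulations, false positives stay within
        twice the nominal 0.01 x n budget."""
        total_fp = 0
        n_rows = 0
        for seed in range(50):
            m, _ = _synthetic_log2(seed=seed, frac_differential=0.0)
            res = permutation_fdr(m, DifferentialConfig(seed=seed + 1))
            total_fp += int(res["significant"].sum())
            n_rows = max(n_rows, len(res))
        assert total_fp / 50 <= 0.01 * n_rows * 2

    def test_requires_two_conditions(self, rng):
        values = rng.normal(20, 1, (5, 4))
        df = pd.DataFrame(values, index=list("abcde"), columns=["s1", "s2", "s3", "s4"])
        m = IntensityMatrix(df, {f"s{i}": "only" for i in range(1, 5)}, "log2")
        with pytest.raises(ValueError):
            permutation_fdr(m)


class TestPcaScores:
    def test_identical_samples_have_identical_scores(self, rng):
        values = rng.normal(20, 1, (30, 5))
        values[:, 3] = values[:, 1]
        m = make_matrix(values)
        scores, _ = pca_scores(m)
        np.testing.assert_allclose(scores.iloc[3], scores.iloc[1], atol=1e-9)

    def test_rank_one_matrix_explained_by_first_component(self, rng):
        pattern = rng.normal(0, 1, 6)
        weights = rng.normal(0, 2, 40)
        m = make_matrix(20 + np.outer(weights, pattern))
        _, evr = pca_scores(m)
        assert evr[0] == pytest.approx(1.0, abs=1e-6)

    def test_explained_variance_fractions_well_formed(self, rng):
        m = make_matrix(rng.normal(20, 1, (50, 8)))
        _, evr = pca_scores(m)
        assert (np.diff(evr) <= 1e-12).all()
        assert ((evr >= 0) & (evr <= 1)).all()
        assert evr.sum() <= 1 + 1e-9

    def test_matches_eigendecomposition_oracle(self, rng):
        values = rng.normal(0, 1, (10, 6))
        m = make_matrix(values + 20)
        scores, _ = pca_scores(m)
        # oracle: eigendecomposition of the covariance of row-centred samples
        x = (values + 20).T
        xc = x - x.mean(axis=0)
        cov = xc.T @ xc
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        oracle = xc @ v[:, order]
        for k in range(scores.shape[1] - 1):  # last component is degenerate (rank)
            got, want = scores.to_numpy()[:, k], oracle[:, k]
            assert np.allclose(got, want, atol=1e-8) or np.allclose(got, -want, atol=1e-8)

    def test_missing_values_rejected(self, rng):
        values = rng.normal(20, 1, (10, 4))
        values[0, 0] = np.nan
        with pytest.raises(ValueError, match="imput"):
            pca_scores(make_matrix(values))


class TestPearsonHierarchicalCluster:
    def test_identical_samples_merge_first_at_zero(self, rng):
        values = rng.normal(20, 1, (30, 4))
        values[:, 2] = values[:, 0]
        linkage_matrix, samples = pearson_hierarchical_cluster(make_matrix(values))
        assert linkage_matrix[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert {int(linkage_matrix[0, 0]), int(linkage_matrix[0, 1])} == {0, 2}

    def test_three_sample_average_linkage_hand_trace(self):
        rng = np.random.default_rng(0)
        values = rng.normal(0, 1, (50, 3))
        values[:, 1] = values[:, 0] + rng.normal(0, 0.1, 50)  # s1 ~ s2
        m = make_matrix(values + 20, n_a=1)
        corr = np.corrcoef(values.T + 20)
        d12, d13, d23 = 1 - corr[0, 1], 1 - corr[0, 2], 1 - corr[1, 2]
        linkage_matrix, _ = pearson_hierarchical_cluster(m)
        assert linkage_matrix[0, 2] == pytest.approx(d12, abs=1e-12)
        assert linkage_matrix[1, 2] == pytest.approx((d13 + d23) / 2, abs=1e-12)

    def test_condition_recovery_with_separated_templates(self, rng):
        noise = 0.5
        template_a = rng.normal(20, 2, 100)
        template_b = template_a + rng.choice([-1, 1], 100) * 5 * noise
        values = np.column_stack(
            [template_a + rng.normal(0, noise, 100) for _ in range(5)]
            + [template_b + rng.normal(0, noise, 100) for _ in range(5)]
        )
        m = make_matrix(values)
        linkage_matrix, samples = pearson_hierarchical_cluster(m)
        clusters = fcluster(linkage_matrix, 2, criterion="maxclust")
        assert len(set(clusters[:5])) == 1
        assert len(set(clusters[5:])) == 1
        assert clusters[0] != clusters[5]

    def test_constant_sample_rejected_by_name(self, rng):
        values = rng.normal(20, 1, (10, 4))
        values[:, 1] = 7.0
        with pytest.raises(ValueError, match="s2"):
            pearson_hierarchical_cluster(make_matrix(values))


class TestVolcanoTable:
    def test_p_of_one_maps_to_zero(self):
        res = pd.DataFrame(
            {
                "row_id": ["r1"],
                "mean_difference": [0.5],
                "d_statistic": [1.0],
                "p_value": [1.0],
                "significant": [False],
                "reason": [""],
            }
        )
        table = volcano_table(res)
        assert table["neg_log10_p"].iloc[0] == 0.0

    def test_row_counts_and_flags_preserved(self):
        m, _ = _synthetic_log2()
        res = permutation_fdr(m, DifferentialConfig(seed=5, n_permutations=50))
        table = volcano_table(res)
        assert len(table) == int((res["reason"] == "").sum())
        merged = table.merge(res, on="row_id", suffixes=("", "_res"))
        assert (merged["significant"] == merged["significant_res"]).all()

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            volcano_table(pd.DataFrame())
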
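import numpy as np
import pandas as pd
import pytest

from phosdia import IntensityMatrix, SimConfig, generate_experiment


def make_matrix(values, scale="log2", n_a=None, sample_prefix="s"):
    """Build an IntensityMatrix from a 2-D array, first n_a columns = condition a."""
    values = np.asarray(values, dtype=float)
    n_rows, n_samples = values.shape
    if n_a is None:
        n_a = n_samples // 2
    samples = [f"{sample_prefix}{j + 1}" for j in range(n_samples)]
    design = {s: ("a" if j < n_a else "b") for j, s in enumerate(samples)}
    df = pd.DataFrame(values, index=[f"r{i + 1}" for i in range(n_rows)], columns=samples)
    return IntensityMatrix(df, design, scale)


@pytest.fixture(scope="session")
def small_experiment():
    """One deterministic ~100-peptide synthetic experiment shared by tests."""
    cfg = SimConfig(
        n_protein_groups=40,
        peptides_per_group_mean=2.5,
        n_terms=5,
        term_size_range=(5, 15),
        seed=11,
    )
    return generate_experiment(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
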
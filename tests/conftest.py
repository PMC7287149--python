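import numpy as np
import pytest

import csenet as cn


@pytest.fixture
def small_matrix():
    """2 genes x 3 samples, hand-enterable values."""
    return cn.ExpressionMatrix(
        ["gA", "gB"], ["s1", "s2", "s3"],
        np.array([[1.0, 2.0, 3.0], [4.0, 6.0, 5.0]]),
    )


@pytest.fixture
def two_subexp_design():
    """6 samples in 2 sub-experiments of 3."""
    return cn.ExperimentDesign(
        {f"s{k}": "A" if k <= 3 else "B" for k in range(1, 7)}
    )


@pytest.fixture(scope="session")
def default_dataset():
    """One draw of the default synthetic compendium (shared, read-only)."""
    return cn.generate_dataset(cn.GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def default_networks(default_dataset):
    """CSE and non-CSE Pearson networks at sparsity 0.005 on the default draw."""
    X, design, truth = default_dataset
    centered = cn.centralize_within_subexperiments(X, design)
    net_cse = cn.threshold_to_sparsity(cn.pearson_matrix(centered), 0.005)
    net_raw = cn.threshold_to_sparsity(cn.pearson_matrix(X), 0.005)
    return net_cse, net_raw


def random_score_matrix(n: int, seed: int) -> cn.ScoreMatrix:
    """Symmetric continuous score matrix with unit diagonal."""
    rng = np.random.default_rng(seed)
    raw = rng.uniform(-1.0, 1.0, size=(n, n))
    scores = np.triu(raw, k=1)
    scores = scores + scores.T
    np.fill_diagonal(scores, 1.0)
    return cn.ScoreMatrix([f"g{i:03d}" for i in range(n)], scores, "pearson")
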
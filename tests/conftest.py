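import logging

import numpy as np
import pytest

import metharg as m

logging.disable(logging.INFO)


@pytest.fixture(scope="session")
def small_proteins():
    """A small synthetic annotated-protein collection (fixed seed)."""
    return m.generate_synthetic_dataset(
        m.SyntheticConfig(n_proteins=60, seed=11)
    )


@pytest.fixture(scope="session")
def window_sets(small_proteins):
    """(positives, negatives) at window length 19 after similarity filtering."""
    cfg = m.PipelineConfig(window_length=19)
    return m.build_window_sets(small_proteins, cfg)


@pytest.fixture(scope="session")
def freq_table(window_sets):
    positives, _ = window_sets
    return m.fit_positional_frequency(positives)


@pytest.fixture(scope="session")
def encoded_balanced(window_sets, freq_table):
    """A balanced encoded dataset (X DataFrame, y) for selection/model tests."""
    positives, negatives = window_sets
    n = min(len(positives), len(negatives), 120)
    windows = list(positives)[:n] + list(negatives)[:n]
    return m.encode_dataset(windows, freq_table)


@pytest.fixture(scope="session")
def separable_xy():
    """A linearly separable two-feature toy set."""
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(0, 0.3, (10, 2)), rng.normal(3, 0.3, (10, 2))])
    y = np.array([0] * 10 + [1] * 10)
    return X, y
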
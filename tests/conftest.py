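import numpy as np
import pandas as pd
import pytest

from tmecrossmap.synthetic import (
    SyntheticCohortConfig,
    generate_planted_gep_dataset,
)


@pytest.fixture(scope="session")
def small_config():
    """Small planted dataset config: quick to factorize, full structure."""
    return SyntheticCohortConfig(
        n_genes=300,
        n_samples_a=80,
        n_samples_b=80,
        k_true=4,
        k_shared=2,
        noise_scale=0.3,
        markers_per_program=20,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_planted_gep_dataset(small_config)


@pytest.fixture(scope="session")
def medium_dataset():
    """The reference planted dataset: k_true=6, 3 shared, moderate noise."""
    cfg = SyntheticCohortConfig(
        n_genes=1000,
        n_samples_a=200,
        n_samples_b=200,
        k_true=6,
        k_shared=3,
        noise_scale=0.5,
        seed=7,
    )
    return generate_planted_gep_dataset(cfg)


def matched_cosine(W_true: np.ndarray, W_est: np.ndarray) -> float:
    """Mean cosine similarity under the optimal Hungarian column matching."""
    from scipy.optimize import linear_sum_assignment

    A = W_true / np.linalg.norm(W_true, axis=0, keepdims=True)
    B = W_est / np.linalg.norm(W_est, axis=0, keepdims=True)
    C = A.T @ B
    ri, ci = linear_sum_assignment(-C)
    return float(C[ri, ci].mean())
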
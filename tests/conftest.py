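"""Shared fixtures: tiny cohorts and atlases built in memory."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from connsig import CohortDataset, generate_atlas
from connsig.connectome import n_pairs


def make_cohort(
    n_cases: int,
    n_controls: int,
    n_regions: int,
    seed: int = 0,
    effect: np.ndarray | float = 0.0,
    with_covariates: bool = False,
) -> CohortDataset:
    """Minimal cohort: Gaussian z-space connectomes, flat covariates."""
    rng = np.random.default_rng(seed)
    n = n_cases + n_controls
    L = n_pairs(n_regions)
    conn = rng.normal(size=(n, L))
    conn[:n_cases] += effect
    pheno = pd.DataFrame(
        {
            "subject_id": [f"s{seed}_{i}" for i in range(n)],
            "group": ["case"] * n_cases + ["control"] * n_controls,
            "role": ["case"] * n_cases + ["control"] * n_controls,
            "sex": rng.binomial(1, 0.5, n) if with_covariates else np.zeros(n, dtype=int),
            "site": rng.integers(0, 2, n) if with_covariates else np.zeros(n, dtype=int),
            "age": rng.uniform(6, 45, n) if with_covariates else np.full(n, 20.0),
            "mean_fd": rng.uniform(0.1, 0.2, n) if with_covariates else np.full(n, 0.15),
        }
    )
    return CohortDataset(phenotypes=pheno, connectomes=conn)


@pytest.fixture
def atlas16():
    return generate_atlas(n_regions=16, n_networks=4, seed=0)


@pytest.fixture
def atlas64():
    return generate_atlas(n_regions=64, n_networks=12, seed=0)
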
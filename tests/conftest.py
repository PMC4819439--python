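"""Shared fixtures: small count matrices and scaled-down synthetic datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from grnx.io_formats import ExpressionMatrix, SampleMeta
from grnx.synthetic import SimConfig, generate_truth, simulate_counts


def nb_counts(rng: np.random.Generator, mu, phi: float, size=None):
    """Negative-binomial draws parameterized by (mean, dispersion)."""
    mu = np.asarray(mu, dtype=float)
    if phi < 1e-8:
        return rng.poisson(mu, size)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mu), size)


def two_group_matrix(rng: np.random.Generator, mu_a, mu_b, phi: float,
                     n_a: int = 3, n_b: int = 3, time_h: float = 36.0,
                     gene_prefix: str = "g") -> ExpressionMatrix:
    """Matrix with conditions 'A' and 'B' drawn from the given NB means."""
    mu_a = np.asarray(mu_a, dtype=float)
    cols, metas = {}, []
    for i in range(n_a):
        cols[f"A_r{i + 1}"] = nb_counts(rng, mu_a, phi)
        metas.append(SampleMeta(f"A_r{i + 1}", "A", time_h, i + 1))
    for i in range(n_b):
        cols[f"B_r{i + 1}"] = nb_counts(rng, mu_b, phi)
        metas.append(SampleMeta(f"B_r{i + 1}", "B", time_h, i + 1))
    counts = pd.DataFrame(cols, index=[f"{gene_prefix}{j}" for j in range(len(mu_a))])
    return ExpressionMatrix(counts, metas)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Scaled-down study design: fast but preserves all structure."""
    return SimConfig(genes_per_domain=60, n_shared_ventral=60, n_housekeeping=60,
                     n_decoy_tf_peaks=60)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return generate_truth(small_config, seed=11)


@pytest.fixture(scope="session")
def small_matrix(small_truth):
    return simulate_counts(small_truth, seed=12)
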
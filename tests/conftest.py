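"""Shared fixtures: simulated datasets and fitted models reused across tests.

Heavy fits are session-scoped so the sparse benchmark scenario is fitted
once and inspected by several tests.
"""

import numpy as np
import pytest
from scipy import sparse

import bann
from bann.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def sparse_dataset():
    """Sparse additive scenario: H2=0.6, rho=1, 1% sets enriched, N=J=2000."""
    cfg = SimulationConfig(n_individuals=2000, n_snps=2000, seed=7)
    X, snp_map, mask, trait = simulate_dataset(cfg)
    return X, snp_map, mask, trait


@pytest.fixture(scope="session")
def sparse_fit(sparse_dataset):
    X, _, mask, trait = sparse_dataset
    return bann.fit(X, trait.y, mask, grid_size=10)


@pytest.fixture(scope="session")
def small_dataset():
    """Small instance for fast structural tests."""
    cfg = SimulationConfig(n_individuals=300, n_snps=200, seed=1)
    return simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def toy_mask(J, sets):
    """Hand-built annotation mask with explicit member lists per set."""
    from bann.annotation import AnnotationMask

    rows, cols = [], []
    for g, members in enumerate(sets):
        for j in members:
            rows.append(j)
            cols.append(g)
    m = sparse.csc_matrix((np.ones(len(rows)), (rows, cols)), shape=(J, len(sets)))
    return AnnotationMask(
        snp_ids=np.array([f"rs{j}" for j in range(J)], dtype=object),
        set_names=np.array([f"S{g}" for g in range(len(sets))], dtype=object),
        membership=m,
        set_kind=np.array(["gene"] * len(sets), dtype=object),
    )
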
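"""Shared fixtures: small handcrafted matrices and session-scoped simulation batches.

The simulation batches are generated once per session and shared between the
module tests and the acceptance tests to keep the suite fast. Seeds are fixed
constants so every run exercises identical data.
"""

from __future__ import annotations

import numpy as np
import pytest

from wingpop import popgen_io, synthetic_data
from wingpop.popgen_io import HaplotypeMatrix, SiteTable

NULL_SEED_BASE = 11_000
INTRO_SEED_BASE = 22_000
SCAN_SEED_BASE = 33_000

N_NULL_REPS = 50
N_INTRO_REPS = 50
N_SCAN_REPS = 20


def small_matrix(alleles, positions=None, scaffold="S68", samples=None):
    """Build a HaplotypeMatrix (and matching SiteTable) from a nested list."""
    alleles = np.asarray(alleles, dtype=np.int8)
    n_sites, n_haps = alleles.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 10
    if samples is None:
        assert n_haps % 2 == 0
        samples = [f"s{i}" for i in range(n_haps // 2)]
    labels = [f"{s}|{p}" for s in samples for p in (0, 1)]
    positions = np.asarray(positions, dtype=np.int64)
    sites = SiteTable(
        scaffold,
        positions,
        np.array(["A"] * n_sites),
        np.array(["T"] * n_sites),
    )
    return sites, HaplotypeMatrix(alleles, labels, positions.copy(), scaffold=scaffold)


@pytest.fixture(scope="session")
def null_sims():
    """50 no-gene-flow quartets (300 kb chunks, small panels) for null-D checks."""
    datasets = []
    for rep in range(N_NULL_REPS):
        cfg = synthetic_data.QuartetSimConfig(
            seed=NULL_SEED_BASE + rep,
            f_intro=0.0,
            flank=100_000,
            L_region=100_000,
            n_bar=5,
            n_checker=5,
        )
        datasets.append(synthetic_data.simulate_quartet(cfg))
    return datasets


@pytest.fixture(scope="session")
def intro_sims():
    """50 full-introgression quartets at the default study conditions."""
    datasets = []
    for rep in range(N_INTRO_REPS):
        cfg = synthetic_data.QuartetSimConfig(seed=INTRO_SEED_BASE + rep, f_intro=1.0)
        datasets.append(synthetic_data.simulate_quartet(cfg))
    return datasets


@pytest.fixture(scope="session")
def scan_sims():
    """20 introgression quartets at the study's differentiation-scan panel sizes."""
    datasets = []
    for rep in range(N_SCAN_REPS):
        cfg = synthetic_data.QuartetSimConfig(
            seed=SCAN_SEED_BASE + rep, f_intro=1.0, n_bar=17, n_checker=24
        )
        datasets.append(synthetic_data.simulate_quartet(cfg))
    return datasets
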
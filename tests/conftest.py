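"""Shared fixtures: small simulated populations reused across modules."""

import numpy as np
import pytest

from hetqtl import simdata


@pytest.fixture(scope="session")
def small_cfg():
    """Two-chromosome genome: quick to simulate, enough recombination."""
    return simdata.SimConfig(
        n_individuals=300,
        chromosomes=((100_000_000, 100.0), (80_000_000, 80.0)),
        snp_density=100.0,
        coverage=0.2,
        obs_error_rate=0.01,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_arch():
    return simdata.QTLArchitecture(
        loci=(simdata.QTL("chr1", 50.0, a=0.6, d=0.5, advantageous="M"),),
        residual_sd=1.0,
        trait="trait",
    )


@pytest.fixture(scope="session")
def small_population(small_cfg, small_arch):
    return simdata.simulate_f2_population(small_cfg, small_arch)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
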
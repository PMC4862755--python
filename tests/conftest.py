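import numpy as np
import pytest

from subloci.io import variant_records
from subloci.simulate import (
    SimulationConfig,
    simulate_gwas,
    simulate_tissue_panels,
    simulate_variants_and_ld,
)


@pytest.fixture(scope="session")
def sim_cfg():
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def sim_bundle(sim_cfg):
    """Default synthetic genome: variant table, LD panel, gene annotation."""
    variants, panel, genes = simulate_variants_and_ld(sim_cfg)
    return variants, panel, genes


@pytest.fixture(scope="session")
def tissue_bundle(sim_cfg, sim_bundle):
    _, _, genes = sim_bundle
    return simulate_tissue_panels(sim_cfg, genes, seed=17)


@pytest.fixture(scope="session")
def null_stats(sim_cfg, sim_bundle):
    """Summary statistics with no planted signal (pure null)."""
    variants, _, _ = sim_bundle
    return simulate_gwas(variants, [], seed=23,
                         within_block_r2=sim_cfg.within_block_r2)


@pytest.fixture(scope="session")
def variant_map(null_stats):
    return {v.id: v for v in variant_records(null_stats)}


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
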
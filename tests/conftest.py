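import pytest

from ucescan.simulate import (
    SimulationConfig,
    random_planted_elements,
    simulate_all,
)


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory):
    """One medium synthetic data set shared by read-only tests."""
    cfg = SimulationConfig(
        seed=11,
        n_species=8,
        genome_length=80_000,
        n_chromosomes=2,
        divergence=0.2,
        n_genes=18,
        theta_neutral=0.01,
        ortholog_mismatch_fraction=0.0,
        ortholog_missing_fraction=0.0,
    )
    cfg.planted_elements = random_planted_elements(cfg, 30, (18, 90))
    outdir = tmp_path_factory.mktemp("sim_bundle")
    paths = simulate_all(cfg, str(outdir))
    return cfg, paths


@pytest.fixture()
def tiny_config():
    return SimulationConfig(
        seed=3, n_species=4, genome_length=6_000, n_chromosomes=1,
        divergence=0.3, n_genes=4,
    )
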
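import pytest

from coldsrna.simulate import (SimulationConfig, generate_catalog,
                               generate_edge_tables, simulate_counts)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_mirna=8, n_tf=6, n_targets=20, n_cis_nat_pairs=4,
        n_trans_nat_pairs=3, n_lncrna=3, seed=42,
    )


@pytest.fixture(scope="session")
def small_catalog(small_config):
    catalog, sequences = generate_catalog(small_config)
    return catalog, sequences


@pytest.fixture(scope="session")
def small_counts(small_config, small_catalog):
    catalog, _ = small_catalog
    return simulate_counts(catalog, small_config)


@pytest.fixture(scope="session")
def small_edges(small_config, small_catalog):
    catalog, _ = small_catalog
    return generate_edge_tables(catalog, small_config)
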
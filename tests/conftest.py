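import pytest

from minigene import (
    BacktranslationConfig,
    design_pools,
    load_codon_table,
    random_protein,
)


@pytest.fixture(scope="session")
def codon_table():
    return load_codon_table()


@pytest.fixture(scope="session")
def bt_config():
    return BacktranslationConfig(seed=7)


@pytest.fixture(scope="session")
def figure_scale_design():
    """The 18-target / 8-well example scale."""
    return design_pools(n_targets=18, n_wells=8, pool_size_max=5,
                        min_replicates=2, seed=11)


@pytest.fixture(scope="session")
def tetanus_sized_protein():
    """A synthetic stand-in matching the 1315-aa tetanospasmin length."""
    return random_protein(1315, seed=42, record_id="TetX_synthetic")
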
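import numpy as np
import pytest

from sedadna.simulate import (
    DamageModel,
    FragmentModel,
    make_reference_db,
    make_taxonomy,
    simulate_mito_panel,
    simulate_sample_reads,
)


@pytest.fixture(scope="session")
def taxonomy_2f():
    """2 families x 2 genera x 2 species (15 nodes)."""
    return make_taxonomy(2, 2, 2)


@pytest.fixture(scope="session")
def db_5pct(taxonomy_2f):
    """One 1-kb genome per species, 5% congener divergence."""
    return make_reference_db(taxonomy_2f, 1000, 0.05, seed=11)


@pytest.fixture(scope="session")
def clean_reads(db_5pct):
    """2,000 undamaged, error-free reads drawn evenly from all species."""
    ab = {t: 1.0 for t in db_5pct.taxa()}
    frag = FragmentModel(mean_len=55, sd_len=12, min_len=35, max_len=90)
    return simulate_sample_reads(
        db_5pct, ab, 2000, frag=frag, dmg=DamageModel.none(), seed=12
    )


@pytest.fixture(scope="session")
def mito_panel():
    """8-tip panel, 5 mutations per branch, 4-kb genome."""
    return simulate_mito_panel(8, 5, 4000, seed=21)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
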
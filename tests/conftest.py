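import numpy as np
import pandas as pd
import pytest

from cellumend.mend import ForcingSeries, MendParams, MendState
from cellumend.synthetic import (SyntheticDesign, TraitReference,
                                 gen_paired_communities)


@pytest.fixture(scope="session")
def small_design():
    return SyntheticDesign(n_taxa=100, n_samples_per_group=12, depth=2000,
                           seed=42)


@pytest.fixture(scope="session")
def small_table(small_design):
    return gen_paired_communities(small_design)


@pytest.fixture
def two_taxon_ref():
    return TraitReference(table=pd.DataFrame(
        {"rrn_copies": [2.0, 4.0], "genome_size_mbp": [4.0, 8.0],
         "gc_percent": [40.0, 60.0]},
        index=pd.Index(["a", "b"], name="taxon_id")))


@pytest.fixture(scope="session")
def constant_forcing():
    n = 400
    return ForcingSeries(temperature=np.full(n, 16.3),
                         moisture=np.full(n, 0.3),
                         litter_input=np.full(n, 0.005))


@pytest.fixture(scope="session")
def default_params():
    return MendParams()


@pytest.fixture(scope="session")
def default_init():
    return MendState()
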
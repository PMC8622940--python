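import numpy as np
import pandas as pd
import pytest

from medipdmr import normalize
from medipdmr.consensus import remove_sex_chromosomes
from medipdmr.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic cohort shared by integration-style tests."""
    cfg = SimulationConfig(seed=5, n_regions=400, n_genes=120)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def small_normalized(small_study):
    """Autosomal normalized matrix + regions for the small cohort."""
    st = small_study
    regions = remove_sex_chromosomes(st.regions)
    counts = st.counts.reindex(regions["region_id"])
    lengths = regions.set_index("region_id")["length"]
    mat = normalize.log_transform(normalize.rpkm(counts, lengths, st.library_sizes))
    batch = pd.Series(st.design["batch"].to_numpy(), index=st.design["sample_id"])
    mat, _ = normalize.combat_adjust(
        mat, batch, normalize.build_protected_design(st.design)
    )
    return mat, regions


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
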
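import numpy as np
import pytest

from clinekit import simulate as sim


@pytest.fixture(scope="session")
def panel96():
    """96-locus SNP panel at the study's end-to-end divergence."""
    return sim.simulate_parental_frequencies(96, 0.344, seed=101)


@pytest.fixture(scope="session")
def diag_panel():
    """Fully diagnostic 20-locus panel (every locus fixed between lineages)."""
    return sim.simulate_parental_frequencies(20, 1.0, seed=0, diagnostic=True)


@pytest.fixture(scope="session")
def transect_dataset(panel96):
    """25-site transect under the study-scale cline (c=1300 km, w=600 km)."""
    cline = sim.TrueCline(1300.0, 600.0)
    return sim.simulate_transect(25, cline, 16, panel96, seed=202, span=2400.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
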
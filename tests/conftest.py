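import warnings

import pytest
from hypothesis import settings

from triomics.simulate import SimConfig, simulate_all

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_bundle():
    """One default simulation shared by the recovery tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_all(SimConfig(seed=1))


@pytest.fixture(scope="session")
def small_cfg():
    """A reduced configuration for fast structural checks."""
    return SimConfig(seed=3, n_genes=60, n_chrom=2, chrom_length=400_000,
                     ipms_n_proteins=120, ipms_n_enriched=20, ipms_n_direct=8,
                     frip_n_targets=20, n_dmr_hypo=10, n_dmr_hyper=12,
                     n_dmr_switching=6, n_convergent=5)


@pytest.fixture(scope="session")
def small_bundle(small_cfg):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_all(small_cfg)
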
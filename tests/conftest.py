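import pytest
from hypothesis import settings

import neuroflux as nf

settings.register_profile("suite", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def cortex():
    return nf.load_region_config("cortex")


@pytest.fixture(scope="session")
def striatum():
    return nf.load_region_config("striatum")


@pytest.fixture(scope="session")
def hippocampus():
    return nf.load_region_config("hippocampus")


@pytest.fixture(scope="session")
def generic_init(cortex):
    """Region-agnostic starting point used for recovery fits."""
    return nf.FluxSet.from_primary(
        ratio_glu=cortex.ratio_glu, ratio_gaba=cortex.ratio_gaba,
        v_tca_glu=0.4, v_tca_gaba_net=0.15, v_shunt=0.05, v_tca_a_net=0.12,
        v_pc=0.04, v_x=0.8, v_dil_glu=0.05, v_dil_gaba=0.02, v_dil_a=0.1,
        v_dil_gln=0.1)


@pytest.fixture(scope="session")
def group_table():
    return nf.labeled_group_table()
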
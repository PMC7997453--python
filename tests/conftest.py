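import numpy as np
import pytest

from cypddi import presets
from cypddi.synth import RISynthSpec, TDISynthSpec, gen_ri_dataset, gen_tdi_dataset

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, deadline=None, max_examples=30)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def ri_design_sta_3a4():
    return presets.ri_design("STA", "CYP3A4")


@pytest.fixture(scope="session")
def tdi_design_sta_3a4():
    return presets.tdi_design("STA", "CYP3A4")


@pytest.fixture(scope="session")
def exact_ri_dataset(ri_design_sta_3a4):
    """Noiseless competitive grid generated with Vmax=10, Km=0.4, Ki=0.15."""
    spec = RISynthSpec(design=ri_design_sta_3a4, vmax=10.0, km=0.4, ki=0.15,
                       cv=0.0, seed=0)
    return gen_ri_dataset(spec)


@pytest.fixture(scope="session")
def exact_tdi_dataset(tdi_design_sta_3a4):
    """Noiseless inactivation grid generated with kinact=0.11, KI=2.45."""
    spec = TDISynthSpec(design=tdi_design_sta_3a4, kinact=0.11, ki_half=2.45,
                        cv=0.0, seed=0)
    return gen_tdi_dataset(spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210227)
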
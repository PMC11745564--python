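import pytest

from flowtrast.beam import BeamSpec, peak_irradiance
from flowtrast.catalog import load_catalog
from flowtrast.config import DEFAULT_POWERS_MW

DYE_ORDER = ["CFl", "CFl-1Br", "CFl-2Br", "CFl-4Br"]


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def dyes(catalog):
    """All catalog dyes in increasing order of bromination."""
    return [catalog[name] for name in DYE_ORDER]


@pytest.fixture(scope="session")
def irradiance_grid():
    """The seven default peak irradiances [W/cm²], 0.06–3.63 kW/cm²."""
    return [peak_irradiance(p, 50.0, 100.0) for p in DEFAULT_POWERS_MW]


@pytest.fixture(scope="session")
def default_beam_at():
    def _make(I0):
        return BeamSpec(I0=I0)

    return _make
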
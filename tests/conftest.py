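import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import sigmacomp as sc

settings.register_profile(
    "default", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def ctx() -> sc.CellContext:
    return sc.CellContext()


@pytest.fixture
def fig2a_scenario():
    """Two sigma species at equal 1 nM core affinity, fixed core and sigma70."""
    def make(alt_total: float = 0.0, kd: float = 1e-9) -> sc.Scenario:
        return sc.Scenario(
            species=(sc.SigmaSpecies("sigma70", 5700.0, kd_core=kd),
                     sc.SigmaSpecies("sigmaAlt", alt_total, kd_core=kd)),
            core=sc.CorePool(11400.0))
    return make


@pytest.fixture(scope="session")
def symmetric_cycle():
    """Symmetric two-species transcription-cycle scenario (strong binding)."""
    species = (sc.SigmaSpecies("s70", 7600.0, kd_core=1e-11, kon_core=1e8),
               sc.SigmaSpecies("salt", 7600.0, kd_core=1e-11, kon_core=1e8))
    core = sc.CorePool(11400.0)

    def promoter(name: str, cognate: str, **kw) -> sc.PromoterClass:
        return sc.PromoterClass(name=name, cognate_sigma=cognate, count=200.0,
                                km=1e-9, **kw)
    return species, core, promoter
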
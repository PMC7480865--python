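import numpy as np
import pytest

from podomap.grid import CovariateStack, GridRaster, GridSpec


@pytest.fixture
def spec4() -> GridSpec:
    return GridSpec(4, 4, 0.0, 0.0, 5.0)


@pytest.fixture
def raster4(spec4) -> GridRaster:
    return GridRaster(spec4, np.arange(16, dtype=float).reshape(4, 4))


@pytest.fixture
def stack4(spec4) -> CovariateStack:
    a = GridRaster(spec4, np.arange(16, dtype=float).reshape(4, 4))
    b = GridRaster(spec4, np.ones((4, 4)) * 2.0)
    return CovariateStack(names=["a", "b"], layers=[a, b])


@pytest.fixture(scope="session")
def small_scenario():
    """A 40x40 scenario shared by pipeline-level tests (module-scoped)."""
    from podomap.synth import ScenarioSpec, make_scenario

    spec = ScenarioSpec(
        grid=GridSpec(40, 40, 0.0, 0.0, 5.0), n_survey_sites=150, rng_seed=11,
        n_countries=4, n_ius=16,
    )
    return make_scenario(spec)
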
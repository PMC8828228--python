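import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from amus import (
    BandSet,
    ReferenceLibrary,
    SpecimenPhantomConfig,
    SpectrumVector,
    phantom_reference_library,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def band_set() -> BandSet:
    return BandSet()


@pytest.fixture(scope="session")
def library(band_set) -> ReferenceLibrary:
    """Two-class library with clearly distinct shapes: a bright near-flat
    whitish core and a steeply sloped blood spectrum."""
    return ReferenceLibrary(
        {
            "whitish_core": SpectrumVector(np.full(9, 0.85), band_set),
            "red_component": SpectrumVector(
                np.array([0.05, 0.07, 0.45, 0.55, 0.35, 0.85, 0.9, 0.92, 0.93]),
                band_set,
            ),
        }
    )


@pytest.fixture(scope="session")
def phantom_config() -> SpecimenPhantomConfig:
    """Small, fast frame used across tests (6.0 x 8.0 mm at 0.05 mm pitch)."""
    return SpecimenPhantomConfig(
        image_shape=(120, 160),
        core_control_points=((1.0, 1.5), (3.5, 2.5), (5.0, 4.0), (7.0, 4.5)),
        core_width_mm=0.8,
        seed=7,
    )


@pytest.fixture(scope="session")
def phantom_library(phantom_config) -> ReferenceLibrary:
    return phantom_reference_library(phantom_config)
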
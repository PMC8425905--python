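import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ctsize import phantoms, segmentation

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def pelvis_case():
    """Rendered single-object scene plus its spec (shared, read-only)."""
    spec = phantoms.scene_library("pelvis", size_scale=1.0, seed=7)
    ct, truth = phantoms.render(spec, ctdi_vol_mGy=10.0)
    return spec, ct, truth


@pytest.fixture(scope="session")
def two_legs_case():
    spec = phantoms.scene_library("two_legs", size_scale=1.0, seed=11)
    ct, truth = phantoms.render(spec, ctdi_vol_mGy=10.0)
    return spec, ct, truth


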
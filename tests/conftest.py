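import numpy as np
import pytest

from bronchoquant.image_io import HUImage
from bronchoquant.phantom import PhantomSpec, render_phantom
from bronchoquant.wall_detection import IBMConfig


@pytest.fixture(scope="session")
def default_cfg() -> IBMConfig:
    return IBMConfig()


@pytest.fixture(scope="session")
def clean_phantom():
    """Noiseless vessel-free mid-size airway and its rendered slice."""
    spec = PhantomSpec(lumen_radius_mm=4.75, wall_thickness_mm=1.0)
    return spec, render_phantom(spec)


@pytest.fixture(scope="session")
def pa_phantom():
    """Noiseless airway with a pulmonary-arterial-enhanced vessel in contact."""
    spec = PhantomSpec(
        lumen_radius_mm=4.75,
        wall_thickness_mm=1.0,
        vessel_radius_mm=5.0,
        vessel_hu=725.0,
        vessel_gap_mm=-0.5,
    )
    return spec, render_phantom(spec)


@pytest.fixture()
def constant_image():
    return HUImage(np.full((60, 60), -1000.0), spacing_mm=0.5)
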
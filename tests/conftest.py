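import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from sipspect import AcquisitionGeometry, PhantomConfig, make_phantom


@pytest.fixture
def small_geom():
    """16^3-compatible geometry with 24 views, attenuation + PSF on."""
    return AcquisitionGeometry(n_projections=24, matrix=(16, 16), pixel_size_mm=4.42)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def desk_phantom():
    """One small untextured phantom shared by slower tests."""
    cfg = PhantomConfig(shape=(48, 48, 32), kidney_volume_ml=80.0, background_texture_cv=0.0)
    return make_phantom(cfg, seed=3)
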
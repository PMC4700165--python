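import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hrctex.patches import HUPatch

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_patch(pixels, label="GG", fh_id=0, patch_id=0):
    return HUPatch(pixels=np.asarray(pixels, dtype=float), label=label,
                   fh_id=fh_id, patch_id=patch_id)


@pytest.fixture
def random_patch(rng):
    """A 40x40 patch of iid HU noise over the lung attenuation range."""
    return make_patch(rng.uniform(-1000, 200, size=(40, 40)))


@pytest.fixture(scope="session")
def small_phantom_table():
    """Feature table for a small 4-class phantom dataset (shared, read-only)."""
    import hrctex

    patches = hrctex.generate_dataset(4, 4, seed=11)
    return hrctex.extract_features(patches)
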
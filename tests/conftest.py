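import warnings

import numpy as np
import pytest

import gantryscan as gs

# the all-out-of-volume warning is expected in a few edge-case tests
warnings.filterwarnings("ignore", message="slice lies entirely outside")


@pytest.fixture(scope="session")
def scorer():
    return gs.AnalyticScorer(halfsat=0.02)


@pytest.fixture(scope="session")
def single_centered():
    """Fixture layout: one 14 mm sphere on the central scan line."""
    return gs.make_fixture("single_centered", seed=0)


@pytest.fixture(scope="session")
def two_tumor():
    """Fixture layout: on-axis 14 mm lesion + off-axis 18 mm lesion."""
    return gs.make_fixture("two_tumor", seed=0)


@pytest.fixture(scope="session")
def small_phantom():
    """A small phantom with a single 6 mm-radius sphere, cheap enough for
    exhaustive voxel checks."""
    lesion = gs.LesionSpec.sphere((20.0, 20.0, 15.0), 12.0, -0.3)
    return gs.build_phantom(
        extent=(40.0, 40.0, 30.0), spacing=(1.0, 1.0, 1.0),
        lesions=[lesion], texture_seed=7,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
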
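import numpy as np
import pytest

from dfcvar.core_io import BoldVolumeSeries
from dfcvar.synthetic import CohortDesign, generate_cohort
from dfcvar.variability import WindowScheme


#: standard 3 mm MNI-space affine (radiological x flip), origin at (90, -126, -72)
MNI3MM_AFFINE = np.array(
    [
        [-3.0, 0.0, 0.0, 90.0],
        [0.0, 3.0, 0.0, -126.0],
        [0.0, 0.0, 3.0, -72.0],
        [0.0, 0.0, 0.0, 1.0],
    ]
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_bold(rng):
    """A 10x10x10x60 noise volume with identity-scaled 3 mm affine."""
    data = rng.standard_normal((10, 10, 10, 60))
    affine = np.diag([3.0, 3.0, 3.0, 1.0])
    return BoldVolumeSeries(data=data, affine=affine, tr_seconds=2.0)


@pytest.fixture
def default_scheme():
    return WindowScheme(50, 1)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced synthetic cohort reused across tests (expensive to build)."""
    design = CohortDesign(n_per_group=6, n_hc=3, seed=99)
    return generate_cohort(design)
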
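import numpy as np
import pytest

from qmripred.signal_models import DceAcquisition, DiffusionAcquisition
from qmripred.synthetic_cohort import CohortConfig


@pytest.fixture
def dwi_acq():
    return DiffusionAcquisition(np.array([0.0, 600.0]))


@pytest.fixture
def dki_acq():
    return DiffusionAcquisition(np.array([0.0, 500.0, 1000.0, 1500.0, 2000.0]))


@pytest.fixture
def ivim_acq():
    return DiffusionAcquisition(
        np.array([0.0, 10, 20, 30, 50, 80, 100, 150, 200, 400, 600, 800]))


@pytest.fixture
def dce_acq():
    return DceAcquisition.uniform(35, 8.1, 4)


@pytest.fixture
def tiny_config():
    """A small, fast cohort for pipeline tests."""
    return CohortConfig(n_responders=3, n_nonresponders=2, seed=7,
                        grid_shape=(9, 9, 5), spacing_mm=(4.0, 4.0, 5.0),
                        diameter_range_cm=(1.5, 2.8),
                        dce_n_frames=20, dce_dt_s=8.1)
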
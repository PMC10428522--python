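import numpy as np
import pytest

from specres import default_grid, default_models
from specres.pipeline import build_calibration_set


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def models():
    tcb, lvm = default_models()
    return {"TCB": tcb, "LVM": lvm}


@pytest.fixture(scope="session")
def calib(models, grid):
    """Noiseless calibration set shared across tests (fits are exact)."""
    return build_calibration_set(models, grid)
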
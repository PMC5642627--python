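import pytest

from rascea import calibrated_config_path, default_config_path, load_config
from rascea.pipeline import base_case
from rascea.survival import WeibullCurve

#: the control-arm PFS curve in native 14-day-cycle units, used as the
#: canonical example curve throughout the suite
CONTROL_PFS = WeibullCurve(
    scale=0.00267, shape=1.89552, time_unit="cycle_14d", label="PFS control"
)


@pytest.fixture(scope="session")
def calibrated():
    return load_config(calibrated_config_path())


@pytest.fixture(scope="session")
def default_ps():
    return load_config(default_config_path())


@pytest.fixture(scope="session")
def bc(calibrated):
    return base_case(calibrated)
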
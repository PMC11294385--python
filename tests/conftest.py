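import pytest

from simstitch.chem import builtin_molecule, make_complex
from simstitch.metrics import CalibrationModel
from simstitch.stitching import plan_windows


@pytest.fixture(scope="session")
def paper_plan():
    """The reference 4-window stitching plan: 0.70-1.15, width 0.15, overlap 0.05."""
    return plan_windows(0.70, 1.15, 0.15, 0.05)


@pytest.fixture(scope="session")
def identity_model():
    """Calibration for data already expressed on the 1/K0 axis."""
    return CalibrationModel(slope=1.0, intercept=0.0)


@pytest.fixture(scope="session")
def pro():
    return builtin_molecule("Pro", role="selector")


@pytest.fixture(scope="session")
def phe():
    return builtin_molecule("Phe", role="selector")


@pytest.fixture(scope="session")
def pro_dimer(pro):
    """[Pro+Pro-H+Cu(II)]+ — a convenient reference complex channel."""
    return make_complex([pro, pro])
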
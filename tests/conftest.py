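import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from cytocycle.datasets import CELL_LINE_CONSTRAINTS, drug_params
from cytocycle.growth_calibration import fit_transition_params
from cytocycle.pharmacodynamics import CellLineModel


@pytest.fixture(scope="session")
def u87_calib():
    return fit_transition_params(CELL_LINE_CONSTRAINTS["U87"], seed=1)


@pytest.fixture(scope="session")
def u251_calib():
    return fit_transition_params(CELL_LINE_CONSTRAINTS["U251"], seed=1)


@pytest.fixture(scope="session")
def u87_base(u87_calib):
    return u87_calib.params


@pytest.fixture(scope="session")
def u87_model(u87_base):
    return CellLineModel(
        "U87",
        u87_base,
        tuple(drug_params("U87", d) for d in ("PD0325901", "Abemaciclib", "TAK-960")),
    )


@pytest.fixture(scope="session")
def u251_model(u251_calib):
    return CellLineModel(
        "U251",
        u251_calib.params,
        tuple(drug_params("U251", d) for d in ("PD0325901", "Abemaciclib", "TAK-960")),
    )
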
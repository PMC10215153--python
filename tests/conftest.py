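import numpy as np
import pytest

from vjms.geometry import make_knee_geometry, place_component
from vjms.equilibrium import KneeModel
from vjms.ligaments import build_ligament_set
from vjms.study import StudyConfig, run_study


@pytest.fixture(scope="session")
def base_geometry():
    return make_knee_geometry()


@pytest.fixture(scope="session")
def ligament_set(base_geometry):
    return build_ligament_set(base_geometry)


@pytest.fixture(scope="session")
def baseline_model(base_geometry, ligament_set):
    return KneeModel(place_component(base_geometry, "baseline"),
                     ligament_set)


@pytest.fixture(scope="session")
def study_results():
    """The full default malrotation study (3 conditions x 5 angles x
    neutral + 5 laxity tests); shared by the acceptance checks."""
    return run_study(StudyConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(20230503)
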
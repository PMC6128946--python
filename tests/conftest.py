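import numpy as np
import pytest

from nirscart.study import AcquisitionConfig, StudyDesign, generate_study


@pytest.fixture(scope="session")
def default_study():
    """A full-size synthetic study with the default design."""
    return generate_study(StudyDesign(seed=11))


@pytest.fixture(scope="session")
def small_study():
    """A reduced study for pipeline-level tests: 3 repair + 2 control
    ponies, one joint each, 8 locations, no unreachable locations."""
    design = StudyDesign(
        n_repair_ponies=3,
        n_control_ponies=2,
        joints_per_pony=1,
        locations_per_joint=8,
        n_unreachable=0,
        seed=5,
    )
    acq = AcquisitionConfig(n_arthro_repeats=15, n_invitro_repeats=3)
    return generate_study(design, acquisition=acq)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
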
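import numpy as np
import pytest

from myotendon import synthetic_data as sd
from myotendon import static_posture_battery as spb
from myotendon.mtu_model import MuscleParams


@pytest.fixture(scope="session")
def toy_limb():
    return sd.make_toy_limb(n_dof=2, n_mtu=4, seed=0)


@pytest.fixture(scope="session")
def study_bundle():
    """Default two-trial (walk/run) noise-free bundle with ground truth."""
    return sd.make_study_bundle(seed=0)


@pytest.fixture(scope="session")
def small_battery(toy_limb):
    return spb.run_battery(toy_limb, n_poses=300, seed=1)


@pytest.fixture
def plain_muscle():
    """A parallel-fibred, moderately stiff-tendoned reference muscle."""
    return MuscleParams(
        name="plain", m=2e-3, ell_o=0.030, L_S=0.040, alpha_o=0.0, F_max=20.0,
        tau_act=0.007, tau_deact=0.027,
    )


@pytest.fixture
def pennate_muscle():
    return MuscleParams(
        name="pennate", m=2.55e-3, ell_o=0.0242, L_S=0.0592,
        alpha_o=np.radians(30.0), F_max=29.816, tau_act=0.007, tau_deact=0.027,
    )
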
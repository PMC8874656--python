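import pytest

from rtdkit import reference
from rtdkit.control import build_system_kernel
from rtdkit.core import default_grid
from rtdkit.fitting import OperatingCondition
from rtdkit.synthetic import default_truth


@pytest.fixture(scope="session")
def truth():
    """Ground-truth RTD parameters of the reference line, per unit/condition."""
    return default_truth()


@pytest.fixture(scope="session")
def center_kernels(truth):
    """Full-line kernels at the center-point speeds for 15/50/90 kg/h."""
    kernels = {}
    for flow in (15.0, 50.0, 90.0):
        p1 = truth["blender1"][(flow, reference.CENTER_SPEED_B1)]
        p2 = truth["blender2"][(flow, reference.CENTER_SPEED_B2)]
        pf = truth["feedframe"][(flow,)]
        grid = default_grid(
            p1.theta + p2.theta + pf.theta,
            p1.tau_tank + p2.tau_tank + pf.tau_tank,
        )
        kernels[flow] = build_system_kernel(p1, p2, pf, grid)
    return kernels


@pytest.fixture
def center_condition():
    return OperatingCondition(50.0, reference.CENTER_SPEED_B1, reference.CENTER_SPEED_B2)
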
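import numpy as np
import pytest

from phasicz import HodgkinHuxley, Mahajan, simulate_ap
from phasicz.impedance import TestSignalSpec, impedance_trace


@pytest.fixture(scope="session")
def mahajan():
    return Mahajan()


@pytest.fixture(scope="session")
def hh():
    return HodgkinHuxley()


@pytest.fixture(scope="session")
def mahajan_traj(mahajan):
    """Mahajan paced to steady state at the default protocol (dt = 0.01 ms);
    expensive, computed once per session."""
    return simulate_ap(mahajan, dt=0.01)


@pytest.fixture(scope="session")
def hh_traj(hh):
    return simulate_ap(hh, dt=0.01)


@pytest.fixture(scope="session")
def mahajan_zt50(mahajan, mahajan_traj):
    """50 Hz impedance trace along the steady-state beat (0.1 ms sampling)."""
    return impedance_trace(mahajan, mahajan_traj, TestSignalSpec(50.0),
                           stride=10)


@pytest.fixture(scope="session")
def mahajan_states(mahajan_traj):
    """A spread of states across diastole/upstroke/plateau/repolarization,
    avoiding the piecewise-rate stitch voltages so finite differences are
    clean."""
    stitch = np.array([-40.0, -47.13, -7.0, -10.0, -30.0])
    idx = np.linspace(0, len(mahajan_traj) - 1, 120).astype(int)
    keep = [i for i in idx
            if np.abs(mahajan_traj.V[i] - stitch).min() > 0.05]
    return keep[:40]
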
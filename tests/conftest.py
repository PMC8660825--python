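import numpy as np
import pytest

from g2mcycle.parameters import build_default_parameters
from g2mcycle.simulate import SimulationResult, estimate_period, integrate


@pytest.fixture(scope="session")
def params():
    return build_default_parameters()


@pytest.fixture(scope="session")
def wt_result(params):
    """One wild-type run shared across tests (300 h from the bundled
    on-attractor state)."""
    return integrate(params, t_end=300.0)


@pytest.fixture(scope="session")
def wt_period(wt_result):
    return estimate_period(wt_result, species="MPF")


def make_synthetic_result(signal, times=None):
    """Wrap a single synthetic trajectory into a SimulationResult (the
    named species carries the signal; everything else is zero)."""
    from g2mcycle.registry import INDEX, N_SPECIES

    name, values = signal
    times = np.asarray(times)
    traj = np.zeros((N_SPECIES, times.size))
    traj[INDEX[name]] = values
    return SimulationResult(times, traj)
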
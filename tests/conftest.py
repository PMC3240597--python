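import numpy as np
import pytest

import circlock as cl
from circlock import experiments as ex


@pytest.fixture(scope="session")
def model():
    return cl.build_default_model()


@pytest.fixture(scope="session")
def wt_trajectory(model):
    """Wild-type run: 40 days, 20-day transient discard, 0.05 h sampling."""
    settings = cl.SimulationSettings(
        t_end=40 * 24.0, output_step=0.05, transient_discard=20 * 24.0
    )
    return cl.integrate(model, settings)


@pytest.fixture(scope="session")
def wt_summary(wt_trajectory):
    return cl.summarize(wt_trajectory, "Bmal")


@pytest.fixture(scope="session")
def ctx(model):
    """Shared experiment context (wild-type reference computed once)."""
    return ex.ExperimentContext.create(model)


def synthetic_trajectory(
    signal_fn, t_end=10 * 24.0, dt=0.05, n_species=19, discard=0.0
):
    """Trajectory whose first column carries an analytic test signal."""
    times = np.arange(0.0, t_end + dt / 2, dt)
    states = np.ones((len(times), n_species))
    states[:, 0] = signal_fn(times)
    settings = cl.SimulationSettings(
        t_end=t_end, output_step=dt, transient_discard=discard
    )
    return cl.Trajectory(times, states, settings)


@pytest.fixture
def make_synthetic_trajectory():
    return synthetic_trajectory
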
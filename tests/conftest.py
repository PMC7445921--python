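import pytest

from pharmflow import integrate, run_closed_loop, scenarios


@pytest.fixture(scope="session")
def baseline_traj():
    """Open-loop baseline run (undersized fixed schedule, recurrent stockouts)."""
    return integrate(scenarios.baseline())


@pytest.fixture(scope="session")
def tracking_run():
    """Closed-loop run under constant demand (trajectory, controller state)."""
    return run_closed_loop(scenarios.tracking())


@pytest.fixture(scope="session")
def seasonal_run():
    """Closed-loop run against the three-season demand year."""
    return run_closed_loop(scenarios.seasonal())
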
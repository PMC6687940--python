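import pytest

import trichoflux as tf


@pytest.fixture(scope="session")
def params():
    return tf.ModelParameters()


@pytest.fixture(scope="session")
def schedule():
    return tf.ForcingSchedule()


@pytest.fixture(scope="session")
def default_run(params, schedule):
    """The standard 4-day default simulation (3-day spin-up, dt = 0.001 d)."""
    return tf.run(params, schedule, days=4, dt_days=0.001, spinup_days=3)
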
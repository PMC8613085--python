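import numpy as np
import pytest
from hypothesis import settings

from mousestress import SimConfig, Task, simulate_cohort

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_cohort():
    """Eight participants, all four tasks, both stages, default effects."""
    return simulate_cohort(SimConfig(n_participants=8, seed=11))


@pytest.fixture(scope="session")
def two_task_cohort():
    """Point-and-click + drag-and-drop cohort for the separability probe."""
    cfg = SimConfig(
        n_participants=40,
        seed=5,
        tasks=(Task.POINT_AND_CLICK, Task.DRAG_AND_DROP),
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
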
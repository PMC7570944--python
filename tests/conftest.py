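import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from herdsocial import TrajectoryDataset, load_cattle_closeness

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def cattle_W():
    """The bundled 10-animal example closeness matrix."""
    return load_cattle_closeness()


def make_dataset(positions, slot_seconds=0.1, animals=None):
    """TrajectoryDataset from a (T, N, 2) array with generated ids."""
    positions = np.asarray(positions, dtype=float)
    T, N = positions.shape[:2]
    if animals is None:
        animals = tuple(f"a{i:02d}" for i in range(1, N + 1))
    return TrajectoryDataset(
        animals=animals,
        timeslots=np.arange(T),
        positions=positions,
        slot_seconds=slot_seconds,
    )


@pytest.fixture
def random_dataset():
    """Small random-walk dataset (N=6, T=40) for oracle comparisons."""
    rng = np.random.default_rng(42)
    pos = np.cumsum(rng.normal(0, 1, size=(40, 6, 2)), axis=0) + 50.0
    return make_dataset(pos)
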
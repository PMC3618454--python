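import numpy as np
import pytest

from forage import Arena, Trajectory, generate_dispersed, generate_patched


@pytest.fixture
def arena():
    return Arena()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def dispersed_env(arena):
    return generate_dispersed(arena, seed=11)


@pytest.fixture
def patched_env(arena):
    return generate_patched(arena, seed=11)


@pytest.fixture
def right_angle_path():
    return Trajectory(np.array([[0.0, 0.0], [10.0, 0.0], [10.0, 5.0]]))


def rotate(points, angle_deg, pivot=(0.0, 0.0)):
    """Reference rigid rotation used by isometry tests."""
    theta = np.radians(angle_deg)
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    pivot = np.asarray(pivot, dtype=float)
    return (np.asarray(points, dtype=float) - pivot) @ rot.T + pivot
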
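import numpy as np
import pytest

from phyto3d import PlantConfig, generate_plant, laser_profile


@pytest.fixture(scope="session")
def small_plant():
    """A deterministic day-1 plant used by several measurement tests."""
    return generate_plant(PlantConfig(day_index=1, seed=11))


@pytest.fixture(scope="session")
def small_plant_cloud(small_plant):
    """Noiseless labeled laser sampling of the small plant."""
    from phyto3d import sample_sensor

    return sample_sensor(small_plant, laser_profile(noise_sigma=0.0), seed=3)


def random_rigid_motion(rng):
    """A uniformly random rotation matrix and a translation vector."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    t = rng.uniform(-100.0, 100.0, 3)
    return rot, t
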
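import numpy as np
import pytest

from dosepred3d import PhantomConfig, StructureMask, VolumeGrid, generate_phantom, scaled_config


@pytest.fixture(scope="session")
def small_config() -> PhantomConfig:
    """Phantom anatomy scaled to a 32^3 grid at 3 mm (fast unit-test size)."""
    return scaled_config(grid_shape=(32, 32, 32), spacing_mm=3.0)


@pytest.fixture(scope="session")
def study_config() -> PhantomConfig:
    """The scaled-down study grid: 48^3 at 3 mm."""
    return scaled_config(grid_shape=(48, 48, 48), spacing_mm=3.0)


@pytest.fixture(scope="session")
def plan_sample(study_config):
    return generate_phantom(study_config, plan_seed=1234, plan_id="fixture_plan")


@pytest.fixture(scope="session")
def small_plan(small_config):
    return generate_phantom(small_config, plan_seed=42, plan_id="small_plan")


def random_dose_and_mask(rng, shape=(32, 32, 32), max_dose=50.0):
    """A random dose field and a random non-empty mask on one geometry."""
    dose = VolumeGrid(rng.uniform(0, max_dose, shape).astype(np.float32))
    mask_vals = (rng.random(shape) < 0.3).astype(np.uint8)
    if mask_vals.sum() == 0:
        mask_vals[tuple(s // 2 for s in shape)] = 1
    return dose, StructureMask("roi", mask_vals)
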
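import numpy as np
import pytest

import syndesmo3d as s3


@pytest.fixture(scope="session")
def male_mesh():
    """Male reference phantom, surfaces + truth (mesh path, no volume)."""
    spec = s3.make_preset_spec("male", seed=1)
    surfaces, _, truth = s3.generate_phantom(spec, with_volume=False)
    return surfaces, truth


@pytest.fixture(scope="session")
def female_mesh():
    spec = s3.make_preset_spec("female", seed=2)
    surfaces, _, truth = s3.generate_phantom(spec, with_volume=False)
    return surfaces, truth


@pytest.fixture(scope="session")
def male_voxel():
    """Male reference phantom voxelized at 0.625 mm with 10 debris blobs."""
    spec = s3.make_preset_spec("male", seed=1, n_debris=10,
                               debris_volume_mm3=100.0)
    surfaces, volume, truth = s3.generate_phantom(spec)
    return surfaces, volume, truth


@pytest.fixture(scope="session")
def female_voxel():
    spec = s3.make_preset_spec("female", seed=2, n_debris=10,
                               debris_volume_mm3=100.0)
    surfaces, volume, truth = s3.generate_phantom(spec)
    return surfaces, volume, truth


@pytest.fixture(scope="session")
def male_measured(male_mesh):
    """Full 3-D mesh-path measurement of the male reference phantom."""
    surfaces, truth = male_mesh
    record, landmarks, plane_x, plane_y = s3.measure_surfaces(
        surfaces, truth.articular_seed, frame=truth.frame)
    return record, landmarks, plane_x, plane_y


@pytest.fixture()
def rng():
    return np.random.default_rng(20231115)


def random_rotation(rng) -> np.ndarray:
    """Uniform-ish random rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)]])
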
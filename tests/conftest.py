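import dataclasses

import numpy as np
import pytest

from pcleval import default_phantom_spec, generate_phantom
from pcleval.imaging import LabelMask
from pcleval.phantom import place_cysts


@pytest.fixture(scope="session")
def iso_base_spec():
    """Default curved-pancreas spec at 1 mm isotropic spacing."""
    return default_phantom_spec(seed=11, spacing=(1.0, 1.0, 1.0), grid_shape=(120, 120, 72))


@pytest.fixture(scope="session")
def four_group_phantom(iso_base_spec):
    """Noiseless phantom with one cyst per volume group and a duct."""
    spec = place_cysts([40.0, 150.0, 500.0, 1500.0], iso_base_spec)
    ct, truth = generate_phantom(spec)
    return spec, ct, truth


@pytest.fixture(scope="session")
def straight_cylinder_mask():
    """Solid cylinder along z: length 120 mm, radius 5 mm, 1 mm isotropic."""
    x, y, z = np.meshgrid(np.arange(24), np.arange(24), np.arange(130), indexing="ij")
    lab = ((x - 12) ** 2 + (y - 12) ** 2 <= 25) & (z >= 5) & (z < 125)
    return LabelMask(lab, (1.0, 1.0, 1.0), semantics="pancreas")


def make_instance(voxel_ids, grid_shape, inst_id=1, voxel_volume=1.0, source="gt"):
    """Hand-built LesionInstance for small constructed voxel sets."""
    from pcleval.instances import LesionInstance

    ids = frozenset(int(i) for i in voxel_ids)
    coords = np.stack(np.unravel_index(np.fromiter(ids, dtype=np.int64), grid_shape), axis=1)
    return LesionInstance(
        id=inst_id,
        voxel_ids=ids,
        grid_shape=grid_shape,
        volume_mm3=len(ids) * voxel_volume,
        centroid_mm=tuple(coords.mean(axis=0).astype(float)),
        source=source,
    )
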
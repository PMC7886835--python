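import numpy as np
import pytest

from fluorodose.conditions import FluoroConditions
from fluorodose.geometry import CArmPose, RoomModel
from fluorodose.phantom import VoxelPhantom, synth_ct_torso


@pytest.fixture(scope="session")
def torso():
    """Default synthetic torso (128x128x64 @ 3 mm), shared read-only."""
    return synth_ct_torso(seed=0)


@pytest.fixture(scope="session")
def small_torso():
    """Coarse torso for fast Monte Carlo tests."""
    return synth_ct_torso(64, 64, 32, spacing_mm=6.0, seed=0)


@pytest.fixture()
def table2_conditions():
    """The study beam: 76 kV, 2.5 mA, 20x20 cm, SID 100 cm, 15 fps, 0.3 mmCu."""
    return FluoroConditions()


@pytest.fixture()
def pa_pose():
    return CArmPose()


@pytest.fixture()
def open_room():
    """Large room without walls or table for free-field benchmarks."""
    return RoomModel(size_m=(6.0, 6.0, 6.0), floor_below_iso_m=3.0,
                     walls_enabled=False, table_enabled=False)


def water_slab(n=(40, 40, 40), spacing_mm=5.0, origin=None):
    """Homogeneous water block phantom for closed-form benchmarks."""
    shape = tuple(n)
    hu = np.zeros(shape, dtype=np.int16)
    if origin is None:
        origin = -0.5 * spacing_mm * np.asarray(shape)
    from fluorodose.materials import Material
    return VoxelPhantom(
        hu=hu, spacing=(spacing_mm,) * 3, origin=origin,
        material_id=np.full(shape, Material.WATER, dtype=np.uint8),
        density=np.ones(shape),
        skin_mask=np.ones(shape, dtype=bool))
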
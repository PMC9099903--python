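import numpy as np
import pytest

import urbantree as ut


@pytest.fixture(scope="session")
def street_scene():
    """Small fully-rendered street scene, zero detection noise, with clutter.

    One 120 m street, 13 trees (10 m spacing, 2 m lateral offset), one
    building block, three pole-like non-tree objects and one expected
    spurious detection per image.
    """
    cfg = ut.SceneConfig(
        area_width=120.0,
        area_height=60.0,
        street_axes=[[(0.0, 30.0), (120.0, 30.0)]],
        building_rects=[(10.0, 5.0, 40.0, 20.0)],
        pole_count=3,
        false_detection_rate=1.0,
        n_training_points=600,
        seed=2,
    )
    return ut.generate_scene(cfg)


@pytest.fixture(scope="session")
def ortho_stack(street_scene):
    return street_scene.ortho


def make_raster(values, origin=(0.0, 0.0), cell_size=0.25):
    return ut.Raster(origin, cell_size, np.asarray(values, dtype=float))
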
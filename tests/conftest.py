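import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from fibrometry import InstanceMask, SceneSpec, render_scene


@pytest.fixture(scope="session")
def small_scene():
    """A compact scene with modest cell sizes, shared across tests."""
    spec = SceneSpec(
        width_px=640, height_px=640, n_fibers=5, n_vessels=2,
        fiber_length_px=(180.0, 40.0), fiber_width_px=(9.0, 2.0),
        vessel_length_px=(140.0, 25.0), vessel_width_px=(22.0, 3.0),
        curvature=0.12, noise_sd=0.02, seed=42,
    )
    return render_scene(spec)


@pytest.fixture(scope="session")
def scene_bundle(small_scene, tmp_path_factory):
    """The small scene exported to disk as a bundle."""
    from fibrometry import export_scene

    out = tmp_path_factory.mktemp("bundle")
    paths = export_scene(small_scene, out)
    return small_scene, out, paths


def make_mask(grid, class_label="fiber", offset=(0, 0), confidence=None,
              instance_id=None):
    return InstanceMask(
        class_label=class_label, offset=offset,
        grid=np.asarray(grid, dtype=bool),
        confidence=confidence, instance_id=instance_id,
    )


@pytest.fixture
def square_mask_factory():
    def make(side, offset=(0, 0), **kw):
        return make_mask(np.ones((side, side), dtype=bool), offset=offset, **kw)

    return make
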
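"""Shared fixtures: phantoms and meshes reused across the suite."""

import numpy as np
import pytest

from bctsim.phantom import (CHEST, FAT, PhantomSpec, TissueLabelMap,
                            generate_phantom)
from bctsim.mesh import CavitySpec, apply_virtual_lumpectomy, build_mesh


@pytest.fixture(scope="session")
def spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def label_map(spec):
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def breast_mesh(label_map):
    return build_mesh(label_map, 3.0)


@pytest.fixture(scope="session")
def cavity_spec(spec):
    return CavitySpec(center=spec.tumor_centre(), bed_axes=spec.tumor_axes,
                      margin=5.0)


@pytest.fixture(scope="session")
def lumpectomy_mesh(breast_mesh, cavity_spec):
    return apply_virtual_lumpectomy(breast_mesh, cavity_spec)


def block_label_map(width_mm=40.0, height_mm=20.0, pitch=0.5,
                    chest_cols=4) -> TissueLabelMap:
    """Rectangular single-material block clamped on its left edge."""
    nx = int(round(width_mm / pitch))
    ny = int(round(height_mm / pitch))
    grid = np.zeros((ny, nx), dtype=np.uint8)
    grid[:, :chest_cols] = CHEST
    grid[:, chest_cols:] = FAT
    return TissueLabelMap(grid=grid, pixel_pitch=pitch)


@pytest.fixture(scope="session")
def block_map():
    return block_label_map()
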
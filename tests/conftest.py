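"""Shared fixtures: small grids and procedurally generated masks."""
from __future__ import annotations

import numpy as np
import pytest

from dirqa.core import StructureMask, VoxelGrid


def make_grid(shape=(12, 12, 6), spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    return VoxelGrid(origin=origin, spacing=spacing, shape=shape)


def mask_from_array(arr, grid=None, label="m", role="GTVp"):
    arr = np.asarray(arr, dtype=bool)
    if grid is None:
        grid = make_grid(shape=arr.shape)
    return StructureMask(label=label, role=role, grid=grid, occupancy=arr)


def box_mask(grid, lo, hi, label="box", role="GTVp"):
    """Axis-aligned box of voxels with index lo (incl.) .. hi (excl.)."""
    occ = np.zeros(grid.shape, dtype=bool)
    occ[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    return StructureMask(label=label, role=role, grid=grid, occupancy=occ)


def random_blob_mask(rng, grid, n_seeds=3, label="blob", role="GTVn"):
    """Small random blob: union of a few random boxes, clipped to the grid."""
    occ = np.zeros(grid.shape, dtype=bool)
    for _ in range(n_seeds):
        lo = [rng.integers(0, max(1, s - 2)) for s in grid.shape]
        size = [int(rng.integers(1, 4)) for _ in grid.shape]
        hi = [min(s, l + sz) for l, sz, s in zip(lo, size, grid.shape)]
        occ[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    return StructureMask(label=label, role=role, grid=grid, occupancy=occ)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def unit_grid():
    return make_grid()
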
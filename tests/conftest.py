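import numpy as np
import pytest

from astrolayer.geometry import make_cortex_geometry
from astrolayer.morphometry import AstrocyteObject, VoxelVolume, extract_objects


@pytest.fixture
def geometry():
    """1 mm flat cortical slab, depth along the row (y) axis."""
    return make_cortex_geometry(1000.0)


def digitized_ellipsoid(semi_axes, voxel_size=(0.5, 0.5, 0.5), rotation=None):
    """Voxelize an ellipsoid with given semi-axes (µm) into a labeled volume."""
    semi_axes = np.asarray(semi_axes, dtype=float)
    vs = np.asarray(voxel_size, dtype=float)
    reach = semi_axes.max() * 1.2
    shape = np.ceil(2 * reach / vs).astype(int) + 3
    center = (shape - 1) / 2.0 * vs
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    pts = np.stack([g.ravel() for g in grids], axis=1) * vs - center
    if rotation is not None:
        pts = pts @ np.asarray(rotation)
    inside = ((pts / semi_axes) ** 2).sum(axis=1) <= 1.0
    labels = inside.reshape(tuple(shape)).astype(np.int32)
    return VoxelVolume(labels, tuple(vs))


def digitized_ball(radius_vox=15, voxel=1.0):
    n = 2 * radius_vox + 4
    zz, yy, xx = np.mgrid[0:n, 0:n, 0:n]
    c = (n - 1) / 2.0
    mask = ((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2) <= radius_vox**2
    return VoxelVolume(mask.astype(np.int32), (voxel,) * 3)


def single_object(volume: VoxelVolume) -> AstrocyteObject:
    objs = extract_objects(volume)
    assert len(objs) == 1
    return objs[0]


def rotation_about_z(angle_deg):
    """Rotation in the (z, x) plane of the (z, y, x) frame (the XZ image plane)."""
    a = np.radians(angle_deg)
    return np.array(
        [[np.cos(a), 0.0, np.sin(a)], [0.0, 1.0, 0.0], [-np.sin(a), 0.0, np.cos(a)]]
    )
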
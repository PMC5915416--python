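"""Voxel-space astrocyte generator with layer-dependent morphology.

Renders labeled 3D volumes of synthetic astrocytes: an ellipsoidal soma
with planted territorial volume, axis ratios and orientation relative to
the cortical surface, plus a recursive tree of cylindrical processes.
Layer membership fixes the depth range and the morphology distributions,
emulating the layer phenotypes of interest — radially elongated,
large-territory, highly arborized cells in the upper layers versus
tangentially elongated cells in the deep layers and small flat cells at
the pia.

Every generated cell has exactly one truth record; rerunning with the
same seed reproduces the volume bit-for-bit.  Label collisions (cells
packed too densely) raise, never merge silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..geometry import CortexGeometry
from ..morphometry import VoxelVolume
from ..sholl import ProcessTree
from ._seeds import child_rng

__all__ = [
    "LayerMorphology",
    "LayerSpec",
    "default_layer_spec",
    "simulate_astrocytes",
    "CollisionError",
]


class CollisionError(RuntimeError):
    """Two cells claimed the same voxel — the field is overcrowded."""


@dataclass(frozen=True)
class LayerMorphology:
    """Morphology distributions for one layer (means/sds; sds >= 0).

    Orientation is the angle of the soma major axis against the
    surface-tangent plane in degrees (90 = radial, 0 = tangential);
    volume is the soma territorial volume in µm³.
    """

    name: str
    count: int
    depth_range: tuple[float, float]
    orientation_mean: float = 45.0
    orientation_sd: float = 10.0
    volume_mean: float = 8000.0
    volume_sd: float = 1000.0
    elongation_mean: float = 1.5
    elongation_sd: float = 0.2
    flatness_mean: float = 1.2
    flatness_sd: float = 0.1
    n_branches: int = 4
    branch_length_mean: float = 25.0
    branch_length_sd: float = 5.0
    branch_radius: float = 1.0

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")
        for sd in (self.orientation_sd, self.volume_sd, self.elongation_sd, self.flatness_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        if not 0.0 <= self.orientation_mean <= 90.0:
            raise ValueError("orientation mean must be in [0°, 90°]")


@dataclass(frozen=True)
class LayerSpec:
    layers: tuple[LayerMorphology, ...]

    @property
    def total_cells(self) -> int:
        return sum(l.count for l in self.layers)


def default_layer_spec(cells_per_layer: int = 4) -> LayerSpec:
    """Layer phenotypes emulating the observed laminar gradient:
    small flat pial cells (layer I), radial large-territory arborized
    cells in II/III, intermediate middle layers, tangential cells in VI."""
    c = cells_per_layer
    return LayerSpec(
        layers=(
            LayerMorphology("I", c, (0.9, 1.0), 60.0, 15.0, 3000.0, 500.0,
                            1.4, 0.15, 2.0, 0.3, 3, 12.0, 3.0, 0.8),
            LayerMorphology("II/III", c, (0.65, 0.9), 75.0, 10.0, 10000.0, 1500.0,
                            1.9, 0.2, 1.2, 0.1, 6, 28.0, 5.0, 1.0),
            LayerMorphology("IV", c, (0.5, 0.65), 45.0, 15.0, 7000.0, 1000.0,
                            1.4, 0.15, 1.2, 0.1, 4, 20.0, 4.0, 1.0),
            LayerMorphology("V", c, (0.25, 0.5), 40.0, 15.0, 7000.0, 1000.0,
                            1.5, 0.15, 1.2, 0.1, 4, 20.0, 4.0, 1.0),
            LayerMorphology("VI", c, (0.0, 0.25), 15.0, 10.0, 6500.0, 1000.0,
                            1.8, 0.2, 1.3, 0.1, 3, 18.0, 4.0, 1.0),
        )
    )


def _soma_axes(volume: float, elongation: float, flatness: float) -> tuple[float, float, float]:
    """Semi-axes (a >= b >= c) of an ellipsoid with the given volume and
    ratios a/b = elongation, b/c = flatness."""
    b = (3.0 * volume * flatness / (4.0 * np.pi * elongation)) ** (1.0 / 3.0)
    return elongation * b, b, b / flatness


def _orientation_frame(theta_deg: float, geometry: CortexGeometry, rng) -> np.ndarray:
    """Orthonormal frame whose first axis makes ``theta_deg`` with the
    tangent plane (azimuth random in the tangent plane)."""
    t1, t2 = geometry.tangent_basis()
    phi = rng.uniform(0.0, 2.0 * np.pi)
    t = np.cos(phi) * t1 + np.sin(phi) * t2
    th = np.radians(theta_deg)
    u = np.cos(th) * t + np.sin(th) * geometry.normal
    # complete the frame
    v = np.cross(geometry.normal, u)
    if np.linalg.norm(v) < 1e-9:
        v = t1
    v /= np.linalg.norm(v)
    w = np.cross(u, v)
    return np.stack([u, v, w])


def _paint(labels, coords, label):
    """Write ``label`` into the grid, refusing to overwrite other cells."""
    existing = labels[coords[:, 0], coords[:, 1], coords[:, 2]]
    clash = (existing != 0) & (existing != label)
    if clash.any():
        other = int(existing[clash][0])
        raise CollisionError(
            f"cell {label} collides with cell {other}: reduce counts or volumes"
        )
    labels[coords[:, 0], coords[:, 1], coords[:, 2]] = label


def _ellipsoid_coords(center, frame, axes, voxel_size, shape):
    """Voxel indices inside the oriented ellipsoid."""
    vs = np.asarray(voxel_size)
    reach = max(axes)
    lo = np.maximum(np.floor((center - reach) / vs).astype(int), 0)
    hi = np.minimum(np.ceil((center + reach) / vs).astype(int) + 1, shape)
    if np.any(lo >= hi):
        return np.empty((0, 3), dtype=int)
    grids = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
    pts = np.stack([g.ravel() for g in grids], axis=1)
    rel = pts * vs - center
    q = (rel @ frame.T) / np.asarray(axes)
    inside = (q**2).sum(axis=1) <= 1.0
    return pts[inside]


def _cylinder_coords(p0, p1, radius, voxel_size, shape):
    """Voxel indices within ``radius`` of the segment p0→p1 (µm)."""
    vs = np.asarray(voxel_size)
    lo = np.maximum(np.floor((np.minimum(p0, p1) - radius) / vs).astype(int), 0)
    hi = np.minimum(np.ceil((np.maximum(p0, p1) + radius) / vs).astype(int) + 1, shape)
    if np.any(lo >= hi):
        return np.empty((0, 3), dtype=int)
    grids = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
    pts = np.stack([g.ravel() for g in grids], axis=1)
    phys = pts * vs
    u = p1 - p0
    L2 = float(u @ u)
    t = np.clip((phys - p0) @ u / L2, 0.0, 1.0) if L2 > 0 else np.zeros(len(phys))
    d2 = ((phys - (p0 + t[:, None] * u)) ** 2).sum(axis=1)
    return pts[d2 <= radius**2]


def _grow_tree(start, direction, length, radius, rng, n_segments=5, branch_prob=0.35):
    """Recursive polyline tree: returns list of (p0, p1, radius) segments
    and the node table for an SWC-style trace."""
    segments = []
    nodes = [(start, -1)]

    def grow(p, d, remaining, r, parent_idx, depth):
        if remaining <= 0 or depth > 4:
            return
        step = remaining / n_segments
        for _ in range(n_segments):
            drift = rng.normal(0.0, 0.25, size=3)
            d = d + drift
            d /= np.linalg.norm(d)
            p_new = p + d * step
            segments.append((p, p_new, r))
            nodes.append((p_new, parent_idx))
            parent_idx = len(nodes) - 1
            p = p_new
            if rng.random() < branch_prob and depth < 4:
                bd = d + rng.normal(0.0, 0.8, size=3)
                bd /= np.linalg.norm(bd)
                grow(p, bd, remaining * 0.5, r * 0.7, parent_idx, depth + 1)
        return

    grow(np.asarray(start, dtype=float), np.asarray(direction, dtype=float), length, radius, 0, 0)
    return segments, nodes


def simulate_astrocytes(
    geometry: CortexGeometry,
    layer_spec: LayerSpec,
    seed: int = 0,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    lateral_spacing: float | None = None,
    with_processes: bool = True,
) -> tuple[VoxelVolume, pd.DataFrame, dict[int, ProcessTree]]:
    """Render a labeled volume of synthetic astrocytes.

    Cells are laid out on a jittered lateral grid inside their layer's
    depth band; each is an oriented ellipsoidal soma (26-connected by
    construction) plus, optionally, a cylinder-tree of processes rooted
    on the soma.  Returns ``(volume, truth, trees)`` where ``truth`` has
    one row per cell (label, layer, depth, planted orientation/volume/
    ratios, branch count) and ``trees`` maps labels to the process
    centerline traces (for Sholl ground truth).

    Raises :class:`CollisionError` if two cells would share a voxel.
    """
    rng = child_rng(seed, "astrocytes")
    vs = np.asarray(voxel_size, dtype=float)
    depth_um = geometry.depth_extent

    # worst-case lateral footprint decides the grid pitch
    def reach(layer):
        a, _, _ = _soma_axes(
            layer.volume_mean + 3 * layer.volume_sd,
            layer.elongation_mean + 3 * layer.elongation_sd,
            1.0,
        )
        proc = (layer.branch_length_mean + 3 * layer.branch_length_sd) if with_processes else 0.0
        return a + proc

    max_reach = max(reach(l) for l in layer_spec.layers)
    pitch = lateral_spacing if lateral_spacing is not None else 2.0 * max_reach + 4.0
    n_max = max(l.count for l in layer_spec.layers)
    width_um = n_max * pitch
    size_z = int(np.ceil(pitch / vs[0])) + 1
    size_y = int(np.ceil(depth_um / vs[1])) + 1
    size_x = int(np.ceil(width_um / vs[2])) + 1
    labels = np.zeros((size_z, size_y, size_x), dtype=np.int32)
    shape = np.array(labels.shape)

    truth_rows = []
    trees: dict[int, ProcessTree] = {}
    label = 0
    for layer in layer_spec.layers:
        for i in range(layer.count):
            label += 1
            depth = float(rng.uniform(*layer.depth_range))
            theta = float(np.clip(rng.normal(layer.orientation_mean, layer.orientation_sd), 0.0, 90.0))
            volume = max(float(rng.normal(layer.volume_mean, layer.volume_sd)), 50.0)
            elong = max(float(rng.normal(layer.elongation_mean, layer.elongation_sd)), 1.0)
            flat = max(float(rng.normal(layer.flatness_mean, layer.flatness_sd)), 1.0)
            axes = _soma_axes(volume, elong, flat)
            center = np.array(
                [
                    pitch / 2.0 + rng.uniform(-1.0, 1.0),
                    np.clip(depth * depth_um, axes[0] + 1, depth_um - axes[0] - 1),
                    (i + 0.5) * pitch + rng.uniform(-1.0, 1.0),
                ]
            )
            frame = _orientation_frame(theta, geometry, rng)
            coords = _ellipsoid_coords(center, frame, axes, vs, shape)
            if len(coords) == 0:
                raise CollisionError(f"cell {label}: soma fell outside the volume")
            _paint(labels, coords, label)

            n_br = layer.n_branches if with_processes else 0
            node_pos = [center]
            node_parent = [-1]
            for _ in range(n_br):
                d0 = rng.normal(size=3)
                d0 /= np.linalg.norm(d0)
                length = max(float(rng.normal(layer.branch_length_mean, layer.branch_length_sd)), 2.0)
                start = center + d0 * 0.9 * min(axes)
                segs, nodes = _grow_tree(start, d0, length, layer.branch_radius, rng)
                # a centerline voxel chain stays 26-connected only if the
                # paint radius reaches the nearest voxel center anywhere
                r_min = float(np.sqrt(3.0) / 2.0 * vs.max())
                for p0, p1, r in segs:
                    _paint(labels, _cylinder_coords(p0, p1, max(r, r_min), vs, shape), label)
                offset = len(node_pos)
                for j, (p, parent) in enumerate(nodes):
                    node_pos.append(p)
                    node_parent.append(0 if parent == -1 else parent + offset)
            trees[label] = ProcessTree(
                positions=np.asarray(node_pos, dtype=float),
                parents=np.asarray(node_parent, dtype=int),
            )
            truth_rows.append(
                {
                    "label": label,
                    "layer": layer.name,
                    "relative_depth": depth,
                    "orientation_deg": theta,
                    "soma_volume_um3": volume,
                    "elongation": elong,
                    "flatness": flat,
                    "n_branches": n_br,
                }
            )
    truth = pd.DataFrame(truth_rows).set_index("label")
    return VoxelVolume(labels=labels, voxel_size=tuple(vs)), truth, trees
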
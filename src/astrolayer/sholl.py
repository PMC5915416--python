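"""Sholl analysis: intersection profiles of astrocyte process structures.

Counts crossings of a traced process tree (or a voxelized substructure)
with concentric spheres (3D) or circles (2D, after z-projection) centered
on the soma.  Trees use the standard SWC node table; voxel mode counts
connected components of the substructure inside thin spherical shells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "ProcessTree",
    "ShollProfile",
    "sholl_tree",
    "sholl_voxels",
    "read_swc",
    "write_swc",
]


@dataclass
class ProcessTree:
    """A rooted process trace: SWC-style node table.

    ``positions`` are (n, 3) in µm, (z, y, x) order internally; each
    node's parent index precedes it (root has parent -1).
    """

    positions: np.ndarray
    parents: np.ndarray
    radii: np.ndarray | None = None
    node_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.parents = np.asarray(self.parents, dtype=int)
        n = len(self.positions)
        if n == 0:
            raise ValueError("empty tree")
        if len(self.parents) != n:
            raise ValueError("positions and parents length mismatch")
        if np.count_nonzero(self.parents < 0) != 1:
            raise ValueError("tree must have exactly one root")
        if np.any(self.parents >= np.arange(n)):
            raise ValueError("each parent must precede its child")

    @property
    def root(self) -> np.ndarray:
        return self.positions[int(np.flatnonzero(self.parents < 0)[0])]

    def segments(self) -> tuple[np.ndarray, np.ndarray]:
        """Parent/child endpoint arrays of all edges, shape (m, 3) each."""
        child = np.flatnonzero(self.parents >= 0)
        return self.positions[self.parents[child]], self.positions[child]


@dataclass
class ShollProfile:
    radii: np.ndarray
    counts: np.ndarray
    mode: str
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(np.diff(self.radii) <= 0):
            raise ValueError("radii must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    def filtered(self, min_radius: float) -> "ShollProfile":
        """Restrict the profile to shells at distance > ``min_radius``
        from the center (a reporting filter for distal arborization)."""
        keep = self.radii > min_radius
        return ShollProfile(self.radii[keep], self.counts[keep], self.mode, self.center)


def _segment_sphere_crossings(p0, p1, center, r) -> int:
    """Number of transversal intersection points of segment p0→p1 with the
    sphere |x − center| = r.  Tangencies do not count."""
    u = p1 - p0
    w = p0 - center
    a = float(u @ u)
    if a == 0.0:
        return 0
    b = 2.0 * float(w @ u)
    c = float(w @ w) - r * r
    disc = b * b - 4.0 * a * c
    if disc <= 0.0:  # tangent (= 0) or miss
        return 0
    sq = np.sqrt(disc)
    roots = ((-b - sq) / (2 * a), (-b + sq) / (2 * a))
    # half-open (0, 1]: a node exactly on the shell is attributed to the
    # segment ending at it, never double-counted with its child segments
    return sum(1 for t in roots if 0.0 < t <= 1.0)


def sholl_tree(tree: ProcessTree, center=None, radii=None, mode: str = "3d") -> ShollProfile:
    """Sholl profile of a traced tree.

    ``counts[i]`` is the number of intersection points of the tree's
    segments with the sphere (3D) or circle (2D) of radius ``radii[i]``
    around ``center``; for 2D the tree is first z-projected (the section
    axis is dropped).  Tangent touches do not count.
    """
    if mode not in ("2d", "3d"):
        raise ValueError(f"mode must be '2d' or '3d', got {mode!r}")
    if radii is None:
        raise ValueError("radii are required")
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0) or np.any(np.diff(radii) <= 0):
        raise ValueError("radii must be positive and strictly increasing")
    center = np.asarray(tree.root if center is None else center, dtype=float)
    p0, p1 = tree.segments()
    if mode == "2d":
        p0, p1, center = p0[:, 1:], p1[:, 1:], center[1:]
    counts = np.zeros(len(radii), dtype=int)
    for i, r in enumerate(radii):
        counts[i] = sum(
            _segment_sphere_crossings(a, b, center, r) for a, b in zip(p0, p1)
        )
    return ShollProfile(radii, counts, mode, center)


def sholl_voxels(
    coords: np.ndarray,
    voxel_size,
    center,
    radii,
    shell_thickness: float | None = None,
) -> ShollProfile:
    """Sholl profile of a voxelized substructure.

    ``counts[i]`` is the number of 26-connected components of the voxel
    set intersecting the half-open spherical shell
    ``[r − h/2, r + h/2)``, ``h`` = ``shell_thickness`` (default: the
    smallest voxel pitch).
    """
    coords = np.asarray(coords)
    if coords.ndim != 2 or coords.shape[1] != 3 or len(coords) == 0:
        raise ValueError("coords must be a non-empty (n, 3) index array")
    voxel_size = np.asarray(voxel_size, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0) or np.any(np.diff(radii) <= 0):
        raise ValueError("radii must be positive and strictly increasing")
    h = float(voxel_size.min()) if shell_thickness is None else float(shell_thickness)
    center = np.asarray(center, dtype=float)
    phys = coords * voxel_size
    dist = np.linalg.norm(phys - center, axis=1)
    lo = coords.min(axis=0)
    mask_shape = coords.max(axis=0) - lo + 1
    struct = np.ones((3, 3, 3), dtype=bool)
    counts = np.zeros(len(radii), dtype=int)
    for i, r in enumerate(radii):
        sel = (dist >= r - h / 2) & (dist < r + h / 2)
        if not sel.any():
            continue
        shell = np.zeros(mask_shape, dtype=bool)
        idx = coords[sel] - lo
        shell[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        _, n = ndimage.label(shell, structure=struct)
        counts[i] = n
    return ShollProfile(radii, counts, "3d", center)


# --- SWC I/O (7-column dialect; columns: id type x y z radius parent) ---

def read_swc(path) -> ProcessTree:
    """Read a standard 7-column SWC trace.

    SWC stores (x, y, z); positions are reordered to the package's
    (z, y, x) convention.
    """
    ids, types, xs, ys, zs, rads, parents = [], [], [], [], [], [], []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        f = line.split()
        ids.append(int(f[0]))
        types.append(int(f[1]))
        xs.append(float(f[2]))
        ys.append(float(f[3]))
        zs.append(float(f[4]))
        rads.append(float(f[5]))
        parents.append(int(f[6]))
    id_map = {nid: i for i, nid in enumerate(ids)}
    parent_idx = np.array([-1 if p == -1 else id_map[p] for p in parents])
    pos = np.column_stack([zs, ys, xs])
    return ProcessTree(pos, parent_idx, radii=np.array(rads), node_ids=np.array(ids))


def write_swc(tree: ProcessTree, path) -> None:
    rads = tree.radii if tree.radii is not None else np.ones(len(tree.positions))
    lines = []
    for i, ((z, y, x), p, r) in enumerate(zip(tree.positions, tree.parents, rads)):
        parent_id = -1 if p < 0 else p + 1
        ntype = 1 if p < 0 else 7  # soma root, then generic process
        lines.append(f"{i + 1} {ntype} {x:.4f} {y:.4f} {z:.4f} {r:.4f} {parent_id}")
    Path(path).write_text("\n".join(lines) + "\n")
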
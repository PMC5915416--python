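"""3D morphometry of labeled astrocytes.

Operates on integer-labeled voxel volumes (one label per cell) with known
physical voxel sizes and computes the per-cell shape descriptor set used
for morphological typing: voxel-count volume and face-count surface area,
compactness and sphericity, convex-hull metrics (solidity, convexity),
a second-moment ellipsoid fit (axis lengths, elongation, flatness, and
orientation angles against the three coordinate planes), surface-referenced
orientation angles, and the volume/surface of a signal-thresholded
substructure (e.g. the microtubule skeleton inside a cell's territory).

Conventions
-----------
* arrays are indexed ``(z, y, x)`` = (section, row, column); voxel sizes
  are given in the same order, in µm; physical coordinates refer to voxel
  centers, 0-based.
* object extraction treats each distinct non-zero label as one cell and
  requires 26-connectivity.
* all orientation angles are folded into [0°, 90°].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

from .geometry import CortexGeometry

logger = logging.getLogger(__name__)

__all__ = [
    "VoxelVolume",
    "AstrocyteObject",
    "EllipsoidFit",
    "FEATURE_NAMES",
    "extract_objects",
    "shape_metrics",
    "convex_hull_metrics",
    "fit_ellipsoid",
    "relative_orientation",
    "substructure_mask",
    "orientation_2d",
    "morphometric_vector",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class VoxelVolume:
    """A 3D grid of non-negative integer labels with physical voxel sizes.

    ``voxel_size`` is ``(dz, dy, dx)`` in µm, matching the ``(z, y, x)``
    axis order of ``labels``; label 0 is background.
    """

    labels: np.ndarray
    voxel_size: tuple[float, float, float]
    axis_order: str = "zyx"

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 3:
            raise ValueError(f"labels must be 3D, got shape {arr.shape}")
        if np.issubdtype(arr.dtype, np.floating):
            raise ValueError("labels must be an integer array")
        if any(s <= 0 for s in self.voxel_size):
            raise ValueError(f"voxel sizes must be > 0, got {self.voxel_size}")
        object.__setattr__(self, "labels", arr)
        object.__setattr__(self, "voxel_size", tuple(float(s) for s in self.voxel_size))

    @property
    def voxel_volume(self) -> float:
        dz, dy, dx = self.voxel_size
        return dz * dy * dx


@dataclass
class AstrocyteObject:
    """One labeled cell: its voxel index set and physical frame."""

    label: int
    coords: np.ndarray  # (n, 3) integer voxel indices (z, y, x)
    voxel_size: tuple[float, float, float]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3 or len(self.coords) == 0:
            raise ValueError("coords must be a non-empty (n, 3) index array")

    @property
    def n_voxels(self) -> int:
        return len(self.coords)

    @property
    def physical_coords(self) -> np.ndarray:
        """Voxel-center positions in µm, shape (n, 3), (z, y, x) order."""
        return self.coords * np.asarray(self.voxel_size)

    @property
    def centroid(self) -> np.ndarray:
        return self.physical_coords.mean(axis=0)

    def to_mask(self, pad: int = 0) -> tuple[np.ndarray, np.ndarray]:
        """Boolean mask of the object's bounding box (optionally padded)
        and the bounding-box origin in voxel indices."""
        lo = self.coords.min(axis=0) - pad
        hi = self.coords.max(axis=0) + pad
        mask = np.zeros(hi - lo + 1, dtype=bool)
        idx = self.coords - lo
        mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        return mask, lo


@dataclass
class EllipsoidFit:
    """Second-moment ellipsoid of a voxel object.

    Semi-axes satisfy ``r1 >= r2 >= r3``; ``axes[i]`` is the unit
    direction of semi-axis ``i`` in (z, y, x) component order.  Plane
    angles are the inclination of the major axis against the XY, XZ and
    YZ coordinate planes, each in [0°, 90°].
    """

    center: np.ndarray
    radii: np.ndarray  # (r1, r2, r3), µm, descending
    axes: np.ndarray  # rows = unit axis directions
    degenerate: bool = False

    @property
    def elongation(self) -> float:
        return float(self.radii[0] / self.radii[1])

    @property
    def flatness(self) -> float:
        return float(self.radii[1] / self.radii[2])

    @property
    def major_axis(self) -> np.ndarray:
        return self.axes[0]

    def _plane_angle(self, normal_component: float) -> float:
        return math.degrees(math.asin(min(1.0, abs(normal_component))))

    @property
    def angle_xy(self) -> float:
        """Angle of the major axis vs the XY plane (z is the normal)."""
        return self._plane_angle(self.major_axis[0])

    @property
    def angle_xz(self) -> float:
        return self._plane_angle(self.major_axis[1])

    @property
    def angle_yz(self) -> float:
        return self._plane_angle(self.major_axis[2])


def extract_objects(
    volume: VoxelVolume, min_voxels: int = 1, check_connectivity: bool = False
) -> list[AstrocyteObject]:
    """Extract one object per distinct non-zero label.

    Objects with fewer than ``min_voxels`` voxels are dropped (and
    logged).  An all-background volume yields an empty list.
    """
    objects: list[AstrocyteObject] = []
    labels = volume.labels
    present = np.unique(labels)
    present = present[present != 0]
    if len(present) == 0:
        return objects
    # one pass over the full grid, then split per label
    flat_idx = np.flatnonzero(labels)
    coords_all = np.column_stack(np.unravel_index(flat_idx, labels.shape))
    values = labels.reshape(-1)[flat_idx]
    order = np.argsort(values, kind="stable")
    coords_all, values = coords_all[order], values[order]
    bounds = np.searchsorted(values, present, side="left")
    bounds = np.append(bounds, len(values))
    for i, lab in enumerate(present):
        coords = coords_all[bounds[i] : bounds[i + 1]]
        if len(coords) < min_voxels:
            logger.info("label %d dropped: %d voxels < floor %d", lab, len(coords), min_voxels)
            continue
        obj = AstrocyteObject(int(lab), coords, volume.voxel_size)
        if check_connectivity and not _is_connected(obj):
            logger.warning("label %d is not 26-connected", lab)
        objects.append(obj)
    return objects


def _is_connected(obj: AstrocyteObject) -> bool:
    mask, _ = obj.to_mask()
    _, n = ndimage.label(mask, structure=_STRUCT26)
    return n == 1


def surface_area(obj: AstrocyteObject) -> float:
    """Exposed-face surface area in µm².

    Counts voxel faces between object and non-object voxels, weighting
    each by its physical face area.  Face counting over-estimates the
    area of smooth surfaces by a direction-averaged factor of ~1.5 (the
    mean of |nx|+|ny|+|nz| over the sphere); comparisons between
    face-count areas are consistent, and sphericity/compactness tests
    carry this documented bias constant.
    """
    mask, _ = obj.to_mask(pad=1)
    dz, dy, dx = obj.voxel_size
    face_areas = (dy * dx, dz * dx, dz * dy)  # faces normal to z, y, x
    total = 0.0
    for axis, fa in enumerate(face_areas):
        d = np.diff(mask.astype(np.int8), axis=axis)
        total += np.count_nonzero(d) * fa
    return float(total)


def shape_metrics(obj: AstrocyteObject) -> dict[str, float]:
    """Volume, surface area, compactness and sphericity of one object.

    ``sphericity = pi^(1/3) (6V)^(2/3) / A`` and ``compactness =
    36 pi V^2 / A^3`` (both equal 1 for a perfect ball with exact area).
    """
    dz, dy, dx = obj.voxel_size
    volume = obj.n_voxels * dz * dy * dx
    area = surface_area(obj)
    sph = math.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / area
    comp = 36.0 * math.pi * volume**2 / area**3
    return {
        "volume": volume,
        "surface_area": area,
        "compactness": comp,
        "sphericity": sph,
    }


def convex_hull_metrics(obj: AstrocyteObject) -> dict[str, float]:
    """Convex-hull volume/area and the derived solidity and convexity.

    ``solidity = V / V_hull`` and ``convexity = A_hull / A``.  The hull
    is voxelized: its volume counts the voxel centers lying inside the
    convex hull of the object's voxel centers, and its surface area is
    the face-count area of that voxelized hull.  Measuring object and
    hull with the same discrete estimator keeps their ratios honest:
    convex voxel bodies score solidity = convexity = 1 exactly, hull
    dominance ``V_hull >= V`` always holds, and the smooth-surface
    face-count bias cancels between numerator and denominator.
    Degenerate (coplanar) objects raise ``ValueError``.
    """
    pts = obj.physical_coords
    if len(pts) < 4:
        raise ValueError("convex hull requires >= 4 voxels")
    try:
        hull = ConvexHull(pts)
    except QhullError as e:
        raise ValueError(f"degenerate (coplanar) object, no 3D hull: {e}") from None
    # voxelize the hull over the object's bounding box
    lo = obj.coords.min(axis=0)
    hi = obj.coords.max(axis=0)
    grids = np.meshgrid(*[np.arange(l, h + 1) for l, h in zip(lo, hi)], indexing="ij")
    cand = np.stack([g.ravel() for g in grids], axis=1)
    phys = cand * np.asarray(obj.voxel_size)
    A_eq, b_eq = hull.equations[:, :3], hull.equations[:, 3]
    inside = np.ones(len(phys), dtype=bool)
    for start in range(0, len(phys), 262_144):  # chunked: points x facets
        sl = slice(start, start + 262_144)
        inside[sl] = (phys[sl] @ A_eq.T + b_eq <= 1e-9).all(axis=1)
    hull_obj = AstrocyteObject(obj.label, cand[inside], obj.voxel_size)
    sm = shape_metrics(obj)
    hm = shape_metrics(hull_obj)
    return {
        "hull_volume": hm["volume"],
        "hull_surface_area": hm["surface_area"],
        "solidity": sm["volume"] / hm["volume"],
        "convexity": hm["surface_area"] / sm["surface_area"],
    }


def fit_ellipsoid(obj: AstrocyteObject) -> EllipsoidFit:
    """Fit the second-moment ellipsoid of the voxel set.

    The covariance of voxel-center positions (plus the per-voxel uniform
    self-moment ``size²/12``, which regularizes one-voxel-thick objects)
    is eigen-decomposed; semi-axes are ``sqrt(5 λ)`` so that a uniform
    solid ellipsoid is recovered exactly in the continuum limit.
    """
    pts = obj.physical_coords
    if len(pts) < 4:
        raise ValueError("ellipsoid fit requires >= 4 voxels")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False, bias=True)
    cov += np.diag(np.square(obj.voxel_size)) / 12.0
    evals, evecs = np.linalg.eigh(cov)  # ascending
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    degenerate = bool(evals[-1] <= 0 or evals[0] / max(evals[-1], 1e-300) > 1e12)
    radii = np.sqrt(5.0 * np.clip(evals, 0.0, None))
    return EllipsoidFit(center=center, radii=radii, axes=evecs.T.copy(), degenerate=degenerate)


def relative_orientation(fit: EllipsoidFit, geometry: CortexGeometry) -> float:
    """Angle (deg) between the major axis and the surface-tangent plane.

    90° = radial (aligned with the cortical normal), 0° = tangential.
    """
    if fit.degenerate:
        raise ValueError("degenerate major axis: orientation undefined")
    c = abs(float(fit.major_axis @ geometry.normal))
    return math.degrees(math.asin(min(1.0, c)))


def relative_plane_angles(fit: EllipsoidFit, geometry: CortexGeometry) -> tuple[float, float]:
    """XZ/YZ-style plane angles re-expressed in the surface frame.

    The cortical normal replaces the image's y axis and one tangent
    direction replaces x; the returned pair (relative-XZ, relative-YZ)
    are the major-axis inclinations against the two planes of that
    frame, in [0°, 90°].  Relative-XZ is the orientation against the
    tangent plane itself, i.e. the radial/tangential angle.
    """
    t1, _ = geometry.tangent_basis()
    v = fit.major_axis
    rel_xz = math.degrees(math.asin(min(1.0, abs(float(v @ geometry.normal)))))
    rel_yz = math.degrees(math.asin(min(1.0, abs(float(v @ t1)))))
    return rel_xz, rel_yz


def substructure_mask(
    cell: AstrocyteObject, signal: VoxelVolume, threshold: float
) -> np.ndarray:
    """Voxels of ``cell`` whose signal exceeds ``threshold``.

    Returns an (n, 3) index array; mirrors extracting a labeled
    substructure (e.g. microtubule signal) restricted to one cell's
    territory.  Grid shapes must match.
    """
    sig = np.asarray(signal.labels if isinstance(signal, VoxelVolume) else signal)
    zmax, ymax, xmax = cell.coords.max(axis=0)
    if any(m >= s for m, s in zip((zmax, ymax, xmax), sig.shape)):
        raise ValueError(f"signal grid {sig.shape} does not cover the cell ROI")
    vals = sig[cell.coords[:, 0], cell.coords[:, 1], cell.coords[:, 2]]
    return cell.coords[vals > threshold]


def orientation_2d(mask: np.ndarray, surface_direction) -> tuple[float, float]:
    """2D elongation and orientation angle of a z-projected mask.

    Fits the second-moment ellipse of the 2D pixel set and reports
    ``(elongation, angle)`` where the angle is between the major axis and
    ``surface_direction`` (the local surface tangent in the image plane,
    (row, col) components), folded into [0°, 90°].  Isotropic masks (a
    moment tie) return elongation 1 and angle ``nan``.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2 or not mask.any():
        raise ValueError("mask must be a non-empty 2D array")
    pts = np.column_stack(np.nonzero(mask)).astype(float)
    cov = np.cov(pts, rowvar=False, bias=True) + np.eye(2) / 12.0
    evals, evecs = np.linalg.eigh(cov)
    elong = float(math.sqrt(evals[1] / evals[0]))
    if abs(evals[1] - evals[0]) <= 1e-9 * max(evals[1], 1.0):
        return 1.0, float("nan")
    major = evecs[:, 1]
    t = np.asarray(surface_direction, dtype=float)
    t = t / np.linalg.norm(t)
    cosang = min(1.0, abs(float(major @ t)))
    return elong, math.degrees(math.acos(cosang))


#: The 24 named per-cell shape descriptors, in canonical order.
FEATURE_NAMES: tuple[str, ...] = (
    "volume",
    "surface_area",
    "compactness",
    "sphericity",
    "hull_volume",
    "hull_surface_area",
    "solidity",
    "convexity",
    "major_axis_length",
    "middle_axis_length",
    "minor_axis_length",
    "elongation",
    "flatness",
    "angle_xy",
    "angle_xz",
    "angle_yz",
    "relative_xz",
    "relative_yz",
    "substructure_volume",
    "substructure_surface_area",
    "hull_complement",
    "surface_to_volume",
    "substructure_fraction",
    "bbox_fill",
)


def morphometric_vector(
    obj: AstrocyteObject,
    geometry: CortexGeometry,
    signal: VoxelVolume | None = None,
    signal_threshold: float = 0.0,
    max_absent_fraction: float = 0.25,
) -> dict[str, float]:
    """Assemble the 24-parameter morphometric vector for one cell.

    Component failures (degenerate hulls or fits) leave their entries as
    NaN; a cell with more than ``max_absent_fraction`` of entries absent
    is rejected with ``ValueError`` (mirroring exclusion of cells whose
    morphology cannot be scored reliably).
    """
    out: dict[str, float] = {name: float("nan") for name in FEATURE_NAMES}
    sm = shape_metrics(obj)
    out.update(sm)
    out["surface_to_volume"] = sm["surface_area"] / sm["volume"]
    try:
        out.update(convex_hull_metrics(obj))
        out["hull_complement"] = 1.0 - out["volume"] / out["hull_volume"]
    except ValueError:
        logger.info("label %d: degenerate hull", obj.label)
    try:
        fit = fit_ellipsoid(obj)
        out["major_axis_length"] = float(fit.radii[0])
        out["middle_axis_length"] = float(fit.radii[1])
        out["minor_axis_length"] = float(fit.radii[2])
        if not fit.degenerate:
            out["elongation"] = fit.elongation
            out["flatness"] = fit.flatness
            out["angle_xy"] = fit.angle_xy
            out["angle_xz"] = fit.angle_xz
            out["angle_yz"] = fit.angle_yz
            rel_xz, rel_yz = relative_plane_angles(fit, geometry)
            out["relative_xz"] = rel_xz
            out["relative_yz"] = rel_yz
    except ValueError:
        logger.info("label %d: ellipsoid fit failed", obj.label)
    extent = obj.coords.max(axis=0) - obj.coords.min(axis=0) + 1
    out["bbox_fill"] = obj.n_voxels / float(np.prod(extent))
    if signal is not None:
        sub = substructure_mask(obj, signal, signal_threshold)
        if len(sub) > 0:
            sub_obj = AstrocyteObject(obj.label, sub, obj.voxel_size)
            ssm = shape_metrics(sub_obj)
            out["substructure_volume"] = ssm["volume"]
            out["substructure_surface_area"] = ssm["surface_area"]
            out["substructure_fraction"] = ssm["volume"] / out["volume"]
        else:
            out["substructure_volume"] = 0.0
            out["substructure_surface_area"] = 0.0
            out["substructure_fraction"] = 0.0
    n_absent = sum(1 for v in out.values() if not np.isfinite(v))
    if n_absent > max_absent_fraction * len(FEATURE_NAMES):
        raise ValueError(
            f"label {obj.label}: {n_absent}/{len(FEATURE_NAMES)} features absent; cell excluded"
        )
    return out
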
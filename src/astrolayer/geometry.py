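"""Cortex geometry: mapping positions to relative cortical depth.

The cortex is modelled as a flat slab bounded by two parallel planes, the
corpus callosum (CC, relative depth 0) and the pia (relative depth 1).
Depth increases along a fixed unit normal; the two remaining directions
span the surface-tangent plane.  All downstream analyses consume only the
relative depth of a position and the tangent/normal frame, so the flat
slab is sufficient even though a real pial surface is curved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CortexGeometry", "make_cortex_geometry"]


@dataclass(frozen=True)
class CortexGeometry:
    """Flat-slab cortical coordinate frame.

    Parameters
    ----------
    depth_extent
        Physical distance (µm) from the CC plane to the pia plane.
    normal
        Unit vector pointing from CC toward pia, in (z, y, x) order
        matching image axis conventions.
    origin
        A point on the CC plane (µm).
    """

    depth_extent: float
    normal: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 1.0, 0.0])
    )
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        if self.depth_extent <= 0:
            raise ValueError(f"depth_extent must be > 0, got {self.depth_extent}")
        n = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise ValueError("normal must be nonzero")
        object.__setattr__(self, "normal", n / norm)
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))

    def relative_depth(self, position) -> float:
        """Relative depth of ``position`` (µm): 0 at CC, 1 at the pia.

        Positions outside the slab are clipped to [0, 1].
        """
        p = np.asarray(position, dtype=float)
        d = float((p - self.origin) @ self.normal) / self.depth_extent
        return float(np.clip(d, 0.0, 1.0))

    def tangent_basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Two orthonormal vectors spanning the surface-tangent plane."""
        n = self.normal
        # pick the coordinate axis least aligned with the normal
        a = np.zeros(3)
        a[int(np.argmin(np.abs(n)))] = 1.0
        t1 = np.cross(n, a)
        t1 /= np.linalg.norm(t1)
        t2 = np.cross(n, t1)
        return t1, t2

    def depth_position(self, relative_depth: float, tangent_offset=None) -> np.ndarray:
        """Physical position at a given relative depth (inverse of
        :meth:`relative_depth` along the normal)."""
        p = self.origin + relative_depth * self.depth_extent * self.normal
        if tangent_offset is not None:
            t1, t2 = self.tangent_basis()
            p = p + tangent_offset[0] * t1 + tangent_offset[1] * t2
        return p


def make_cortex_geometry(depth_extent: float, seed: int | None = None) -> CortexGeometry:
    """Build a flat-slab geometry spanning ``depth_extent`` µm.

    ``seed`` is accepted for interface uniformity with the other
    generators; the slab itself is deterministic.
    """
    return CortexGeometry(depth_extent=float(depth_extent))
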
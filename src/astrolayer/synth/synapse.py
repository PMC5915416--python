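"""Synthetic serial-section synapse stacks with planted ensheathment.

Builds a class-labeled EM-style stack (axon / dendrite / astrocyte)
containing one cross-sectioned axon–dendrite interface spanning a known
section range, and places astrocyte profiles at interface edges (and
around the caps) so that the perimeter-summation quantifier recovers a
requested ensheathment fraction.  Default calibration follows FIB-SEM
acquisition geometry: 3.854 × 4.891 nm pixels, 20 nm section step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..ensheathment import ASTROCYTE, AXON, DENDRITE, SerialStack
from ._seeds import child_rng

__all__ = ["SynapseTruth", "simulate_synapse_stack"]


@dataclass(frozen=True)
class SynapseTruth:
    """Planted ground truth for one synthetic synapse stack."""

    f_target: float
    f_planted: float  # achievable fraction actually laid down
    n_sections: int
    first_section: int
    last_section: int
    perimeter_nm: float
    astro_nm: float
    covered_edges: int
    cap_covered: tuple[bool, bool]
    seed: int


def _place_blob(section: np.ndarray, center_rc, radius_nm: float, pixel_size) -> None:
    """Mark background pixels within ``radius_nm`` of a point as astrocyte."""
    dy, dx = pixel_size
    r0, c0 = center_rc
    ry, rx = int(np.ceil(radius_nm / dy)), int(np.ceil(radius_nm / dx))
    rows = np.arange(max(0, r0 - ry), min(section.shape[0], r0 + ry + 1))
    cols = np.arange(max(0, c0 - rx), min(section.shape[1], c0 + rx + 1))
    rr, cc = np.meshgrid((rows - r0) * dy, (cols - c0) * dx, indexing="ij")
    disc = rr**2 + cc**2 <= radius_nm**2
    win = section[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    win[disc & (win == 0)] = ASTROCYTE


def simulate_synapse_stack(
    f_target: float,
    n_sections: int = 10,
    pixel_size: tuple[float, float] = (4.891, 3.854),
    dz: float = 20.0,
    seed: int = 0,
    interface_px: int = 60,
    jitter_px: int = 0,
    blob_radius_nm: float = 80.0,
) -> tuple[SerialStack, SynapseTruth]:
    """Generate a stack whose ensheathment fraction is ``f_target``.

    The interface spans sections 1..n_sections of an (n_sections + 2)-
    section stack (one astrocyte-evaluable cap section at each end).
    Coverable units are the 2·n_sections edges (Δz each) and the two
    caps (their in-plane length each); the generator picks the unit
    combination whose total length best matches ``f_target × P`` — for
    targets representable on that grid the match is exact.  With
    ``jitter_px`` > 0 the interface row and edge columns wobble by up to
    that many pixels per section, emulating section-to-section
    segmentation noise.
    """
    if not 0.0 <= f_target <= 1.0:
        raise ValueError(f"f_target must be in [0, 1], got {f_target}")
    if n_sections < 3:
        raise ValueError("need n_sections >= 3")
    rng = child_rng(seed, "synapse-stack")
    dy, dx = pixel_size
    pad = int(np.ceil(150.0 / min(dy, dx)))  # room for contact blobs
    height = 2 * pad + 40
    width = 2 * pad + interface_px + 20
    r_if = height // 2  # dendrite starts at this row
    c0 = pad + 10
    c1 = c0 + interface_px - 1

    total = n_sections + 2
    stack = np.zeros((total, height, width), dtype=np.uint8)
    rows_off = np.zeros(total, dtype=int)
    col_off = np.zeros((total, 2), dtype=int)
    if jitter_px > 0:
        rows_off[1:-1] = rng.integers(-jitter_px, jitter_px + 1, size=n_sections)
        col_off[1:-1] = rng.integers(-jitter_px, jitter_px + 1, size=(n_sections, 2))

    for z in range(1, total - 1):
        r = r_if + rows_off[z]
        a, b = c0 + col_off[z, 0], c1 + col_off[z, 1]
        stack[z, r - 12 : r, a : b + 1] = AXON
        stack[z, r : r + 12, a : b + 1] = DENDRITE
    # cap sections: axon and dendrite present but separated (no contact)
    for z in (0, total - 1):
        stack[z, r_if - 12 : r_if - 4, c0 : c1 + 1] = AXON
        stack[z, r_if + 4 : r_if + 12, c0 : c1 + 1] = DENDRITE

    cap_len = (interface_px - 1) * dx
    P = n_sections * 2.0 * dz + 2.0 * cap_len
    target_A = f_target * P

    # choose cap coverage + edge count minimizing |A − target|
    best = None
    for cap1 in (False, True):
        for cap2 in (False, True):
            caps = cap_len * (cap1 + cap2)
            k = int(round((target_A - caps) / dz))
            k = min(max(k, 0), 2 * n_sections)
            A = caps + k * dz
            err = abs(A - target_A)
            if best is None or err < best[0]:
                best = (err, k, cap1, cap2, A)
    _, k_edges, cap1, cap2, A_planted = best

    # flag edges: fill edge 0 (left) across sections first, then edge 1
    covered = []  # (section, side)
    for side in (0, 1):
        for z in range(1, total - 1):
            if len(covered) < k_edges:
                covered.append((z, side))
    for z, side in covered:
        r = r_if + rows_off[z] - 1  # interface row (bottom axon row)
        col = (c0 + col_off[z, 0] - 3) if side == 0 else (c1 + col_off[z, 1] + 3)
        _place_blob(stack[z], (r, col), blob_radius_nm, pixel_size)
    for cap_flag, z_out in ((cap1, 0), (cap2, total - 1)):
        if cap_flag:
            _place_blob(stack[z_out], (r_if - 1, (c0 + c1) // 2), blob_radius_nm, pixel_size)

    truth = SynapseTruth(
        f_target=float(f_target),
        f_planted=float(A_planted / P),
        n_sections=n_sections,
        first_section=1,
        last_section=total - 2,
        perimeter_nm=float(P),
        astro_nm=float(A_planted),
        covered_edges=k_edges,
        cap_covered=(cap1, cap2),
        seed=int(seed),
    )
    return SerialStack(sections=stack, dz=dz, pixel_size=pixel_size), truth
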
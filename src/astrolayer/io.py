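"""File I/O: multi-page TIFF label stacks with JSON sidecar metadata.

Label volumes travel as multi-page TIFF plus a JSON file carrying the
physical calibration (voxel sizes in µm for fluorescence volumes, pixel
sizes and section interval in nm for EM stacks); feature tables and
truth tables are plain CSV.  SWC reading/writing lives in
:mod:`astrolayer.sholl`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .ensheathment import SerialStack
from .morphometry import VoxelVolume

__all__ = [
    "write_volume",
    "read_volume",
    "write_serial_stack",
    "read_serial_stack",
]


def write_volume(volume: VoxelVolume, tif_path, meta_path=None) -> None:
    """Write a labeled volume as multi-page TIFF + JSON voxel sizes."""
    tif_path = Path(tif_path)
    tifffile.imwrite(tif_path, np.asarray(volume.labels))
    meta = {"voxel_size_um": list(volume.voxel_size), "axis_order": volume.axis_order}
    mp = Path(meta_path) if meta_path else tif_path.with_suffix(".json")
    mp.write_text(json.dumps(meta, indent=2))


def read_volume(tif_path, meta_path=None) -> VoxelVolume:
    tif_path = Path(tif_path)
    mp = Path(meta_path) if meta_path else tif_path.with_suffix(".json")
    meta = json.loads(mp.read_text())
    return VoxelVolume(
        labels=tifffile.imread(tif_path),
        voxel_size=tuple(meta["voxel_size_um"]),
        axis_order=meta.get("axis_order", "zyx"),
    )


def write_serial_stack(stack: SerialStack, tif_path, meta_path=None) -> None:
    """Write an EM class-label stack as multi-page TIFF + JSON (nm units)."""
    tif_path = Path(tif_path)
    tifffile.imwrite(tif_path, np.asarray(stack.sections))
    meta = {"dz_nm": stack.dz, "pixel_size_nm": list(stack.pixel_size)}
    mp = Path(meta_path) if meta_path else tif_path.with_suffix(".json")
    mp.write_text(json.dumps(meta, indent=2))


def read_serial_stack(tif_path, meta_path=None) -> SerialStack:
    tif_path = Path(tif_path)
    mp = Path(meta_path) if meta_path else tif_path.with_suffix(".json")
    meta = json.loads(mp.read_text())
    return SerialStack(
        sections=tifffile.imread(tif_path),
        dz=meta["dz_nm"],
        pixel_size=tuple(meta["pixel_size_nm"]),
    )
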
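"""3D morphometry of synthetic astrocytes.

Generates a small labeled volume of astrocytes with layer-dependent
morphology, extracts each cell and computes its 24-parameter shape
vector, then compares the measured territorial volume and orientation
against the generator's planted truth.
"""

import pandas as pd

from astrolayer.geometry import make_cortex_geometry
from astrolayer.morphometry import extract_objects, fit_ellipsoid, morphometric_vector, relative_orientation
from astrolayer.synth import default_layer_spec, simulate_astrocytes

geometry = make_cortex_geometry(depth_extent=1000.0)  # 1 mm CC -> pia slab
volume, truth, trees = simulate_astrocytes(
    geometry, default_layer_spec(cells_per_layer=2), seed=1, voxel_size=(2.0, 2.0, 2.0)
)

rows = []
for obj in extract_objects(volume):
    vec = morphometric_vector(obj, geometry)
    angle = relative_orientation(fit_ellipsoid(obj), geometry)
    rows.append(
        {
            "label": obj.label,
            "layer": truth.loc[obj.label, "layer"],
            "territory_um3": vec["hull_volume"],
            "elongation": vec["elongation"],
            "measured_angle_deg": angle,
            "planted_angle_deg": truth.loc[obj.label, "orientation_deg"],
        }
    )

table = pd.DataFrame(rows).set_index("label")
print(table.round(1))
print(
    "\nEach row is one cell: hull ('territorial') volume in um^3, the "
    "major-axis elongation, and the orientation angle against the pial "
    "surface (90 = radial, 0 = tangential) next to the planted truth. "
    "Upper-layer cells come out radial with larger territories; deep-layer "
    "cells tangential."
)
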
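"""Sholl arborization profiles of generated process trees.

Builds the process trees of two synthetic astrocytes (an upper-layer
cell with rich arborization vs a deep-layer cell with sparse processes)
and counts process intersections with concentric shells around the soma.
"""

import numpy as np

from astrolayer.geometry import make_cortex_geometry
from astrolayer.synth import LayerMorphology, LayerSpec, simulate_astrocytes
from astrolayer.sholl import sholl_tree

spec = LayerSpec(
    layers=(
        LayerMorphology("II/III", 1, (0.65, 0.9), 75.0, 5.0, 8000.0, 500.0,
                        1.8, 0.1, 1.2, 0.05, 6, 30.0, 5.0, 1.0),
        LayerMorphology("VI", 1, (0.0, 0.25), 15.0, 5.0, 6000.0, 500.0,
                        1.8, 0.1, 1.2, 0.05, 2, 18.0, 4.0, 1.0),
    )
)
geometry = make_cortex_geometry(400.0)
_, truth, trees = simulate_astrocytes(geometry, spec, seed=3, voxel_size=(2.0, 2.0, 2.0))

radii = np.arange(5.0, 50.0, 5.0)
for label, row in truth.iterrows():
    profile = sholl_tree(trees[label], radii=radii, mode="3d")
    distal = profile.filtered(min_radius=30.0)
    print(f"layer {row['layer']:6s} crossings per shell: {list(profile.counts)}")
    print(f"{'':13s}distal (>30 um) total: {int(distal.counts.sum())}")

print(
    "\nEach count is the number of process segments crossing a sphere of "
    "that radius around the soma. The upper-layer cell keeps more "
    "crossings at distal shells - the arborization difference the "
    "profiles are designed to expose."
)
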
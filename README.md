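# astrolayer

Quantitative analysis of layer-specific astrocyte diversity in the
neocortex, as a tested, reusable Python library.

Protoplasmic astrocytes of cortical layers II–VI were long treated as
one homogeneous population.  Quantifying their differences across
layers takes five kinds of measurement, all implemented here:

* **3D morphometry** — extract labeled astrocytes from voxel volumes
  and compute a 24-parameter shape vector per cell: volume, face-count
  surface area, compactness/sphericity, voxelized convex-hull metrics
  (solidity, convexity), a second-moment ellipsoid fit (axis lengths,
  elongation R1/R2, flatness R2/R3) and orientation angles referenced
  to the pial surface (90° = radial, 0° = tangential).
* **Unbiased morphological clustering** — z-scoring; feature selection
  by the multimodal index
  `MMI = (M3² + 1)/(M4 + 3(n−1)²/((n−2)(n−3)))` (M3 = sample skewness,
  M4 = sample excess kurtosis, both bias-corrected) at threshold 0.55;
  Ward clustering; cluster number by the elbow (largest second
  difference) of the within-cluster distance curve; silhouette
  `s(i) = (b(i) − a(i))/max(a(i), b(i))`; t-SNE for display; and
  layer × cluster enrichment by a two-sided Fisher exact test (full
  enumeration or seeded Monte Carlo).
* **Sholl analysis** — 2D/3D intersection profiles of traced process
  trees (SWC) or voxelized substructures around the soma.
* **Synapse ensheathment** — from serial-section EM segmentations,
  the fraction f = A/P of the synaptic axon–dendrite interface
  perimeter apposed by astrocyte, with
  `P = n_sections·2Δz + cap₁ + cap₂` and A summing Δz per
  astrocyte-contacted edge (apposed area > 0.005 µm²) plus covered
  caps.
* **Depth-binned marker intensity and paired expression** — 0–100
  rescaled nuclear intensities with per-bin positive fractions
  (bins: bin1 0.9–1.0 … bin4 0–0.25 relative depth), and a paired
  upper-vs-deep RPKM contrast with per-animal-ratio fold changes and
  paired t-tests.

A first-class synthetic-data module (`astrolayer.synth`) generates
every input with known ground truth — labeled astrocyte volumes with
planted orientation/volume/axis ratios, feature tables with planted
bimodality and cluster structure, synapse stacks with planted coverage
fractions, paired expression with planted fold changes — so every
quantifier is validated by parameter recovery.

## Worked example

```python
import numpy as np
from astrolayer.geometry import make_cortex_geometry
from astrolayer.synth import default_layer_spec, simulate_astrocytes
from astrolayer.morphometry import extract_objects, fit_ellipsoid, relative_orientation

geometry = make_cortex_geometry(depth_extent=1000.0)       # 1 mm CC -> pia
volume, truth, trees = simulate_astrocytes(
    geometry, default_layer_spec(cells_per_layer=2), seed=1,
    voxel_size=(1.0, 1.0, 1.0), with_processes=False,      # clean somata
)
for obj in extract_objects(volume)[:3]:
    angle = relative_orientation(fit_ellipsoid(obj), geometry)
    print(obj.label, truth.loc[obj.label, "layer"],
          round(angle, 1), round(truth.loc[obj.label, "orientation_deg"], 1))
```

prints one line per cell — label, layer, measured orientation against
the pial surface, planted orientation:

```
1 I 46.2 46.2
2 I 89.8 90.0
3 II/III 61.1 61.1
```

i.e. the moment-tensor fit recovers the planted cell orientation to a
fraction of a degree on clean volumes.  The `examples/` directory holds
one such narrative script per capability (morphometry, clustering,
Sholl, ensheathment, marker intensity, expression); each builds a small
synthetic input, runs the method and explains the numbers it prints.

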
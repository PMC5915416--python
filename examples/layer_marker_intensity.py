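"""Depth-binned nuclear marker intensity quantification.

Simulates nuclear marker intensities (a Lef1-like pattern: positive
cells concentrated in the superficial bins), rescales raw medians to
0-100 per image, thresholds positivity with Otsu, and tests the bin
effect by one-way ANOVA with Bonferroni pairwise comparisons.
"""

from astrolayer.layerstats import positive_fraction, scale_intensities
from astrolayer.synth import BinEffect, simulate_intensity_cells

effects = {
    "bin1": BinEffect(positive_proportion=0.85),
    "bin2": BinEffect(positive_proportion=0.80),
    "bin3": BinEffect(positive_proportion=0.25),
    "bin4": BinEffect(positive_proportion=0.10),
}
cells, truth = simulate_intensity_cells(effects, n_per_bin=150, seed=11)
cells["scaled_intensity"] = scale_intensities(cells["raw_intensity"].to_numpy())

out = positive_fraction(cells, threshold_rule="otsu")
print(f"Otsu positivity threshold on the 0-100 scale: {out['threshold']:.1f}")
print("\nfraction of marker-positive astrocytes per bin:")
print(out["per_bin"].round(3))
print(f"\none-way ANOVA across bins: p = {out['anova_p']:.2e}")
for (b1, b2), p in sorted(out["pairwise_bonferroni"].items()):
    print(f"  {b1} vs {b2}: Bonferroni p = {p:.3g}")
print(
    "\nbin1 is the most superficial depth bin (relative depth 0.9-1.0, "
    "layer I) and bin4 the deepest (0-0.25, layer VI). The marker is "
    "enriched in superficial astrocytes, and the ANOVA confirms the "
    "layer dependence."
)
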
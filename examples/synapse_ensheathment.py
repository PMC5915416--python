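"""Astrocyte ensheathment of synapses from serial-section stacks.

Generates EM-style serial-section stacks with planted ensheathment
fractions (upper-layer synapses heavily covered, deep-layer synapses
sparsely covered), reconstructs each synaptic axon-dendrite interface,
and compares the two groups with Welch's t-test.
"""

import numpy as np

from astrolayer.ensheathment import compare_groups, ensheathment_fraction, reconstruct_synapse
from astrolayer.synth import simulate_synapse_stack

def measure(f_target, seed):
    stack, truth = simulate_synapse_stack(f_target, seed=seed, jitter_px=1)
    seed_pt = (5, stack.sections.shape[1] // 2 - 1, stack.sections.shape[2] // 2)
    rec = reconstruct_synapse(stack, seed_pt)
    res = ensheathment_fraction(rec)
    return res

rng = np.random.default_rng(0)
bin2 = []  # upper-layer synapses: high planted coverage
bin4 = []  # deep-layer synapses: low planted coverage
for i in range(16):
    bin2.append(measure(float(np.clip(rng.normal(0.75, 0.08), 0, 1)), seed=100 + i).fraction)
    bin4.append(measure(float(np.clip(rng.normal(0.40, 0.08), 0, 1)), seed=200 + i).fraction)

one = measure(0.5, seed=999)
print(f"single synapse: perimeter P = {one.perimeter_nm:.0f} nm, "
      f"astrocytic A = {one.astro_nm:.0f} nm, fraction f = {one.fraction:.3f}")

out = compare_groups(bin2, bin4)
print(f"bin2 mean f = {out['mean_a']:.3f}, bin4 mean f = {out['mean_b']:.3f}, "
      f"Welch p = {out['p']:.2e}")
print(
    "\nf = A/P is the share of the synaptic interface perimeter apposed "
    "by astrocyte. Upper-layer (bin2) synapses are ensheathed roughly "
    "twice as much as deep-layer (bin4) ones in this simulation, and the "
    "difference is highly significant."
)
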
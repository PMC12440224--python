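"""Optimize a single stimulus against the five-term loss and validate it.

The generator trains a tanh-decoded parameter tensor (initialized from white
noise) with AdamW until the measured mean |cosine| similarities hit the
assigned targets; the balancing decoder guarantees that neither half of the
lattice carries a mean-luminance or contrast cue.
"""

import numpy as np

from temposeg import CorrelationSpec, GeneratorConfig, GridSpec, optimize_stimulus

grid = GridSpec()
spec = CorrelationSpec(xi_within=0.8, xi_cross=0.2)
stim, diag = optimize_stimulus(spec, grid, GeneratorConfig(), seed=0)

print(f"steps run            : {diag['steps']}")
print(f"converged            : {diag['converged']}")
print(f"measured within |cos|: {diag['measured_within']:.3f}  (target {spec.xi_within})")
print(f"measured cross  |cos|: {diag['measured_cross']:.3f}  (target {spec.xi_cross})")

split = grid.area_split_col
left, right = stim.values[:, :split, :], stim.values[:, split:, :]
print(f"per-frame area mean difference (max): "
      f"{np.abs(left.mean(axis=(0, 1)) - right.mean(axis=(0, 1))).max():.2e}")
print("\nThe last line shows the architectural spatial-cue balance: the two")
print("halves are indistinguishable by mean luminance on every frame.")
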
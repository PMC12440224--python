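"""Synthesize a latent-factor stimulus bank and inspect its similarity structure.

Builds dynamic 8x16 textures whose element-pairwise temporal correlations
follow assigned within-area and cross-area targets, then measures the mean
absolute cosine similarity actually realized.
"""

from temposeg import (
    CorrelationSpec,
    GridSpec,
    mean_similarities,
    synthesize_latent,
)

grid = GridSpec()  # 8 x 16 elements, 30 frames at 30 Hz

for w, c in [(0.9, 0.1), (0.5, 0.3), (0.5, 0.5)]:
    stim = synthesize_latent(CorrelationSpec(w, c), grid, seed=1)
    mw, mc = mean_similarities(stim)
    print(f"assigned within={w:.1f} cross={c:.1f}  ->  measured within={mw:.3f} cross={mc:.3f}")

print(
    "\nMeasured values scatter around the targets (sampling noise of 30-frame"
    "\nseries); the (0.5, 0.5) spec is a null texture with no segmentation cue."
)
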
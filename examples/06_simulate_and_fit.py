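"""Simulate proportion-correct surfaces and fit observer parameters.

Runs the two-interval protocol over a reduced design for the naive
(noiseless, unweighted) observer and for a noisy observer, then recovers the
noisy observer's parameters by grid search on its own surface.
"""

from temposeg import (
    ExperimentDesign,
    GridSpec,
    ObserverParams,
    batch_synthesize,
    grid_search,
    simulate_surface,
)

grid = GridSpec()
design = ExperimentDesign(levels=(0.2, 0.4, 0.6, 0.8), n_variants=8)
bank = batch_synthesize(design, grid, seed=6)

naive = simulate_surface(bank, ObserverParams.naive(), n_trials=200, seed=1)
print("naive observer (s=1, sigma=inf):")
for (w, c), pc in sorted(naive.entries.items()):
    print(f"  within={w:.1f} cross={c:.1f}: proportion correct {pc:.2f}")

truth = ObserverParams(signal_rate=0.6, sigma_delta=6.0)
ref = simulate_surface(bank, truth, n_trials=300, seed=2)
fit = grid_search(bank, ref, n_s=6, n_sigma=5, sigma_max=16.5, n_trials=100, seed=3)
print(f"\ngrid search over 6 x 5 parameter pairs:")
print(f"  truth   : s={truth.signal_rate:.2f}, sigma={truth.sigma_delta:.1f}")
print(f"  best fit: s={fit.best_params.signal_rate:.2f}, "
      f"sigma={fit.best_params.sigma_delta:.1f}, R^2={fit.best_r2:.3f}")
print("\nThe naive observer is near ceiling off the diagonal; adding internal")
print("noise (s < 1) grades performance with the within/cross gap, and the")
print("grid search localizes the signal rate sharply (sigma more shallowly).")
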
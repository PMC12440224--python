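"""Analytic latent-factor synthesis of correlation-structured textures.

Construction: each area carries a shared latent sequence (``zA``, ``zB``)
with ``corr(zA, zB) = xi_cross / xi_within``; every cell's sequence is

    sqrt(xi_within) * z_area + sqrt(1 - xi_within) * eps_cell

with i.i.d. idiosyncratic noise ``eps``.  Expected pairwise correlation is
then ``xi_within`` inside an area and ``xi_cross`` across areas.  Sequences
are zero-mean by construction, so cosine similarity is a sample correlation;
at 30 frames it scatters around the population value with sd ~ 0.18.

This synthesizer is instantaneous and serves as an independent fixture and
oracle for the validation, observer and simulation machinery; unlike the
optimized generator it guarantees only the similarity structure (not
spatial-cue invisibility or an exactly flat spectrum).
"""

from __future__ import annotations

import numpy as np

from .grid import CorrelationSpec, ExperimentDesign, GridSpec, InfeasibleSpecError
from .stimulus import StimulusBank, StimulusTensor

__all__ = ["synthesize_latent", "batch_synthesize"]


def _standardize(x: np.ndarray) -> np.ndarray:
    """Exactly zero-mean, unit-sample-variance version of a sequence."""
    x = x - x.mean()
    sd = x.std()
    if sd == 0:
        raise ValueError("degenerate (constant) random draw")
    return x / sd


def synthesize_latent(spec: CorrelationSpec, grid: GridSpec, seed: int) -> StimulusTensor:
    """Draw one stimulus with the assigned correlation structure.

    The area latents are standardized and exactly decorrelated/recombined so
    the *population* structure is exact; sampling noise remains in the
    per-cell idiosyncratic terms.  The result is rescaled by its maximum
    absolute value into [-1, 1] (cosine similarity is scale-free).
    """
    if spec.xi_cross > spec.xi_within:
        raise InfeasibleSpecError(
            f"xi_cross={spec.xi_cross} exceeds xi_within={spec.xi_within}"
        )
    rng = np.random.default_rng(seed)
    n = grid.n_frames
    z_a = _standardize(rng.standard_normal(n))
    raw = rng.standard_normal(n)
    # residual exactly orthogonal to z_a, then standardized
    resid = _standardize(raw - (raw @ z_a) / (z_a @ z_a) * z_a)
    rho = 0.0 if spec.xi_within == 0 else spec.xi_cross / spec.xi_within
    z_b = rho * z_a + np.sqrt(max(0.0, 1.0 - rho**2)) * resid

    w = spec.xi_within
    shared = np.sqrt(w)
    idio = np.sqrt(max(0.0, 1.0 - w))
    half = grid.n_cells_per_area

    eps = rng.standard_normal((grid.n_cells, n))
    eps -= eps.mean(axis=1, keepdims=True)
    flat = np.empty((grid.n_cells, n))
    flat[:half] = shared * z_a + idio * eps[:half]
    flat[half:] = shared * z_b + idio * eps[half:]

    peak = np.max(np.abs(flat))
    if peak > 0:
        flat = flat / peak
    values = grid.unflatten_series(flat)
    return StimulusTensor(values=values, spec=spec, seed=seed, source="latent")


def batch_synthesize(
    design: ExperimentDesign, grid: GridSpec, seed: int
) -> StimulusBank:
    """Synthesize the full bank: every signal and null spec x n_variants."""
    root = np.random.SeedSequence(seed)
    bank = StimulusBank(grid=grid, source="latent", seed=seed)
    specs = design.all_specs()
    children = root.spawn(len(specs))
    for spec, child in zip(specs, children):
        sub_seeds = child.generate_state(design.n_variants)
        for variant, s in enumerate(sub_seeds):
            stim = synthesize_latent(spec, grid, int(s) % (2**31))
            stim.variant_id = variant
            bank.add(stim)
    return bank
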
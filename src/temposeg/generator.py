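"""Gradient-based synthesis of correlation-constrained dynamic textures.

The generator treats a single stimulus as the object of optimization: a
parameter tensor (initialized from a white-noise prior) is pushed through a
small deterministic decoder and trained, with a hand-written AdamW loop and
analytic subgradients, against a five-term objective:

* within-area similarity loss  — mean over same-area element pairs of
  ``| |cos(p_i, p_j)| - xi_within |`` (one term per area),
* cross-area similarity loss   — the same over pairs spanning the areas,
* distribution loss            — per-area deviation of mean and variance
  from global targets (mean 0, variance 1/3, approximating a uniform
  distribution on [-1, 1]),
* equalization loss            — absolute mean and variance differences
  between the two areas,
* variance-expansion loss      — *negative* mean pairwise L1 distance
  between distinct same-area sequences, a weak pressure toward white-noise-
  like variability.

The decoder ends in ``tanh`` (range control) followed by a balancing layer:
each area's frames are centered (zero spatial mean) and the two areas'
per-frame spatial RMS values are matched to their geometric mean.  This
builds the spatial-cue invisibility requirement — no mean-luminance or
contrast difference between the areas on any frame — directly into the
architecture; the absolute-similarity targets admit exact solutions inside
this constraint set (sign-balanced factor constructions), so the similarity
terms still converge.  See docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .grid import CorrelationSpec, ExperimentDesign, GridSpec
from .stimulus import StimulusBank, StimulusTensor

__all__ = [
    "GeneratorConfig",
    "LossWeights",
    "LossBreakdown",
    "sample_noise_prior",
    "model_forward",
    "similarity_losses",
    "distribution_losses",
    "variance_expansion_loss",
    "total_loss",
    "optimize_stimulus",
    "generate_bank",
    "build_bank",
]


@dataclass(frozen=True)
class LossWeights:
    """Scalar weights of the five loss groups and the distribution targets.

    Defaults let the correlation terms dominate; the variance-expansion term
    is a weak regularizer.
    """

    alpha1: float = 1.0   # within-area similarity (both areas)
    alpha2: float = 1.0   # cross-area similarity
    alpha3: float = 0.5   # per-area distribution (mean/variance)
    alpha4: float = 0.5   # area equalization
    alpha5: float = 0.01  # variance expansion
    mu_g: float = 0.0
    sigma_g2: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if min(self.alpha1, self.alpha2, self.alpha3, self.alpha4, self.alpha5) < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.sigma_g2 <= 0:
            raise ValueError("sigma_g2 must be positive")


@dataclass(frozen=True)
class GeneratorConfig:
    """Optimizer and decoder settings.

    ``balance`` selects the decoder's output balancing layer: ``"dc_match"``
    (default) zeroes each area's spatial mean per frame and matches the two
    areas' per-frame spatial RMS, ``"dc"`` removes only the spatial means,
    ``"none"`` is plain tanh.  ``tol`` is the early-stop tolerance on the
    worst absolute error between measured and assigned mean similarity.
    """

    learning_rate: float = 0.03
    max_steps: int = 3000
    tol: float = 0.01
    check_every: int = 25
    weight_decay: float = 0.0
    noise_std: float = 0.5
    balance: str = "dc_match"

    def __post_init__(self) -> None:
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        if self.balance not in ("none", "dc", "dc_match"):
            raise ValueError(f"unknown balance mode {self.balance!r}")


@dataclass
class LossBreakdown:
    """Per-term loss values; ``total`` is the weighted sum."""

    l_within_a: float
    l_within_b: float
    l_cross: float
    l_dist_a: float
    l_dist_b: float
    l_equalize: float
    l_var_a: float
    l_var_b: float
    total: float


def sample_noise_prior(grid: GridSpec, seed: int, std: float = 0.5) -> np.ndarray:
    """White-noise prior tensor, i.i.d. zero-mean Gaussian, (rows, cols, frames)."""
    rng = np.random.default_rng(seed)
    return std * rng.standard_normal(grid.shape)


# ---------------------------------------------------------------------------
# decoder
# ---------------------------------------------------------------------------

def model_forward(
    config: GeneratorConfig,
    params: np.ndarray,
    noise: np.ndarray | None = None,
    grid: GridSpec | None = None,
) -> np.ndarray:
    """Decode parameters (plus the fixed noise input) into a stimulus tensor.

    The map is deterministic: tanh squashing, optional per-area-per-frame
    standardization, then a global rescale that guarantees values in [-1, 1].
    """
    x = params if noise is None else params + noise
    if grid is None:
        r, c, n = x.shape
        grid = GridSpec(n_rows=r, n_cols=c, n_frames=n)
    f, _ = _decode_with_cache(config, x, grid)
    return f


def _decode_with_cache(
    config: GeneratorConfig, x: np.ndarray, grid: GridSpec
) -> tuple[np.ndarray, dict]:
    """Forward pass keeping intermediates needed for the backward pass."""
    if x.shape != grid.shape:
        raise ValueError(f"parameter shape {x.shape} does not match grid {grid.shape}")
    h0 = np.tanh(x)
    cache: dict = {"h0": h0}
    split = grid.area_split_col
    sl_a, sl_b = np.s_[:, :split, :], np.s_[:, split:, :]
    cache["slices"] = (sl_a, sl_b)
    if config.balance == "none":
        h = h0
    else:
        ca = h0[sl_a] - h0[sl_a].mean(axis=(0, 1), keepdims=True)
        cb = h0[sl_b] - h0[sl_b].mean(axis=(0, 1), keepdims=True)
        h = np.empty_like(h0)
        if config.balance == "dc_match":
            ra = np.sqrt(np.maximum((ca**2).mean(axis=(0, 1), keepdims=True), 1e-24))
            rb = np.sqrt(np.maximum((cb**2).mean(axis=(0, 1), keepdims=True), 1e-24))
            ka = np.sqrt(rb / ra)  # scale A to the geometric-mean RMS
            kb = np.sqrt(ra / rb)
            h[sl_a] = ka * ca
            h[sl_b] = kb * cb
            cache.update(ca=ca, cb=cb, ra=ra, rb=rb, ka=ka, kb=kb)
        else:
            h[sl_a] = ca
            h[sl_b] = cb
    c = max(1.0, float(np.max(np.abs(h))))
    cache["c"] = c
    f = h / c
    return f, cache


def _decode_backward(config: GeneratorConfig, grad_f: np.ndarray, cache: dict) -> np.ndarray:
    """Chain the loss gradient back through rescale, balancing and tanh.

    The global safety rescale ``c`` is treated as a constant (stop-gradient);
    the cosine-similarity terms are scale-free so this does not bias the
    descent direction of the dominant loss terms.
    """
    g = grad_f / cache["c"]
    sl_a, sl_b = cache["slices"]
    if config.balance == "dc":
        out = np.empty_like(g)
        out[sl_a] = g[sl_a] - g[sl_a].mean(axis=(0, 1), keepdims=True)
        out[sl_b] = g[sl_b] - g[sl_b].mean(axis=(0, 1), keepdims=True)
        g = out
    elif config.balance == "dc_match":
        ca, cb = cache["ca"], cache["cb"]
        ra, rb = cache["ra"], cache["rb"]
        ka, kb = cache["ka"], cache["kb"]
        ua, ub = g[sl_a], g[sl_b]
        n_a = ca.shape[0] * ca.shape[1]
        a_dot = (ua * ca).sum(axis=(0, 1), keepdims=True)
        b_dot = (ub * cb).sum(axis=(0, 1), keepdims=True)
        # chain through both RMS couplings: h_A = sqrt(r_B/r_A) c_A etc.
        ga = ka * ua + (b_dot * kb - a_dot * ka) / (2.0 * ra) * ca / (n_a * ra)
        gb = kb * ub + (a_dot * ka - b_dot * kb) / (2.0 * rb) * cb / (n_a * rb)
        out = np.empty_like(g)
        out[sl_a] = ga - ga.mean(axis=(0, 1), keepdims=True)
        out[sl_b] = gb - gb.mean(axis=(0, 1), keepdims=True)
        g = out
    h0 = cache["h0"]
    return g * (1.0 - h0**2)


# ---------------------------------------------------------------------------
# loss terms (values and analytic subgradients w.r.t. the decoded stimulus)
# ---------------------------------------------------------------------------

def _masks(grid: GridSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    m = grid.n_cells
    half = grid.n_cells_per_area
    in_a = np.arange(m) < half
    same = in_a[:, None] == in_a[None, :]
    off = ~np.eye(m, dtype=bool)
    within_a = same & off & in_a[:, None]
    within_b = same & off & ~in_a[:, None]
    cross = ~same
    return within_a, within_b, cross


def _cosine(flat: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    norms = np.linalg.norm(flat, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-norm time series: cosine similarity undefined")
    unit = flat / norms[:, None]
    return unit @ unit.T, unit, norms


def similarity_losses(
    stimulus: np.ndarray | StimulusTensor,
    spec: CorrelationSpec,
    grid: GridSpec | None = None,
) -> tuple[float, float, float]:
    """Within-A, within-B and cross similarity losses of a stimulus.

    Each is the mean over the relevant (off-diagonal) pairs of the absolute
    deviation between measured |cos| and the assigned target.
    """
    values = stimulus.values if isinstance(stimulus, StimulusTensor) else np.asarray(stimulus)
    if grid is None:
        r, c, n = values.shape
        grid = GridSpec(n_rows=r, n_cols=c, n_frames=n)
    flat = grid.flatten_series(values)
    cos, _, _ = _cosine(flat)
    wa, wb, cr = _masks(grid)

    def _mean(mask: np.ndarray, target: float) -> float:
        if not mask.any():
            return 0.0
        return float(np.abs(np.abs(cos[mask]) - target).mean())

    return _mean(wa, spec.xi_within), _mean(wb, spec.xi_within), _mean(cr, spec.xi_cross)


def distribution_losses(
    stimulus: np.ndarray | StimulusTensor,
    weights: LossWeights | None = None,
    grid: GridSpec | None = None,
) -> tuple[float, float, float]:
    """Per-area distribution losses and the area-equalization penalty."""
    weights = weights or LossWeights()
    values = stimulus.values if isinstance(stimulus, StimulusTensor) else np.asarray(stimulus)
    if grid is None:
        r, c, n = values.shape
        grid = GridSpec(n_rows=r, n_cols=c, n_frames=n)
    split = grid.area_split_col
    fa, fb = values[:, :split, :], values[:, split:, :]
    ma, mb = fa.mean(), fb.mean()
    va, vb = fa.var(), fb.var()
    l_a = float(abs(va - weights.sigma_g2) + abs(ma - weights.mu_g))
    l_b = float(abs(vb - weights.sigma_g2) + abs(mb - weights.mu_g))
    l_eq = float(abs(ma - mb) + abs(va - vb))
    return l_a, l_b, l_eq


def variance_expansion_loss(
    stimulus: np.ndarray | StimulusTensor, grid: GridSpec | None = None
) -> tuple[float, float]:
    """Negative mean pairwise L1 distance between distinct same-area sequences."""
    values = stimulus.values if isinstance(stimulus, StimulusTensor) else np.asarray(stimulus)
    if grid is None:
        r, c, n = values.shape
        grid = GridSpec(n_rows=r, n_cols=c, n_frames=n)
    flat = grid.flatten_series(values)
    half = grid.n_cells_per_area
    out = []
    for block in (flat[:half], flat[half:]):
        n_el = block.shape[0]
        if n_el < 2:
            out.append(0.0)
            continue
        diff = np.abs(block[:, None, :] - block[None, :, :]).sum(axis=2)
        total = diff.sum() / 2.0
        out.append(-float(total / (n_el * (n_el - 1) / 2)))
    return out[0], out[1]


def total_loss(breakdown: LossBreakdown | None = None, weights: LossWeights | None = None,
               **components: float) -> float:
    """Weighted total of the five loss groups."""
    weights = weights or LossWeights()
    if breakdown is None:
        breakdown = LossBreakdown(total=0.0, **components)
    return (
        weights.alpha1 * (breakdown.l_within_a + breakdown.l_within_b)
        + weights.alpha2 * breakdown.l_cross
        + weights.alpha3 * (breakdown.l_dist_a + breakdown.l_dist_b)
        + weights.alpha4 * breakdown.l_equalize
        + weights.alpha5 * (breakdown.l_var_a + breakdown.l_var_b)
    )


def _loss_and_grad(
    f: np.ndarray, spec: CorrelationSpec, weights: LossWeights, grid: GridSpec
) -> tuple[LossBreakdown, np.ndarray, float, float]:
    """All loss terms and the total's subgradient w.r.t. the decoded stimulus.

    Also returns the measured mean within/cross |cos| (byproducts of the
    similarity computation, used for convergence checks).
    """
    flat = grid.flatten_series(f)
    m, n = flat.shape
    half = grid.n_cells_per_area
    cos, unit, norms = _cosine(flat)
    wa, wb, cr = _masks(grid)
    abs_cos = np.abs(cos)

    if not (wa.any() and cr.any()):
        raise ValueError("grid too small: every area needs >= 2 cells")
    dev_w = abs_cos - spec.xi_within
    dev_c = abs_cos - spec.xi_cross
    la = float(np.abs(dev_w[wa]).mean())
    lb = float(np.abs(dev_w[wb]).mean())
    lab = float(np.abs(dev_c[cr]).mean())
    measured_within = float(abs_cos[wa | wb].mean())
    measured_cross = float(abs_cos[cr].mean())

    # subgradient matrix G over ordered pairs; each ordered entry carries the
    # 1/P weight of its term's mean, times the alpha of its group
    g_mat = np.zeros_like(cos)
    sgn = np.sign(dev_w) * np.sign(cos)
    g_mat[wa] = weights.alpha1 * sgn[wa] / wa.sum()
    g_mat[wb] = weights.alpha1 * sgn[wb] / wb.sum()
    sgn_c = np.sign(dev_c) * np.sign(cos)
    g_mat[cr] = weights.alpha2 * sgn_c[cr] / cr.sum()
    v = 2.0 * (g_mat @ unit)
    grad_flat = (v - (np.einsum("ij,ij->i", v, unit))[:, None] * unit) / norms[:, None]

    # distribution + equalization terms
    blocks = (flat[:half], flat[half:])
    means = [b.mean() for b in blocks]
    varis = [b.var() for b in blocks]
    l_da = float(abs(varis[0] - weights.sigma_g2) + abs(means[0] - weights.mu_g))
    l_db = float(abs(varis[1] - weights.sigma_g2) + abs(means[1] - weights.mu_g))
    l_eq = float(abs(means[0] - means[1]) + abs(varis[0] - varis[1]))

    n_el = half * n
    for idx, (b, sl) in enumerate(zip(blocks, (np.s_[:half], np.s_[half:]))):
        s_var = np.sign(varis[idx] - weights.sigma_g2)
        s_mean = np.sign(means[idx] - weights.mu_g)
        dvar = 2.0 * (b - means[idx]) / n_el
        grad_flat[sl] += weights.alpha3 * (s_var * dvar + s_mean / n_el)
        s_eq_m = np.sign(means[idx] - means[1 - idx])
        s_eq_v = np.sign(varis[idx] - varis[1 - idx])
        grad_flat[sl] += weights.alpha4 * (s_eq_m / n_el + s_eq_v * dvar)

    # variance expansion
    l_vs = []
    n_pairs = half * (half - 1) / 2 if half > 1 else 1
    for b, sl in zip(blocks, (np.s_[:half], np.s_[half:])):
        if half < 2:
            l_vs.append(0.0)
            continue
        d = b[:, None, :] - b[None, :, :]
        ad = np.abs(d)
        l_vs.append(-float(ad.sum() / 2.0 / n_pairs))
        grad_flat[sl] += weights.alpha5 * (-np.sign(d).sum(axis=1) / n_pairs)
    l_va, l_vb = l_vs

    breakdown = LossBreakdown(
        l_within_a=la, l_within_b=lb, l_cross=lab,
        l_dist_a=l_da, l_dist_b=l_db, l_equalize=l_eq,
        l_var_a=l_va, l_var_b=l_vb, total=0.0,
    )
    breakdown.total = total_loss(breakdown, weights)
    return breakdown, grid.unflatten_series(grad_flat), measured_within, measured_cross


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------

def optimize_stimulus(
    spec: CorrelationSpec,
    grid: GridSpec | None = None,
    config: GeneratorConfig | None = None,
    weights: LossWeights | None = None,
    seed: int = 0,
) -> tuple[StimulusTensor, dict]:
    """Train one stimulus against the five-term objective.

    Returns the decoded stimulus and a diagnostics dict with the loss trace,
    final measured mean similarities, the convergence flag and the number of
    steps taken.
    """
    grid = grid or GridSpec()
    config = config or GeneratorConfig()
    weights = weights or LossWeights()

    noise = sample_noise_prior(grid, seed, std=config.noise_std)
    delta = np.zeros_like(noise)
    m1 = np.zeros_like(delta)
    m2 = np.zeros_like(delta)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lr, wd = config.learning_rate, config.weight_decay

    trace: list[float] = []
    converged = False
    mw = mc = float("nan")
    step = 0
    for step in range(1, config.max_steps + 1):
        x = noise + delta
        f, cache = _decode_with_cache(config, x, grid)
        breakdown, grad_f, mw, mc = _loss_and_grad(f, spec, weights, grid)
        if not np.isfinite(breakdown.total):
            raise FloatingPointError(f"non-finite loss at step {step}")
        trace.append(breakdown.total)
        if step % config.check_every == 0 or step == config.max_steps:
            err = max(abs(mw - spec.xi_within), abs(mc - spec.xi_cross))
            if err <= config.tol:
                converged = True
                break
        grad = _decode_backward(config, grad_f, cache)
        m1 = beta1 * m1 + (1 - beta1) * grad
        m2 = beta2 * m2 + (1 - beta2) * grad**2
        m1_hat = m1 / (1 - beta1**step)
        m2_hat = m2 / (1 - beta2**step)
        delta -= lr * (m1_hat / (np.sqrt(m2_hat) + eps) + wd * delta)

    f, _ = _decode_with_cache(config, noise + delta, grid)
    stim = StimulusTensor(
        values=f, spec=spec, seed=seed, source="vit",
        converged=converged, measured_within=mw, measured_cross=mc,
    )
    diagnostics = {
        "loss_trace": np.asarray(trace),
        "steps": step,
        "converged": converged,
        "measured_within": mw,
        "measured_cross": mc,
        "final_loss": trace[-1] if trace else float("nan"),
    }
    return stim, diagnostics


def build_bank(
    specs: list[CorrelationSpec],
    n_variants: int,
    grid: GridSpec | None = None,
    config: GeneratorConfig | None = None,
    weights: LossWeights | None = None,
    seed: int = 0,
    progress: Callable[[str], None] | None = None,
) -> StimulusBank:
    """Optimize ``n_variants`` stimuli for each spec in a list."""
    grid = grid or GridSpec()
    bank = StimulusBank(grid=grid, source="vit", seed=seed)
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(specs))
    for spec, child in zip(specs, children):
        sub_seeds = child.generate_state(n_variants)
        for variant, s in enumerate(sub_seeds):
            stim, _ = optimize_stimulus(spec, grid, config, weights, seed=int(s) % (2**31))
            stim.variant_id = variant
            bank.add(stim)
            if progress is not None:
                progress(f"{spec.key()} variant {variant}: "
                         f"within={stim.measured_within:.3f} cross={stim.measured_cross:.3f}")
    return bank


def generate_bank(
    design: ExperimentDesign,
    grid: GridSpec | None = None,
    config: GeneratorConfig | None = None,
    weights: LossWeights | None = None,
    seed: int = 0,
    progress: Callable[[str], None] | None = None,
) -> StimulusBank:
    """Optimize the full bank: every signal and null spec x n_variants."""
    return build_bank(
        design.all_specs(), design.n_variants, grid, config, weights, seed, progress
    )
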
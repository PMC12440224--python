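"""Validation analyses for generated stimulus banks.

Three checks establish that a bank carries the intended (and only the
intended) segmentation cue:

* assigned-vs-measured regression of mean absolute cosine similarity,
* spatial-cue invisibility (per-frame mean-luminance and RMS-contrast
  differences between the two areas of the rendered stimulus),
* temporal power spectra per area (quasi-whiteness, no area asymmetry).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .grid import CorrelationSpec, GridSpec
from .rendering import RenderSpec, render_luminance
from .stimulus import StimulusBank, StimulusTensor

__all__ = [
    "similarity_matrix",
    "mean_similarities",
    "assigned_vs_measured_r2",
    "spatial_cue_report",
    "temporal_spectrum",
]


def similarity_matrix(stimulus: StimulusTensor | np.ndarray, grid: GridSpec | None = None) -> np.ndarray:
    """Absolute cosine similarity between every pair of element sequences.

    Returns an (n_cells, n_cells) symmetric matrix with unit diagonal, cells
    ordered by the canonical column-major flattening.
    """
    if isinstance(stimulus, StimulusTensor):
        values = stimulus.values
        grid = grid or stimulus.grid()
    else:
        values = np.asarray(stimulus, dtype=float)
        if grid is None:
            r, c, n = values.shape
            grid = GridSpec(n_rows=r, n_cols=c, n_frames=n)
    flat = grid.flatten_series(values)
    return _abs_cosine(flat, grid)


def _abs_cosine(flat: np.ndarray, grid: GridSpec) -> np.ndarray:
    norms = np.linalg.norm(flat, axis=1)
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        k = int(bad[0])
        raise ZeroNormSeriesError(
            f"cell (row={k % grid.n_rows}, col={k // grid.n_rows}) has a zero-norm series"
        )
    unit = flat / norms[:, None]
    sim = np.abs(unit @ unit.T)
    np.clip(sim, 0.0, 1.0, out=sim)
    np.fill_diagonal(sim, 1.0)
    return sim


class ZeroNormSeriesError(ValueError):
    """A cell's temporal sequence has zero norm; cosine similarity undefined."""


def _pair_masks(grid: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks over the similarity matrix: within (off-diagonal), cross."""
    m = grid.n_cells
    half = grid.n_cells_per_area
    in_a = np.arange(m) < half
    same = in_a[:, None] == in_a[None, :]
    within = same & ~np.eye(m, dtype=bool)
    cross = ~same
    return within, cross


def mean_similarities(stimulus: StimulusTensor, grid: GridSpec | None = None) -> tuple[float, float]:
    """Mean absolute cosine similarity over within-area and cross-area pairs.

    The diagonal (self-similarity, identically 1) is excluded.
    """
    grid = grid or stimulus.grid()
    sim = similarity_matrix(stimulus, grid)
    within, cross = _pair_masks(grid)
    return float(sim[within].mean()), float(sim[cross].mean())


def assigned_vs_measured_r2(bank: StimulusBank) -> tuple[float, pd.DataFrame]:
    """Regression R^2 of measured mean |cos| on assigned targets.

    Pools two points per stimulus — (xi_within, measured within) and
    (xi_cross, measured cross) — across the whole bank, and returns the
    ordinary least-squares coefficient of determination together with the
    scatter table.
    """
    rows = []
    for stim in bank:
        mw, mc = mean_similarities(stim, bank.grid)
        rows.append(
            {"spec": stim.spec.key(), "variant": stim.variant_id,
             "kind": "within", "assigned": stim.spec.xi_within, "measured": mw}
        )
        rows.append(
            {"spec": stim.spec.key(), "variant": stim.variant_id,
             "kind": "cross", "assigned": stim.spec.xi_cross, "measured": mc}
        )
    if not rows:
        raise ValueError("bank is empty")
    table = pd.DataFrame(rows)
    if table["assigned"].nunique() < 2:
        raise ValueError("need at least 2 distinct assigned values for a regression")
    fit = stats.linregress(table["assigned"], table["measured"])
    return float(fit.rvalue**2), table


def spatial_cue_report(
    bank: StimulusBank, render_spec: RenderSpec | None = None
) -> pd.DataFrame:
    """Per-spec spatial-cue statistics on the rendered luminance stimulus.

    For every frame the spatial mean and the spatial RMS deviation (about the
    frame's own spatial mean) of the luminance image are computed separately
    for the left and right halves.  The absolute area differences are
    averaged across frames (and variants) and expressed as percent of the
    mean luminance.  The returned frame has one row per spec with columns
    ``mean_diff_pct`` and ``rms_diff_pct``; its ``attrs`` carry the maxima
    across specs (``peak_mean_diff_pct``, ``peak_rms_diff_pct``).
    """
    render_spec = render_spec or RenderSpec(attribute="luminance")
    rows = []
    for key, variants in bank.stimuli.items():
        mean_diffs, rms_diffs = [], []
        for stim in variants:
            frames = render_luminance(stim, render_spec)
            half_px = frames.shape[1] // 2
            left = frames[:, :half_px, :]
            right = frames[:, half_px:, :]
            lm = left.mean(axis=(0, 1))
            rm = right.mean(axis=(0, 1))
            l_rms = left.std(axis=(0, 1))
            r_rms = right.std(axis=(0, 1))
            mean_diffs.append(np.abs(lm - rm).mean())
            rms_diffs.append(np.abs(l_rms - r_rms).mean())
        spec = variants[0].spec
        rows.append(
            {
                "spec": key,
                "xi_within": spec.xi_within,
                "xi_cross": spec.xi_cross,
                "is_null": spec.is_null,
                "mean_diff_pct": 100.0 * float(np.mean(mean_diffs)) / render_spec.mean_level,
                "rms_diff_pct": 100.0 * float(np.mean(rms_diffs)) / render_spec.mean_level,
            }
        )
    report = pd.DataFrame(rows)
    report.attrs["peak_mean_diff_pct"] = float(report["mean_diff_pct"].max())
    report.attrs["peak_rms_diff_pct"] = float(report["rms_diff_pct"].max())
    report.attrs["avg_mean_diff_pct"] = float(report["mean_diff_pct"].mean())
    report.attrs["avg_rms_diff_pct"] = float(report["rms_diff_pct"].mean())
    return report


def temporal_spectrum(bank: StimulusBank) -> pd.DataFrame:
    """Mean temporal power density per area, in dB, per frequency bin.

    A plain (single-segment) periodogram is taken over the frame axis of
    every cell, averaged over cells within each area and over all stimuli in
    the bank.  Frequencies run from 0 to ``frame_rate / 2`` Hz.  ``scaling=
    'spectrum'`` is used so that the summed power of a cell equals its
    time-domain mean square (Parseval).
    """
    grid = bank.grid
    if grid.n_frames < 2:
        raise ValueError("need at least 2 frames for a spectrum")
    half = grid.n_cells_per_area
    acc_a, acc_b, count = None, None, 0
    freqs = None
    for stim in bank:
        flat = grid.flatten_series(stim.values)
        freqs, power = sps.periodogram(
            flat, fs=grid.frame_rate, detrend=False, scaling="spectrum", axis=1
        )
        pa = power[:half].mean(axis=0)
        pb = power[half:].mean(axis=0)
        acc_a = pa if acc_a is None else acc_a + pa
        acc_b = pb if acc_b is None else acc_b + pb
        count += 1
    if count == 0:
        raise ValueError("bank is empty")
    with np.errstate(divide="ignore"):
        db_a = 10.0 * np.log10(acc_a / count)
        db_b = 10.0 * np.log10(acc_b / count)
    return pd.DataFrame({"freq_hz": freqs, "areaA_dB": db_a, "areaB_dB": db_b})
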
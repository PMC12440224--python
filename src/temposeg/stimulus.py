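"""Stimulus containers: a single tensor and an in-memory bank of them."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

from .grid import CorrelationSpec, GridSpec

__all__ = ["StimulusTensor", "StimulusBank"]


@dataclass
class StimulusTensor:
    """A single dynamic texture: (n_rows, n_cols, n_frames) values in [-1, 1].

    ``values[i, j, :]`` is the temporal sequence of the element at row i,
    column j.  ``source`` records whether the stimulus came from the
    gradient-optimized generator (``"vit"``) or the analytic latent-factor
    synthesizer (``"latent"``).
    """

    values: np.ndarray
    spec: CorrelationSpec
    seed: int = 0
    source: str = "latent"
    variant_id: int = 0
    converged: bool | None = None
    measured_within: float | None = None
    measured_cross: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3-D, got shape {self.values.shape}")
        if np.max(np.abs(self.values)) > 1.0 + 1e-9:
            raise ValueError("stimulus values must lie in [-1, 1]")
        if self.source not in ("vit", "latent"):
            raise ValueError(f"unknown source {self.source!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def grid(self, frame_rate: float = 30.0) -> GridSpec:
        r, c, n = self.values.shape
        return GridSpec(n_rows=r, n_cols=c, n_frames=n, frame_rate=frame_rate)

    def copy(self) -> "StimulusTensor":
        return replace(self, values=self.values.copy())


@dataclass
class StimulusBank:
    """A keyed collection of stimuli: spec key -> list of variants."""

    grid: GridSpec
    stimuli: dict[str, list[StimulusTensor]] = field(default_factory=dict)
    source: str = "latent"
    seed: int | None = None

    def add(self, stim: StimulusTensor) -> None:
        if stim.values.shape != self.grid.shape:
            raise ValueError(
                f"stimulus shape {stim.values.shape} does not match bank grid {self.grid.shape}"
            )
        self.stimuli.setdefault(stim.spec.key(), []).append(stim)

    def specs(self) -> list[CorrelationSpec]:
        return [variants[0].spec for variants in self.stimuli.values()]

    def get(self, spec: CorrelationSpec) -> list[StimulusTensor]:
        key = spec.key()
        if key not in self.stimuli:
            raise KeyError(f"bank has no stimuli for spec {key}")
        return self.stimuli[key]

    def __len__(self) -> int:
        return sum(len(v) for v in self.stimuli.values())

    def __iter__(self) -> Iterator[StimulusTensor]:
        for variants in self.stimuli.values():
            yield from variants
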
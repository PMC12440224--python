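"""Grid geometry, area partition and experiment-design arithmetic.

The stimulus is a rectangular lattice of ``n_rows x n_cols`` elements, each
carrying a temporal sequence of ``n_frames`` samples.  The lattice is split
down the middle into a left area A (columns ``0 .. n_cols/2 - 1``) and a right
area B; correlation targets are assigned within each area and across the two.

All indexing is 0-based.  Flattening is column-major over space,
``k = col * n_rows + row``, so that ``k // n_rows`` recovers the column and
``k % n_rows`` the row.  With this convention area A occupies the first half
of the flat index range, ``k < n_rows * n_cols / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GridSpec",
    "CorrelationSpec",
    "ExperimentDesign",
    "make_grid",
    "flatten_index",
    "unflatten_index",
    "grid_distance",
    "distance_matrix",
    "enumerate_pairs",
    "null_spec_for",
    "default_levels",
]


class InvalidGeometryError(ValueError):
    """Raised for grid geometries that cannot be split into two equal areas."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the element lattice.

    Parameters
    ----------
    n_rows, n_cols : int
        Lattice size in elements.  ``n_cols`` must be even so the lattice
        splits into two equal areas.
    n_frames : int
        Temporal length of every element's sequence.
    frame_rate : float
        Presentation rate in Hz (30 frames at 30 Hz is a 1 s clip).
    """

    n_rows: int = 8
    n_cols: int = 16
    n_frames: int = 30
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1 or self.n_frames < 1:
            raise InvalidGeometryError("all grid counts must be >= 1")
        if self.n_cols % 2 != 0:
            raise InvalidGeometryError(
                f"n_cols must be even to split into two areas, got {self.n_cols}"
            )
        if self.frame_rate <= 0:
            raise InvalidGeometryError("frame_rate must be positive")

    @property
    def area_split_col(self) -> int:
        return self.n_cols // 2

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def n_cells_per_area(self) -> int:
        return self.n_cells // 2

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n_rows, self.n_cols, self.n_frames)

    # -- area masks ------------------------------------------------------
    def area_mask(self, area: str) -> np.ndarray:
        """Boolean (n_rows, n_cols) mask of area ``"A"`` (left) or ``"B"``."""
        mask = np.zeros((self.n_rows, self.n_cols), dtype=bool)
        if area == "A":
            mask[:, : self.area_split_col] = True
        elif area == "B":
            mask[:, self.area_split_col :] = True
        else:
            raise ValueError(f"area must be 'A' or 'B', got {area!r}")
        return mask

    def area_flat_indices(self, area: str) -> np.ndarray:
        """Flat indices of an area under the canonical flattening."""
        half = self.n_cells_per_area
        if area == "A":
            return np.arange(half)
        if area == "B":
            return np.arange(half, self.n_cells)
        raise ValueError(f"area must be 'A' or 'B', got {area!r}")

    def flatten_series(self, values: np.ndarray) -> np.ndarray:
        """Reshape (n_rows, n_cols, n_frames) -> (n_cells, n_frames) rows."""
        if values.shape[:2] != (self.n_rows, self.n_cols):
            raise ValueError(
                f"expected spatial shape {(self.n_rows, self.n_cols)}, got {values.shape[:2]}"
            )
        # column-major over space: cell k = col * n_rows + row
        return values.transpose(1, 0, 2).reshape(self.n_cells, *values.shape[2:])

    def unflatten_series(self, flat: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`flatten_series`."""
        if flat.shape[0] != self.n_cells:
            raise ValueError(f"expected {self.n_cells} rows, got {flat.shape[0]}")
        return flat.reshape(self.n_cols, self.n_rows, *flat.shape[1:]).transpose(1, 0, 2)

    def unflatten_map(self, flat: np.ndarray) -> np.ndarray:
        """Reshape a flat per-cell vector (n_cells,) onto the (rows, cols) grid."""
        if flat.shape[0] != self.n_cells:
            raise ValueError(f"expected {self.n_cells} entries, got {flat.shape[0]}")
        return flat.reshape(self.n_cols, self.n_rows).T

    def target_map(self) -> np.ndarray:
        """Ground-truth partition template: +1 on area A, -1 on area B."""
        return np.where(self.area_mask("A"), 1.0, -1.0)


def make_grid(
    n_rows: int = 8, n_cols: int = 16, n_frames: int = 30, frame_rate: float = 30.0
) -> GridSpec:
    """Construct a :class:`GridSpec`, validating the two-area geometry."""
    return GridSpec(n_rows=n_rows, n_cols=n_cols, n_frames=n_frames, frame_rate=frame_rate)


def flatten_index(row: int, col: int, grid: GridSpec) -> int:
    """Map (row, col) to the canonical flat index ``k = col * n_rows + row``."""
    if not (0 <= row < grid.n_rows and 0 <= col < grid.n_cols):
        raise IndexError(f"(row={row}, col={col}) outside grid {grid.n_rows}x{grid.n_cols}")
    return col * grid.n_rows + row


def unflatten_index(k: int, grid: GridSpec) -> tuple[int, int]:
    """Inverse of :func:`flatten_index`."""
    if not (0 <= k < grid.n_cells):
        raise IndexError(f"flat index {k} outside [0, {grid.n_cells})")
    return (k % grid.n_rows, k // grid.n_rows)


def grid_distance(k1: int, k2: int, grid: GridSpec) -> float:
    """Euclidean distance between two cells, in element units."""
    r1, c1 = unflatten_index(k1, grid)
    r2, c2 = unflatten_index(k2, grid)
    return float(np.hypot(r1 - r2, c1 - c2))


def distance_matrix(grid: GridSpec) -> np.ndarray:
    """(n_cells, n_cells) matrix of pairwise Euclidean element distances."""
    k = np.arange(grid.n_cells)
    rows = k % grid.n_rows
    cols = k // grid.n_rows
    dr = rows[:, None] - rows[None, :]
    dc = cols[:, None] - cols[None, :]
    return np.sqrt(dr.astype(float) ** 2 + dc.astype(float) ** 2)


@dataclass(frozen=True)
class CorrelationSpec:
    """Target absolute-similarity pair for one stimulus.

    ``xi_within`` is the target mean absolute cosine similarity between any
    two element sequences inside the same area (the same value is used for
    both areas); ``xi_cross`` is the target for pairs spanning the two areas.
    A null (control) stimulus has matched targets, ``xi_cross == xi_within``,
    and hence carries no segmentation cue.
    """

    xi_within: float
    xi_cross: float
    is_null: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.xi_cross <= 1.0 and 0.0 <= self.xi_within <= 1.0):
            raise ValueError("similarity targets must lie in [0, 1]")
        if self.xi_cross > self.xi_within + 1e-12:
            raise InfeasibleSpecError(
                f"xi_cross={self.xi_cross} exceeds xi_within={self.xi_within}"
            )
        if self.is_null and abs(self.xi_cross - self.xi_within) > 1e-12:
            raise ValueError("a null spec must have xi_cross == xi_within")

    @property
    def gap(self) -> float:
        return self.xi_within - self.xi_cross

    def key(self) -> str:
        """Stable string key, decimal-formatted to avoid float-drift in manifests."""
        w = _format_level(self.xi_within)
        c = _format_level(self.xi_cross)
        return f"w{w}_c{c}" + ("_null" if self.is_null else "")


class InfeasibleSpecError(ValueError):
    """Raised when xi_cross > xi_within (no consistent similarity structure)."""


def _format_level(x: float) -> str:
    return f"{round(float(x), 6):g}"


def default_levels(n: int = 9) -> list[float]:
    """The canonical similarity levels 0.1 .. 0.9 in steps of 0.1."""
    return [float(Fraction(i, 10)) for i in range(1, n + 1)]


def enumerate_pairs(levels: Sequence[float]) -> list[CorrelationSpec]:
    """All signal specs (w, c) with ``w >= c`` over the given levels.

    For n levels this yields n(n+1)/2 specs (45 of the 81 possible ordered
    pairs at the canonical nine levels); pairs with cross exceeding within are
    excluded because they support no segmentation.
    """
    lv = [round(float(x), 6) for x in levels]
    if any(not (0.0 <= x <= 1.0) for x in lv):
        raise ValueError("levels must lie in [0, 1]")
    if sorted(lv) != lv:
        raise ValueError("levels must be sorted ascending")
    return [
        CorrelationSpec(xi_within=w, xi_cross=c)
        for w in lv
        for c in lv
        if c <= w
    ]


def null_spec_for(spec: CorrelationSpec) -> CorrelationSpec:
    """Null (control) spec matched to a signal spec's within-area target."""
    return CorrelationSpec(xi_within=spec.xi_within, xi_cross=spec.xi_within, is_null=True)


@dataclass(frozen=True)
class ExperimentDesign:
    """Full stimulus/trial design over a level grid.

    Defaults follow the canonical design: nine similarity levels, 45 signal
    pairs, 30 stimulus variants per spec, and (for human sessions) 30 trials
    per pair and three attributes, giving 3 x 45 x 30 = 4,050 trials.
    """

    levels: tuple[float, ...] = tuple(default_levels())
    n_variants: int = 30
    n_trials_per_pair: int = 30
    attributes: tuple[str, ...] = ("luminance", "color", "gabor")

    def __post_init__(self) -> None:
        if self.n_variants < 1 or self.n_trials_per_pair < 1:
            raise ValueError("counts must be >= 1")
        bad = set(self.attributes) - {"luminance", "color", "gabor"}
        if bad:
            raise ValueError(f"unknown attributes: {sorted(bad)}")

    def signal_specs(self) -> list[CorrelationSpec]:
        return enumerate_pairs(self.levels)

    def null_specs(self) -> list[CorrelationSpec]:
        """One null spec per distinct within level."""
        return [
            CorrelationSpec(xi_within=w, xi_cross=w, is_null=True)
            for w in sorted({round(float(x), 6) for x in self.levels})
        ]

    def all_specs(self) -> list[CorrelationSpec]:
        return self.signal_specs() + self.null_specs()

    @property
    def n_pairs(self) -> int:
        n = len(self.levels)
        return n * (n + 1) // 2

    @property
    def schedule_length(self) -> int:
        """Total trial count: |attributes| x pairs x trials-per-pair."""
        return len(self.attributes) * self.n_pairs * self.n_trials_per_pair

    @property
    def n_stimuli(self) -> int:
        """Bank size: (signal specs + null specs) x variants."""
        return (self.n_pairs + len(set(self.levels))) * self.n_variants

    def to_dict(self) -> dict:
        return {
            "levels": [_format_level(x) for x in self.levels],
            "n_variants": self.n_variants,
            "n_trials": self.n_trials_per_pair,
            "attributes": list(self.attributes),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentDesign":
        return cls(
            levels=tuple(float(x) for x in d["levels"]),
            n_variants=int(d["n_variants"]),
            n_trials_per_pair=int(d["n_trials"]),
            attributes=tuple(d["attributes"]),
        )


def reduced_validation_design(n_variants: int = 2) -> list[CorrelationSpec]:
    """Nine signal specs spanning the design triangle, for reduced-scale checks.

    Within levels {0.1, 0.3, 0.5, 0.7, 0.9} crossed with feasible cross levels
    covering the diagonal, the low-cross edge and interior points.
    """
    pairs = [
        (0.1, 0.1),
        (0.3, 0.1),
        (0.5, 0.1),
        (0.5, 0.3),
        (0.5, 0.5),
        (0.7, 0.3),
        (0.9, 0.1),
        (0.9, 0.5),
        (0.9, 0.9),
    ]
    return [CorrelationSpec(xi_within=w, xi_cross=c) for w, c in pairs]
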
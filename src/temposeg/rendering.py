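"""Render stimulus tensors into displayable frame stacks.

Three attributes are supported, matching the psychophysical conditions:

* ``luminance`` — each element is a Gaussian luminance bulb whose contrast
  follows the element's sequence,
* ``color`` — a red/green bulb: R modulates with +F, G in anti-phase scaled
  by the equiluminant R:G ratio, B constant,
* ``gabor`` — a Gabor patch whose spatial phase is modulated by the sequence
  (phase excursion bounded by pi/4 so the step between frames never exceeds
  90 degrees, preventing luminance flicker cues).

Display values are normalized: mean level 0.5 maps to the monitor's mean
luminance, 0 and 1 to its extremes.  Physical photometry is out of scope.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .stimulus import StimulusTensor

__all__ = [
    "RenderSpec",
    "render_luminance",
    "render_color",
    "render_gabor",
    "render",
    "write_movie",
    "MovieEncoderError",
]


@dataclass(frozen=True)
class RenderSpec:
    """Display geometry and attribute parameters.

    ``element_size_deg`` is the element diameter (0.5 deg); the Gaussian
    envelope width ``envelope_sigma_arcmin`` is 5.25 arcmin; the Gabor
    carrier ``spatial_freq_cpd`` is 2 cycles/deg; ``iso_lum_rg`` is the
    red:green equiluminance ratio (0.58, a population mean from a
    minimum-motion measurement); ``pixels_per_degree`` defaults to 46,
    i.e. about 1.3 arcmin per pixel.
    """

    attribute: str = "luminance"
    mean_level: float = 0.5
    element_size_deg: float = 0.5
    envelope_sigma_arcmin: float = 5.25
    pixels_per_degree: int = 46
    spatial_freq_cpd: float = 2.0
    iso_lum_rg: float = 0.58
    orientation_policy: str = "per_element"
    orientation_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.mean_level < 1.0):
            raise ValueError("mean_level must lie in (0, 1)")
        if self.pixels_per_degree < 1:
            raise ValueError("pixels_per_degree must be >= 1")
        if self.attribute not in ("luminance", "color", "gabor"):
            raise ValueError(f"unknown attribute {self.attribute!r}")
        if self.orientation_policy not in ("per_element", "per_interval"):
            raise ValueError(f"unknown orientation_policy {self.orientation_policy!r}")

    @property
    def element_px(self) -> int:
        return max(1, round(self.element_size_deg * self.pixels_per_degree))

    @property
    def sigma_deg(self) -> float:
        return self.envelope_sigma_arcmin / 60.0


def _element_coords(spec: RenderSpec) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-center coordinates within one element, in degrees, origin centered."""
    px = spec.element_px
    offsets = (np.arange(px) - (px - 1) / 2.0) / spec.pixels_per_degree
    x, y = np.meshgrid(offsets, offsets)  # x horizontal, y vertical
    return x, y


def _envelope(spec: RenderSpec) -> np.ndarray:
    x, y = _element_coords(spec)
    # Gaussian bulb: note the negative exponent
    return np.exp(-(x**2 + y**2) / spec.sigma_deg**2)


def _upsample(values: np.ndarray, px: int) -> np.ndarray:
    """Expand (rows, cols, frames) element values to per-pixel resolution."""
    return values.repeat(px, axis=0).repeat(px, axis=1)


def _modulation(stimulus: StimulusTensor, spec: RenderSpec) -> np.ndarray:
    """Per-pixel contrast modulation F(i,j,t) * envelope(x, y)."""
    values = stimulus.values
    px = spec.element_px
    env = _envelope(spec)
    rows, cols, _ = values.shape
    env_full = np.tile(env, (rows, cols))
    return _upsample(values, px) * env_full[:, :, None]


def _check_range(frames: np.ndarray, spec: RenderSpec) -> np.ndarray:
    if frames.max() > 1.0 + 1e-12 or frames.min() < -1e-12:
        warnings.warn(
            "rendered values exceed the display range [0, 1]; clipping "
            f"(mean_level={spec.mean_level})",
            stacklevel=3,
        )
        frames = np.clip(frames, 0.0, 1.0)
    return frames


def render_luminance(stimulus: StimulusTensor, spec: RenderSpec | None = None) -> np.ndarray:
    """Luminance-bulb rendering -> (rows_px, cols_px, frames) in [0, 2*mean]."""
    spec = spec or RenderSpec(attribute="luminance")
    frames = spec.mean_level * (1.0 + _modulation(stimulus, spec))
    return _check_range(frames, spec)


def render_color(stimulus: StimulusTensor, spec: RenderSpec | None = None) -> np.ndarray:
    """Red/green-bulb rendering -> (rows_px, cols_px, frames, 3) RGB stack."""
    spec = spec or RenderSpec(attribute="color")
    mod = _modulation(stimulus, spec)
    r = spec.mean_level * (1.0 + mod)
    g = spec.iso_lum_rg * spec.mean_level * (1.0 - mod)
    b = np.full_like(mod, spec.mean_level)
    frames = np.stack([r, g, b], axis=-1)
    return _check_range(frames, spec)


def render_gabor(stimulus: StimulusTensor, spec: RenderSpec | None = None) -> np.ndarray:
    """Gabor-phase rendering -> (rows_px, cols_px, frames).

    The carrier is ``cos(2*pi*omega*r - (pi/4)*F)`` with
    ``r = y*cos(theta) + x*sin(theta)``; orientation theta is drawn uniformly
    on [0, 2*pi), per element or once per interval according to the policy.
    """
    spec = spec or RenderSpec(attribute="gabor")
    values = stimulus.values
    rows, cols, n_frames = values.shape
    rng = np.random.default_rng(spec.orientation_seed)
    if spec.orientation_policy == "per_element":
        thetas = rng.uniform(0.0, 2.0 * np.pi, size=(rows, cols))
    else:
        thetas = np.full((rows, cols), rng.uniform(0.0, 2.0 * np.pi))

    x, y = _element_coords(spec)
    env = _envelope(spec)
    px = spec.element_px
    out = np.empty((rows * px, cols * px, n_frames))
    for i in range(rows):
        for j in range(cols):
            r = y * np.cos(thetas[i, j]) + x * np.sin(thetas[i, j])
            carrier_phase = 2.0 * np.pi * spec.spatial_freq_cpd * r
            phase = carrier_phase[:, :, None] - (np.pi / 4.0) * values[i, j, :][None, None, :]
            out[i * px : (i + 1) * px, j * px : (j + 1) * px, :] = (
                spec.mean_level * (1.0 + np.cos(phase) * env[:, :, None])
            )
    return _check_range(out, spec)


def render(stimulus: StimulusTensor, spec: RenderSpec) -> np.ndarray:
    """Dispatch on ``spec.attribute``."""
    fn = {"luminance": render_luminance, "color": render_color, "gabor": render_gabor}
    return fn[spec.attribute](stimulus, spec)


class MovieEncoderError(RuntimeError):
    """No encoder available for the requested movie format."""


def _quantize(frames: np.ndarray, dtype: type) -> np.ndarray:
    info = np.iinfo(dtype)
    return np.round(np.clip(frames, 0.0, 1.0) * info.max).astype(dtype)


def write_movie(
    frames: np.ndarray,
    path: str | Path,
    fmt: str = "gif",
    frame_rate: float = 30.0,
    metadata: dict | None = None,
) -> np.ndarray:
    """Export a rendered frame stack as a movie or image sequence.

    ``frames`` is (rows_px, cols_px, n_frames) or (..., n_frames, 3) with
    values in [0, 1].  Formats: ``gif`` (8-bit), ``mp4`` (requires an
    ffmpeg-backed imageio plugin) or ``image-sequence`` (16-bit PNGs, one per
    frame, written into the directory ``path``; lossless at the stored
    16-bit precision).  Returns the quantized stack actually written, so
    callers can verify bit-exact round trips.  A JSON metadata sidecar is
    written next to the output when ``metadata`` is given.
    """
    path = Path(path)
    frames = np.asarray(frames)
    if frames.ndim == 3:
        stack = frames.transpose(2, 0, 1)  # (T, H, W)
    elif frames.ndim == 4:
        stack = frames.transpose(2, 0, 1, 3)  # (T, H, W, 3)
    else:
        raise ValueError(f"frames must be 3-D or 4-D, got shape {frames.shape}")

    if fmt == "gif":
        data = _quantize(stack, np.uint8)
        iio.imwrite(path, data, duration=1000.0 / frame_rate, loop=0)
    elif fmt == "image-sequence":
        data = _quantize(stack, np.uint16)
        path.mkdir(parents=True, exist_ok=True)
        for t, frame in enumerate(data):
            iio.imwrite(path / f"frame_{t:04d}.png", frame)
    elif fmt == "mp4":
        data = _quantize(stack, np.uint8)
        try:
            import imageio.v2 as iio2

            with iio2.get_writer(path, fps=frame_rate, format="FFMPEG") as writer:
                for frame in data:
                    writer.append_data(frame)
        except Exception as exc:  # pragma: no cover - depends on ffmpeg plugin
            raise MovieEncoderError(
                "mp4 export needs an ffmpeg-backed imageio plugin; "
                "use fmt='gif' or 'image-sequence' instead"
            ) from exc
    else:
        raise ValueError(f"unknown movie format {fmt!r}")

    if metadata is not None:
        side = (path / "metadata.json") if fmt == "image-sequence" else path.with_suffix(path.suffix + ".json")
        side.write_text(json.dumps(metadata, indent=2))
    return data


def read_image_sequence(path: str | Path) -> np.ndarray:
    """Read back a PNG image sequence written by :func:`write_movie`."""
    files = sorted(Path(path).glob("frame_*.png"))
    if not files:
        raise FileNotFoundError(f"no frame_*.png files under {path}")
    return np.stack([iio.imread(f) for f in files], axis=0)
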
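"""Stimulus synthesis: contrast-scaled sketches, drifting/tilted noisy
Gabors, the uniform flicker adapter and the random-pixel mask.

All stimuli live on a mid-grey display background (pixel value 127,
12 cd/m^2); sketch pixels map to black = 7 cd/m^2 and white = 22 cd/m^2 at
full contrast.  Contrast scaling of sketches/images interpolates linearly
between the background luminance (c = 0) and the full black/white map
(c = 1) — the background is not the midpoint of 7 and 22, so symmetric
scaling about the mean could not reproduce the stated endpoint luminances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .sketch import BACKGROUND, BLACK, WHITE, BinaryImage, Sketch

__all__ = [
    "LuminanceMap",
    "GaborSpec",
    "FlickerSpec",
    "FrameStack",
    "michelson_contrast",
    "render_at_contrast",
    "make_gabor_frames",
    "make_flicker_frames",
    "make_mask",
]


@dataclass(frozen=True)
class LuminanceMap:
    """Display luminances in cd/m^2 for the three sketch pixel states."""

    L_black: float = 7.0
    L_white: float = 22.0
    L_background: float = 12.0

    def __post_init__(self) -> None:
        if not self.L_black < self.L_background < self.L_white:
            raise ValueError("luminances must satisfy black < background < white")


def michelson_contrast(L_max: float, L_min: float) -> float:
    """(L_max - L_min) / (L_max + L_min) for a luminance pair."""
    if L_min < 0 or L_max < L_min:
        raise ValueError("need L_max >= L_min >= 0")
    if L_max + L_min == 0:
        raise ValueError("Michelson contrast undefined for two zero luminances")
    return (L_max - L_min) / (L_max + L_min)


def render_at_contrast(
    img: Sketch | BinaryImage | np.ndarray,
    c: float,
    lum: LuminanceMap = LuminanceMap(),
) -> np.ndarray:
    """Render a sketch or binary image as a luminance grid at contrast ``c``.

    Background pixels stay at ``L_background``; black/white pixels move from
    the background (c = 0) to their full luminance (c = 1) linearly in ``c``.
    Binary images are treated as two-state (0 = black, 1 = white).
    """
    if not 0 <= c <= 1:
        raise ValueError("contrast must lie in [0, 1]")
    if isinstance(img, Sketch):
        states = img.pixels.astype(np.int8)
    elif isinstance(img, BinaryImage):
        states = img.pixels.astype(np.int8)
    else:
        states = np.asarray(img, dtype=np.int8)
    out = np.full(states.shape, lum.L_background, dtype=float)
    out[states == BLACK] = lum.L_background + c * (lum.L_black - lum.L_background)
    out[states == WHITE] = lum.L_background + c * (lum.L_white - lum.L_background)
    return out


@dataclass(frozen=True)
class GaborSpec:
    """A noisy Gabor patch.

    ``orientation`` is in degrees from vertical; ``noise_sigma`` is the SD of
    the static Gaussian pixel noise in 8-bit pixel-value units; the Gaussian
    envelope sigma defaults to size/6 so +-3 sigma spans the patch.
    """

    spatial_freq: float  # cycles/deg
    orientation: float = 0.0  # deg from vertical
    temporal_freq: float = 10.0  # Hz
    size: float = 5.0  # deg
    pixels_per_deg: float = 32.0
    noise_sigma: float = 50.0  # pixel-value units
    contrast: float = 1.0
    envelope_sigma: float | None = None  # deg; None -> size / 6

    def __post_init__(self) -> None:
        if not 0 <= self.contrast <= 1:
            raise ValueError("contrast must lie in [0, 1]")
        if self.spatial_freq <= 0 or self.size <= 0 or self.pixels_per_deg <= 0:
            raise ValueError("spatial_freq, size and pixels_per_deg must be > 0")

    @property
    def sigma_deg(self) -> float:
        return self.size / 6.0 if self.envelope_sigma is None else self.envelope_sigma


@dataclass(frozen=True)
class FlickerSpec:
    """Uniform full-field adapter alternating between two luminances."""

    L_high: float = 22.0
    L_low: float = 7.0
    alternation_freq: float = 10.0  # Hz
    field_size: float = 5.0  # deg

    def __post_init__(self) -> None:
        if self.L_high <= self.L_low:
            raise ValueError("L_high must exceed L_low")
        if self.alternation_freq <= 0:
            raise ValueError("alternation frequency must be > 0")


@dataclass(frozen=True)
class FrameStack:
    """An ordered stack of frames at a fixed frame rate."""

    frames: np.ndarray  # (n_frames, h, w)
    frame_rate: float  # Hz
    duration: float  # ms
    clip_fraction: float = 0.0

    def __post_init__(self) -> None:
        expected = int(round(self.duration * self.frame_rate / 1000.0))
        if self.frames.shape[0] != expected:
            raise ValueError(
                f"frame count {self.frames.shape[0]} != round(duration*rate/1000)"
                f" = {expected}"
            )

    def __len__(self) -> int:
        return self.frames.shape[0]


def _n_frames(duration_ms: float, frame_rate: float) -> int:
    n = int(round(duration_ms * frame_rate / 1000.0))
    if n < 1:
        raise ValueError("duration too short for one frame")
    return n


def make_gabor_frames(
    spec: GaborSpec,
    duration: float = 25.0,
    frame_rate: float = 120.0,
    direction: str = "none",
    noise_seed: int = 0,
    mean_level: float = 127.0,
) -> FrameStack:
    """Render a drifting (or static) Gabor in static Gaussian noise.

    The carrier is a cosine grating whose phase advances by
    ``360 * temporal_freq / frame_rate`` degrees per frame in the requested
    direction; one noise field is drawn from ``noise_seed`` and added
    identically to every frame, after contrast scaling of the carrier, so
    contrast manipulations leave the noise power untouched.  Output is in
    8-bit pixel-value units, clipped to [0, 255]; the fraction of clipped
    samples is recorded on the stack.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if direction not in ("left", "right", "none"):
        raise ValueError("direction must be 'left', 'right' or 'none'")
    n = _n_frames(duration, frame_rate)
    npx = int(round(spec.size * spec.pixels_per_deg))
    half = spec.size / 2.0
    x = np.linspace(-half, half, npx, endpoint=False) + half / npx
    xx, yy = np.meshgrid(x, x)
    theta = np.deg2rad(spec.orientation)
    # distance along the modulation axis (perpendicular to the bars)
    u = xx * np.cos(theta) + yy * np.sin(theta)
    envelope = np.exp(-(xx**2 + yy**2) / (2.0 * spec.sigma_deg**2))

    sign = {"right": 1.0, "left": -1.0, "none": 0.0}[direction]
    dphi = 2.0 * np.pi * spec.temporal_freq / frame_rate
    rng = np.random.default_rng(noise_seed)
    noise = rng.normal(0.0, spec.noise_sigma, size=(npx, npx))

    frames = np.empty((n, npx, npx))
    for k in range(n):
        carrier = np.cos(2.0 * np.pi * spec.spatial_freq * u - sign * dphi * k)
        signal = mean_level * spec.contrast * envelope * carrier
        frames[k] = mean_level + signal + noise
    clipped = ((frames < 0) | (frames > 255)).mean()
    frames = np.clip(frames, 0.0, 255.0)
    return FrameStack(
        frames=frames,
        frame_rate=frame_rate,
        duration=duration,
        clip_fraction=float(clipped),
    )


def make_flicker_frames(
    spec: FlickerSpec, duration: float, frame_rate: float = 120.0
) -> FrameStack:
    """Square-wave uniform flicker, starting on the high luminance."""
    if duration <= 0:
        raise ValueError("duration must be > 0")
    n = _n_frames(duration, frame_rate)
    half_period = frame_rate / (2.0 * spec.alternation_freq)
    if abs(half_period - round(half_period)) > 1e-9:
        warnings.warn(
            f"flicker half-period {half_period:.3f} frames is not an integer; "
            "rounding to the nearest frame",
            stacklevel=2,
        )
    half = max(1, int(round(half_period)))
    idx = (np.arange(n) // half) % 2
    levels = np.where(idx == 0, spec.L_high, spec.L_low)
    frames = np.broadcast_to(levels[:, None, None], (n, 1, 1)).astype(float).copy()
    return FrameStack(frames=frames, frame_rate=frame_rate, duration=duration)


def make_mask(size: tuple[int, int], seed: int = 0) -> np.ndarray:
    """Random black/white pixel mask (uint8 values 0 or 255), seeded."""
    h, w = size
    if h <= 0 or w <= 0:
        raise ValueError("mask dimensions must be positive")
    rng = np.random.default_rng(seed)
    return np.where(rng.random((h, w)) < 0.5, 0, 255).astype(np.uint8)
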
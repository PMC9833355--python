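"""Phase-space-reconstruction (delay-map) images of ECG segments.

Each 10-s segment is embedded in two dimensions as the point set
``{(x_t, x_{t+tau})}``, min-max rescaled per segment, and binned into a
``grid x grid`` occupancy histogram whose pixels sum to one.  The image
captures waveform morphology — and in particular the relative extent of the
T-wave loop versus the R-wave loop — without locating any fiducial points.

Binning convention: bin index = ``floor(u * grid)`` with half-open bins
``[i/grid, (i+1)/grid)``; ``u = 1`` is clamped into the last bin.  Rows hold
the delayed coordinate ``x_{t+tau}``, columns the current coordinate
``x_t``, so reversing a segment in time exactly transposes its image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import EcgSegment

DEFAULT_DELAY_MS = 20.0
DEFAULT_GRID = 32


@dataclass(frozen=True)
class PsrParams:
    """Delay-map parameters: lag in samples, image side length."""

    delay_samples: int = 10  # 20 ms at 500 Hz
    grid: int = DEFAULT_GRID
    normalization: str = "per-segment min-max"
    intensity: str = "count-fraction"

    def __post_init__(self) -> None:
        if self.delay_samples < 1:
            raise ValueError("delay_samples must be >= 1")
        if self.grid < 2:
            raise ValueError("grid must be >= 2")
        if self.normalization != "per-segment min-max":
            raise ValueError("only per-segment min-max normalization is supported")
        if self.intensity != "count-fraction":
            raise ValueError("only count-fraction intensity is supported")

    @staticmethod
    def from_delay_ms(delay_ms: float = DEFAULT_DELAY_MS, fs: float = 500.0, grid: int = DEFAULT_GRID):
        return PsrParams(delay_samples=max(1, int(round(delay_ms * fs / 1000.0))), grid=grid)


@dataclass
class PsrImage:
    """Nonnegative ``grid x grid`` delay-map histogram of one segment."""

    pixels: np.ndarray
    segment_index: int
    channel: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("pixels must be a square 2-D array")
        if np.any(self.pixels < 0):
            raise ValueError("pixels must be nonnegative")


def psr_image(segment: EcgSegment, params: PsrParams = PsrParams()) -> PsrImage:
    """Delay-map image of one segment.

    A constant segment has no amplitude range; its entire mass is placed on
    the centre pixel by convention (degenerate but defined).
    """
    x = segment.samples
    tau = params.delay_samples
    g = params.grid
    if x.size < tau + 2:
        raise ValueError(
            f"segment of {x.size} samples too short for delay {tau} (need >= {tau + 2})"
        )
    pixels = np.zeros((g, g))
    mn, mx = x.min(), x.max()
    if mx == mn:
        pixels[g // 2, g // 2] = 1.0
        return PsrImage(pixels, segment.segment_index, segment.channel)
    u = (x - mn) / (mx - mn)
    col = np.minimum((u[:-tau] * g).astype(int), g - 1)  # x_t
    row = np.minimum((u[tau:] * g).astype(int), g - 1)  # x_{t+tau}
    np.add.at(pixels, (row, col), 1.0)
    pixels /= row.size
    return PsrImage(pixels, segment.segment_index, segment.channel)


def batch_images(segments: list, params: PsrParams = PsrParams()) -> list:
    """Order-preserving map of :func:`psr_image` over segments.

    Raises with the offending ``segment_index`` named if any segment fails.
    """
    if segments:
        fs0 = segments[0].fs
        if any(s.fs != fs0 for s in segments):
            raise ValueError("all segments must share the same sampling rate")
    out = []
    for seg in segments:
        try:
            out.append(psr_image(seg, params))
        except ValueError as e:
            raise ValueError(f"segment {seg.segment_index}: {e}") from e
    return out


def images_to_array(images: list) -> np.ndarray:
    """Stack PsrImages into an (N, grid, grid) float array."""
    return np.stack([im.pixels for im in images]) if images else np.empty((0, 0, 0))
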
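"""Core data containers shared across the pipeline.

Conventions used throughout the package:

* amplitudes are in millivolts, times in seconds from recording start;
* the three Holter channels A/B/C are surrogates of the S-ICD primary,
  alternate and secondary sensing vectors respectively;
* 10-second analysis windows are half-open ``[10k, 10(k+1))`` and 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical Holter channel -> S-ICD sensing-vector surrogate mapping
DEFAULT_CHANNEL_MAP = {"A": "primary", "B": "alternate", "C": "secondary"}

#: sensing vectors in lead order A < B < C
VECTOR_ORDER = ("primary", "alternate", "secondary")


@dataclass
class EcgRecording:
    """Multi-channel uniformly sampled ECG.

    Parameters
    ----------
    samples
        Array of shape ``(n_channels, n_samples)`` in mV.
    fs
        Sampling frequency in Hz.
    channel_map
        Channel label -> sensing-vector name; must cover exactly the three
        S-ICD vectors.
    """

    samples: np.ndarray
    fs: float
    channel_map: dict = field(default_factory=lambda: dict(DEFAULT_CHANNEL_MAP))

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (n_channels, n_samples) array")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if sorted(self.channel_map.values()) != sorted(VECTOR_ORDER):
            raise ValueError(
                "channel_map must cover exactly the vectors "
                f"{VECTOR_ORDER}, got {tuple(self.channel_map.values())}"
            )
        if self.samples.shape[0] != len(self.channel_map):
            raise ValueError("one sample row required per mapped channel")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def channel_labels(self) -> list:
        """Channel labels in lead order (A, B, C)."""
        return sorted(self.channel_map)

    def vector_of(self, label: str) -> str:
        return self.channel_map[label]

    def channel(self, label: str) -> np.ndarray:
        """Samples of one channel by its label."""
        return self.samples[self.channel_labels.index(label)]


@dataclass
class EcgSegment:
    """One 10-s (by default) window of a single channel."""

    samples: np.ndarray
    fs: float
    segment_index: int
    channel: str  # sensing-vector name
    start_time_s: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("segment samples must be 1-D")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass
class TrSeries:
    """Time-ordered per-segment T:R estimates for one sensing vector.

    ``source`` tags where the values came from: ``"oracle"`` (explicit-wave
    detector), ``"cnn"`` (image regressor) or ``"truth"`` (generator ground
    truth).
    """

    channel: str
    segment_index: np.ndarray
    start_time_s: np.ndarray
    tr: np.ndarray
    source: str

    def __post_init__(self) -> None:
        self.segment_index = np.asarray(self.segment_index, dtype=int)
        self.start_time_s = np.asarray(self.start_time_s, dtype=float)
        self.tr = np.asarray(self.tr, dtype=float)
        if not (self.segment_index.size == self.start_time_s.size == self.tr.size):
            raise ValueError("segment_index, start_time_s, tr must be equal length")
        if self.segment_index.size and np.any(np.diff(self.segment_index) <= 0):
            raise ValueError("segment_index must be strictly increasing")
        if self.source not in ("oracle", "cnn", "truth"):
            raise ValueError(f"unknown source tag {self.source!r}")
        finite = self.tr[np.isfinite(self.tr)]
        if finite.size and finite.min() < 0:
            raise ValueError("tr values must be nonnegative")

    def __len__(self) -> int:
        return self.tr.size

    def valid(self) -> "TrSeries":
        """Copy with flagged (NaN) segments dropped."""
        keep = np.isfinite(self.tr)
        return TrSeries(
            channel=self.channel,
            segment_index=self.segment_index[keep],
            start_time_s=self.start_time_s[keep],
            tr=self.tr[keep],
            source=self.source,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "channel": self.channel,
                "segment_index": self.segment_index,
                "start_time_s": self.start_time_s,
                "tr": self.tr,
                "source": self.source,
            }
        )


def trseries_to_csv(series_list: list, path) -> None:
    """Write one or more TrSeries to the canonical CSV layout."""
    frames = [s.to_frame() for s in series_list]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def trseries_from_csv(path) -> list:
    """Read TrSeries (one per channel) back from CSV."""
    df = pd.read_csv(path)
    out = []
    for (channel, source), grp in df.groupby(["channel", "source"], sort=False):
        grp = grp.sort_values("segment_index")
        out.append(
            TrSeries(
                channel=channel,
                segment_index=grp["segment_index"].to_numpy(),
                start_time_s=grp["start_time_s"].to_numpy(),
                tr=grp["tr"].to_numpy(),
                source=source,
            )
        )
    return out
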
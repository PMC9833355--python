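"""Characterisation of T:R dynamics over a 24-h screening period.

For each sensing vector: mean/SD of the per-segment T:R series, the count
and proportion of 10-s segments above the 1:3 eligibility threshold, a
trailing half-hour rolling mean (one point per segment), and an occupancy
histogram of the fraction of the recording spent in each T:R range.
A vector-selection rule recommends the most stable eligible vector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .containers import VECTOR_ORDER, TrSeries

SCREENING_THRESHOLD = 1.0 / 3.0
DEFAULT_ROLLING_WINDOW_S = 1800.0
DEFAULT_BIN_WIDTH = 0.05


def rolling_mean(series: TrSeries, window_s: float = DEFAULT_ROLLING_WINDOW_S) -> dict:
    """Trailing mean of the preceding ``window_s`` seconds, one point per segment.

    The value at segment end time ``t`` averages every segment whose start
    falls in ``(t - window_s, t]``; points earlier than one full window use
    all available preceding segments and are flagged as warm-up.
    """
    s = series.valid()
    if len(s) == 0:
        return {"time_s": np.array([]), "value": np.array([]), "warmup": np.array([], bool)}
    t = s.start_time_s
    seg_len = float(t[1] - t[0]) if t.size > 1 else 10.0
    csum = np.concatenate(([0.0], np.cumsum(s.tr)))
    # point at each segment's end; average over segments fully inside the
    # trailing window, i.e. starts in [t_end - window_s, t_end - seg_len]
    lo = np.searchsorted(t, t - (window_s - seg_len) - 1e-9, side="left")
    hi = np.arange(1, t.size + 1)
    value = (csum[hi] - csum[lo]) / (hi - lo)
    n_full = max(1, int(round(window_s / seg_len)))
    warmup = (hi - lo) < n_full
    return {"time_s": t + seg_len, "value": value, "warmup": warmup}


def occupancy_histogram(
    series: TrSeries,
    bin_width: float = DEFAULT_BIN_WIDTH,
    range_: tuple = (0.0, 1.0),
) -> dict:
    """Fraction of the recording spent in each T:R range.

    Half-open bins ``[a, a + w)``; values at or above the upper range edge
    are clamped into the last bin.  Returns bin edges, per-bin fractions
    (summing to 1) and raw segment counts.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    s = series.valid()
    if len(s) == 0:
        raise ValueError("empty series")
    lo, hi = range_
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    # small epsilon so values sitting on a bin edge up to float error land
    # in the upper (half-open) bin
    idx = np.clip(np.floor((s.tr - lo) / bin_width + 1e-9).astype(int), 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    return {"edges": edges, "fractions": counts / counts.sum(), "counts": counts.astype(int)}


def threshold_stats(series: TrSeries, threshold: float = SCREENING_THRESHOLD) -> tuple:
    """(count, proportion) of segments strictly above the screening threshold."""
    s = series.valid()
    if len(s) == 0:
        raise ValueError("empty series")
    count = int(np.sum(s.tr > threshold))
    return count, count / len(s)


def format_percent(count: int, n: int) -> str:
    """Report-style percentage: 0 -> "0%", below 1% -> "<1%", else integer."""
    if count == 0:
        return "0%"
    pct = 100.0 * count / n
    if pct < 1.0:
        return "<1%"
    return f"{round(pct):.0f}%"


@dataclass
class VectorSummary:
    """Per-vector bundle of longitudinal T:R statistics."""

    channel: str
    mean_tr: float
    sd_tr: float
    n_segments: int
    n_above_threshold: int
    prop_above_threshold: float
    percent_label: str
    rolling: dict = field(repr=False, default_factory=dict)
    histogram: dict = field(repr=False, default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "channel": self.channel,
            "mean_tr": self.mean_tr,
            "sd_tr": self.sd_tr,
            "n_segments": self.n_segments,
            "n_above_threshold": self.n_above_threshold,
            "prop_above_threshold": self.prop_above_threshold,
            "percent_label": self.percent_label,
        }


def summarize_vector(
    series: TrSeries,
    threshold: float = SCREENING_THRESHOLD,
    rolling_window_s: float = DEFAULT_ROLLING_WINDOW_S,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> VectorSummary:
    """Assemble the full per-vector summary (mean, SD, threshold, dynamics)."""
    s = series.valid()
    if len(s) == 0:
        raise ValueError("empty series")
    count, prop = threshold_stats(s, threshold)
    return VectorSummary(
        channel=s.channel,
        mean_tr=float(np.mean(s.tr)),
        sd_tr=float(np.std(s.tr, ddof=1)) if len(s) > 1 else 0.0,
        n_segments=len(s),
        n_above_threshold=count,
        prop_above_threshold=prop,
        percent_label=format_percent(count, len(s)),
        rolling=rolling_mean(s, rolling_window_s),
        histogram=occupancy_histogram(s, bin_width),
    )


@dataclass
class ScreeningReport:
    """Vector-selection outcome over a long recording.

    Eligibility over a 24-h recording is defined here (as a documented
    extension of the snapshot pass/fail screen) as spending at most
    ``eligibility_max_prop`` of the recording above the threshold.  Among
    eligible vectors the recommendation minimises
    ``(prop_above_threshold, sd_tr, lead order A < B < C)`` lexicographically.
    """

    summaries: list
    threshold: float
    eligibility_max_prop: float
    eligible: dict
    recommended: str | None
    ranking: list
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "eligibility_max_prop": self.eligibility_max_prop,
            "eligible": self.eligible,
            "recommended": self.recommended,
            "ranking": self.ranking,
            "note": self.note,
            "vectors": {s.channel: s.to_dict() for s in self.summaries},
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)


def select_vector(
    summaries: list,
    threshold: float = SCREENING_THRESHOLD,
    eligibility_max_prop: float = 0.01,
) -> ScreeningReport:
    """Rank vectors by stability and recommend the best eligible one."""
    if not summaries:
        raise ValueError("no vector summaries given")
    lead_rank = {v: i for i, v in enumerate(VECTOR_ORDER)}

    def key(s: VectorSummary):
        return (s.prop_above_threshold, s.sd_tr, lead_rank.get(s.channel, 99))

    ranking = [s.channel for s in sorted(summaries, key=key)]
    eligible = {s.channel: s.prop_above_threshold <= eligibility_max_prop for s in summaries}
    eligible_order = [ch for ch in ranking if eligible[ch]]
    if eligible_order:
        recommended, note = eligible_order[0], ""
    else:
        recommended = None
        note = (
            "no vector met the eligibility criterion (at most "
            f"{eligibility_max_prop:.1%} of the recording above the threshold); "
            "ranking reflects relative stability only"
        )
    return ScreeningReport(
        summaries=list(summaries),
        threshold=threshold,
        eligibility_max_prop=eligibility_max_prop,
        eligible=eligible,
        recommended=recommended,
        ranking=ranking,
        note=note,
    )
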
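"""Per-segment T:R estimation.

Two estimators are provided:

* :func:`oracle_tr` — an explicit R/T-wave detector used as label source
  and transparent baseline.  R peaks are found by adaptive-threshold peak
  finding on a band-passed copy of the segment; the T amplitude is the
  largest baseline-corrected excursion 150–450 ms after each R peak
  (truncated at 60% of the running RR interval); the segment value is the
  median over beats of T/R.
* the CNN route — :func:`train_cnn` / :func:`predict_tr` regress T:R
  directly from 32x32 delay-map images, without locating any waves.

T:R (not R:T) is the regression target: as the T amplitude approaches
zero, T:R approaches zero smoothly whereas R:T diverges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .cnn import CnnConfig, CnnRegressor
from .containers import EcgSegment, TrSeries
from .preprocess import segment as segment_recording
from .psr import PsrParams, batch_images, images_to_array, psr_image

log = logging.getLogger(__name__)

MIN_BEATS = 3
REFRACTORY_S = 0.25
T_WINDOW_S = (0.15, 0.45)
T_RR_FRACTION = 0.6
BASELINE_WINDOW_S = (-0.12, -0.07)  # isoelectric PR stretch relative to R


def _detect_r_peaks(x: np.ndarray, fs: float) -> np.ndarray:
    """Adaptive-threshold R-peak detection on a 5–25 Hz band-passed copy."""
    sos = sps.butter(2, (5.0, 25.0), btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    env = np.abs(bp)
    thr = 0.4 * np.percentile(env, 99.5)
    if thr <= 0:
        return np.array([], dtype=int)
    peaks, _ = sps.find_peaks(env, height=thr, distance=max(1, int(REFRACTORY_S * fs)))
    # refine to the raw-signal extremum near each detection
    half = int(0.04 * fs)
    med = np.median(x)
    refined = []
    for p in peaks:
        lo, hi = max(0, p - half), min(x.size, p + half + 1)
        refined.append(lo + int(np.argmax(np.abs(x[lo:hi] - med))))
    return np.unique(refined)


def oracle_tr(seg: EcgSegment) -> float:
    """Median per-beat T/R of one segment; NaN when quality is insufficient.

    Returns NaN (never raises) for flat segments or when fewer than
    ``MIN_BEATS`` usable beats are detected.
    """
    x = seg.samples
    fs = seg.fs
    if x.size == 0 or np.ptp(x) == 0:
        return float("nan")
    peaks = _detect_r_peaks(x, fs)
    if peaks.size < MIN_BEATS:
        return float("nan")
    rr = np.diff(peaks) / fs
    ratios = []
    for i, p in enumerate(peaks):
        rr_here = rr[i] if i < rr.size else rr[-1]
        b_lo = p + int(BASELINE_WINDOW_S[0] * fs)
        b_hi = p + int(BASELINE_WINDOW_S[1] * fs)
        t_lo = p + int(T_WINDOW_S[0] * fs)
        t_hi = p + int(min(T_WINDOW_S[1], T_RR_FRACTION * rr_here) * fs)
        if b_lo < 0 or t_hi > x.size or t_hi <= t_lo:
            continue  # beat too close to the segment edge
        baseline = np.median(x[b_lo:b_hi])
        r_amp = abs(x[p] - baseline)
        if r_amp == 0:
            continue
        t_amp = np.max(np.abs(x[t_lo:t_hi] - baseline))
        ratios.append(t_amp / r_amp)
    if len(ratios) < MIN_BEATS:
        return float("nan")
    return float(np.median(ratios))


def oracle_tr_series(segments: list, channel: str | None = None) -> TrSeries:
    """Apply :func:`oracle_tr` to an ordered list of one channel's segments."""
    if not segments:
        raise ValueError("no segments given")
    return TrSeries(
        channel=channel or segments[0].channel,
        segment_index=np.array([s.segment_index for s in segments]),
        start_time_s=np.array([s.start_time_s for s in segments]),
        tr=np.array([oracle_tr(s) for s in segments]),
        source="oracle",
    )


@dataclass
class TrainedModel:
    """Fitted PSR-image -> T:R regressor plus its provenance."""

    net: CnnRegressor
    psr_params: PsrParams
    config: CnnConfig
    n_train: int
    final_loss: float
    training_curve: list = field(default_factory=list)

    def predict_images(self, images: np.ndarray) -> np.ndarray:
        return np.clip(self.net.predict(images), 0.0, None)

    def save(self, path) -> None:
        self.net.save(path)

    @classmethod
    def load(cls, path, psr_params: PsrParams = PsrParams()) -> "TrainedModel":
        net = CnnRegressor.load(path)
        return cls(
            net=net,
            psr_params=psr_params,
            config=net.config,
            n_train=0,
            final_loss=float("nan"),
        )


def build_training_set(
    recordings: list,
    params: PsrParams = PsrParams(),
    window_s: float = 10.0,
) -> tuple:
    """Assemble paired (image, label) arrays from recordings.

    ``recordings`` is a list of either ``(EcgRecording, ground_truth)``
    tuples (labels taken from the generator's per-segment truth) or bare
    ``EcgRecording`` objects (labels from :func:`oracle_tr`).  Flagged
    (NaN-labelled) segments are excluded; the exclusion count is logged.
    Returns ``(images, labels, recording_ids)`` where ``recording_ids``
    supports leakage-free train/validation splitting by recording.
    """
    images, labels, rec_ids = [], [], []
    n_excluded = 0
    for rec_id, item in enumerate(recordings):
        if isinstance(item, tuple):
            recording, truth = item
        else:
            recording, truth = item, None
        segs_by_vector = segment_recording(recording, window_s)
        for vector, segs in segs_by_vector.items():
            if truth is not None:
                grp = truth[truth["channel"] == vector].set_index("segment_index")["tr"]
                lab = np.array([grp.get(s.segment_index, np.nan) for s in segs])
            else:
                lab = np.array([oracle_tr(s) for s in segs])
            for s, y in zip(segs, lab):
                if not np.isfinite(y):
                    n_excluded += 1
                    continue
                images.append(psr_image(s, params).pixels)
                labels.append(y)
                rec_ids.append(rec_id)
    if n_excluded:
        log.info("build_training_set: excluded %d flagged segments", n_excluded)
    if not images:
        raise ValueError("no usable (image, label) pairs after exclusions")
    return np.stack(images), np.asarray(labels, dtype=float), np.asarray(rec_ids)


def train_cnn(
    images: np.ndarray,
    labels: np.ndarray,
    config: CnnConfig = CnnConfig(),
    psr_params: PsrParams = PsrParams(),
    min_pairs: int = 200,
    verbose: bool = False,
) -> TrainedModel:
    """Fit the CNN regressor; deterministic given ``config.seed``."""
    images = np.asarray(images)
    labels = np.asarray(labels, dtype=float)
    if images.shape[0] != labels.size:
        raise ValueError("images and labels must pair up")
    if labels.size < min_pairs:
        raise ValueError(f"need >= {min_pairs} training pairs, got {labels.size}")
    if labels.min() < 0 or labels.max() > 2:
        raise ValueError("labels must lie in [0, 2]")
    net = CnnRegressor(config, input_side=images.shape[-1])
    curve = net.fit(images, labels, verbose=verbose)
    return TrainedModel(
        net=net,
        psr_params=psr_params,
        config=config,
        n_train=int(labels.size),
        final_loss=float(curve[-1]),
        training_curve=curve,
    )


def predict_tr(model: TrainedModel, segments: list, params: PsrParams | None = None) -> TrSeries:
    """CNN T:R series for an ordered list of one channel's segments."""
    params = params or model.psr_params
    if params.grid != model.net.input_side:
        raise ValueError(
            f"model expects {model.net.input_side}x{model.net.input_side} images, "
            f"got grid={params.grid}"
        )
    if not segments:
        raise ValueError("no segments given")
    imgs = images_to_array(batch_images(segments, params))
    return TrSeries(
        channel=segments[0].channel,
        segment_index=np.array([s.segment_index for s in segments]),
        start_time_s=np.array([s.start_time_s for s in segments]),
        tr=model.predict_images(imgs),
        source="cnn",
    )


def split_by_recording(
    rec_ids: np.ndarray,
    holdout_frac: float = 0.2,
    seed: int = 0,
    groups: dict | None = None,
) -> tuple:
    """Train/holdout boolean masks split by recording id (no temporal leakage).

    When ``groups`` maps recording id -> group label, the holdout is
    stratified: at least one recording of every group is held out, so the
    holdout spans the full label range.
    """
    rng = np.random.default_rng(seed)
    uniq = np.unique(rec_ids)
    if groups:
        hold = []
        for g in sorted(set(groups.values())):
            members = np.array([u for u in uniq if groups.get(u) == g])
            n_hold = max(1, int(round(holdout_frac * members.size)))
            hold.extend(rng.choice(members, size=n_hold, replace=False))
        hold = np.array(hold)
    else:
        n_hold = max(1, int(round(holdout_frac * uniq.size)))
        hold = rng.choice(uniq, size=n_hold, replace=False)
    hold_mask = np.isin(rec_ids, hold)
    return ~hold_mask, hold_mask
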
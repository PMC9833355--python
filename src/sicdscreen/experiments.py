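"""Desk-scale reproduction experiments on synthetic cohorts.

These drivers wire the full pipeline together for the package's headline
checks: explicit-detector recovery of known T:R, CNN recovery on held-out
recordings, and the two-group cohort contrast.  Problem sizes default to
desk scale (tens of minutes of signal per recording rather than 24 h); the
statistical structure — group presets, within-recording fluctuation,
between-patient spread — is unchanged by the shorter duration because the
generator calibrates segment-level T:R per recording.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import estimate, preprocess, stats
from .cnn import CnnConfig
from .psr import PsrParams
from .synth import SynthParams, cohort_params, generate_recording, make_preset


def oracle_recovery_experiment(
    seed: int = 0,
    tr_levels=np.arange(0.05, 0.51, 0.05),
    duration_s: float = 30.0,
) -> dict:
    """Max |oracle - truth| over noise-free recordings spanning ``tr_levels``."""
    worst = 0.0
    n = 0
    for tr in tr_levels:
        params = SynthParams(
            duration_s=duration_s,
            tr_mean=float(tr),
            tr_sd=0.0,
            baseline_wander_amp=0.0,
            mains_amp=0.0,
            noise_sd=0.0,
            seed=seed,
        )
        rec, _ = generate_recording(params)
        for seg in preprocess.segment(rec)["primary"]:
            worst = max(worst, abs(estimate.oracle_tr(seg) - tr))
            n += 1
    return {"max_abs_error": float(worst), "n_segments": n}


def cnn_recovery_experiment(
    seed: int = 0,
    n_per_group: int = 3,
    duration_s: float = 2400.0,
    epochs: int = 15,
    holdout_frac: float = 0.34,
) -> dict:
    """Train the CNN on mixed-preset recordings; score on held-out recordings.

    The train/holdout split is by recording (stratified so both presets are
    represented in the holdout), avoiding temporal leakage.  Labels are the
    generator's segment-level ground truth.
    """
    rng = np.random.default_rng(seed)
    recordings, groups = [], {}
    for i, preset in enumerate(["hf"] * n_per_group + ["normal"] * n_per_group):
        params = make_preset(
            preset, duration_s=duration_s, seed=int(rng.integers(0, 2**31 - 1))
        )
        rec, truth = generate_recording(params)
        recordings.append((preprocess.preprocess_chain(rec), truth))
        groups[i] = preset
    images, labels, rec_ids = estimate.build_training_set(recordings, PsrParams())
    train_mask, hold_mask = estimate.split_by_recording(
        rec_ids, holdout_frac, seed=seed, groups=groups
    )
    model = estimate.train_cnn(
        images[train_mask],
        labels[train_mask],
        CnnConfig(epochs=epochs, seed=seed),
    )
    pred = model.predict_images(images[hold_mask])
    truth_held = labels[hold_mask]
    mae = float(np.mean(np.abs(pred - truth_held)))
    r = float(np.corrcoef(pred, truth_held)[0, 1])
    return {
        "mae": mae,
        "pearson_r": r,
        "n_train": int(train_mask.sum()),
        "n_holdout": int(hold_mask.sum()),
        "model": model,
    }


def cohort_experiment(
    seed: int = 0,
    n_hf: int = 14,
    n_normal: int = 7,
    duration_s: float = 7200.0,
    channel: str = "primary",
) -> dict:
    """Simulate the two-group cohort and compare per-patient T:R summaries.

    Each simulated patient contributes one recording; the per-patient mean
    and SD of the oracle-estimated T:R series (one value per 10-s segment,
    ``channel`` vector) feed Welch t and Mann–Whitney U group comparisons.
    """
    rows = []
    for pid, (group, params) in enumerate(
        cohort_params(n_hf=n_hf, n_normal=n_normal, duration_s=duration_s, seed=seed)
    ):
        rec, _ = generate_recording(params)
        clean = preprocess.preprocess_chain(rec)
        segs = preprocess.segment(clean)[channel]
        series = estimate.oracle_tr_series(segs, channel).valid()
        rows.append(
            {
                "patient": pid,
                "group": "HF" if group == "hf" else "Normal",
                "mean_tr": float(np.mean(series.tr)),
                "sd_tr": float(np.std(series.tr, ddof=1)),
                "n_segments": len(series),
            }
        )
    per_patient = pd.DataFrame(rows)
    comparisons = stats.compare_groups(per_patient)
    return {"per_patient": per_patient, "comparisons": comparisons}
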
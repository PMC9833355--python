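import numpy as np
import pytest

from sicdscreen import preprocess
from sicdscreen.containers import EcgSegment
from sicdscreen.synth import SynthParams, generate_recording


def clean_synth_params(tr: float, duration_s: float = 60.0, seed: int = 0, **kw) -> SynthParams:
    """Noise-free generator parameters with a fixed true T:R."""
    base = dict(
        tr_mean=tr,
        tr_sd=0.0,
        baseline_wander_amp=0.0,
        mains_amp=0.0,
        noise_sd=0.0,
        seed=seed,
    )
    base.update(kw)
    return SynthParams(duration_s=duration_s, **base)


def make_segment(samples, fs=500.0, index=0, channel="primary"):
    return EcgSegment(
        samples=np.asarray(samples, dtype=float),
        fs=fs,
        segment_index=index,
        channel=channel,
        start_time_s=10.0 * index,
    )


@pytest.fixture(scope="session")
def clean_beats_segments():
    """Noise-free segments with true T:R = 0.25 (primary channel)."""
    rec, truth = generate_recording(clean_synth_params(0.25, duration_s=60.0, seed=3))
    return preprocess.segment(rec)["primary"], truth
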
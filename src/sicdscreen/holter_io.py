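"""ASCII Holter reader/writer, run configuration, and the end-to-end pipeline.

The ASCII dialect is a plain 3-column whitespace-delimited file of sample
values in mV (channels A, B, C in lead order), with ``#``-prefixed header
lines declaring the sampling rate and the channel -> sensing-vector map::

    # fs=500
    # channels=A:primary,B:alternate,C:secondary
    0.012 0.009 0.015
    ...
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass

import numpy as np
import yaml

from . import estimate, longitudinal, preprocess, synth
from .containers import DEFAULT_CHANNEL_MAP, EcgRecording, trseries_to_csv
from .psr import PsrParams

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class HolterAsciiDialect:
    columns: tuple = ("A", "B", "C")
    comment: str = "#"
    float_format: str = "%.9g"


@dataclass
class RunConfig:
    """Resolved parameters of a full pipeline run."""

    fs: float = 500.0
    segment_s: float = 10.0
    mains_hz: float = 50.0
    highpass_hz: float = 0.5
    lowpass_hz: float = 40.0
    psr_delay_ms: float = 20.0
    psr_grid: int = 32
    smoothing_min: float = 30.0
    threshold: float = 1.0 / 3.0
    eligibility_max_prop: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fs", "segment_s", "mains_hz", "highpass_hz", "lowpass_hz",
                     "psr_delay_ms", "smoothing_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def psr_params(self) -> PsrParams:
        return PsrParams.from_delay_ms(self.psr_delay_ms, self.fs, self.psr_grid)


def write_holter(recording: EcgRecording, path, dialect: HolterAsciiDialect = HolterAsciiDialect()) -> None:
    """Write a recording in the ASCII dialect (header + one row per sample)."""
    labels = recording.channel_labels
    chmap = ",".join(f"{l}:{recording.channel_map[l]}" for l in labels)
    fs = recording.fs
    fs_str = f"{int(fs)}" if float(fs).is_integer() else f"{fs!r}"
    with open(path, "w") as fh:
        fh.write(f"{dialect.comment} fs={fs_str}\n")
        fh.write(f"{dialect.comment} channels={chmap}\n")
        fmt = " ".join([dialect.float_format] * len(labels)) + "\n"
        cols = [recording.channel(l) for l in labels]
        for row in zip(*cols):
            fh.write(fmt % row)


def read_holter(path, dialect: HolterAsciiDialect = HolterAsciiDialect(), fs: float | None = None) -> EcgRecording:
    """Read an ASCII Holter file; malformed rows raise with the line number."""
    channel_map = None
    header_fs = None
    data: list = []
    n_cols = len(dialect.columns)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(dialect.comment):
                body = line.lstrip(dialect.comment).strip()
                if body.startswith("fs="):
                    header_fs = float(body[3:])
                elif body.startswith("channels="):
                    channel_map = dict(
                        pair.split(":", 1) for pair in body[len("channels="):].split(",")
                    )
                continue
            fields = line.split()
            if len(fields) != n_cols:
                raise ValueError(
                    f"{path}: line {lineno}: expected {n_cols} fields, got {len(fields)}"
                )
            try:
                data.append([float(v) for v in fields])
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: non-numeric field") from None
    rate = header_fs if header_fs is not None else fs
    if rate is None:
        raise ValueError(f"{path}: no '# fs=' header and no fs override given")
    samples = (
        np.array(data, dtype=float).T if data else np.empty((n_cols, 0))
    )
    return EcgRecording(
        samples=samples,
        fs=rate,
        channel_map=channel_map or dict(DEFAULT_CHANNEL_MAP),
    )


def run_pipeline(
    config: RunConfig,
    preset: str | None = None,
    input_path=None,
    hours: float | None = None,
    estimator: str = "oracle",
    model: "estimate.TrainedModel | None" = None,
    outdir=None,
    make_plots: bool = False,
):
    """Run simulate/read -> preprocess -> segment -> estimate -> report.

    Exactly one of ``preset`` (synthetic recording) or ``input_path``
    (ASCII Holter file) must be given.  Returns ``(ScreeningReport,
    series_by_vector)``; when ``outdir`` is set, also writes the TrSeries
    CSV, the report JSON (with the resolved config embedded) and a Markdown
    summary, plus PNG plots when requested.
    """
    if (preset is None) == (input_path is None):
        raise ValueError("give exactly one of preset or input_path")
    try:
        if preset is not None:
            params = synth.make_preset(
                preset, duration_s=(hours or 24.0) * 3600.0, fs=config.fs, seed=config.seed
            )
            recording, _truth = synth.generate_recording(params)
        else:
            recording = read_holter(input_path, fs=config.fs)
        log.info("stage input: %d channels x %d samples at %g Hz",
                 recording.samples.shape[0], recording.n_samples, recording.fs)

        clean = preprocess.preprocess_chain(
            recording, config.highpass_hz, config.mains_hz, config.lowpass_hz
        )
        segs = preprocess.segment(clean, config.segment_s)
        log.info("stage segment: %d segments per channel",
                 len(next(iter(segs.values()))))

        series_by_vector = {}
        for vector, seg_list in segs.items():
            if estimator == "oracle":
                series = estimate.oracle_tr_series(seg_list, vector)
            elif estimator == "cnn":
                if model is None:
                    raise ValueError("estimator='cnn' requires a trained model")
                series = estimate.predict_tr(model, seg_list, config.psr_params())
            else:
                raise ValueError(f"unknown estimator {estimator!r}")
            series_by_vector[vector] = series

        summaries = [
            longitudinal.summarize_vector(
                s,
                threshold=config.threshold,
                rolling_window_s=config.smoothing_min * 60.0,
            )
            for s in series_by_vector.values()
        ]
        report = longitudinal.select_vector(
            summaries, config.threshold, config.eligibility_max_prop
        )
    except Exception as e:
        raise RuntimeError(f"pipeline failed: {e}") from e

    if outdir is not None:
        import pathlib

        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        trseries_to_csv(list(series_by_vector.values()), outdir / "trseries.csv")
        payload = report.to_dict()
        payload["config"] = asdict(config)
        payload["estimator"] = estimator
        (outdir / "report.json").write_text(json.dumps(payload, indent=2))
        (outdir / "summary.md").write_text(_markdown_summary(report))
        if make_plots:
            _write_plots(series_by_vector, report, config, outdir)
    return report, series_by_vector


def _markdown_summary(report) -> str:
    lines = [
        "| Vector | Segments > 1/3 (N) | Proportion of recording |",
        "|---|---|---|",
    ]
    for s in report.summaries:
        lines.append(f"| {s.channel} | {s.n_above_threshold} | {s.percent_label} |")
    lines.append("")
    lines.append(f"Recommended vector: {report.recommended or 'none eligible'}")
    return "\n".join(lines) + "\n"


def _write_plots(series_by_vector, report, config: RunConfig, outdir) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 4))
    for vector, series in series_by_vector.items():
        roll = longitudinal.rolling_mean(series, config.smoothing_min * 60.0)
        ax.plot(roll["time_s"] / 3600.0, roll["value"], label=vector)
    ax.axhline(config.threshold, color="k", ls="--", lw=1, label="1:3 threshold")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("T:R (preceding half-hour mean)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "rolling_tr.png", dpi=120)
    plt.close(fig)

    fig, axes = plt.subplots(1, len(series_by_vector), figsize=(12, 3), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, (vector, series) in zip(axes, series_by_vector.items()):
        hist = longitudinal.occupancy_histogram(series)
        centers = (hist["edges"][:-1] + hist["edges"][1:]) / 2
        ax.bar(centers, hist["fractions"], width=0.045)
        ax.axvline(config.threshold, color="k", ls="--", lw=1)
        ax.set_title(vector)
        ax.set_xlabel("T:R")
    axes[0].set_ylabel("fraction of recording")
    fig.tight_layout()
    fig.savefig(outdir / "occupancy_hist.png", dpi=120)
    plt.close(fig)
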
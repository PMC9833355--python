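import numpy as np
import pytest

from sicdscreen.containers import TrSeries
from sicdscreen.longitudinal import (
    VectorSummary,
    format_percent,
    occupancy_histogram,
    rolling_mean,
    select_vector,
    summarize_vector,
    threshold_stats,
)


def series(values, channel="primary", source="oracle"):
    values = np.asarray(values, dtype=float)
    idx = np.arange(values.size)
    return TrSeries(
        channel=channel,
        segment_index=idx,
        start_time_s=10.0 * idx,
        tr=values,
        source=source,
    )


class TestRollingMean:
    def test_constant_series_is_constant(self):
        roll = rolling_mean(series(np.full(400, 0.2)))
        assert np.allclose(roll["value"], 0.2)
        assert roll["value"].size == 400

    def test_step_ramps_over_half_hour(self):
        x = np.concatenate([np.zeros(360), np.full(360, 0.5)])  # step after 1 h
        roll = rolling_mean(series(x))
        v = roll["value"]
        # 30 min (180 segments) after the step the mean reaches 0.5 exactly
        assert v[359] == 0.0
        assert v[360 + 90 - 1] == pytest.approx(0.25)  # halfway through the ramp
        assert np.allclose(v[360 + 180 - 1 :], 0.5)
        # strictly increasing during the ramp
        assert np.all(np.diff(v[359 : 360 + 180]) > 0)

    def test_warmup_flagged(self):
        roll = rolling_mean(series(np.full(200, 0.1)))
        assert roll["warmup"][:179].all()
        assert not roll["warmup"][180:].any()

    def test_one_point_per_segment(self):
        roll = rolling_mean(series(np.linspace(0, 0.5, 250)))
        assert roll["time_s"].size == 250

    def test_empty_series(self):
        s = series([0.1, 0.2]).valid()
        s.tr = np.array([])
        s.segment_index = np.array([], dtype=int)
        s.start_time_s = np.array([])
        roll = rolling_mean(s)
        assert roll["value"].size == 0


class TestOccupancyHistogram:
    def test_single_bin_holds_all_mass(self):
        hist = occupancy_histogram(series(np.full(100, 0.2)))
        assert hist["fractions"][4] == 1.0  # [0.20, 0.25)
        assert hist["fractions"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_counts_sum_to_n(self):
        x = np.random.default_rng(0).uniform(0, 1, size=500)
        hist = occupancy_histogram(series(x))
        assert hist["counts"].sum() == 500

    def test_uniform_values_spread_evenly(self):
        x = np.random.default_rng(1).uniform(0, 1, size=20000)
        hist = occupancy_histogram(series(x))
        assert np.allclose(hist["fractions"], 0.05, atol=0.01)

    def test_values_at_or_above_one_clamped_to_last_bin(self):
        hist = occupancy_histogram(series([1.0, 1.4, 0.99]))
        assert hist["counts"][-1] == 3

    def test_bad_bin_width(self):
        with pytest.raises(ValueError):
            occupancy_histogram(series([0.1]), bin_width=0.0)


class TestThresholdStats:
    def test_strict_inequality_and_proportion(self):
        x = np.array([0.3, 1 / 3, 0.34, 0.5])
        count, prop = threshold_stats(series(x))
        assert count == 2  # 1/3 itself is not above
        assert prop == 0.5

    def test_brute_force_equivalence(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.uniform(0, 0.6, size=rng.integers(5, 200))
            count, prop = threshold_stats(series(x), 1 / 3)
            brute = len([v for v in x if v > 1 / 3])
            assert count == brute
            assert prop == brute / x.size

    @pytest.mark.parametrize(
        "n_above,n,label",
        [(2613, 8640, "30%"), (0, 8640, "0%"), (8640, 8640, "100%"), (19, 8640, "<1%")],
    )
    def test_percent_formatting(self, n_above, n, label):
        assert format_percent(n_above, n) == label


class TestSummarizeVector:
    def test_constant_series(self):
        s = summarize_vector(series(np.full(200, 0.2)))
        assert s.mean_tr == pytest.approx(0.2)
        assert s.sd_tr == 0.0
        assert s.n_above_threshold == 0

    def test_two_value_arithmetic(self):
        s = summarize_vector(series([0.1, 0.3]))
        assert s.mean_tr == pytest.approx(0.2)
        assert s.sd_tr == pytest.approx(0.1414, abs=1e-4)  # sample SD, n-1

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            summarize_vector(series([np.nan, np.nan]))

    def test_nan_segments_excluded(self):
        s = summarize_vector(series([0.1, np.nan, 0.3]))
        assert s.n_segments == 2
        assert s.mean_tr == pytest.approx(0.2)


def summary(channel, prop, sd, n=8640):
    n_above = int(round(prop * n))
    return VectorSummary(
        channel=channel,
        mean_tr=0.1,
        sd_tr=sd,
        n_segments=n,
        n_above_threshold=n_above,
        prop_above_threshold=prop,
        percent_label=format_percent(n_above, n),
    )


class TestSelectVector:
    def test_stable_vector_recommended(self):
        report = select_vector(
            [
                summary("primary", 0.12, 0.08),
                summary("alternate", 0.09, 0.07),
                summary("secondary", 0.0, 0.02),
            ]
        )
        assert report.recommended == "secondary"
        assert report.eligible == {"primary": False, "alternate": False, "secondary": True}

    def test_single_eligible_vector(self):
        report = select_vector([summary("alternate", 0.0, 0.05)])
        assert report.recommended == "alternate"

    def test_lead_order_tie_break(self):
        report = select_vector(
            [summary("alternate", 0.0, 0.05), summary("primary", 0.0, 0.05)]
        )
        assert report.recommended == "primary"
        assert report.ranking == ["primary", "alternate"]

    def test_none_eligible_gives_null_with_ranking(self):
        report = select_vector(
            [summary("primary", 0.5, 0.1), summary("alternate", 0.2, 0.1)]
        )
        assert report.recommended is None
        assert report.ranking == ["alternate", "primary"]
        assert report.note

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            select_vector([])

    def test_json_roundtrip(self):
        import json

        report = select_vector([summary("primary", 0.0, 0.01)])
        payload = json.loads(report.to_json())
        assert payload["recommended"] == "primary"
        assert payload["vectors"]["primary"]["n_segments"] == 8640
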
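"""Flap/glide classification, stream merging, and the condition summaries."""

import numpy as np
import pandas as pd
import pytest

from ibisflight import ecg as ecg_mod
from ibisflight import segmentation, synthetic, vedba
from ibisflight.ecg import BeatSeries
from ibisflight.session import SessionMeta
from ibisflight.vedba import VeDBASeries


def _hr_series(duration=10.0, value=400.0):
    r = np.arange(0, duration + 0.001, 60.0 / value)
    return ecg_mod.resample_hr(BeatSeries.from_r_times(r))


class TestClassify:
    def test_constant_zero_is_one_glide_segment(self):
        out = segmentation.classify_flap_glide(np.zeros(1600), 1600.0)
        assert set(out.states) == {"glide"}
        assert len(out.segments) == 1
        assert out.segments[0][0] == "glide"

    def test_800mg_sinusoid_is_all_flap(self):
        # |800 sin| dips under 300 mg only ~0.025 s per crossing: every
        # sub-threshold dwell is shorter than one wingbeat, so no glide.
        fs = 1600.0
        t = np.arange(int(4 * fs)) / fs
        hv = 800.0 * np.sin(2 * np.pi * 5.0 * t)
        out = segmentation.classify_flap_glide(hv, fs)
        assert set(out.states) == {"flap"}

    def test_square_wave_flips_at_block_boundaries(self):
        fs = 1000.0
        block = int(2 * fs)
        hv = np.concatenate([np.full(block, 800.0), np.full(block, 50.0),
                             np.full(block, 800.0)])
        out = segmentation.classify_flap_glide(hv, fs)
        assert set(out.states[:block]) == {"flap"}
        assert set(out.states[block:2 * block]) == {"glide"}
        assert set(out.states[2 * block:]) == {"flap"}

    def test_short_dips_relabelled_flap(self):
        fs = 1000.0
        hv = np.full(int(fs), 800.0)
        hv[300:400] = 0.0                      # 0.1 s < one wingbeat
        out = segmentation.classify_flap_glide(hv, fs)
        assert set(out.states) == {"flap"}

    def test_segments_tile_the_record(self, flap_glide_session):
        _, gen = flap_glide_session
        hv = vedba.dynamic_heave(gen.trace) * 1000.0
        out = segmentation.classify_flap_glide(hv, gen.trace.sampling_rate)
        total = sum(e - s for _, s, e in out.segments)
        assert total == pytest.approx(gen.trace.duration, abs=1e-9)
        for (_, _, e0), (_, s1, _) in zip(out.segments, out.segments[1:]):
            assert e0 == pytest.approx(s1, abs=1e-12)

    def test_threshold_and_min_glide_monotonicity(self, flap_glide_session):
        _, gen = flap_glide_session
        hv = vedba.dynamic_heave(gen.trace) * 1000.0
        fs = gen.trace.sampling_rate
        props_thr = [np.mean(segmentation.classify_flap_glide(hv, fs,
                             threshold=thr).states == "glide")
                     for thr in (100.0, 300.0, 600.0, 900.0)]
        assert all(a <= b + 1e-12 for a, b in zip(props_thr, props_thr[1:]))
        props_mg = [np.mean(segmentation.classify_flap_glide(hv, fs,
                            min_glide=mg).states == "glide")
                    for mg in (0.0, 0.2, 1.0, 5.0)]
        assert all(a >= b - 1e-12 for a, b in zip(props_mg, props_mg[1:]))

    def test_ground_truth_recovery_exceeds_99_percent(self, flap_glide_session):
        _, gen = flap_glide_session
        hv = vedba.dynamic_heave(gen.trace) * 1000.0
        out = segmentation.classify_flap_glide(hv, gen.trace.sampling_rate)
        assert np.mean(out.states == gen.states) > 0.99

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            segmentation.classify_flap_glide(np.array([]), 1600.0)


class TestMerge:
    def _states(self, duration=10.0, flip_at=None, fs=100.0):
        hv = np.full(int(duration * fs), 800.0)
        if flip_at is not None:
            hv[int(flip_at * fs):] = 0.0
        return segmentation.classify_flap_glide(hv, fs)

    def test_full_coverage_no_missing(self):
        hr = _hr_series(11.0)
        v = VeDBASeries(times=np.arange(1.0, 11.0), vedba=np.full(10, 500.0))
        merged = segmentation.merge_streams(hr, v, self._states(11.0))
        assert len(merged) == 10
        assert not merged["hr_missing"].any()

    def test_hr_gap_rows_flagged(self):
        r = np.concatenate([np.arange(0, 4.0, 0.15), np.arange(7.0, 10.0, 0.15)])
        hr = ecg_mod.resample_hr(BeatSeries.from_r_times(r), max_gap=2.0)
        v = VeDBASeries(times=np.arange(1.0, 10.0), vedba=np.full(9, 500.0))
        merged = segmentation.merge_streams(hr, v, self._states(10.0))
        gap_rows = merged[(merged["time_s"] >= 6.0) & (merged["time_s"] < 7.0)]
        assert gap_rows["hr_missing"].all()
        assert not merged[merged["time_s"] <= 3.0]["hr_missing"].any()

    def test_state_at_the_instant(self):
        hr = _hr_series(10.0)
        v = VeDBASeries(times=np.arange(10.0), vedba=np.full(10, 500.0))
        merged = segmentation.merge_streams(hr, v, self._states(10.0, flip_at=5.5))
        assert merged.loc[merged["time_s"] == 5.0, "state"].item() == "flap"
        assert merged.loc[merged["time_s"] == 6.0, "state"].item() == "glide"

    def test_disjoint_ranges_rejected(self):
        hr = _hr_series(5.0)
        v = VeDBASeries(times=np.arange(100.0, 110.0), vedba=np.full(10, 1.0))
        with pytest.raises(ValueError, match="overlap"):
            segmentation.merge_streams(hr, v, self._states(10.0))


def _toy_session(state="glide", n=10, hr=400.0, ved=500.0, **meta):
    m = {"bird": "310", "date": "2020-08-01", "flight_number": 1,
         "logger_shape": "cube", "wind_angle": "+2"}
    m.update(meta)
    return pd.DataFrame({
        "time_s": np.arange(n, dtype=float), "hr_bpm": hr, "hr_missing": False,
        "vedba_mg": ved, "state": state, **m})


class TestProportionAndSummaries:
    def test_gliding_proportion_pure_and_alternating(self):
        assert segmentation.gliding_proportion(_toy_session("glide")) == 1.0
        df = _toy_session(n=10)
        df.loc[::2, "state"] = "flap"
        assert segmentation.gliding_proportion(df) == 0.5

    def test_generated_75_percent_recovered(self, flap_glide_session):
        plan, gen = flap_glide_session
        hv = vedba.dynamic_heave(gen.trace) * 1000.0
        states = segmentation.classify_flap_glide(hv, gen.trace.sampling_rate)
        v = vedba.vedba_1hz(gen.trace)
        hr = _hr_series(plan.duration)
        merged = segmentation.merge_streams(hr, v, states)
        assert segmentation.gliding_proportion(merged) == pytest.approx(0.75, abs=0.05)

    def test_condition_summary_means_and_pooling(self):
        s1 = _toy_session(n=10, hr=400.0, ved=500.0)
        s2 = _toy_session(n=30, hr=500.0, ved=700.0, flight_number=2)
        out = segmentation.condition_summary([s1, s2])
        assert len(out) == 1
        row = out.iloc[0]
        assert row["recorded_seconds"] == 40
        assert row["mean_hr_bpm"] == pytest.approx((10 * 400 + 30 * 500) / 40)
        assert row["mean_vedba_mg"] == pytest.approx((10 * 500 + 30 * 700) / 40)
        assert row["n_flights_310"] == 2

    def test_condition_ordering_recovered(self):
        conditions = [("cube", "+2"), ("drop", "+2"), ("cube", "+6"), ("drop", "+6")]
        sessions = []
        for i, (shape, angle) in enumerate(conditions):
            hr = 460.0 - 40.0 * i
            sessions.append(_toy_session(n=50, hr=hr, logger_shape=shape,
                                         wind_angle=angle))
        out = segmentation.condition_summary(sessions)
        means = {(r["logger_shape"], r["wind_angle"]): r["mean_hr_bpm"]
                 for _, r in out.iterrows()}
        assert means[("cube", "+2")] > means[("drop", "+2")] \
            > means[("cube", "+6")] > means[("drop", "+6")]

    def test_unknown_condition_rejected(self):
        bad = _toy_session(logger_shape="sphere")
        with pytest.raises(ValueError, match="unknown condition"):
            segmentation.condition_summary([bad])

    def test_flap_glide_summary_group_means(self, rng):
        flap = _toy_session("flap", n=400)
        glide = _toy_session("glide", n=400, flight_number=2)
        flap["vedba_mg"] = rng.normal(850, 100, 400)
        glide["vedba_mg"] = rng.normal(240, 50, 400)
        out = segmentation.flap_glide_summary([flap, glide]).set_index("state")
        se_f = 100 / np.sqrt(400)
        se_g = 50 / np.sqrt(400)
        assert abs(out.loc["flap", "mean_vedba_mg"] - 850) < 3 * se_f
        assert abs(out.loc["glide", "mean_vedba_mg"] - 240) < 3 * se_g

    def test_absent_state_reported_missing(self):
        out = segmentation.flap_glide_summary([_toy_session("glide")])
        out = out.set_index("state")
        assert np.isnan(out.loc["flap", "mean_hr_bpm"])
        assert out.loc["flap", "n_seconds"] == 0

    def test_label_swap_swaps_group_means(self):
        a = _toy_session("flap", n=10, ved=900.0)
        b = _toy_session("glide", n=10, ved=100.0, flight_number=2)
        fwd = segmentation.flap_glide_summary([a, b]).set_index("state")
        a2, b2 = a.copy(), b.copy()
        a2["state"], b2["state"] = "glide", "flap"
        rev = segmentation.flap_glide_summary([a2, b2]).set_index("state")
        assert fwd.loc["flap", "mean_vedba_mg"] == rev.loc["glide", "mean_vedba_mg"]
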
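import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluorodose.acquisition import (
    RenderError,
    ScreenLayout,
    UltrasonicReading,
    IncompletePositionError,
    UnreadableFrameError,
    digit_templates,
    distance_to_tof,
    recognize_frame,
    render_screen_frame,
    sound_speed,
    stream_conditions,
    sweep_validation,
    table_position,
    tof_to_distance,
)
from fluorodose.conditions import FluoroConditions


def representable(kvp=76, ma=2.5, fov=20, sid=100, lat=0, cc=0, fps=15, t=0.0,
                  beam=True):
    return FluoroConditions(kvp=float(kvp), ma=float(ma), fov_cm=float(fov),
                            sid_cm=float(sid), lateral_deg=float(lat),
                            caudcran_deg=float(cc), fps=float(fps),
                            irradiation_time_s=float(t), beam_on=beam)


conditions_strategy = st.builds(
    representable,
    kvp=st.integers(40, 150),
    ma=st.integers(1, 999).map(lambda v: v / 10),
    fov=st.integers(5, 48),
    sid=st.integers(80, 120),
    lat=st.integers(-90, 90),
    cc=st.integers(-30, 30),
    fps=st.integers(1, 30),
    t=st.integers(0, 9999).map(lambda v: v / 10),
    beam=st.booleans(),
)


class TestRoundTrip:
    @settings(max_examples=60, deadline=None)
    @given(cond=conditions_strategy)
    def test_recognize_inverts_render_at_zero_noise(self, cond):
        rec = recognize_frame(render_screen_frame(cond))
        for name in ("kvp", "ma", "fov_cm", "sid_cm", "lateral_deg",
                     "caudcran_deg", "fps", "irradiation_time_s", "beam_on"):
            assert getattr(rec, name) == getattr(cond, name), name

    def test_500_randomized_frames_all_fields_correct(self):
        rng = np.random.default_rng(0)
        layout = ScreenLayout()
        templates = digit_templates()
        errors = 0
        for _ in range(500):
            cond = representable(
                kvp=rng.integers(40, 151), ma=rng.integers(1, 1000) / 10,
                fov=rng.integers(5, 49), sid=rng.integers(80, 121),
                lat=rng.integers(-90, 91), cc=rng.integers(-30, 31),
                fps=rng.integers(1, 31), t=rng.integers(0, 10000) / 10,
                beam=bool(rng.integers(0, 2)))
            rec = recognize_frame(render_screen_frame(cond, layout), layout, templates)
            if rec != cond.but(timestamp_s=rec.timestamp_s):
                errors += 1
        assert errors == 0

    def test_render_deterministic(self):
        c = representable()
        a = render_screen_frame(c, noise_level=0.1, seed=5)
        b = render_screen_frame(c, noise_level=0.1, seed=5)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, render_screen_frame(c, noise_level=0.1, seed=6))

    def test_leading_blank_padding_round_trips(self):
        cond = representable(fov=7)   # 1 digit in a 2-slot field
        assert recognize_frame(render_screen_frame(cond)).fov_cm == 7.0

    def test_unrepresentable_value_raises(self):
        layout = ScreenLayout()
        with pytest.raises(RenderError):
            layout.fields["fov_cm"].format_value(123.0)   # 3 digits, 2 slots


class TestRecognizeErrors:
    def test_all_black_frame_unreadable(self):
        with pytest.raises(UnreadableFrameError):
            recognize_frame(np.zeros(ScreenLayout().frame_shape))

    def test_occluded_roi_names_field(self):
        layout = ScreenLayout()
        img = render_screen_frame(representable(), layout)
        roi = layout.fields["sid_cm"]
        img[roi.y:roi.y + roi.height, roi.x:roi.x + roi.width] = 0.5
        with pytest.raises(UnreadableFrameError) as exc:
            recognize_frame(img, layout)
        assert exc.value.field_name == "sid_cm"

    def test_wrong_frame_shape_rejected(self):
        with pytest.raises(ValueError):
            recognize_frame(np.zeros((10, 10)))


class TestNoiseDegradation:
    def test_accuracy_monotone_in_noise(self):
        layout = ScreenLayout()
        templates = digit_templates()
        rng = np.random.default_rng(3)
        rates = []
        for noise in (0.0, 0.2, 0.6):
            ok = 0
            n = 150
            for k in range(n):
                cond = representable(kvp=rng.integers(40, 151),
                                     ma=rng.integers(1, 1000) / 10,
                                     lat=rng.integers(-90, 91))
                img = render_screen_frame(cond, layout, noise_level=noise, seed=k)
                try:
                    rec = recognize_frame(img, layout, templates)
                    ok += rec == cond.but(timestamp_s=rec.timestamp_s)
                except UnreadableFrameError:
                    pass
            rates.append(ok / n)
        assert rates[0] == 1.0
        assert rates[0] >= rates[1] >= rates[2]


class TestStream:
    def _frames(self, conds, period=0.2):
        return [(round(i * period, 10), render_screen_frame(c))
                for i, c in enumerate(conds)]

    def test_cadence_10s_gives_50_records(self):
        conds = [representable(t=round(0.2 * i, 1)) for i in range(50)]
        recs = list(stream_conditions(self._frames(conds)))
        assert len(recs) == 50
        assert not any(r.get("stale") for r in recs)

    def test_condition_change_latency_bound(self):
        conds = ([representable(kvp=76)] * 10 + [representable(kvp=90)] * 10)
        recs = list(stream_conditions(self._frames(conds)))
        t_first = next(r["timestamp_s"] for r in recs if r["kvp"] == 90.0)
        assert 2.0 <= t_first <= 2.2

    def test_stale_flag_only_on_unreadable_frames(self):
        conds = [representable()] * 5
        frames = self._frames(conds)
        frames[2] = (frames[2][0], np.zeros(ScreenLayout().frame_shape))
        recs = list(stream_conditions(frames))
        assert [r.get("stale") for r in recs] == [False, False, True, False, False]
        assert recs[2]["kvp"] == 76.0   # carried over from last good record

    def test_gap_marker_before_first_good_record(self):
        frames = [(0.0, np.zeros(ScreenLayout().frame_shape)),
                  (0.2, render_screen_frame(representable()))]
        recs = list(stream_conditions(frames))
        assert recs[0].get("gap") is True
        assert recs[1]["kvp"] == 76.0

    def test_ultrasonic_merge_nearest_timestamp(self):
        conds = [representable()] * 3
        us = [(0.0, (0.0, 0.0, 0.0)), (0.39, (20.0, 0.0, -10.0))]
        recs = list(stream_conditions(self._frames(conds), ultrasonic=us))
        assert recs[0]["table_offset_mm"] == [0.0, 0.0, 0.0]
        assert recs[2]["table_offset_mm"] == [20.0, 0.0, -10.0]


class TestUltrasonics:
    def test_sound_speed_model(self):
        assert sound_speed(0.0) == pytest.approx(331.3)
        assert sound_speed(20.0) == pytest.approx(343.42)
        # dv/dT = 0.606 exactly
        assert sound_speed(30.0) - sound_speed(29.0) == pytest.approx(0.606, rel=1e-12)

    def test_tof_to_distance_closed_form(self):
        r = UltrasonicReading(tof_s=(1.165e-3,) * 3, temperature_c=20.0)
        d = tof_to_distance(r)
        assert d[0] == pytest.approx(343.42 * 1.165e-3 / 2 * 100, rel=1e-12)
        assert d[0] == pytest.approx(20.0, abs=0.01)
        half = tof_to_distance(UltrasonicReading(tof_s=(1.165e-3 / 2,) * 3,
                                                 temperature_c=20.0))
        assert half[0] == pytest.approx(d[0] / 2, rel=1e-12)

    def test_temperature_changes_distance_by_speed_ratio(self):
        tof = 2.0e-3
        d0 = tof_to_distance(UltrasonicReading(tof_s=(tof,) * 3, temperature_c=0.0))
        d20 = tof_to_distance(UltrasonicReading(tof_s=(tof,) * 3, temperature_c=20.0))
        assert d20[0] / d0[0] == pytest.approx(343.42 / 331.3, rel=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(d=st.floats(1.0, 400.0), t=st.floats(-10.0, 50.0))
    def test_tof_distance_bijection(self, d, t):
        tof = distance_to_tof(d, t)
        back = tof_to_distance(UltrasonicReading(tof_s=(float(tof),) * 3,
                                                 temperature_c=t))
        assert back[0] == pytest.approx(d, abs=1e-12 * max(1.0, d))

    def test_reading_validation(self):
        with pytest.raises(ValueError):
            UltrasonicReading(tof_s=(0.0, 1e-3, 1e-3), temperature_c=20.0)
        with pytest.raises(ValueError):
            UltrasonicReading(tof_s=(1e-3,) * 3, temperature_c=60.0)
        with pytest.raises(ValueError):
            sound_speed(99.0)


class TestTablePosition:
    def test_zero_offset_at_calibration(self):
        ref = (30.0, 25.0, 40.0)
        reading = UltrasonicReading(tof_s=tuple(float(x) for x in
                                                distance_to_tof(ref, 23.0)),
                                    temperature_c=23.0)
        assert np.allclose(table_position(reading, ref), 0.0, atol=1e-10)

    def test_noiseless_sweep_exact_at_all_points(self):
        res = sweep_validation(span_cm=10.0, step_cm=2.0)
        assert res["offsets_cm"].size == 11
        assert np.abs(res["per_axis_error_mm"]).max() < 1e-9

    def test_missing_axis_raises(self):
        reading = UltrasonicReading(tof_s=(1e-3, None, 1e-3), temperature_c=20.0)
        with pytest.raises(IncompletePositionError):
            table_position(reading, (30.0, 30.0, 30.0))
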
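"""Frame schedules, SUV conversion, late-window summaries and TAC file I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petkin import (
    FrameSchedule,
    ScheduleError,
    SubjectMeta,
    TacParseError,
    TimeActivityCurve,
    UnitError,
    from_suv,
    late_window_summary,
    make_frame_schedule,
    read_tac_table,
    to_suv,
    write_tac_table,
)


@pytest.mark.parametrize(
    "spec, n_frames, end_min",
    [
        ([(10, 60), (17, 600)], 27, 180.0),
        ([(12, 10), (18, 60), (8, 300)], 38, 60.0),
        ([(1, 60)], 1, 1.0),
    ],
)
def test_make_frame_schedule_standard_protocols(spec, n_frames, end_min):
    sched = make_frame_schedule(spec)
    assert sched.n_frames == n_frames
    assert sched.starts[0] == 0.0
    assert sched.total_duration == pytest.approx(end_min, abs=1e-12)
    assert np.all(np.diff(sched.midpoints) > 0)
    # contiguity
    assert np.allclose(sched.starts[1:], sched.ends[:-1])


@pytest.mark.parametrize("bad", [[], [(0, 60)], [(5, -1)], [(3, 0)]])
def test_make_frame_schedule_rejects_invalid_specs(bad):
    with pytest.raises(ScheduleError):
        make_frame_schedule(bad)


def test_frame_schedule_rejects_overlap_and_inversion():
    with pytest.raises(ScheduleError):
        FrameSchedule(starts=[0.0, 0.5], ends=[1.0, 1.5])
    with pytest.raises(ScheduleError):
        FrameSchedule(starts=[0.0], ends=[0.0])


class TestSuvConversion:
    def test_uniform_concentration_gives_unit_suv(self):
        sched = make_frame_schedule([(4, 60)])
        meta = SubjectMeta(injected_dose_mbq=7.4, body_weight_g=25.0)
        conc = 7.4 * 1000 / 25.0
        tac = TimeActivityCurve(schedule=sched, values=np.full(4, conc), unit="kBq/cc")
        suv = to_suv(tac, meta)
        assert suv.unit == "SUV"
        assert np.allclose(suv.values, 1.0)

    def test_zero_and_linearity(self):
        sched = make_frame_schedule([(4, 60)])
        meta = SubjectMeta(injected_dose_mbq=5.0, body_weight_g=20.0)
        zero = to_suv(TimeActivityCurve(schedule=sched, values=np.zeros(4)), meta)
        assert np.all(zero.values == 0)
        conc = 2 * 5.0 * 1000 / 20.0
        double = to_suv(
            TimeActivityCurve(schedule=sched, values=np.full(4, conc)), meta
        )
        assert np.allclose(double.values, 2.0)

    def test_already_suv_raises(self):
        sched = make_frame_schedule([(4, 60)])
        tac = TimeActivityCurve(schedule=sched, values=np.ones(4), unit="SUV")
        with pytest.raises(UnitError):
            to_suv(tac, SubjectMeta(injected_dose_mbq=1, body_weight_g=1))

    @given(
        dose=st.floats(0.5, 50), weight=st.floats(10, 50),
        scale=st.floats(0.01, 100),
    )
    @settings(max_examples=50, deadline=None)
    def test_round_trip_is_machine_exact(self, dose, weight, scale):
        sched = make_frame_schedule([(5, 60)])
        meta = SubjectMeta(injected_dose_mbq=dose, body_weight_g=weight)
        values = scale * np.array([0.1, 1.0, 2.5, 0.7, 0.01])
        tac = TimeActivityCurve(schedule=sched, values=values)
        back = from_suv(to_suv(tac, meta), meta)
        assert np.allclose(back.values, values, rtol=1e-14, atol=0)


class TestLateWindowSummary:
    def test_monotone_decreasing_peak_is_first_frame(self):
        sched = make_frame_schedule([(6, 60)])
        tac = TimeActivityCurve(schedule=sched, values=np.linspace(3, 1, 6), unit="SUV")
        peak, _ = late_window_summary(tac, 2.0)
        assert peak == 3.0

    def test_final_30min_of_standard_long_schedule_is_three_frames(self):
        sched = make_frame_schedule([(10, 60), (17, 600)])
        values = np.zeros(27)
        values[-3:] = [1.0, 2.0, 3.0]
        tac = TimeActivityCurve(schedule=sched, values=values, unit="SUV")
        peak, late = late_window_summary(tac, 30.0)
        assert late == pytest.approx(2.0)
        assert peak == 3.0

    def test_constant_curve(self):
        sched = make_frame_schedule([(5, 300)])
        tac = TimeActivityCurve(schedule=sched, values=np.full(5, 0.7), unit="SUV")
        assert late_window_summary(tac, 10.0) == (pytest.approx(0.7), pytest.approx(0.7))

    def test_window_errors(self):
        sched = make_frame_schedule([(5, 300)])
        tac = TimeActivityCurve(schedule=sched, values=np.ones(5), unit="SUV")
        with pytest.raises(ValueError):
            late_window_summary(tac, 30.0)  # window >= scan


class TestTacTableIO:
    def test_round_trip_identity(self, tmp_path, blood_2fa):
        path = tmp_path / "lv.csv"
        write_tac_table(blood_2fa, path)
        back = read_tac_table(path)
        assert back == blood_2fa  # schedule, values, unit and labels, bit-exact

    def test_inverted_frame_cites_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        lines = ["frame_start_min,frame_end_min,value"]
        starts = [0.0, 1.0, 2.0, 3.0, 4.0]
        for i, s in enumerate(starts):
            end = s + 1.0 if i != 3 else s - 0.5
            lines.append(f"{s},{end},1.0")
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(TacParseError) as err:
            read_tac_table(path)
        assert err.value.row == 3

    def test_missing_column_and_nan_rejected(self, tmp_path):
        p1 = tmp_path / "m.csv"
        p1.write_text("frame_start_min,value\n0.0,1.0\n")
        with pytest.raises(TacParseError):
            read_tac_table(p1)
        p2 = tmp_path / "n.csv"
        p2.write_text("frame_start_min,frame_end_min,value\n0.0,1.0,nan\n")
        with pytest.raises(TacParseError):
            read_tac_table(p2)

    def test_extra_columns_ignored_with_warning(self, tmp_path, caplog):
        path = tmp_path / "extra.csv"
        path.write_text(
            "# unit: SUV\n"
            "frame_start_min,frame_end_min,value,voxels\n"
            "0.0,1.0,0.5,12\n1.0,2.0,0.4,12\n"
        )
        with caplog.at_level("WARNING"):
            tac = read_tac_table(path)
        assert tac.values.tolist() == [0.5, 0.4]
        assert any("voxels" in rec.message for rec in caplog.records)

    def test_tab_autodetect(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text(
            "frame_start_min\tframe_end_min\tvalue\n0.0\t1.0\t2.5\n1.0\t2.0\t1.5\n"
        )
        tac = read_tac_table(path)
        assert tac.values.tolist() == [2.5, 1.5]
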
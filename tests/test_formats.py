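"""Command grammar, file dialects and their round-trip identities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from zfplate import formats
from zfplate.formats import (
    CentroidTrace,
    EventCommand,
    FormatError,
    MotionTrace,
    ParseError,
    Roi,
    RoiSet,
    Section,
    SectionsSpec,
    parse_event_string,
)


class TestParseEventString:
    @pytest.mark.parametrize("s,field,value", [
        ("a0.01", "amplitude_a", 0.01),
        ("a0.0005", "amplitude_a", 0.0005),
        ("b250", "light_b", 250),
        ("f625", "frequency_f", 625.0),
        ("d20", "duration_d", 20.0),
    ])
    def test_single_fields(self, s, field, value):
        assert getattr(parse_event_string(s), field) == value

    def test_defaults_when_absent(self):
        cmd = parse_event_string("a0.01")
        assert cmd.light_b is None          # light unchanged
        assert cmd.duration_d == 0.0
        assert cmd.delays_D == ()
        assert cmd.command_id is None

    def test_full_command(self):
        cmd = parse_event_string("2a0.3f1000d20D100D280b250")
        assert cmd.command_id == 2
        assert cmd.amplitude_a == 0.3
        assert cmd.frequency_f == 1000.0
        assert cmd.delays_D == (100.0, 280.0)
        assert cmd.light_b == 250

    def test_zero_amplitude_command_is_stimulus_free(self):
        cmd = parse_event_string("a0f625d0")
        assert cmd.amplitude_a == 0.0
        assert cmd.is_stimulus_free
        assert not parse_event_string("a0.01").is_stimulus_free
        assert not parse_event_string("b100").is_stimulus_free

    def test_modality(self):
        assert parse_event_string("a0.3f625d20").modality == "acoustic"
        assert parse_event_string("b0").modality == "visual"
        assert parse_event_string("a0f625d0").modality == "none"

    @pytest.mark.parametrize("bad,pos", [
        ("a0.01x5", 5),      # unknown letter
        ("a", 0),            # letter without number
        ("0.5a1", 1),        # stray text after id
        ("a1 b2", 2),        # whitespace inside
    ])
    def test_malformed_token_names_position(self, bad, pos):
        with pytest.raises(ParseError) as exc:
            parse_event_string(bad)
        assert exc.value.position == pos

    def test_negative_value_is_validation_error(self):
        with pytest.raises(FormatError):
            parse_event_string("a-0.5")

    def test_duplicate_field_rejected(self):
        with pytest.raises(ParseError):
            parse_event_string("a0.1a0.2")

    @given(st.text(max_size=12))
    @settings(max_examples=300, deadline=None)
    def test_total_on_grammar_rejects_rest(self, s):
        """Fuzz: every input either parses or raises a FormatError."""
        try:
            cmd = parse_event_string(s)
        except FormatError:
            return
        assert isinstance(cmd, EventCommand)

    @given(
        cid=st.one_of(st.none(), st.integers(0, 9)),
        a=st.one_of(st.none(), st.floats(0.0005, 1.0, allow_nan=False)),
        f=st.one_of(st.none(), st.integers(1, 2000)),
        d=st.one_of(st.none(), st.integers(0, 500)),
        delays=st.lists(st.integers(0, 900), max_size=3),
        b=st.one_of(st.none(), st.integers(0, 255)),
    )
    @settings(max_examples=150, deadline=None)
    def test_roundtrip_on_canonical_strings(self, cid, a, f, d, delays, b):
        parts = []
        if cid is not None:
            parts.append(str(cid))
        if a is not None:
            parts.append(f"a{repr(float(a)) if not float(a).is_integer() else int(a)}")
        if f is not None:
            parts.append(f"f{f}")
        if d is not None:
            parts.append(f"d{d}")
        parts += [f"D{x}" for x in delays]
        if b is not None:
            parts.append(f"b{b}")
        s = "".join(parts)
        if not s or s == str(cid):
            return
        assert parse_event_string(s).to_string() == s


class TestEventsFile:
    def test_empty_file(self, tmp_path):
        p = tmp_path / "events.csv"
        p.write_text("time_s,command_string\n")
        assert formats.read_events_file(p) == []

    def test_twelve_intensity_battery(self, tmp_path):
        amps = [0.0005, 0.001, 0.003, 0.0075, 0.01, 0.03,
                0.06, 0.075, 0.1, 0.3, 0.5, 1]
        p = tmp_path / "events.csv"
        lines = ["time_s,command_string"]
        lines += [f"{120 * i},a{a}f625d20" for i, a in enumerate(amps)]
        p.write_text("\n".join(lines) + "\n")
        events = formats.read_events_file(p)
        assert len({e.amplitude_a for e in events}) == 12

    def test_interleaved_modalities_order_preserved(self, tmp_path):
        p = tmp_path / "events.csv"
        p.write_text(
            "time_s,command_string\n10,b0\n20,a0.3f625d20\n30,b250\n"
        )
        events = formats.read_events_file(p)
        assert [e.modality for e in events] == ["visual", "acoustic", "visual"]
        assert [e.scheduled_time for e in events] == [10, 20, 30]

    def test_unsorted_input_sorted_with_warning(self, tmp_path):
        p = tmp_path / "events.csv"
        p.write_text("time_s,command_string\n30,a0.1\n10,a0.3\n")
        with pytest.warns(UserWarning, match="not sorted"):
            events = formats.read_events_file(p)
        assert [e.scheduled_time for e in events] == [10, 30]

    def test_roundtrip(self, tmp_path):
        events = [parse_event_string("a0.1f625d20", 5.0),
                  parse_event_string("b0", 10.0)]
        p = tmp_path / "events.csv"
        formats.write_events_file(p, events)
        back = formats.read_events_file(p)
        assert [(e.scheduled_time, e.raw) for e in back] == \
            [(e.scheduled_time, e.raw) for e in events]


class TestRois:
    def test_grid_ordering_row_major(self):
        rois = RoiSet.grid(rows=8, cols=12, well_width=10, well_height=10)
        assert rois.well_ids[:3] == ["A1", "A2", "A3"]
        assert rois.well_ids[-1] == "H12"
        assert len(rois) == 96

    def test_overlap_rejected(self):
        with pytest.raises(FormatError, match="overlap"):
            RoiSet([Roi("A1", 0, 0, 10, 10), Roi("A2", 5, 5, 10, 10)])

    def test_out_of_frame_rejected(self):
        rois = RoiSet([Roi("A1", 0, 0, 10, 10)])
        with pytest.raises(FormatError, match="exceeds frame"):
            rois.validate_against_frame((8, 8))

    def test_roundtrip(self, tmp_path):
        rois = RoiSet.grid(rows=2, cols=3, well_width=20, well_height=15)
        p = tmp_path / "rois.csv"
        formats.write_rois(p, rois)
        back = formats.read_rois(p)
        assert back.plate_format == rois.plate_format
        assert back.rois == rois.rois


class TestTraces:
    def test_motion_roundtrip_identity(self, tmp_path):
        t = MotionTrace(np.arange(10), fps=30.0, t0=2.5)
        p = tmp_path / "m.csv"
        formats.write_motion_trace(p, t)
        back = formats.read_motion_trace(p)
        assert back.fps == 30.0 and back.t0 == 2.5
        np.testing.assert_array_equal(back.values, t.values)

    def test_centroid_roundtrip_preserves_nan(self, tmp_path):
        pts = np.array([[1.5, 2.5], [np.nan, np.nan], [3.0, 4.0]])
        t = CentroidTrace(pts, fps=285.0)
        p = tmp_path / "c.csv"
        formats.write_centroid_trace(p, t)
        back = formats.read_centroid_trace(p)
        np.testing.assert_array_equal(back.points, pts)

    def test_negative_motion_rejected_with_line(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("# fps: 30\n# t0: 0\nframe,delta_pixels\n0,5\n1,-2\n")
        with pytest.raises(FormatError, match=":5"):
            formats.read_motion_trace(p)

    def test_nonpositive_fps_rejected(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("# fps: 0\nframe,delta_pixels\n0,5\n")
        with pytest.raises(FormatError, match="fps"):
            formats.read_motion_trace(p)

    def test_nan_motion_rejected(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("# fps: 30\nframe,delta_pixels\n0,nan\n")
        with pytest.raises(FormatError, match="NaN"):
            formats.read_motion_trace(p)

    @given(
        n=st.integers(1, 40),
        fps=st.sampled_from([30.0, 285.0]),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=100, deadline=None)
    def test_roundtrip_property(self, tmp_path_factory, n, fps, seed):
        """Write-read identity on randomly generated valid trace files."""
        rng = np.random.default_rng(seed)
        d = tmp_path_factory.mktemp("traces")
        m = MotionTrace(rng.integers(0, 100, n), fps=fps,
                        t0=float(rng.uniform(0, 10)))
        formats.write_motion_trace(d / "m.csv", m)
        back = formats.read_motion_trace(d / "m.csv")
        np.testing.assert_array_equal(back.values, m.values)
        assert back.fps == m.fps and back.t0 == m.t0
        pts = rng.uniform(0, 50, (n, 2))
        pts[rng.random(n) < 0.2] = np.nan
        c = CentroidTrace(pts, fps=fps)
        formats.write_centroid_trace(d / "c.csv", c)
        back_c = formats.read_centroid_trace(d / "c.csv")
        np.testing.assert_array_equal(back_c.points, c.points)

    def test_slice_time(self):
        t = MotionTrace(np.arange(300), fps=30.0)
        sub = t.slice_time(2.0, 4.0)
        assert sub.t0 == 2.0
        assert len(sub) == 60
        np.testing.assert_array_equal(sub.values, np.arange(60, 120))


class TestSections:
    def test_overlap_permitted(self):
        spec = SectionsSpec([
            Section("day1", 0, 100, "time"),
            Section("block", 50, 150, "event"),
        ])
        assert len(spec) == 2

    def test_start_after_end_rejected(self):
        with pytest.raises(FormatError, match="precede"):
            Section("bad", 10, 5, "time")

    def test_roundtrip(self, tmp_path):
        spec = SectionsSpec([
            Section("day1", 0, 100, "time"),
            Section("df3", 50, 150, "event", "b0"),
        ])
        p = tmp_path / "sections.csv"
        formats.write_sections(p, spec)
        back = formats.read_sections(p)
        assert back.sections == spec.sections

    def test_event_selector(self):
        sec = Section("df", 0, 100, "event", "b0")
        events = [parse_event_string("b0", 10.0),
                  parse_event_string("a0.3f625d20", 20.0),
                  parse_event_string("b0", 200.0)]
        sel = sec.select_events(events)
        assert len(sel) == 1 and sel[0].scheduled_time == 10.0
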
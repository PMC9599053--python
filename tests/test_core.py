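"""Event log, clocks, CSV round trip, and session summaries."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from pigscreen.core import (
    CSV_COLUMNS,
    EventLog,
    EventRecord,
    LogOrderError,
    ResponseBox,
    ScreenGeometry,
    SessionFileError,
    SimulatedClock,
    TrialResult,
    encode_payload,
    log_event,
    parse_payload,
    read_session_csv,
    summarize_session,
    write_session_csv,
)
from pigscreen.session import write_session_files

from conftest import make_ctx, make_event


class TestClock:
    def test_simulated_advance_is_exact(self):
        clock = SimulatedClock()
        clock.advance(1.25)
        clock.advance(0.75)
        assert clock.now == 2.0

    def test_clock_never_goes_backwards(self):
        clock = SimulatedClock(5.0)
        with pytest.raises(ValueError):
            clock.advance(-1.0)
        with pytest.raises(ValueError):
            clock.advance_to(4.0)


class TestEventLog:
    def test_append_grows_log_by_one(self):
        log = EventLog()
        log_event(log, make_event(0.0, "touch", x=0.5, y=0.5))
        assert len(log) == 1
        assert log[0].event_type == "touch"

    def test_out_of_order_timestamp_rejected(self):
        log = EventLog([make_event(5.0)])
        with pytest.raises(LogOrderError):
            log.append(make_event(4.0))

    def test_ordering_is_per_subject_session(self):
        log = EventLog([make_event(5.0)])
        # a different subject may lag behind
        log.append(make_event(1.0, subject_id="pigB"))
        assert len(log) == 2

    def test_response_registered_requires_coordinates(self):
        with pytest.raises(ValueError, match="x and y"):
            make_event(0.0, "response_registered")

    def test_unknown_event_type_rejected(self):
        with pytest.raises(ValueError, match="event_type"):
            make_event(0.0, "nose_boop")


class TestPayload:
    def test_round_trip(self):
        d = {"choice": "large", "n": "4"}
        assert parse_payload(encode_payload(d)) == d

    def test_reserved_characters_rejected(self):
        with pytest.raises(ValueError):
            encode_payload({"a;b": 1})


class TestCsvIO:
    def test_three_events_make_four_lines(self, tmp_path):
        log = EventLog([make_event(float(i)) for i in range(3)])
        path = write_session_csv(log, tmp_path / "s.csv")
        lines = path.read_text().splitlines()
        assert len(lines) == 4
        assert lines[0] == ",".join(CSV_COLUMNS)

    def test_each_response_is_a_new_line(self, tmp_path):
        n = 17
        log = EventLog(
            [make_event(float(i), "response_registered", x=0.5, y=0.5) for i in range(n)]
        )
        path = write_session_csv(log, tmp_path / "s.csv")
        body = path.read_text().splitlines()[1:]
        assert sum("response_registered" in line for line in body) == n

    def test_round_trip_identity(self, tmp_path):
        log = EventLog(
            [
                make_event(0.0, "trial_start", trial_index=0, payload="trial_type=free_choice"),
                make_event(1.5, "response_registered", trial_index=0, x=0.25, y=0.75,
                           payload="choice=large;side=left"),
                make_event(1.5, "pellet_command", trial_index=0, payload="cue=1"),
            ]
        )
        path = write_session_csv(log, tmp_path / "s.csv")
        assert list(read_session_csv(path)) == list(log)

    def test_truncated_line_names_line_number(self, tmp_path):
        log = EventLog([make_event(0.0), make_event(1.0)])
        path = write_session_csv(log, tmp_path / "s.csv")
        lines = path.read_text().splitlines()
        lines[2] = lines[2].rsplit(",", 3)[0]  # truncate the second event row
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(SessionFileError, match="line 3"):
            read_session_csv(path)

    def test_bad_header_rejected(self, tmp_path):
        path = tmp_path / "s.csv"
        path.write_text("a,b,c\n")
        with pytest.raises(SessionFileError, match="line 1"):
            read_session_csv(path)

    def test_payload_with_commas_and_quotes_round_trips(self, tmp_path):
        log = EventLog([make_event(0.0, payload='free text, with "quotes" and, commas')])
        path = write_session_csv(log, tmp_path / "s.csv")
        assert read_session_csv(path)[0].payload == log[0].payload

    def test_two_subjects_two_files(self, tmp_path):
        log = EventLog([make_event(0.0), make_event(0.0, subject_id="pigB")])
        paths = write_session_files(log, tmp_path)
        assert len(paths) == 2
        assert {p.name for p in paths} == {"pigA_s1.csv", "pigB_s1.csv"}

    def test_rerun_refuses_then_suffixes(self, tmp_path):
        log = EventLog([make_event(0.0)])
        write_session_files(log, tmp_path)
        with pytest.raises(FileExistsError):
            write_session_files(log, tmp_path)
        paths = write_session_files(log, tmp_path, on_exists="suffix")
        assert paths[0].name == "pigA_s1_1.csv"


# Hypothesis: CSV round trip is the identity on any valid log ----------------

_payloads = st.text(
    alphabet=st.characters(blacklist_categories=("Cs",), blacklist_characters="\r"),
    max_size=30,
)
_coords = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


@st.composite
def event_logs(draw):
    n = draw(st.integers(min_value=0, max_value=25))
    t = 0.0
    events = []
    for _ in range(n):
        t += draw(st.floats(min_value=0.0, max_value=100.0, allow_nan=False))
        etype = draw(st.sampled_from(["touch", "tone", "manual_note", "response_registered",
                                      "pellet_command", "trial_start", "omission"]))
        kw = dict(payload=draw(_payloads), trial_index=draw(st.none() | st.integers(0, 500)))
        if etype in ("touch", "response_registered"):
            kw["x"], kw["y"] = draw(_coords), draw(_coords)
        events.append(make_event(t, etype, **kw))
    return EventLog(events)


@given(event_logs())
def test_csv_round_trip_property(tmp_path_factory, log):
    path = tmp_path_factory.mktemp("rt") / "log.csv"
    write_session_csv(log, path)
    assert list(read_session_csv(path)) == list(log)


class TestSummary:
    def test_empty_session_is_zero_filled(self):
        s = summarize_session(EventLog())
        assert s["trials_completed"] == 0
        assert s["omissions"] == 0
        assert s["mean_initiation_latency_s"] is None

    def test_tallies_match_hand_count(self):
        # 12 trials: 2 omitted, 10 completed with a response 2 s after start
        ctx = make_ctx()
        for i in range(12):
            ctx.trial_index = i
            ctx.emit("trial_start", payload="trial_type=free_choice")
            if i < 2:
                ctx.clock.advance(60.0)
                ctx.emit("omission")
            else:
                ctx.clock.advance(2.0)
                ctx.emit("response_registered", x=0.5, y=0.5, payload="choice=large;fulfilled=1")
                ctx.emit("pellet_command", payload="cue=1")
            ctx.clock.advance(15.0)
        s = summarize_session(ctx.log)
        assert s["trials_total"] == 12
        assert s["trials_completed"] == 10
        assert s["omissions"] == 2
        assert s["reinforcers_delivered"] == 10
        assert math.isclose(s["mean_initiation_latency_s"], 2.0)


class TestDomainInvariants:
    def test_omitted_trial_cannot_carry_reinforcers(self):
        with pytest.raises(ValueError):
            TrialResult(trial_index=0, trial_type="free_choice", omitted=True,
                        choice="large", reinforcers_delivered=4)

    def test_boxes_must_fit_the_unit_square(self):
        with pytest.raises(ValueError, match="unit square"):
            ResponseBox("b", 0.8, 0.8, 0.4, 0.4)

    def test_overlapping_active_boxes_rejected_at_construction(self):
        a = ResponseBox("a", 0.1, 0.1, 0.4, 0.4)
        b = ResponseBox("b", 0.3, 0.3, 0.4, 0.4)
        with pytest.raises(ValueError, match="overlap"):
            ScreenGeometry([a, b])

    def test_inactive_overlap_is_allowed(self):
        a = ResponseBox("a", 0.1, 0.1, 0.4, 0.4)
        b = ResponseBox("b", 0.3, 0.3, 0.4, 0.4, active=False)
        ScreenGeometry([a, b])  # does not raise
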
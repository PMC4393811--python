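"""Controller state machine: episodes, refractory, test-tag bypass, log I/O."""

from __future__ import annotations

from datetime import datetime, timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pitstop.controller import (
    ActionEvent,
    ControllerConfig,
    EventKind,
    RecordingActuators,
    detect_episodes,
    parse_controller_log,
    process_stream,
    write_controller_log,
)
from pitstop.tag_protocol import ReadRecord, TagID

from conftest import action_events
from reference_controller import reference_log

TARGET = TagID("00F17A23C5")
OTHER = TagID("00A94D10B7")
TESTTAG = TagID("00DEADBEEF")
START = datetime(2014, 6, 10, 6, 0, 0)


def cfg(**kwargs) -> ControllerConfig:
    base = dict(target_tags={TARGET}, test_tags={TESTTAG})
    base.update(kwargs)
    return ControllerConfig(**base)


def reads_at(seconds, tag=TARGET):
    return [
        ReadRecord(START + timedelta(seconds=int(s)), tag) for s in seconds
    ]


def kinds(events, kind):
    return [e for e in events if e.kind is kind]


class TestEpisodeDetection:
    def test_close_reads_form_one_episode(self):
        (ep,) = detect_episodes(TARGET, [10.0, 10.5, 11.0], 1.0)
        assert (ep.first_read_elapsed_s, ep.last_read_elapsed_s, ep.n_reads) == (
            10.0,
            11.0,
            3,
        )

    def test_gap_beyond_threshold_splits_episodes(self):
        eps = detect_episodes(TARGET, [10.0, 10.5, 15.0], 1.0)
        assert len(eps) == 2
        assert eps[1].first_read_elapsed_s == 15.0

    def test_single_read_is_a_degenerate_episode(self):
        (ep,) = detect_episodes(TARGET, [3.0], 1.0)
        assert ep.first_read_elapsed_s == ep.last_read_elapsed_s == 3.0
        assert ep.n_reads == 1

    def test_gap_exactly_at_threshold_does_not_split(self):
        assert len(detect_episodes(TARGET, [0.0, 1.0, 2.0], 1.0)) == 1

    def test_episodes_partition_the_reads(self):
        rng = np.random.default_rng(5)
        times = np.cumsum(rng.exponential(2.0, size=200)).tolist()
        eps = detect_episodes(TARGET, times, 1.0)
        assert sum(ep.n_reads for ep in eps) == len(times)

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="not sorted"):
            detect_episodes(TARGET, [2.0, 1.0], 1.0)


class TestRefractoryRule:
    def test_refractory_suppresses_the_middle_episode(self):
        # episodes at 0, 60, 130 s with 120 s refractory: 60 falls inside
        events = process_stream(reads_at([0, 60, 130]), cfg(refractory_s=120.0))
        assert [e.elapsed_s for e in kinds(events, EventKind.TARGET_PLAYBACK)] == [
            0.0,
            130.0,
        ]
        assert [
            e.elapsed_s for e in kinds(events, EventKind.SUPPRESSED_REFRACTORY)
        ] == [60.0]

    def test_zero_refractory_fires_every_episode(self):
        k = 7
        events = process_stream(
            reads_at(range(0, 10 * k, 10)), cfg(refractory_s=0.0)
        )
        assert len(kinds(events, EventKind.TARGET_PLAYBACK)) == k

    def test_refractory_is_non_extending(self):
        # suppressed episode at 60 must NOT push the dead time past 120
        events = process_stream(
            reads_at([0, 60, 125]), cfg(refractory_s=120.0)
        )
        assert [e.elapsed_s for e in kinds(events, EventKind.TARGET_PLAYBACK)] == [
            0.0,
            125.0,
        ]

    def test_test_tag_bypasses_active_refractory(self):
        reads = sorted(
            reads_at([0, 60]) + reads_at([30], tag=TESTTAG),
            key=lambda r: r.timestamp,
        )
        events = process_stream(reads, cfg(refractory_s=120.0))
        assert len(kinds(events, EventKind.TEST_PLAYBACK)) == 1
        # and the test playback neither starts nor resets the refractory
        assert len(kinds(events, EventKind.SUPPRESSED_REFRACTORY)) == 1  # the 60 s one

    def test_test_tag_does_not_trigger_still_capture(self):
        events = process_stream(
            reads_at([5], tag=TESTTAG), cfg(capture_still=True)
        )
        assert kinds(events, EventKind.STILL_CAPTURE) == []


class TestStreamRules:
    def test_continuous_reads_log_one_marker_on_second_read(self):
        events = process_stream(
            reads_at([10, 10, 11, 11, 12]), cfg(), startup_time=START
        )
        assert len(kinds(events, EventKind.TARGET_PLAYBACK)) == 1
        markers = kinds(events, EventKind.SUPPRESSED_CONTINUOUS)
        assert [m.elapsed_s for m in markers] == [10.0]

    def test_unknown_tags_are_ignored(self):
        events = process_stream(reads_at([0, 5, 10], tag=OTHER), cfg())
        assert events == []

    def test_multi_tag_withholding(self):
        # male read 2 s before a new female episode -> playback withheld
        reads = sorted(
            reads_at([100], tag=OTHER) + reads_at([102]),
            key=lambda r: r.timestamp,
        )
        events = process_stream(reads, cfg(multi_tag_withhold_s=5.0))
        assert kinds(events, EventKind.TARGET_PLAYBACK) == []
        assert len(kinds(events, EventKind.WITHHELD_MULTITAG)) == 1
        # disabled by default: same stream plays back
        events = process_stream(reads, cfg())
        assert len(kinds(events, EventKind.TARGET_PLAYBACK)) == 1

    def test_still_capture_accompanies_playback(self):
        actuators = RecordingActuators()
        events = process_stream(reads_at([0]), cfg(), actuators)
        assert [e.kind for e in events] == [
            EventKind.TARGET_PLAYBACK,
            EventKind.STILL_CAPTURE,
        ]
        assert [c[0] for c in actuators.calls] == ["play_stimulus", "capture_still"]

    def test_actuator_failure_is_logged_and_processing_continues(self):
        actuators = RecordingActuators(fail_playback=True)
        events = process_stream(reads_at([0, 200]), cfg(), actuators)
        assert len(kinds(events, EventKind.ACTUATOR_ERROR)) == 2
        assert kinds(events, EventKind.TARGET_PLAYBACK) == []

    def test_failed_playback_does_not_start_refractory(self):
        class FlakyActuators(RecordingActuators):
            def play_stimulus(self, ref):
                super().play_stimulus(ref)
                return len(self.calls) > 1  # fail only the first call

        events = process_stream(
            reads_at([0, 60]), cfg(refractory_s=120.0), FlakyActuators()
        )
        assert [e.elapsed_s for e in kinds(events, EventKind.TARGET_PLAYBACK)] == [60.0]

    def test_unsorted_reads_rejected(self):
        reads = reads_at([10]) + reads_at([5])
        with pytest.raises(ValueError, match="not sorted"):
            process_stream(reads, cfg())

    def test_elapsed_uses_startup_time(self):
        events = process_stream(
            reads_at([100]), cfg(), startup_time=START - timedelta(seconds=30)
        )
        assert events[0].elapsed_s == 130.0

    def test_config_validation(self):
        with pytest.raises(ValueError, match="overlap"):
            ControllerConfig(target_tags={TARGET}, test_tags={TARGET})
        with pytest.raises(ValueError, match="episode_gap_s"):
            cfg(episode_gap_s=0.5)
        with pytest.raises(ValueError, match="refractory"):
            cfg(refractory_s=-1.0)
        with pytest.raises(ValueError, match="< 1 s"):
            cfg(actuation_latency_s=1.0)


class TestControllerLogDialect:
    def test_known_line_parses(self):
        events, bad = parse_controller_log(["130.000,TARGET_PLAYBACK,0123456789"])
        assert bad == 0
        assert events == [ActionEvent(130.0, EventKind.TARGET_PLAYBACK, TagID("0123456789"))]

    def test_empty_log(self):
        assert parse_controller_log([]) == ([], 0)

    def test_malformed_lines_skipped_and_counted(self):
        events, bad = parse_controller_log(
            ["1.000,TARGET_PLAYBACK,0123456789", "nonsense", "2.0,NOT_A_KIND,0123456789"]
        )
        assert len(events) == 1 and bad == 2

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(action_events, max_size=100))
    def test_round_trip_identity(self, events):
        parsed, bad = parse_controller_log(write_controller_log(events).splitlines())
        assert bad == 0
        assert parsed == events


class TestAgainstBruteForceReference:
    """The optimized state machine must match a direct scan over the reads."""

    @staticmethod
    def random_stream(rng):
        tags = [TARGET, OTHER, TESTTAG]
        times = np.sort(rng.integers(0, 600, size=rng.integers(1, 120)))
        return [
            ReadRecord(
                START + timedelta(seconds=int(t)),
                tags[int(rng.integers(len(tags)))],
            )
            for t in times
        ]

    def test_identical_logs_on_many_random_streams(self):
        rng = np.random.default_rng(20140610)
        configs = [
            cfg(),
            cfg(refractory_s=0.0),
            cfg(refractory_s=30.0, multi_tag_withhold_s=3.0),
            cfg(capture_still=False, actuation_latency_s=0.25),
            cfg(per_tag_refractory=True, target_tags={TARGET, OTHER}),
        ]
        for i in range(300):
            reads = self.random_stream(rng)
            config = configs[i % len(configs)]
            assert process_stream(reads, config) == reference_log(reads, config), (
                f"mismatch on stream {i}"
            )

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        times=st.lists(st.integers(0, 400), min_size=1, max_size=60),
        tag_picks=st.lists(st.integers(0, 2), min_size=60, max_size=60),
        refractory=st.sampled_from([0.0, 15.0, 120.0]),
    )
    def test_property_equivalence(self, times, tag_picks, refractory):
        tags = [TARGET, OTHER, TESTTAG]
        reads = [
            ReadRecord(START + timedelta(seconds=t), tags[pick])
            for t, pick in zip(sorted(times), tag_picks)
        ]
        config = cfg(refractory_s=refractory)
        assert process_stream(reads, config) == reference_log(reads, config)


class TestRefractoryInvariants:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        times=st.lists(st.integers(0, 2000), min_size=1, max_size=150),
        refractory=st.sampled_from([0.0, 10.0, 60.0, 120.0]),
    )
    def test_playback_spacing_and_counts(self, times, refractory):
        reads = reads_at(sorted(times))
        config = cfg(refractory_s=refractory)
        events = process_stream(reads, config)
        playbacks = kinds(events, EventKind.TARGET_PLAYBACK)
        episodes = detect_episodes(
            TARGET,
            [(r.timestamp - START).total_seconds() for r in reads],
            config.episode_gap_s,
        )
        # counts: playbacks <= episodes <= reads
        assert len(playbacks) <= len(episodes) <= len(reads)
        if refractory == 0.0:
            assert len(playbacks) == len(episodes)
        # spacing: no two playbacks within the refractory period
        for a, b in zip(playbacks, playbacks[1:]):
            assert b.elapsed_s - a.elapsed_s > refractory
        # the log's elapsed clock never runs backwards
        for a, b in zip(events, events[1:]):
            assert b.elapsed_s >= a.elapsed_s
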
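"""The playback-controller state machine.

The controller (in the field, a Python script on a Raspberry Pi fed by the
reader's serial line) consumes the detection stream and decides, for each
detection, whether to act:

1. a *new episode* of a **target** tag triggers the playback actuator (and,
   optionally, a still capture) — unless a playback happened within the
   refractory period, or an optional multi-tag rule withholds it because a
   different tag was read in close temporal proximity;
2. any new episode of a **test** tag triggers the test playback, bypassing
   and not starting the refractory period (its job is field verification);
3. repeated reads of a continuously present tag are collapsed into one
   episode — playback fires once per detection episode, not once per read;
4. every decision is appended to a log keyed by *elapsed seconds since
   controller startup* (the Pi has no battery-backed real-time clock).

An *episode* is a maximal run of reads of one tag whose inter-read gaps do
not exceed ``episode_gap_s``; it operationalizes "one visit".  The
refractory period is *non-extending* dead time, anchored at the last emitted
playback; suppressed episodes do not restart it.  It is global across target
tags on one controller (with a single focal target the distinction is moot).

Actuators are abstracted behind two callbacks returning success; a failure
is logged and processing continues — a field deployment must not die because
one playback glitched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from enum import Enum
from typing import Callable, Iterable, Optional, Protocol, Sequence

from .tag_protocol import ReadRecord, TagID

__all__ = [
    "EventKind",
    "ActionEvent",
    "ControllerConfig",
    "DetectionEpisode",
    "Actuators",
    "NullActuators",
    "RecordingActuators",
    "detect_episodes",
    "process_stream",
    "write_controller_log",
    "parse_controller_log",
    "PAPER_FAITHFUL_KINDS",
]


class EventKind(str, Enum):
    TARGET_PLAYBACK = "TARGET_PLAYBACK"
    TEST_PLAYBACK = "TEST_PLAYBACK"
    STILL_CAPTURE = "STILL_CAPTURE"
    SUPPRESSED_REFRACTORY = "SUPPRESSED_REFRACTORY"
    SUPPRESSED_CONTINUOUS = "SUPPRESSED_CONTINUOUS"
    WITHHELD_MULTITAG = "WITHHELD_MULTITAG"
    ACTUATOR_ERROR = "ACTUATOR_ERROR"


#: The field controller logged only actual playbacks; the SUPPRESSED_* /
#: WITHHELD_* entries are bookkeeping this implementation adds.  Filtering a
#: log to these kinds yields the field-faithful view.
PAPER_FAITHFUL_KINDS = frozenset({EventKind.TARGET_PLAYBACK, EventKind.TEST_PLAYBACK})


@dataclass(frozen=True, order=True)
class ActionEvent:
    """One controller decision, on the elapsed-since-startup clock (ms resolution)."""

    elapsed_s: float
    kind: EventKind
    tag_id: TagID

    def __post_init__(self) -> None:
        if self.elapsed_s < 0:
            raise ValueError(f"elapsed_s must be >= 0, got {self.elapsed_s}")


@dataclass(frozen=True)
class ControllerConfig:
    """Controller behaviour knobs.

    refractory_s
        Dead time after an emitted target playback during which further
        target playbacks are suppressed; 0 disables (field study: 120 s).
    episode_gap_s
        Inter-read gap above which a read starts a new detection episode.
        Must exceed one full read cycle (0.5 s), since a continuously
        present tag is legitimately read only once per cycle; default 1.0 s
        (two cycles) tolerates a single missed window.
    multi_tag_withhold_s
        If set, a new target episode is withheld when a *different* tag was
        read within this many seconds — the defence against male/female
        near-coincidence at the entrance.  Disabled by default.
    actuation_latency_s
        Simulated delay between a read and the actuator call; the hardware
        contract is sub-second, enforced here.
    """

    target_tags: frozenset[TagID]
    test_tags: frozenset[TagID] = frozenset()
    refractory_s: float = 120.0
    episode_gap_s: float = 1.0
    multi_tag_withhold_s: Optional[float] = None
    capture_still: bool = True
    actuation_latency_s: float = 0.0
    per_tag_refractory: bool = False
    stimulus_ref: str = "stimulus.wav"
    test_stimulus_ref: str = "test.wav"

    def __post_init__(self) -> None:
        object.__setattr__(self, "target_tags", frozenset(self.target_tags))
        object.__setattr__(self, "test_tags", frozenset(self.test_tags))
        if self.target_tags & self.test_tags:
            raise ValueError(
                f"target and test tag sets overlap: {self.target_tags & self.test_tags}"
            )
        if self.refractory_s < 0:
            raise ValueError(f"refractory_s must be >= 0, got {self.refractory_s}")
        if self.episode_gap_s <= 0.5:
            raise ValueError(
                f"episode_gap_s must exceed one full read cycle (0.5 s), "
                f"got {self.episode_gap_s}"
            )
        if self.multi_tag_withhold_s is not None and self.multi_tag_withhold_s <= 0:
            raise ValueError(
                f"multi_tag_withhold_s must be positive when set, "
                f"got {self.multi_tag_withhold_s}"
            )
        if not (0 <= self.actuation_latency_s < 1.0):
            raise ValueError(
                f"actuation must occur < 1 s after the read, "
                f"got latency {self.actuation_latency_s}"
            )


@dataclass(frozen=True)
class DetectionEpisode:
    """A maximal run of reads of one tag with inter-read gaps <= episode_gap_s."""

    tag_id: TagID
    first_read_elapsed_s: float
    last_read_elapsed_s: float
    n_reads: int

    def __post_init__(self) -> None:
        if self.last_read_elapsed_s < self.first_read_elapsed_s or self.n_reads < 1:
            raise ValueError("invalid episode bounds")


def detect_episodes(
    tag_id: TagID,
    read_times_s: Sequence[float],
    episode_gap_s: float = 1.0,
) -> list[DetectionEpisode]:
    """Greedy episode segmentation of one tag's time-ordered read times.

    A read starts a new episode iff its gap from the previous read exceeds
    ``episode_gap_s`` (strictly).  Episodes partition the reads.
    """
    episodes: list[DetectionEpisode] = []
    prev: Optional[float] = None
    first: float = 0.0
    count = 0
    for t in read_times_s:
        if prev is not None and t < prev:
            raise ValueError(f"read times not sorted: {t} after {prev}")
        if prev is None or t - prev > episode_gap_s:
            if count:
                episodes.append(DetectionEpisode(tag_id, first, prev, count))
            first, count = t, 0
        count += 1
        prev = t
    if count:
        episodes.append(DetectionEpisode(tag_id, first, prev, count))
    return episodes


class Actuators(Protocol):
    """What the controller can do to the world; success is reported back."""

    def play_stimulus(self, stimulus_ref: str) -> bool: ...

    def capture_still(self) -> bool: ...


class NullActuators:
    """Always-succeeding no-op actuators (pure simulation)."""

    def play_stimulus(self, stimulus_ref: str) -> bool:
        return True

    def capture_still(self) -> bool:
        return True


@dataclass
class RecordingActuators:
    """Test double: records invocations, optionally fails, optionally writes a file."""

    fail_playback: bool = False
    fail_capture: bool = False
    sink_path: Optional[str] = None
    calls: list[tuple[str, str]] = field(default_factory=list)

    def _sink(self, line: str) -> None:
        if self.sink_path is not None:
            with open(self.sink_path, "a", encoding="utf-8") as fh:
                fh.write(line + "\n")

    def play_stimulus(self, stimulus_ref: str) -> bool:
        self.calls.append(("play_stimulus", stimulus_ref))
        self._sink(f"play_stimulus,{stimulus_ref}")
        return not self.fail_playback

    def capture_still(self) -> bool:
        self.calls.append(("capture_still", ""))
        self._sink("capture_still,")
        return not self.fail_capture


def process_stream(
    reads: Iterable[ReadRecord],
    config: ControllerConfig,
    actuators: Optional[Actuators] = None,
    startup_time: Optional[datetime] = None,
) -> list[ActionEvent]:
    """Run the controller state machine over a time-ordered detection stream.

    Parameters
    ----------
    reads
        ReadRecords sorted by timestamp (all tags interleaved), as they would
        arrive on the serial line.
    startup_time
        Real time at which the controller's elapsed clock started.  Defaults
        to the first read's timestamp.  Must not postdate the first read.

    Returns the controller log: ActionEvents with non-decreasing elapsed_s.
    """
    if actuators is None:
        actuators = NullActuators()
    reads = list(reads)
    for a, b in zip(reads, reads[1:]):
        if b.timestamp < a.timestamp:
            raise ValueError(
                f"reads not sorted: {b.timestamp} after {a.timestamp}"
            )
    if not reads:
        return []
    if startup_time is None:
        startup_time = reads[0].timestamp
    if startup_time > reads[0].timestamp:
        raise ValueError("controller startup postdates the first read")

    lat = config.actuation_latency_s
    last_read: dict[TagID, float] = {}
    episode_len: dict[TagID, int] = {}
    last_playback: dict[TagID, float] = {}  # keyed by tag, or _GLOBAL
    GLOBAL = None
    events: list[ActionEvent] = []

    def refractory_active(tag: TagID, now: float) -> bool:
        if config.refractory_s <= 0:
            return False
        key = tag if config.per_tag_refractory else GLOBAL
        anchor = last_playback.get(key)
        return anchor is not None and (now - anchor) <= config.refractory_s

    def safe(call: Callable[[], bool]) -> bool:
        try:
            return bool(call())
        except Exception:
            return False

    for rec in reads:
        tag = rec.tag_id
        now = (rec.timestamp - startup_time).total_seconds()
        t_ev = now + lat
        prev = last_read.get(tag)
        new_episode = prev is None or (now - prev) > config.episode_gap_s

        is_target = tag in config.target_tags
        is_test = tag in config.test_tags

        if new_episode:
            episode_len[tag] = 1
            if is_test:
                if safe(lambda: actuators.play_stimulus(config.test_stimulus_ref)):
                    events.append(ActionEvent(t_ev, EventKind.TEST_PLAYBACK, tag))
                else:
                    events.append(ActionEvent(t_ev, EventKind.ACTUATOR_ERROR, tag))
            elif is_target:
                other_recent = config.multi_tag_withhold_s is not None and any(
                    t != tag and now - t_last <= config.multi_tag_withhold_s
                    for t, t_last in last_read.items()
                )
                if refractory_active(tag, now):
                    events.append(ActionEvent(t_ev, EventKind.SUPPRESSED_REFRACTORY, tag))
                elif other_recent:
                    events.append(ActionEvent(t_ev, EventKind.WITHHELD_MULTITAG, tag))
                else:
                    if safe(lambda: actuators.play_stimulus(config.stimulus_ref)):
                        events.append(ActionEvent(t_ev, EventKind.TARGET_PLAYBACK, tag))
                        key = tag if config.per_tag_refractory else GLOBAL
                        last_playback[key] = t_ev
                        if config.capture_still:
                            if safe(actuators.capture_still):
                                events.append(
                                    ActionEvent(t_ev, EventKind.STILL_CAPTURE, tag)
                                )
                            else:
                                events.append(
                                    ActionEvent(t_ev, EventKind.ACTUATOR_ERROR, tag)
                                )
                    else:
                        events.append(ActionEvent(t_ev, EventKind.ACTUATOR_ERROR, tag))
            # reads of tags that are neither target nor test are ignored
            # (they still update last_read below, feeding the multi-tag rule)
        else:
            episode_len[tag] = episode_len.get(tag, 0) + 1
            if episode_len[tag] == 2 and (is_target or is_test):
                events.append(ActionEvent(t_ev, EventKind.SUPPRESSED_CONTINUOUS, tag))

        last_read[tag] = now

    return events


def write_controller_log(events: Iterable[ActionEvent]) -> str:
    """Serialize the controller log: ``elapsed_s,kind,tag_id`` at ms resolution."""
    return "".join(
        f"{ev.elapsed_s:.3f},{ev.kind.value},{ev.tag_id.value}\n" for ev in events
    )


def parse_controller_log(source: Iterable[str]) -> tuple[list[ActionEvent], int]:
    """Parse a controller log; malformed lines are skipped and counted."""
    events: list[ActionEvent] = []
    n_malformed = 0
    for raw in source:
        line = raw.strip()
        if not line:
            continue
        try:
            elapsed_text, kind_text, tag_text = line.split(",")
            events.append(
                ActionEvent(float(elapsed_text), EventKind(kind_text), TagID(tag_text))
            )
        except ValueError:
            n_malformed += 1
    return events, n_malformed
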
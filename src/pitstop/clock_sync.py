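"""Dual-log clock synchronization via test-tag anchor events.

The controller has no battery-backed real-time clock, so its log counts
elapsed seconds since startup; the reader logs real calendar time.  The
experimenter's test-tag swipe at deployment appears in *both* logs — as a
test-tag detection in the reader log and as a TEST_PLAYBACK in the
controller log — and that shared event anchors the two clocks: the constant
offset ``real_time - elapsed_s`` assigns real times to every controller
entry.

A single anchor assumes zero relative clock drift, which is adequate over a
six-hour deployment.  A two-anchor mode (first and last test-tag events)
fits a linear drift term for longer runs; it is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Iterable, Optional, Sequence

from .controller import ActionEvent, EventKind
from .tag_protocol import ReadRecord, TagID

__all__ = [
    "SyncAnchor",
    "UnanchorableError",
    "AlignedEvent",
    "find_anchor",
    "find_anchors",
    "align",
    "write_merged_log",
    "parse_merged_log",
]


class UnanchorableError(RuntimeError):
    """Raised when one of the two logs lacks a test-tag event to anchor on."""


@dataclass(frozen=True)
class SyncAnchor:
    """A test-tag event present in both logs: elapsed time <-> real time."""

    elapsed_s: float
    real_time: datetime

    def real_time_of(self, elapsed_s: float) -> datetime:
        return self.real_time + timedelta(seconds=elapsed_s - self.elapsed_s)


@dataclass(frozen=True)
class AlignedEvent:
    """A controller event with its reconstructed real time."""

    real_time: datetime
    event: ActionEvent

    @property
    def elapsed_s(self) -> float:
        return self.event.elapsed_s

    @property
    def kind(self) -> EventKind:
        return self.event.kind

    @property
    def tag_id(self) -> TagID:
        return self.event.tag_id


def _test_reads(
    rfid_log: Iterable[ReadRecord], test_tags: frozenset[TagID]
) -> list[ReadRecord]:
    return [r for r in rfid_log if r.tag_id in test_tags]


def _test_events(
    controller_log: Iterable[ActionEvent], test_tags: frozenset[TagID]
) -> list[ActionEvent]:
    return [
        e
        for e in controller_log
        if e.kind is EventKind.TEST_PLAYBACK and e.tag_id in test_tags
    ]


def find_anchor(
    rfid_log: Sequence[ReadRecord],
    controller_log: Sequence[ActionEvent],
    test_tags: Iterable[TagID],
) -> SyncAnchor:
    """Pair the first TEST_PLAYBACK with the first test-tag reader detection.

    Raises :class:`UnanchorableError`, naming the deficient log, when either
    log contains no test-tag event.
    """
    tags = frozenset(test_tags)
    reads = _test_reads(rfid_log, tags)
    events = _test_events(controller_log, tags)
    if not reads:
        raise UnanchorableError("no test-tag detection in the RFID log; cannot anchor")
    if not events:
        raise UnanchorableError(
            "no TEST_PLAYBACK in the controller log; cannot anchor"
        )
    return SyncAnchor(elapsed_s=events[0].elapsed_s, real_time=reads[0].timestamp)


def find_anchors(
    rfid_log: Sequence[ReadRecord],
    controller_log: Sequence[ActionEvent],
    test_tags: Iterable[TagID],
) -> tuple[SyncAnchor, SyncAnchor]:
    """First-first and last-last test-tag pairing, for the linear-drift mode.

    Requires two distinct test-tag events in each log.
    """
    tags = frozenset(test_tags)
    reads = _test_reads(rfid_log, tags)
    events = _test_events(controller_log, tags)
    if len(reads) < 2 or len(events) < 2:
        raise UnanchorableError(
            "drift fitting needs >= 2 test-tag events in each log "
            f"(got {len(reads)} reads, {len(events)} playbacks)"
        )
    return (
        SyncAnchor(events[0].elapsed_s, reads[0].timestamp),
        SyncAnchor(events[-1].elapsed_s, reads[-1].timestamp),
    )


def align(
    controller_log: Iterable[ActionEvent],
    anchor: SyncAnchor,
    drift_anchor: Optional[SyncAnchor] = None,
) -> list[AlignedEvent]:
    """Assign a real time to every controller event.

    With one anchor, a constant offset is applied (zero-drift assumption);
    order is preserved and the mapping is invertible.  With ``drift_anchor``
    given, elapsed time is mapped linearly through both anchors, absorbing a
    constant relative clock-rate error.
    """
    if drift_anchor is not None:
        d_elapsed = drift_anchor.elapsed_s - anchor.elapsed_s
        if d_elapsed == 0:
            raise ValueError("drift anchors must have distinct elapsed times")
        rate = (drift_anchor.real_time - anchor.real_time).total_seconds() / d_elapsed

        def to_real(elapsed: float) -> datetime:
            return anchor.real_time + timedelta(
                seconds=rate * (elapsed - anchor.elapsed_s)
            )

    else:
        to_real = anchor.real_time_of
    return [AlignedEvent(to_real(e.elapsed_s), e) for e in controller_log]


def write_merged_log(aligned: Iterable[AlignedEvent]) -> str:
    """Serialize merged log: ``real_time,elapsed_s,kind,tag_id`` (ms precision)."""
    return "".join(
        ",".join(
            (
                ae.real_time.isoformat(sep=" ", timespec="milliseconds"),
                f"{ae.elapsed_s:.3f}",
                ae.kind.value,
                ae.tag_id.value,
            )
        )
        + "\n"
        for ae in aligned
    )


def parse_merged_log(source: Iterable[str]) -> tuple[list[AlignedEvent], int]:
    aligned: list[AlignedEvent] = []
    n_malformed = 0
    for raw in source:
        line = raw.strip()
        if not line:
            continue
        try:
            real_text, elapsed_text, kind_text, tag_text = line.split(",")
            aligned.append(
                AlignedEvent(
                    datetime.fromisoformat(real_text),
                    ActionEvent(float(elapsed_text), EventKind(kind_text), TagID(tag_text)),
                )
            )
        except ValueError:
            n_malformed += 1
    return aligned, n_malformed
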
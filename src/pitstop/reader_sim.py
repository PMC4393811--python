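"""Duty-cycled single-tag reader: presence intervals -> detection records.

The reader alternates a 0.3 s read window with a 0.2 s power-saving pause,
repeating from t = 0 of the deployment.  Within one read window:

* a tag is *readable* if its presence overlaps the window by at least
  ``min_overlap_s`` (the device needs some minimum energized time to decode
  the 40-bit identity; the exact requirement is firmware detail, so it is a
  single tunable with a conservative default of 0.1 s);
* if exactly one tag is readable, one record is emitted, time-stamped to the
  whole second containing the window start (the log has 1 s resolution);
* if two or more distinct tags are readable, nothing is emitted — the
  single-tag reader cannot store any record while multiple tags are in
  range (tag collision).

Read success is deterministic given the overlap; no probabilistic failure
is modelled, since no failure rate is published for the hardware.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Mapping, Optional, Sequence

from .tag_protocol import ReaderID, ReadRecord, TagID
from .visit_sim import PresenceInterval

__all__ = ["DutyCycle", "simulate_reads", "guaranteed_detection_dwell"]

# Inclusive-boundary slack for overlap >= min_overlap_s comparisons: the
# mathematically exact boundary (e.g. window [0.2, 0.3] vs presence starting
# at 0.2 with min_overlap 0.1) otherwise fails under IEEE rounding.
_EPS = 1e-9


@dataclass(frozen=True)
class DutyCycle:
    """The reader's repeating read/pause schedule."""

    read_window_s: float = 0.3
    pause_s: float = 0.2
    min_overlap_s: float = 0.1

    def __post_init__(self) -> None:
        if self.read_window_s <= 0:
            raise ValueError(f"read_window_s must be positive, got {self.read_window_s}")
        if self.pause_s < 0:
            raise ValueError(f"pause_s must be >= 0, got {self.pause_s}")
        if not (0 < self.min_overlap_s <= self.read_window_s):
            raise ValueError(
                f"min_overlap_s must be in (0, read_window_s], got {self.min_overlap_s}"
            )

    @property
    def cycle_s(self) -> float:
        return self.read_window_s + self.pause_s


def guaranteed_detection_dwell(duty: DutyCycle) -> float:
    """Minimal solo dwell guaranteeing >= 1 read regardless of arrival phase.

    The worst phase leaves just under ``min_overlap_s`` of usable time in the
    window the presence starts in, so the presence must survive the pause and
    still cover ``min_overlap_s`` of the next window:
    ``pause_s + 2 * min_overlap_s``.
    """
    return duty.pause_s + 2.0 * duty.min_overlap_s


def simulate_reads(
    presence: Mapping[TagID, Sequence[PresenceInterval]],
    duty: DutyCycle = DutyCycle(),
    deployment_start: datetime = datetime(2014, 6, 10, 6, 0, 0),
    reader_id: Optional[ReaderID] = None,
) -> list[ReadRecord]:
    """Run the duty-cycled reader over ground-truth presence.

    Returns records sorted by window, at most one per read window, with
    timestamps quantized to the second by flooring.  ``reader_id`` is stamped
    on every record when given (a Generation-2 reader), else omitted.
    """
    if deployment_start.microsecond != 0:
        raise ValueError("deployment_start must be a whole second (1 s log resolution)")
    cycle = duty.cycle_s
    window = duty.read_window_s

    # Accumulate, per read window, each tag's total presence-overlap. Only
    # windows intersecting some interval are ever touched, so cost scales
    # with presence, not deployment length.
    overlaps: dict[int, dict[TagID, float]] = {}
    for tag, intervals in presence.items():
        for iv in intervals:
            k = max(0, math.floor((iv.start_s - window) / cycle))
            while k * cycle < iv.end_s:
                w_start = k * cycle
                ov = min(iv.end_s, w_start + window) - max(iv.start_s, w_start)
                if ov > 0:
                    per_tag = overlaps.setdefault(k, {})
                    per_tag[tag] = per_tag.get(tag, 0.0) + ov
                k += 1

    records: list[ReadRecord] = []
    for k in sorted(overlaps):
        readable = [
            tag
            for tag, ov in overlaps[k].items()
            if ov >= duty.min_overlap_s - _EPS
        ]
        if len(readable) != 1:
            continue  # nothing in range, or collision: no record either way
        stamp_s = math.floor(k * cycle + _EPS)
        records.append(
            ReadRecord(
                timestamp=deployment_start + timedelta(seconds=stamp_s),
                tag_id=readable[0],
                reader_id=reader_id,
            )
        )
    return records
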
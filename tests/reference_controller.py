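"""Brute-force reference for the controller rules: a direct scan over reads.

Deliberately naive and independent of the package's state machine: for every
read it re-derives everything it needs by scanning the full history of prior
reads and prior emitted events.  Used only as an oracle in equivalence tests.
"""

from __future__ import annotations

from datetime import datetime
from typing import Optional, Sequence

from pitstop.controller import ActionEvent, ControllerConfig, EventKind
from pitstop.tag_protocol import ReadRecord


def reference_log(
    reads: Sequence[ReadRecord],
    config: ControllerConfig,
    startup_time: Optional[datetime] = None,
) -> list[ActionEvent]:
    reads = list(reads)
    if not reads:
        return []
    if startup_time is None:
        startup_time = reads[0].timestamp
    lat = config.actuation_latency_s
    events: list[ActionEvent] = []
    seen: list[tuple[float, object]] = []  # (elapsed, tag) of every prior read

    for rec in reads:
        now = (rec.timestamp - startup_time).total_seconds()
        t_ev = now + lat
        same = [t for t, tag in seen if tag == rec.tag_id]
        new_episode = not same or now - same[-1] > config.episode_gap_s

        if new_episode:
            if rec.tag_id in config.test_tags:
                events.append(ActionEvent(t_ev, EventKind.TEST_PLAYBACK, rec.tag_id))
            elif rec.tag_id in config.target_tags:
                playbacks = [
                    e.elapsed_s
                    for e in events
                    if e.kind is EventKind.TARGET_PLAYBACK
                    and (not config.per_tag_refractory or e.tag_id == rec.tag_id)
                ]
                in_refractory = (
                    config.refractory_s > 0
                    and bool(playbacks)
                    and now - playbacks[-1] <= config.refractory_s
                )
                others_recent = config.multi_tag_withhold_s is not None and any(
                    tag != rec.tag_id and now - t <= config.multi_tag_withhold_s
                    for t, tag in seen
                )
                if in_refractory:
                    events.append(
                        ActionEvent(t_ev, EventKind.SUPPRESSED_REFRACTORY, rec.tag_id)
                    )
                elif others_recent:
                    events.append(
                        ActionEvent(t_ev, EventKind.WITHHELD_MULTITAG, rec.tag_id)
                    )
                else:
                    events.append(
                        ActionEvent(t_ev, EventKind.TARGET_PLAYBACK, rec.tag_id)
                    )
                    if config.capture_still:
                        events.append(
                            ActionEvent(t_ev, EventKind.STILL_CAPTURE, rec.tag_id)
                        )
        else:
            # second read of the current episode gets the one continuous-
            # suppression marker; find where this episode began by scanning
            if rec.tag_id in config.target_tags or rec.tag_id in config.test_tags:
                n_in_episode = 1
                prev = same[-1]
                for t in reversed(same[:-1]):
                    if prev - t > config.episode_gap_s:
                        break
                    n_in_episode += 1
                    prev = t
                if n_in_episode == 1:  # this read is the episode's second
                    events.append(
                        ActionEvent(t_ev, EventKind.SUPPRESSED_CONTINUOUS, rec.tag_id)
                    )
        seen.append((now, rec.tag_id))
    return events
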
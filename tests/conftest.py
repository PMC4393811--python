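"""Shared fixtures and hypothesis strategies for the suite."""

from __future__ import annotations

from datetime import datetime, timedelta

import pytest
from hypothesis import strategies as st

from pitstop.controller import ActionEvent, EventKind
from pitstop.tag_protocol import ReaderID, ReadRecord, TagID

EPOCH = datetime(2014, 6, 10, 6, 0, 0)

hex_tag = st.text(alphabet="0123456789ABCDEF", min_size=10, max_size=10).map(TagID)

reader_id = st.text(
    alphabet="ABCDEFGHJKMNPQRSTUVWXYZ0123456789ab", min_size=4, max_size=4
).map(ReaderID)

timestamps = st.integers(min_value=0, max_value=365 * 24 * 3600).map(
    lambda s: EPOCH + timedelta(seconds=s)
)

read_records = st.builds(
    ReadRecord,
    timestamp=timestamps,
    tag_id=hex_tag,
    reader_id=st.one_of(st.none(), reader_id),
)

# elapsed times quantized to the log's millisecond resolution
elapsed_ms = st.integers(min_value=0, max_value=24 * 3600 * 1000).map(
    lambda ms: ms / 1000.0
)

action_events = st.builds(
    ActionEvent,
    elapsed_s=elapsed_ms,
    kind=st.sampled_from(list(EventKind)),
    tag_id=hex_tag,
)


@pytest.fixture(scope="session")
def epoch() -> datetime:
    return EPOCH
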
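"""Tag identities, reader serial settings, and the RFID detection-log dialect.

A PIT (passive integrated transponder) tag carries a 40-bit EM4102-style
identity, written here as a fixed-width 10-character uppercase hex string.
The reader logs one line per detection: the tag number and the current date
and time at one-second resolution.  Two reader generations exist; they speak
different serial settings, and the second generation additionally stamps its
detections with a 4-character alphanumeric reader ID.  The presence of that
reader ID is what tells the controller which serial dialect to expect.

The on-disk log dialect is a headerless CSV::

    YYYY-MM-DD HH:MM:SS,<TAGID>[,<READERID>]

comma-delimited, UTF-8, LF line endings.  Real reader firmware formats vary;
this canonical dialect is the package's interchange format and adapters for
specific firmware can be layered on top of :func:`parse_rfid_log`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from datetime import datetime
from enum import Enum
from typing import Iterable, Optional

__all__ = [
    "TagID",
    "ReaderID",
    "SerialSettings",
    "ReaderGeneration",
    "ReadRecord",
    "TIMESTAMP_FORMAT",
    "infer_generation",
    "parse_rfid_log",
    "write_rfid_log",
]

TIMESTAMP_FORMAT = "%Y-%m-%d %H:%M:%S"

_TAG_RE = re.compile(r"^[0-9A-F]{10}$")
_READER_RE = re.compile(r"^[0-9A-Za-z]{4}$")


@dataclass(frozen=True, order=True)
class TagID:
    """A 40-bit EM4102 tag identity: exactly 10 hex characters, case-normalized."""

    value: str

    def __post_init__(self) -> None:
        norm = str(self.value).strip().upper()
        if not _TAG_RE.match(norm):
            raise ValueError(
                f"invalid tag ID {self.value!r}: expected 10 hex characters"
            )
        object.__setattr__(self, "value", norm)

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True, order=True)
class ReaderID:
    """The 4-character alphanumeric code a Generation-2 reader can be assigned."""

    value: str

    def __post_init__(self) -> None:
        if not _READER_RE.match(str(self.value)):
            raise ValueError(
                f"invalid reader ID {self.value!r}: expected 4 alphanumeric characters"
            )

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class SerialSettings:
    """RS232 framing for the reader-to-controller link.

    The two reader generations are known to differ in baud rate; the exact
    rates are not published, so these are configurable placeholders.  In
    simulation the settings select a parser profile and never alter content.
    """

    baud: int
    data_bits: int = 8
    parity: str = "N"
    stop_bits: int = 1

    def __post_init__(self) -> None:
        if self.baud <= 0:
            raise ValueError(f"baud must be positive, got {self.baud}")


class ReaderGeneration(Enum):
    GEN1 = "GEN1"
    GEN2 = "GEN2"

    @property
    def serial_settings(self) -> SerialSettings:
        return DEFAULT_SERIAL_SETTINGS[self]


#: Placeholder defaults; the generations differ, the true rates are firmware detail.
DEFAULT_SERIAL_SETTINGS = {
    ReaderGeneration.GEN1: SerialSettings(baud=9600),
    ReaderGeneration.GEN2: SerialSettings(baud=57600),
}


@dataclass(frozen=True, order=True)
class ReadRecord:
    """One reader detection: tag identity + real timestamp at 1 s resolution.

    ``reader_id`` is absent for Generation-1 readers, which do not stamp an ID.
    """

    timestamp: datetime
    tag_id: TagID
    reader_id: Optional[ReaderID] = None

    def __post_init__(self) -> None:
        if self.timestamp.microsecond != 0:
            raise ValueError(
                f"read timestamps have 1 s resolution; got sub-second component "
                f"in {self.timestamp.isoformat()}"
            )


def infer_generation(reader_id_token: Optional[str]) -> ReaderGeneration:
    """Infer the reader generation from the presence of a reader-ID token.

    Generation-2 readers can be assigned a four-character alphanumeric code
    which appears in their output; supplying it selects the GEN2 serial
    profile.  An absent/empty token selects GEN1.  A malformed token is an
    error rather than a silent GEN1 fallback, so that typos in a config file
    do not select the wrong serial settings.
    """
    if reader_id_token is None or reader_id_token == "":
        return ReaderGeneration.GEN1
    if not _READER_RE.match(reader_id_token):
        raise ValueError(
            f"malformed reader ID token {reader_id_token!r}: "
            "expected exactly 4 alphanumeric characters"
        )
    return ReaderGeneration.GEN2


def _parse_line(line: str) -> ReadRecord:
    parts = line.split(",")
    if len(parts) == 2:
        ts_text, tag_text = parts
        reader: Optional[ReaderID] = None
    elif len(parts) == 3:
        ts_text, tag_text, reader_text = parts
        reader = ReaderID(reader_text.strip())
    else:
        raise ValueError(f"expected 2 or 3 comma-separated fields: {line!r}")
    timestamp = datetime.strptime(ts_text.strip(), TIMESTAMP_FORMAT)
    return ReadRecord(timestamp=timestamp, tag_id=TagID(tag_text), reader_id=reader)


def parse_rfid_log(source: Iterable[str]) -> tuple[list[ReadRecord], int]:
    """Parse the reader's detection log.

    Parameters
    ----------
    source
        An iterable of lines (an open text file works directly).

    Returns
    -------
    records, n_malformed
        Well-formed records in file order, and the number of malformed lines
        that were skipped.  Blank lines are ignored silently.
    """
    records: list[ReadRecord] = []
    n_malformed = 0
    for raw in source:
        line = raw.strip()
        if not line:
            continue
        try:
            records.append(_parse_line(line))
        except ValueError:
            n_malformed += 1
    return records, n_malformed


def write_rfid_log(records: Iterable[ReadRecord]) -> str:
    """Serialize records to the canonical log dialect (inverse of parse).

    ``parse_rfid_log(write_rfid_log(x).splitlines())`` reproduces ``x``
    exactly, including 1 s timestamp resolution and optional reader IDs.
    """
    lines = []
    for rec in records:
        if not isinstance(rec, ReadRecord):
            raise ValueError(f"not a ReadRecord: {rec!r}")
        fields = [rec.timestamp.strftime(TIMESTAMP_FORMAT), rec.tag_id.value]
        if rec.reader_id is not None:
            fields.append(rec.reader_id.value)
        lines.append(",".join(fields))
    return "".join(line + "\n" for line in lines)
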
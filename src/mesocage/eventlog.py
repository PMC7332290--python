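"""Behavioral event-log records, file dialects, and session/trial parsing.

The home-cage software reports everything that happens at the head-fixation
chamber — RFID-tagged entries, spout licks, servo fixation and release,
imaging-LED on/off marks, cues, trial outcomes — as timestamped plain-text
lines.  This module defines the canonical in-package record format, lossless
reading/writing, an indexed :class:`EventStore`, and the parser that turns a
raw stream of events into :class:`HeadfixSession` and :class:`Trial` objects
with a timebase that can be synchronized to movie frames via the LED marks.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "EVENT_VOCABULARY",
    "OUTCOME_CODES",
    "EventRecord",
    "Dialect",
    "DEFAULT_DIALECT",
    "EventStore",
    "Trial",
    "HeadfixSession",
    "FrameIndexMap",
    "write_log",
    "read_log",
    "parse_sessions",
    "align_timebase",
    "movie_filename",
    "parse_movie_filename",
]

#: Closed vocabulary of event-name tokens the cage software emits.
EVENT_VOCABULARY = frozenset(
    {
        "entry",
        "exit",
        "lick",
        "fix_loose",
        "fix_tight",
        "fix_release",
        "reward_entrance",
        "reward_task",
        "cue_go",
        "cue_nogo",
        "tone_feedback",
        "BrainLEDON",
        "BrainLEDOFF",
        "outcome",
        "weight",
        "alert",
    }
)

#: Closed set of trial outcome codes: go trials score in {+2, -2, -4}
#: (correct / no-or-late response / early lick during the delay) and no-go
#: trials in {+1, -1, -3} (correct rejection / response-window lick / early
#: lick).
OUTCOME_CODES = frozenset({2, -2, -4, 1, -1, -3})

_GO_OUTCOMES = frozenset({2, -2, -4})
_NOGO_OUTCOMES = frozenset({1, -1, -3})


@dataclass(frozen=True)
class EventRecord:
    """One timestamped cage event keyed by RFID tag.

    ``payload`` is kept as the raw string token (or ``None``) so that a
    write -> read round trip is bit-exact; use :meth:`payload_float` /
    :meth:`outcome_code` for typed access.
    """

    timestamp: float
    tag: str
    event: str
    payload: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "timestamp", float(self.timestamp))
        if not np.isfinite(self.timestamp):
            raise ValueError(f"non-finite timestamp: {self.timestamp!r}")
        if self.event not in EVENT_VOCABULARY:
            raise ValueError(f"unknown event token: {self.event!r}")
        if self.event == "outcome":
            code = self.outcome_code()
            if code not in OUTCOME_CODES:
                raise ValueError(f"outcome payload {self.payload!r} not in {sorted(OUTCOME_CODES)}")

    def payload_float(self) -> float:
        if self.payload is None:
            raise ValueError("record has no payload")
        return float(self.payload)

    def outcome_code(self) -> int:
        if self.payload is None:
            raise ValueError("outcome record lacks a payload")
        return int(float(self.payload))


@dataclass(frozen=True)
class Dialect:
    """Field layout of one text-log flavor.

    The package's native dialect is tab-separated
    ``timestamp<TAB>tag<TAB>event<TAB>payload`` with shortest-round-trip
    float timestamps.  Archive flavors (deposited cage logs) can be adapted
    by supplying a different delimiter, field order, and event-name mapping.
    """

    delimiter: str = "\t"
    #: positions of (timestamp, tag, event, payload) within a split line
    field_order: tuple[int, int, int, int] = (0, 1, 2, 3)
    #: mapping from source event tokens to the canonical vocabulary
    event_map: dict[str, str] = field(default_factory=dict)

    def format_line(self, record: EventRecord) -> str:
        fields = ["", "", "", ""]
        ts_i, tag_i, ev_i, pl_i = self.field_order
        fields[ts_i] = repr(record.timestamp)
        fields[tag_i] = record.tag
        fields[ev_i] = record.event
        fields[pl_i] = "" if record.payload is None else record.payload
        return self.delimiter.join(fields)

    def parse_line(self, line: str, lineno: int) -> EventRecord:
        parts = line.rstrip("\n").split(self.delimiter)
        if len(parts) < max(self.field_order) + 1:
            raise ValueError(f"line {lineno}: expected >= {max(self.field_order) + 1} fields, got {len(parts)}")
        ts_i, tag_i, ev_i, pl_i = self.field_order
        try:
            timestamp = float(parts[ts_i])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: bad timestamp {parts[ts_i]!r}") from exc
        if not np.isfinite(timestamp):
            raise ValueError(f"line {lineno}: non-finite timestamp {parts[ts_i]!r}")
        event = self.event_map.get(parts[ev_i], parts[ev_i])
        if event not in EVENT_VOCABULARY:
            raise ValueError(f"line {lineno}: unknown event token {parts[ev_i]!r}")
        payload = parts[pl_i] if parts[pl_i] != "" else None
        try:
            return EventRecord(timestamp, parts[tag_i], event, payload)
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from exc


DEFAULT_DIALECT = Dialect()


def write_log(
    records: Sequence[EventRecord],
    destination: str | Path,
    dialect: Dialect = DEFAULT_DIALECT,
) -> Path:
    """Write time-ordered records to a text log, one line per record.

    Raises ``ValueError`` naming the first out-of-order index if the input
    is not sorted by timestamp (ties allowed).
    """
    for i in range(1, len(records)):
        if records[i].timestamp < records[i - 1].timestamp:
            raise ValueError(f"records not time-ordered at index {i}")
    destination = Path(destination)
    with destination.open("w", encoding="utf-8") as fh:
        for record in records:
            fh.write(dialect.format_line(record))
            fh.write("\n")
    return destination


def read_log(source: str | Path, dialect: Dialect = DEFAULT_DIALECT) -> list[EventRecord]:
    """Read a text log, returning time-ordered records.

    Malformed lines (bad timestamp, unknown event token) raise ``ValueError``
    naming the 1-based line number; unknown tokens are never silently
    dropped.
    """
    records: list[EventRecord] = []
    with Path(source).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            records.append(dialect.parse_line(line, lineno))
    records.sort(key=lambda r: r.timestamp)
    return records


class EventStore:
    """Indexed, time-ordered collection of :class:`EventRecord`.

    A lightweight in-memory stand-in for a relational event database:
    supports queries by tag, event type, and time range, round-trips
    losslessly through the text log, and exports to SQLite/pandas.
    """

    def __init__(self, records: Iterable[EventRecord] = ()) -> None:
        self._records: list[EventRecord] = sorted(records, key=lambda r: r.timestamp)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[EventRecord]:
        return iter(self._records)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, EventStore) and self._records == other._records

    @property
    def records(self) -> list[EventRecord]:
        return list(self._records)

    def add(self, records: Iterable[EventRecord]) -> None:
        self._records.extend(records)
        self._records.sort(key=lambda r: r.timestamp)

    def tags(self) -> list[str]:
        return sorted({r.tag for r in self._records})

    def by_tag(self, tag: str) -> list[EventRecord]:
        return [r for r in self._records if r.tag == tag]

    def by_event(self, event: str) -> list[EventRecord]:
        if event not in EVENT_VOCABULARY:
            raise ValueError(f"unknown event token: {event!r}")
        return [r for r in self._records if r.event == event]

    def between(self, start: float, end: float) -> list[EventRecord]:
        return [r for r in self._records if start <= r.timestamp < end]

    def merge(self, other: "EventStore") -> "EventStore":
        return EventStore(self._records + other._records)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "timestamp": [r.timestamp for r in self._records],
                "tag": [r.tag for r in self._records],
                "event": [r.event for r in self._records],
                "payload": [r.payload for r in self._records],
            }
        )

    def to_sqlite(self, path: str | Path) -> Path:
        """Relational export mirroring the cage software's event table."""
        path = Path(path)
        con = sqlite3.connect(path)
        try:
            con.execute(
                "CREATE TABLE IF NOT EXISTS events "
                "(timestamp REAL NOT NULL, tag TEXT NOT NULL, event TEXT NOT NULL, payload TEXT)"
            )
            con.executemany(
                "INSERT INTO events VALUES (?, ?, ?, ?)",
                [(r.timestamp, r.tag, r.event, r.payload) for r in self._records],
            )
            con.commit()
        finally:
            con.close()
        return path

    @classmethod
    def from_log(cls, source: str | Path, dialect: Dialect = DEFAULT_DIALECT) -> "EventStore":
        return cls(read_log(source, dialect))

    def write(self, destination: str | Path, dialect: Dialect = DEFAULT_DIALECT) -> Path:
        return write_log(self._records, destination, dialect)


@dataclass
class Trial:
    """One cue presentation with its timing windows, licks, and outcome.

    ``licks`` are lick times relative to the cue; ``outcome`` is one of the
    closed outcome codes (or ``None`` while the trial is still open during
    parsing).
    """

    cue_time: float
    cue_kind: str  # "go" | "nogo"
    withhold_duration: float
    delay: float
    response_window: float = 1.25
    licks: list[float] = field(default_factory=list)
    outcome: int | None = None

    def __post_init__(self) -> None:
        if self.cue_kind not in ("go", "nogo"):
            raise ValueError(f"cue_kind must be 'go' or 'nogo', got {self.cue_kind!r}")
        if self.delay < 0:
            raise ValueError("delay must be >= 0")
        if self.response_window <= 0:
            raise ValueError("response_window must be > 0")


@dataclass
class HeadfixSession:
    """One chamber visit that reached the imaging position.

    ``fixed`` distinguishes head-fixed sessions (servo engaged) from no-fix
    sessions where the mouse broke the infrared beam and ran trials without
    restraint.  ``truncated`` flags a fixation without a matching release
    (the stranded-mouse case the cage alerts on); such sessions are retained
    so participation counts stay conservative.
    """

    tag: str
    start: float
    end: float
    fixed: bool
    led_on: float | None = None
    led_off: float | None = None
    trials: list[Trial] = field(default_factory=list)
    licks: list[float] = field(default_factory=list)
    truncated: bool = False

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("session start must precede end")

    @property
    def duration(self) -> float:
        return self.end - self.start

    def outcomes(self) -> list[int]:
        return [t.outcome for t in self.trials if t.outcome is not None]


def _parse_cue_payload(payload: str | None) -> tuple[float, float, float]:
    """Cue payloads carry 'withhold|delay|window' as decimal floats."""
    if payload is None:
        return (0.0, 0.0, 1.25)
    parts = payload.split("|")
    withhold, delay, window = (float(p) for p in parts[:3])
    return withhold, delay, window


def parse_sessions(store: EventStore) -> list[HeadfixSession]:
    """Parse raw events into head-fix (and no-fix) sessions with trials.

    Every ``fix_loose``/``fix_tight`` ... ``fix_release`` pair of one tag
    becomes a session with ``fixed=True``; beam-break episodes that switched
    the imaging LED on without fixation become sessions with ``fixed=False``
    spanning LED-on to exit.  Licks and trials are assigned to the unique
    enclosing session of the same tag.  A fixation with no release before
    the visit ends yields a session flagged ``truncated``.
    """
    sessions: list[HeadfixSession] = []
    for tag in store.tags():
        events = store.by_tag(tag)
        open_session: HeadfixSession | None = None
        open_trial: Trial | None = None
        led_on_pending: float | None = None
        visit_had_fix = False

        def close_trial() -> None:
            nonlocal open_trial
            if open_trial is not None and open_session is not None:
                open_session.trials.append(open_trial)
            open_trial = None

        def close_session(end: float, truncated: bool = False) -> None:
            nonlocal open_session, led_on_pending, visit_had_fix
            close_trial()
            if open_session is not None:
                if end <= open_session.start:
                    end = open_session.start + 1e-6
                open_session.end = end
                open_session.truncated = truncated
                sessions.append(open_session)
            open_session = None
            led_on_pending = None
            visit_had_fix = False

        for rec in events:
            ev = rec.event
            if ev in ("fix_loose", "fix_tight"):
                if open_session is not None and not open_session.fixed:
                    # beam-break episode escalated to fixation; fold it in
                    open_session.fixed = True
                else:
                    if open_session is not None:
                        close_session(rec.timestamp, truncated=open_session.fixed)
                    open_session = HeadfixSession(
                        tag=tag, start=rec.timestamp, end=rec.timestamp + 1e-6, fixed=True
                    )
                    if led_on_pending is not None:
                        open_session.led_on = led_on_pending
                        led_on_pending = None
                visit_had_fix = True
            elif ev == "fix_release":
                if open_session is not None and open_session.fixed:
                    close_session(rec.timestamp)
            elif ev == "BrainLEDON":
                if open_session is not None:
                    open_session.led_on = rec.timestamp
                else:
                    # LED on without fixation: a no-fix session begins here
                    open_session = HeadfixSession(
                        tag=tag,
                        start=rec.timestamp,
                        end=rec.timestamp + 1e-6,
                        fixed=False,
                        led_on=rec.timestamp,
                    )
            elif ev == "BrainLEDOFF":
                if open_session is not None:
                    open_session.led_off = rec.timestamp
            elif ev in ("cue_go", "cue_nogo"):
                close_trial()
                if open_session is not None:
                    withhold, delay, window = _parse_cue_payload(rec.payload)
                    open_trial = Trial(
                        cue_time=rec.timestamp,
                        cue_kind="go" if ev == "cue_go" else "nogo",
                        withhold_duration=withhold,
                        delay=delay,
                        response_window=window,
                    )
            elif ev == "lick":
                if open_session is not None:
                    open_session.licks.append(rec.timestamp)
                    if open_trial is not None:
                        open_trial.licks.append(rec.timestamp - open_trial.cue_time)
            elif ev == "outcome":
                if open_trial is not None:
                    open_trial.outcome = rec.outcome_code()
                    close_trial()
            elif ev == "exit":
                if open_session is not None:
                    # fixed session without release => truncated
                    close_session(rec.timestamp, truncated=open_session.fixed)
            elif ev == "entry":
                if open_session is not None:
                    close_session(rec.timestamp, truncated=open_session.fixed)
        if open_session is not None:
            last_t = events[-1].timestamp
            close_session(last_t, truncated=open_session.fixed)

    sessions.sort(key=lambda s: s.start)
    return sessions


@dataclass(frozen=True)
class FrameIndexMap:
    """Mapping from a uniform 30 Hz grid onto (fractional) source frames."""

    grid_times: np.ndarray
    source_indices: np.ndarray  # fractional indices into the source movie

    @property
    def n_ticks(self) -> int:
        return len(self.grid_times)

    def resample(self, frames: np.ndarray) -> np.ndarray:
        """Linear-interpolate a (T, ...) array onto the uniform grid."""
        idx = self.source_indices
        lo = np.floor(idx).astype(int)
        hi = np.minimum(lo + 1, frames.shape[0] - 1)
        w = (idx - lo).reshape((-1,) + (1,) * (frames.ndim - 1))
        return (1.0 - w) * frames[lo] + w * frames[hi]


def align_timebase(
    session: HeadfixSession,
    frame_times: Sequence[float],
    frame_rate: float = 30.0,
) -> FrameIndexMap:
    """Map a uniform 30 Hz grid between the LED-on/off marks to source frames.

    Camera clocks drift slightly; the acquisition-time frame timestamps are
    linearly interpolated so downstream analysis sees an exact 30 Hz
    timebase anchored on the ``BrainLEDON``/``BrainLEDOFF`` events.
    """
    if session.led_on is None or session.led_off is None:
        raise ValueError("session lacks LED on/off anchors")
    ft = np.asarray(frame_times, dtype=float)
    if ft.ndim != 1 or len(ft) < 2:
        raise ValueError("need at least two frame times")
    if not np.all(np.diff(ft) > 0):
        raise ValueError("frame_times must be strictly increasing")
    if ft[-1] <= session.led_on or ft[0] >= session.led_off:
        raise ValueError("frames lie entirely outside the LED window")
    n = int(round((session.led_off - session.led_on) * frame_rate))
    grid = session.led_on + np.arange(n) / frame_rate
    indices = np.interp(grid, ft, np.arange(len(ft), dtype=float))
    return FrameIndexMap(grid_times=grid, source_indices=indices)


def movie_filename(tag: str, timestamp: float) -> str:
    """Raw-movie naming convention: ``RFIDtag_<tag>_<timestamp>.raw``."""
    return f"RFIDtag_{tag}_{timestamp:.2f}.raw"


def parse_movie_filename(name: str) -> tuple[str, float]:
    stem = name[:-4] if name.endswith(".raw") else name
    parts = stem.split("_")
    if len(parts) != 3 or parts[0] != "RFIDtag":
        raise ValueError(f"not a movie filename: {name!r}")
    return parts[1], float(parts[2])
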
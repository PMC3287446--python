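"""Usage-event streams: parsing, bounce filtering, sessions, raw counts.

The event vocabulary follows the data-portal log structure: *search* and
*view* events touch records and measure interest; *download* and
*taxonomy_download* events measure usage; *metadata_view* events touch no
records and are treated as bounces, excluded from every indicator.

Sessions are reconstructed per anonymized visitor key with the standard
30-minute inactivity rule: a gap of at least 30 minutes starts a new
session, and any session after a visitor's first is a *loyal* one.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import UnknownUnitError, ValidationError
from .registry import AnalysisWindow, Registry, Unit

__all__ = [
    "EVENT_TYPES",
    "SEARCH_TYPES",
    "DOWNLOAD_TYPES",
    "UsageEvent",
    "Session",
    "EventCounts",
    "ParseError",
    "ParseResult",
    "parse_events",
    "filter_bounces",
    "sessionize",
    "count_events",
]

SEARCH_TYPES = frozenset({"search", "view"})
DOWNLOAD_TYPES = frozenset({"download", "taxonomy_download"})
EVENT_TYPES = SEARCH_TYPES | DOWNLOAD_TYPES | {"metadata_view"}


@dataclass(frozen=True)
class UsageEvent:
    """One log line: a visitor touched records of a dataset at an instant."""

    timestamp: datetime
    ip_key: str
    event_type: str
    dataset_id: Optional[str]
    records_touched: int = 0
    record_ids: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValidationError(f"unknown event_type {self.event_type!r}")
        if self.records_touched < 0:
            raise ValidationError("records_touched < 0")
        if self.event_type == "metadata_view" and self.records_touched != 0:
            raise ValidationError("metadata_view must touch 0 records")
        if (
            self.record_ids is not None
            and len(self.record_ids) != self.records_touched
        ):
            raise ValidationError(
                f"|record_ids| ({len(self.record_ids)}) != records_touched "
                f"({self.records_touched})"
            )
        ts = self.timestamp
        if ts.tzinfo is None:
            ts = ts.replace(tzinfo=timezone.utc)
        else:
            ts = ts.astimezone(timezone.utc)
        object.__setattr__(self, "timestamp", ts)


@dataclass(frozen=True)
class Session:
    """A maximal run of one visitor's events with gaps under the threshold."""

    ip_key: str
    start: datetime
    end: datetime
    events: tuple[UsageEvent, ...]
    loyal: bool


@dataclass(frozen=True)
class EventCounts:
    """Raw per-unit, per-window counts feeding the indicator formulas.

    s and S are searched records / search events (interest); d and D are
    downloaded records / download events (usage, incl. taxonomy downloads);
    U and I are unique downloaded / searched record counts, None when the
    log carries no record ids; n is the number of member datasets with at
    least one event.
    """

    unit_id: str
    window: str
    s: int
    d: int
    S: int
    D: int
    n: int
    U: Optional[int] = None
    I: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("s", "d", "S", "D", "n"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} < 0")
        if self.U is not None and self.U > self.d:
            raise ValidationError("U > d")
        if self.I is not None and self.I > self.s:
            raise ValidationError("I > s")


@dataclass(frozen=True)
class ParseError:
    line: int
    message: str
    raw: str = ""


@dataclass
class ParseResult:
    events: list[UsageEvent]
    errors: list[ParseError] = field(default_factory=list)

    def __iter__(self):
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)


_REQUIRED = ["timestamp", "ip_key", "event_type", "records_touched"]


def parse_events(source: str | Path | io.TextIOBase) -> ParseResult:
    """Parse a CSV or JSONL event log into timestamp-ordered events.

    Malformed lines become ParseError records (counted, never silently
    dropped); a missing required column rejects the whole file.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    text = text.strip("\n")
    if not text:
        return ParseResult([])
    first = text.splitlines()[0].lstrip()
    if first.startswith("{"):
        rows, errors = _parse_jsonl(text)
    else:
        rows, errors = _parse_csv(text)

    events: list[UsageEvent] = []
    for line_no, row in rows:
        try:
            events.append(_event_from_row(row))
        except (ValidationError, ValueError, TypeError) as exc:
            errors.append(ParseError(line_no, str(exc), json.dumps(row, default=str)))
    events.sort(key=lambda e: e.timestamp)
    return ParseResult(events, errors)


def _parse_csv(text: str):
    df = pd.read_csv(io.StringIO(text), dtype=str, keep_default_na=False)
    missing = set(_REQUIRED) - set(df.columns)
    if missing:
        raise ValidationError(f"event file missing columns: {sorted(missing)}")
    rows = []
    for i, row in enumerate(df.to_dict("records")):
        rows.append((i + 2, row))  # +2: header line is 1
    return rows, []


def _parse_jsonl(text: str):
    rows, errors = [], []
    for i, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            errors.append(ParseError(i, f"invalid JSON: {exc}", line))
            continue
        missing = set(_REQUIRED) - set(obj)
        if missing:
            errors.append(ParseError(i, f"missing fields: {sorted(missing)}", line))
            continue
        rows.append((i, obj))
    return rows, errors


def _event_from_row(row: dict) -> UsageEvent:
    ts = pd.Timestamp(row["timestamp"])
    if pd.isna(ts):
        raise ValueError(f"unparseable timestamp {row['timestamp']!r}")
    rid = row.get("record_ids")
    if rid in (None, ""):
        record_ids = None
    elif isinstance(rid, str):
        record_ids = frozenset(rid.split(";"))
    else:
        record_ids = frozenset(rid)
    dataset_id = row.get("dataset_id")
    if dataset_id in (None, ""):
        dataset_id = None
    return UsageEvent(
        timestamp=ts.to_pydatetime(),
        ip_key=str(row["ip_key"]),
        event_type=str(row["event_type"]),
        dataset_id=dataset_id,
        records_touched=int(row["records_touched"]),
        record_ids=record_ids,
    )


def filter_bounces(
    events: Sequence[UsageEvent],
) -> tuple[list[UsageEvent], float]:
    """Drop bounce events and report the fraction removed.

    A bounce is a metadata-only visit: any metadata_view event, and any
    search/view event touching zero records. Bounces carry no record usage
    and enter no further calculation.
    """
    def is_bounce(e: UsageEvent) -> bool:
        return e.event_type == "metadata_view" or (
            e.event_type in SEARCH_TYPES and e.records_touched == 0
        )

    kept = [e for e in events if not is_bounce(e)]
    total = len(events)
    fraction = (total - len(kept)) / total if total else 0.0
    return kept, fraction


def sessionize(
    events: Iterable[UsageEvent], gap_minutes: float = 30.0
) -> list[Session]:
    """Group events into per-visitor sessions by the inactivity rule.

    A gap of at least gap_minutes (inclusive — "at least 30 minutes")
    between consecutive events of the same ip_key closes the session. The
    first session of each ip_key has loyal=False; every reappearance is a
    loyal one.
    """
    if gap_minutes <= 0:
        raise ValidationError("gap_minutes must be positive")
    by_ip: dict[str, list[UsageEvent]] = {}
    for e in events:
        by_ip.setdefault(e.ip_key, []).append(e)

    sessions: list[Session] = []
    for ip_key, evs in by_ip.items():
        evs.sort(key=lambda e: e.timestamp)
        run: list[UsageEvent] = []
        n_prior = 0
        for e in evs:
            if run and (
                (e.timestamp - run[-1].timestamp).total_seconds()
                >= gap_minutes * 60.0
            ):
                sessions.append(_close(ip_key, run, loyal=n_prior > 0))
                n_prior += 1
                run = []
            run.append(e)
        if run:
            sessions.append(_close(ip_key, run, loyal=n_prior > 0))
    sessions.sort(key=lambda s: (s.start, s.ip_key))
    return sessions


def _close(ip_key: str, run: list[UsageEvent], loyal: bool) -> Session:
    return Session(
        ip_key=ip_key,
        start=run[0].timestamp,
        end=run[-1].timestamp,
        events=tuple(run),
        loyal=loyal,
    )


def count_events(
    events: Sequence[UsageEvent],
    u: Unit | str,
    window: AnalysisWindow,
    registry: Registry,
) -> EventCounts:
    """Aggregate bounce-filtered events into the unit's raw counts.

    Events are assigned to the half-open window [start, end) by timestamp
    and to the unit by dataset membership. Unique-record counts U and I are
    set unions over record ids and left None (unavailable) whenever any
    contributing event lacks ids.
    """
    unit = registry.unit(u) if isinstance(u, str) else u
    if unit.unit_id not in registry.units:
        raise UnknownUnitError(unit.unit_id)
    members = unit.member_datasets

    s = d = S = D = 0
    searched_ids: set[str] = set()
    downloaded_ids: set[str] = set()
    ids_ok_search = True
    ids_ok_down = True
    used: set[str] = set()
    for e in events:
        if e.dataset_id not in members or e.timestamp not in window:
            continue
        used.add(e.dataset_id)
        if e.event_type in SEARCH_TYPES:
            s += e.records_touched
            S += 1
            if e.record_ids is None:
                ids_ok_search = False
            elif ids_ok_search:
                searched_ids |= e.record_ids
        elif e.event_type in DOWNLOAD_TYPES:
            d += e.records_touched
            D += 1
            if e.record_ids is None:
                ids_ok_down = False
            elif ids_ok_down:
                downloaded_ids |= e.record_ids

    return EventCounts(
        unit_id=unit.unit_id,
        window=window.label,
        s=s,
        d=d,
        S=S,
        D=D,
        n=len(used),
        U=len(downloaded_ids) if ids_ok_down else None,
        I=len(searched_ids) if ids_ok_search else None,
    )
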
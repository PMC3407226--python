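"""Asian dust storm (ADS) event calendars and distributed-lag day classes.

An ADS calendar is an ordered list of disjoint storm events (inclusive date
ranges) inside a study window.  Every study day is assigned exactly one lag
class: ``lag0`` for days inside an event, ``lagK`` (K = 1..7) for the K-th day
after the end of the most recent event, and ``reference`` otherwise.  The lag
classes drive the dust-storm-lag-index (DSLI) dummies of the regression model.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd

__all__ = [
    "AdsEvent",
    "AdsCalendar",
    "LagAssignment",
    "CalendarParseError",
    "CalendarValidationError",
    "N_LAGS",
    "LAG_CLASSES",
    "REFERENCE_CLASS",
    "parse_calendar",
    "calendar_from_dates",
    "count_storm_days",
    "storm_day_fraction",
    "assign_lags",
]

#: Number of post-event lag days carried as indicator classes (lag1..lag7).
N_LAGS = 7

REFERENCE_CLASS = "reference"
LAG_CLASSES = tuple(f"lag{k}" for k in range(N_LAGS + 1)) + (REFERENCE_CLASS,)

_DASHES = "–—−-"  # en dash, em dash, minus, hyphen
_ENTRY_RE = re.compile(
    rf"^\s*(\d{{1,2}})/(\d{{1,2}})\s*(?:[{_DASHES}]\s*(\d{{1,2}})/(\d{{1,2}})\s*)?$"
)


class CalendarParseError(ValueError):
    """A date-list row could not be parsed; message carries the row context."""


class CalendarValidationError(ValueError):
    """Parsed dates violate the calendar invariants (window, overlap)."""


@dataclass(frozen=True, order=True)
class AdsEvent:
    """One dust storm event: a maximal run of consecutive storm days."""

    start_date: date
    end_date: date

    def __post_init__(self) -> None:
        if self.start_date > self.end_date:
            raise CalendarValidationError(
                f"event start {self.start_date} after end {self.end_date}"
            )

    @property
    def n_days(self) -> int:
        return (self.end_date - self.start_date).days + 1

    def days(self) -> list[date]:
        return [self.start_date + timedelta(d) for d in range(self.n_days)]

    def __contains__(self, d: date) -> bool:
        return self.start_date <= d <= self.end_date


@dataclass(frozen=True)
class AdsCalendar:
    """Ordered, disjoint ADS events within an inclusive study window."""

    events: tuple[AdsEvent, ...]
    study_start: date
    study_end: date

    def __post_init__(self) -> None:
        if self.study_start > self.study_end:
            raise CalendarValidationError("empty study window")
        prev_end: date | None = None
        for ev in self.events:
            if ev.start_date < self.study_start or ev.end_date > self.study_end:
                raise CalendarValidationError(
                    f"event {ev.start_date}..{ev.end_date} outside study window "
                    f"{self.study_start}..{self.study_end}"
                )
            if prev_end is not None and ev.start_date <= prev_end + timedelta(1):
                raise CalendarValidationError(
                    f"events not separated by a non-storm day near {ev.start_date}"
                )
            prev_end = ev.end_date

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def window_days(self) -> int:
        """Inclusive calendar length of the study window in days."""
        return (self.study_end - self.study_start).days + 1

    def storm_days(self) -> list[date]:
        out: list[date] = []
        for ev in self.events:
            out.extend(ev.days())
        return out


@dataclass(frozen=True)
class LagAssignment:
    """Lag class for every day of the study window.

    ``classes`` is a pandas Series indexed by day (datetime index, one entry
    per study day) with values in :data:`LAG_CLASSES`.
    """

    classes: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        bad = set(self.classes.unique()) - set(LAG_CLASSES)
        if bad:
            raise ValueError(f"unknown lag classes {sorted(bad)}")

    def counts(self) -> dict[str, int]:
        vc = self.classes.value_counts()
        return {c: int(vc.get(c, 0)) for c in LAG_CLASSES}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"date": self.classes.index.date, "lag_class": self.classes.to_numpy()}
        )

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False)


def _expand_entry(entry: str, year: int, row_context: str) -> list[date]:
    m = _ENTRY_RE.match(entry)
    if not m:
        raise CalendarParseError(f"malformed entry {entry!r} in row {row_context!r}")
    m1, d1 = int(m.group(1)), int(m.group(2))
    try:
        start = date(year, m1, d1)
        if m.group(3) is None:
            end = start
        else:
            end = date(year, int(m.group(3)), int(m.group(4)))
    except ValueError as exc:
        raise CalendarParseError(
            f"invalid date in entry {entry!r} of row {row_context!r}: {exc}"
        ) from exc
    if end < start:
        raise CalendarParseError(
            f"descending range {entry!r} in row {row_context!r}"
        )
    return [start + timedelta(d) for d in range((end - start).days + 1)]


def calendar_from_dates(
    days: Iterable[date], study_start: date, study_end: date
) -> AdsCalendar:
    """Merge a set of storm days into maximal consecutive-run events."""
    uniq = sorted(set(days))
    events: list[AdsEvent] = []
    run_start: date | None = None
    prev: date | None = None
    for d in uniq:
        if run_start is None:
            run_start = prev = d
            continue
        if (d - prev).days == 1:
            prev = d
        else:
            events.append(AdsEvent(run_start, prev))
            run_start = prev = d
    if run_start is not None:
        events.append(AdsEvent(run_start, prev))
    return AdsCalendar(tuple(events), study_start, study_end)


def parse_calendar(
    source: Union[str, Path, io.TextIOBase, Mapping[int, str]],
    study_start: date,
    study_end: date,
) -> AdsCalendar:
    """Parse a year/date-list file into an :class:`AdsCalendar`.

    Each non-comment line reads ``year,entries`` where ``entries`` is a
    comma-separated list of ``M/D`` days or inclusive ``M/D-M/D`` ranges
    (any common dash accepted).  Consecutive storm days are merged into a
    single event, including across month boundaries and across separately
    listed entries.  A mapping ``{year: entries}`` is accepted directly.

    Raises :class:`CalendarParseError` for malformed entries and
    :class:`CalendarValidationError` for duplicate dates or dates outside
    the study window.
    """
    if isinstance(source, Mapping):
        rows = [(int(y), entries) for y, entries in source.items()]
    else:
        if isinstance(source, (str, Path)):
            text = Path(source).read_text()
        else:
            text = source.read()
        rows = []
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            year_str, sep, entries = line.partition(",")
            if not sep:
                raise CalendarParseError(f"line {lineno}: missing ',' in {line!r}")
            try:
                year = int(year_str.strip())
            except ValueError as exc:
                raise CalendarParseError(
                    f"line {lineno}: bad year {year_str!r}"
                ) from exc
            rows.append((year, entries))

    all_days: list[date] = []
    seen: set[date] = set()
    for year, entries in rows:
        context = f"{year}"
        for entry in entries.split(","):
            if not entry.strip():
                continue
            for d in _expand_entry(entry.strip(), year, context):
                if d in seen:
                    raise CalendarValidationError(
                        f"duplicate/overlapping storm day {d} in row {context!r}"
                    )
                if not (study_start <= d <= study_end):
                    raise CalendarValidationError(
                        f"storm day {d} outside study window "
                        f"{study_start}..{study_end} (row {context!r})"
                    )
                seen.add(d)
                all_days.append(d)
    return calendar_from_dates(all_days, study_start, study_end)


def count_storm_days(cal: AdsCalendar) -> int:
    """Size of the union of all event day-sets."""
    return sum(ev.n_days for ev in cal.events)


def storm_day_fraction(cal: AdsCalendar) -> float:
    """Storm days as a percentage of the inclusive study-window length."""
    return 100.0 * count_storm_days(cal) / cal.window_days


def assign_lags(cal: AdsCalendar) -> LagAssignment:
    """Classify every study day into lag0..lag7 or the reference class.

    Event days are lag0 regardless of proximity to an earlier event's end;
    a non-event day K days (1 <= K <= 7) after the end of its most recent
    event is lagK (ties broken toward the smallest lag, i.e. the most recent
    exposure); all remaining days are the reference class.
    """
    index = pd.date_range(cal.study_start, cal.study_end, freq="D")
    classes = pd.Series(REFERENCE_CLASS, index=index, dtype=object)
    # lag days first (later events overwrite with smaller lags), storms last
    for ev in cal.events:
        for k in range(N_LAGS, 0, -1):
            d = ev.end_date + timedelta(k)
            if d > cal.study_end:
                continue
            ts = pd.Timestamp(d)
            current = classes.at[ts]
            if current == REFERENCE_CLASS or (
                current.startswith("lag") and int(current[3:]) > k
            ):
                classes.at[ts] = f"lag{k}"
    for ev in cal.events:
        for d in ev.days():
            classes.at[pd.Timestamp(d)] = "lag0"
    return LagAssignment(classes)
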
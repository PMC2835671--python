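"""Pooling of adverse-event rates reported across published case series.

Each case series reports, per adverse-event type, either a single
proportion, a low-high range (e.g. when two reports of the same cohort
give different figures), or nothing.  Pooling follows the rule used to
build the model's base-case inputs: the plausible range for an event is
the minimum and maximum over every reported value (range reports
contribute both endpoints) across non-excluded series, and the base-case
rate is the midpoint of that range.

Values judged to be outliers are excluded per study and per event via an
explicit flag, never by an automatic rule.
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

logger = logging.getLogger(__name__)

#: Canonical adverse-event categories, in fixed model order.
EVENT_TYPES: tuple[str, ...] = (
    "anastomotic_leak",
    "wound_infection",
    "dvt",
    "return_to_theatre",
    "respiratory",
    "death_30d",
)


class NoEvidenceError(ValueError):
    """No non-excluded series reports the requested event type."""


class StudyTableParseError(ValueError):
    """A cell of the study table could not be interpreted."""


@dataclass(frozen=True)
class StudySeries:
    """One published case series of colorectal-cancer surgeries.

    ``rates`` maps event types to ``(low, high)`` proportion pairs; a
    single reported value is stored as a degenerate pair.
    ``excluded_events`` lists event types whose value this series does
    report but which are flagged as outliers and skipped in pooling.
    """

    label: str
    n_cases: int
    rates: Mapping[str, tuple[float, float]]
    excluded_events: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError(f"{self.label}: n_cases must be >= 1, got {self.n_cases}")
        for event, (low, high) in self.rates.items():
            if event not in EVENT_TYPES:
                raise ValueError(f"{self.label}: unknown event type {event!r}")
            if not (0.0 <= low <= high <= 1.0):
                raise ValueError(
                    f"{self.label}/{event}: rates must satisfy 0 <= low <= high <= 1, "
                    f"got ({low}, {high})"
                )


@dataclass(frozen=True)
class EventRateSummary:
    """Pooled low/high/midpoint for one event type (proportions)."""

    event_type: str
    low: float
    high: float
    midpoint: float

    def __post_init__(self) -> None:
        if not (self.low <= self.midpoint <= self.high):
            raise ValueError("midpoint must lie inside [low, high]")

    @property
    def midpoint_percent_display(self) -> str:
        """Midpoint as percent, rounded half-up to one decimal."""
        return display_percent(self.midpoint)


def display_percent(proportion: float) -> str:
    """Render a proportion as a percentage rounded half-up to 1 dp.

    Half-up (4.35 -> 4.4) matches how the pooled base-case means are
    presented; internal computation always stays unrounded.
    """
    return str(
        Decimal(f"{proportion * 100:.6f}").quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    )


def pool_event_rates(series: Sequence[StudySeries], event_type: str) -> EventRateSummary:
    """Pool an event's reported rates into a low/high/midpoint summary.

    The low (high) is the minimum (maximum) over all reported values of
    all non-excluded series; range reports contribute both endpoints.
    The midpoint is exactly ``(low + high) / 2``.

    Raises
    ------
    NoEvidenceError
        If no non-excluded series reports ``event_type``.
    """
    if event_type not in EVENT_TYPES:
        raise ValueError(f"unknown event type {event_type!r}; valid: {EVENT_TYPES}")
    values: list[float] = []
    for s in series:
        if event_type in s.excluded_events:
            continue
        pair = s.rates.get(event_type)
        if pair is not None:
            values.extend(pair)
    if not values:
        raise NoEvidenceError(f"no evidence for event type {event_type!r}")
    low, high = min(values), max(values)
    return EventRateSummary(event_type=event_type, low=low, high=high, midpoint=(low + high) / 2)


def pool_all_events(series: Sequence[StudySeries]) -> dict[str, EventRateSummary]:
    """Pool every event type that at least one series reports."""
    out: dict[str, EventRateSummary] = {}
    for event in EVENT_TYPES:
        try:
            out[event] = pool_event_rates(series, event)
        except NoEvidenceError:
            logger.info("no evidence for %s; skipped", event)
    return out


# ---------------------------------------------------------------------------
# Study-table I/O.
#
# Delimited text, ';' (or ',' / tab) separated, header row:
#   label;n_cases;<event type>;...
# Cells hold a percentage ("8.2"), a range ("0.5-1.1"), "ns" or blank for
# not reported, and a trailing "!" to flag the value as an excluded outlier.
# ---------------------------------------------------------------------------

_MISSING = {"", "ns", "n/a", "na"}


def _parse_cell(cell: str, *, row: str, column: str) -> tuple[tuple[float, float] | None, bool]:
    """Return ((low, high) proportions or None, excluded_flag)."""
    text = cell.strip()
    excluded = text.endswith("!")
    if excluded:
        text = text[:-1].strip()
    if text.lower() in _MISSING:
        if excluded:
            raise StudyTableParseError(f"row {row!r}, column {column!r}: exclusion flag on empty cell")
        return None, False
    try:
        # Decimal division keeps "8.2" -> 0.082 exact to the nearest float
        if "-" in text:
            lo_s, hi_s = text.split("-", 1)
            lo = float(Decimal(lo_s.strip()) / 100)
            hi = float(Decimal(hi_s.strip()) / 100)
        else:
            lo = hi = float(Decimal(text) / 100)
    except ArithmeticError as exc:
        raise StudyTableParseError(f"row {row!r}, column {column!r}: cannot parse {cell!r}") from exc
    if not (0.0 <= lo <= hi <= 1.0):
        raise StudyTableParseError(
            f"row {row!r}, column {column!r}: value out of [0, 100]% or inverted range: {cell!r}"
        )
    return (lo, hi), excluded


def _detect_delimiter(header: str) -> str:
    for delim in (";", "\t", ","):
        if delim in header:
            return delim
    raise StudyTableParseError("cannot detect delimiter in header row")


def loads_study_table(text: str) -> list[StudySeries]:
    """Parse a study table from a string (see module docstring for format)."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        return []
    delim = _detect_delimiter(lines[0])
    reader = csv.reader(io.StringIO("\n".join(lines)), delimiter=delim)
    header = [h.strip() for h in next(reader)]
    if len(header) < 2 or header[0] != "label" or header[1] != "n_cases":
        raise StudyTableParseError("header must start with 'label;n_cases' then event-type columns")
    events = header[2:]
    for ev in events:
        if ev not in EVENT_TYPES:
            raise StudyTableParseError(f"unknown event-type column {ev!r}; valid: {EVENT_TYPES}")
    series: list[StudySeries] = []
    for rownum, row in enumerate(reader, start=2):
        if not any(cell.strip() for cell in row):
            continue
        if len(row) != len(header):
            raise StudyTableParseError(f"row {rownum}: expected {len(header)} cells, got {len(row)}")
        label = row[0].strip()
        try:
            n_cases = int(row[1].strip())
        except ValueError as exc:
            raise StudyTableParseError(f"row {label!r}, column 'n_cases': {row[1]!r}") from exc
        rates: dict[str, tuple[float, float]] = {}
        excluded: set[str] = set()
        for col, cell in zip(events, row[2:]):
            pair, is_excluded = _parse_cell(cell, row=label, column=col)
            if pair is not None:
                rates[col] = pair
                if is_excluded:
                    excluded.add(col)
        series.append(
            StudySeries(label=label, n_cases=n_cases, rates=rates, excluded_events=frozenset(excluded))
        )
    return series


def load_study_table(path: str | Path) -> list[StudySeries]:
    """Read a delimited study table from ``path``."""
    return loads_study_table(Path(path).read_text())


def dumps_study_table(series: Sequence[StudySeries]) -> str:
    """Serialize series to the ';'-delimited study-table format."""

    def pct(p: float) -> str:
        # exact decimal percent so that write-then-read is the identity
        text = format(Decimal(repr(p)) * 100, "f")
        return text.rstrip("0").rstrip(".") if "." in text else text

    def fmt(pair: tuple[float, float], excluded: bool) -> str:
        lo, hi = pair
        body = pct(lo) if lo == hi else f"{pct(lo)}-{pct(hi)}"
        return body + ("!" if excluded else "")

    lines = ["label;n_cases;" + ";".join(EVENT_TYPES)]
    for s in series:
        cells = [s.label, str(s.n_cases)]
        for ev in EVENT_TYPES:
            pair = s.rates.get(ev)
            cells.append("ns" if pair is None else fmt(pair, ev in s.excluded_events))
        lines.append(";".join(cells))
    return "\n".join(lines) + "\n"


def save_study_table(series: Sequence[StudySeries], path: str | Path) -> None:
    Path(path).write_text(dumps_study_table(series))


def default_study_table_path() -> Path:
    """Path of the packaged Australian/NZ colorectal case-series table."""
    return Path(__file__).parent / "data" / "study_series.csv"


def load_default_study_table() -> list[StudySeries]:
    """The packaged eleven-series Australian/NZ evidence table."""
    return load_study_table(default_study_table_path())
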
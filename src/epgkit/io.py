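"""Reading, validating and writing EPG waveform-annotation files.

An annotation file is the output of manual waveform annotation of an
electrical penetration graph (EPG) recording: an ordered list of
(waveform code, onset seconds) pairs covering one insect's recording.
The seven behavioral waveforms are:

====  =========================================================
code  behavior
====  =========================================================
np    non-probing (stylet out of the plant)
C     stylet pathway through plant tissue
pd    potential drop (brief intracellular puncture during C)
E1    phloem salivation
E2    phloem sap ingestion
F     derailed stylet mechanics (penetration difficulty)
G     xylem sap ingestion
====  =========================================================

The canonical file dialect is two delimited columns (code, onset in
seconds), rows sorted by onset, first onset 0, with an optional terminal
``end`` row carrying the recording duration.  Tab, comma and semicolon
delimiters are accepted on read; tab is written.
"""

from __future__ import annotations

import io as _io
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import pandas as pd

__all__ = [
    "WAVEFORM_CODES",
    "Event",
    "Recording",
    "GrammarViolation",
    "MetadataTable",
    "AnnotationError",
    "normalize_code",
    "read_annotation",
    "write_annotation",
    "validate_grammar",
    "read_metadata",
]

#: The seven legal waveform codes, canonical spelling.
WAVEFORM_CODES: tuple[str, ...] = ("np", "C", "pd", "G", "E1", "E2", "F")

#: 12-hour recording, the standard session length.
DEFAULT_DURATION_S = 43_200.0

#: Display sampling rate of the acquisition hardware (metadata only).
DEFAULT_SAMPLE_RATE_HZ = 100.0

# case-insensitive lookup covering common dialect spellings (NP, Pd, e1, ...)
_CODE_LOOKUP = {c.lower(): c for c in WAVEFORM_CODES}
_CODE_LOOKUP.update({"n": "np", "non-probing": "np", "nonprobing": "np", "z": "np"})

#: Metadata status values; anything else is rejected on read.
STATUS_VALUES = ("completed", "escaped", "excluded_bad_recording")


class AnnotationError(ValueError):
    """Raised for malformed annotation or metadata input."""


def normalize_code(label: str) -> str:
    """Map a waveform label onto its canonical spelling.

    Parsing is case-insensitive (``NP``, ``Pd``, ``e1`` ...).  Raises
    :class:`AnnotationError` for labels outside the seven-code set.
    """
    key = label.strip().lower()
    try:
        return _CODE_LOOKUP[key]
    except KeyError:
        raise AnnotationError(f"unknown label {label!r}") from None


@dataclass(frozen=True)
class Event:
    """One annotated waveform interval ``[start, end)`` in seconds."""

    code: str
    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start

    def __post_init__(self) -> None:
        if self.code not in WAVEFORM_CODES:
            raise AnnotationError(f"unknown waveform code {self.code!r}")
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"invalid event interval [{self.start}, {self.end}) for {self.code}"
            )


@dataclass
class Recording:
    """One insect's fully annotated recording.

    Events are contiguous, non-overlapping, tile ``[0, duration_s]``
    exactly, and no two adjacent events share a code.
    """

    insect_id: str
    events: list[Event]
    duration_s: float = DEFAULT_DURATION_S
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ

    def validate(self) -> None:
        """Raise :class:`AnnotationError` unless all invariants hold."""
        if not self.events:
            raise AnnotationError(f"{self.insect_id}: recording has no events")
        if self.events[0].start != 0:
            raise AnnotationError(f"{self.insect_id}: first event must start at 0")
        if self.events[-1].end != self.duration_s:
            raise AnnotationError(
                f"{self.insect_id}: last event ends at {self.events[-1].end}, "
                f"expected {self.duration_s}"
            )
        for k in range(len(self.events) - 1):
            a, b = self.events[k], self.events[k + 1]
            if a.end != b.start:
                raise AnnotationError(
                    f"{self.insect_id}: events {k} and {k + 1} are not contiguous "
                    f"({a.end} != {b.start})"
                )
            if a.code == b.code:
                raise AnnotationError(
                    f"{self.insect_id}: adjacent events {k} and {k + 1} share "
                    f"code {a.code} (must be merged)"
                )

    def codes(self) -> list[str]:
        return [e.code for e in self.events]

    def total_duration(self, code: str) -> float:
        return sum(e.duration for e in self.events if e.code == code)

    def with_events(self, events: Sequence[Event]) -> "Recording":
        return replace(self, events=list(events))


@dataclass(frozen=True)
class GrammarViolation:
    """One violation of the EPG waveform grammar, reported as data."""

    rule_id: str
    position: int
    message: str
    severity: str  # "error" | "warning"


#: Closed list of grammar rules checked by :func:`validate_grammar`.
GRAMMAR_RULES = {
    "R1": "every E2 must be immediately preceded by E1 or E2",
    "R2": "pd must not be adjacent to np (pd occurs inside probes)",
    "R3": "a probe must not begin with E1/E2 directly from np",
    "R4": "recording must contain at least one np or probe period",
}


def merge_adjacent(events: Iterable[Event]) -> list[Event]:
    """Merge runs of adjacent events sharing a code into single events."""
    merged: list[Event] = []
    for ev in events:
        if merged and merged[-1].code == ev.code and merged[-1].end == ev.start:
            merged[-1] = Event(ev.code, merged[-1].start, ev.end)
        else:
            merged.append(ev)
    return merged


_DELIM_RE = re.compile(r"[\t,;]|\s+")


def _split_line(line: str) -> list[str]:
    return [tok for tok in _DELIM_RE.split(line.strip()) if tok]


def read_annotation(
    source: str | Path | TextIO,
    duration_s: float = DEFAULT_DURATION_S,
    insect_id: str | None = None,
) -> Recording:
    """Parse an annotation file into a validated :class:`Recording`.

    Parameters
    ----------
    source
        Path or open text stream holding two delimited columns:
        waveform label and onset time in seconds, sorted by onset.
        An optional terminal row labeled ``end`` carries the recording
        duration and overrides `duration_s`.  A header row is detected
        (non-numeric second column) and skipped.
    duration_s
        Recording length used when no ``end`` row is present.
    insect_id
        Identifier for the recording; defaults to the file stem.

    Raises
    ------
    AnnotationError
        On empty input, unknown labels, non-monotone onsets, or a first
        onset different from 0.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        text = path.read_text()
        if insect_id is None:
            insect_id = path.name.split(".")[0]
    else:
        text = source.read()
        if insect_id is None:
            insect_id = "recording"

    rows: list[tuple[str, float]] = []
    end_time: float | None = None
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise AnnotationError("empty annotation input")

    for lineno, line in enumerate(lines, start=1):
        toks = _split_line(line)
        if len(toks) < 2:
            raise AnnotationError(f"malformed row at line {lineno}: {line!r}")
        label, onset_tok = toks[0], toks[1]
        try:
            onset = float(onset_tok)
        except ValueError:
            if lineno == 1:  # header row
                continue
            raise AnnotationError(
                f"non-numeric onset {onset_tok!r} at line {lineno}"
            ) from None
        if label.strip().lower() == "end":
            end_time = onset
            continue
        if end_time is not None:
            raise AnnotationError(f"rows after 'end' marker at line {lineno}")
        try:
            code = normalize_code(label)
        except AnnotationError:
            raise AnnotationError(f"unknown label {label} at line {lineno}") from None
        rows.append((code, onset))

    if not rows:
        raise AnnotationError("annotation contains no waveform rows")
    if rows[0][1] != 0:
        raise AnnotationError(f"first onset must be 0, got {rows[0][1]}")
    for k in range(len(rows) - 1):
        if rows[k + 1][1] <= rows[k][1]:
            raise AnnotationError(
                f"non-monotone onsets: {rows[k][1]} then {rows[k + 1][1]}"
            )

    total = end_time if end_time is not None else duration_s
    if rows[-1][1] >= total:
        raise AnnotationError(
            f"last onset {rows[-1][1]} is not before the recording end {total}"
        )

    events = []
    for k, (code, onset) in enumerate(rows):
        end = rows[k + 1][1] if k + 1 < len(rows) else total
        events.append(Event(code, onset, end))
    rec = Recording(insect_id=insect_id, events=merge_adjacent(events), duration_s=total)
    rec.validate()
    return rec


def write_annotation(rec: Recording, sink: str | Path | TextIO) -> None:
    """Write a Recording in the canonical dialect.

    Tab-separated, canonical code spellings, onsets with at most two
    decimal places, terminal ``end`` row.  Refuses to write an invalid
    Recording; ``read_annotation`` of the output reproduces `rec`.
    """
    rec.validate()

    def fmt(t: float) -> str:
        s = f"{t:.2f}".rstrip("0").rstrip(".")
        return s if s else "0"

    buf = _io.StringIO()
    for ev in rec.events:
        buf.write(f"{ev.code}\t{fmt(ev.start)}\n")
    buf.write(f"end\t{fmt(rec.duration_s)}\n")
    payload = buf.getvalue()
    if isinstance(sink, (str, Path)):
        Path(sink).write_text(payload)
    else:
        sink.write(payload)


def validate_grammar(rec: Recording) -> list[GrammarViolation]:
    """Check a Recording against the EPG waveform grammar.

    Rules (violations are returned as data, never raised):

    * R1 (error): every phloem ingestion (E2) event is immediately
      preceded by phloem salivation (E1) or another E2 segment.
    * R2 (error): potential drops (pd) occur inside probes, never
      adjacent to non-probing (np).
    * R3 (warning): a probe should not open with phloem phase (E1/E2)
      straight from np — phloem is reached through pathway.
    * R4 (error): the recording contains at least one waveform period.
    """
    rec.validate()
    out: list[GrammarViolation] = []
    codes = rec.codes()
    if not codes:
        out.append(GrammarViolation("R4", 0, GRAMMAR_RULES["R4"], "error"))
        return out
    for i, code in enumerate(codes):
        prev = codes[i - 1] if i > 0 else None
        nxt = codes[i + 1] if i + 1 < len(codes) else None
        if code == "E2" and prev not in ("E1", "E2"):
            out.append(
                GrammarViolation(
                    "R1", i, f"E2 at index {i} not preceded by E1 (found {prev})", "error"
                )
            )
        if code == "pd" and (prev in (None, "np") or nxt in (None, "np")):
            out.append(
                GrammarViolation(
                    "R2", i, f"pd at index {i} adjacent to np or recording edge", "error"
                )
            )
        if code in ("E1", "E2") and prev == "np":
            out.append(
                GrammarViolation(
                    "R3", i, f"probe at index {i} begins with {code} directly from np",
                    "warning",
                )
            )
    return out


@dataclass
class MetadataTable:
    """Experiment metadata: one row per wired insect.

    Required columns: ``insect_id``, ``file``, ``status`` plus at least
    one group factor (host plant, whitefly species, wire type ...).
    """

    frame: pd.DataFrame
    factors: list[str] = field(default_factory=list)

    def completed(self) -> pd.DataFrame:
        return self.frame[self.frame["status"] == "completed"]

    def __len__(self) -> int:
        return len(self.frame)


def read_metadata(
    source: str | Path | TextIO, factors: Sequence[str] | None = None
) -> MetadataTable:
    """Read the experiment metadata CSV into a typed table.

    `factors` names the grouping columns; by default every extra column
    beyond insect_id/file/status is treated as a factor.
    """
    df = pd.read_csv(source, dtype=str).rename(columns=str.strip)
    required = {"insect_id", "file", "status"}
    missing = required - set(df.columns)
    if missing:
        raise AnnotationError(f"metadata missing required column(s): {sorted(missing)}")
    if df["insect_id"].duplicated().any():
        dupes = df.loc[df["insect_id"].duplicated(), "insect_id"].tolist()
        raise AnnotationError(f"duplicate insect_id values: {dupes}")
    bad = ~df["status"].isin(STATUS_VALUES)
    if bad.any():
        raise AnnotationError(
            f"status value(s) outside {STATUS_VALUES}: "
            f"{sorted(df.loc[bad, 'status'].unique())}"
        )
    if factors is None:
        factors = [c for c in df.columns if c not in required]
    else:
        absent = set(factors) - set(df.columns)
        if absent:
            raise AnnotationError(f"factor column(s) not in metadata: {sorted(absent)}")
    return MetadataTable(frame=df, factors=list(factors))
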
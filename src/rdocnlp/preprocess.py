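"""Note ingestion, sentence segmentation and keyword matching.

Clinical notes are not standard prose: they are dense with abbreviations
("Dr.", "pt.", "q.d."), hard line breaks and list fragments. The segmenter
here is a deterministic rule-based splitter tuned for that register —
determinism makes every downstream offset reproducible and testable, which a
model-based splitter cannot guarantee.

Keyword matching is the single source of truth for the inflection rule used
throughout the package: a dictionary lemma matches a surface token
case-insensitively at word boundaries under the fixed suffix set
``{"", "s", "es", "ed", "ing"}``. A fixed suffix set (rather than a stemmer)
keeps every match explainable: "stressed" matches lemma "stress",
"distress" does not (word boundary), "anxieties" does not ("anxiety" +
suffix never yields it).

All coordinates are 0-based, half-open.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Iterator, Sequence

if TYPE_CHECKING:  # pragma: no cover
    from .dictionaries import KeywordEntry

logger = logging.getLogger(__name__)

#: Inflectional suffixes considered equivalent to the bare lemma.
INFLECTION_SUFFIXES: tuple[str, ...] = ("", "s", "es", "ed", "ing")

#: Abbreviations whose trailing period never ends a sentence.
_PROTECTED_ABBREVS = (
    "dr", "mr", "mrs", "ms", "pt", "pts", "vs", "etc", "e.g", "i.e",
    "q.d", "b.i.d", "t.i.d", "q.i.d", "p.r.n", "a.m", "p.m",
    "st", "jr", "sr", "approx", "no",
)


@dataclass(frozen=True)
class ClinicalNote:
    """One free-text clinical note tied to a patient and a calendar date."""

    patient_id: str
    note_id: str
    date: date
    text: str

    def __post_init__(self) -> None:
        if not self.patient_id or not self.note_id:
            raise ValueError("patient_id and note_id must be non-empty")


@dataclass(frozen=True)
class SentenceSpan:
    """A segmented sentence with character offsets into its note's text.

    ``start``/``end`` are 0-based half-open offsets; ``text`` is exactly
    ``note.text[start:end]``.
    """

    note_id: str
    index: int
    start: int
    end: int
    text: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span offsets [{self.start}, {self.end})")
        if len(self.text) != self.end - self.start:
            raise ValueError("span text length inconsistent with offsets")


@dataclass(frozen=True)
class KeywordMatch:
    """A dictionary lemma located inside a sentence.

    ``surface`` is the matched surface form; ``start``/``end`` are offsets
    within the sentence (not the note).
    """

    term: str
    surface: str
    start: int
    end: int


# ---------------------------------------------------------------------------
# Note ingestion
# ---------------------------------------------------------------------------

REQUIRED_NOTE_FIELDS = ("patient_id", "note_id", "date", "text")


@dataclass
class ReadStats:
    """Bookkeeping for a streaming read: rows seen, skipped, and why."""

    total_rows: int = 0
    skipped: int = 0
    reasons: dict = field(default_factory=dict)

    def skip(self, reason: str) -> None:
        self.skipped += 1
        self.reasons[reason] = self.reasons.get(reason, 0) + 1


def _row_to_note(row: dict) -> ClinicalNote:
    missing = [k for k in REQUIRED_NOTE_FIELDS if not row.get(k)]
    if missing:
        raise ValueError(f"missing field(s): {', '.join(missing)}")
    return ClinicalNote(
        patient_id=str(row["patient_id"]),
        note_id=str(row["note_id"]),
        date=date.fromisoformat(str(row["date"])),
        text=str(row["text"]),
    )


def read_notes(path: str | Path, stats: ReadStats | None = None) -> Iterator[ClinicalNote]:
    """Stream clinical notes from a JSONL or CSV file (constant memory).

    The format is chosen by extension (``.jsonl``/``.json`` vs ``.csv``).
    Malformed rows (missing ids, unparseable dates) are logged and skipped;
    pass a :class:`ReadStats` to collect skip counts. An unreadable file is
    fatal.
    """
    path = Path(path)
    stats = stats if stats is not None else ReadStats()
    if path.suffix.lower() == ".csv":
        rows: Iterable[dict] = _iter_csv_rows(path)
    else:
        rows = _iter_jsonl_rows(path, stats)
    for row in rows:
        stats.total_rows += 1
        try:
            yield _row_to_note(row)
        except ValueError as exc:
            logger.warning("skipping row %d: %s", stats.total_rows, exc)
            stats.skip(str(exc))


def _iter_csv_rows(path: Path) -> Iterator[dict]:
    with path.open(newline="", encoding="utf-8") as fh:
        yield from csv.DictReader(fh)


def _iter_jsonl_rows(path: Path, stats: ReadStats) -> Iterator[dict]:
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                yield json.loads(line)
            except json.JSONDecodeError as exc:
                logger.warning("skipping malformed JSON on line %d: %s", lineno, exc)
                stats.total_rows += 1
                stats.skip("malformed json")


def write_notes_jsonl(notes: Iterable[ClinicalNote], path: str | Path) -> int:
    """Write notes as one JSON object per line; returns the row count."""
    n = 0
    with Path(path).open("w", encoding="utf-8") as fh:
        for note in notes:
            fh.write(json.dumps({
                "patient_id": note.patient_id,
                "note_id": note.note_id,
                "date": note.date.isoformat(),
                "text": note.text,
            }, ensure_ascii=False))
            fh.write("\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# Sentence segmentation
# ---------------------------------------------------------------------------

_ABBREV_RE = re.compile(
    r"(?:^|[\s(])(" + "|".join(re.escape(a) for a in _PROTECTED_ABBREVS) + r")\.$",
    re.IGNORECASE,
)

# Candidate boundary: terminal punctuation followed by whitespace, or a hard
# line break followed by a capitalized/numbered token (common in note lists).
_BOUNDARY_RE = re.compile(
    r"(?:[.!?]+[\"')\]]?(?=\s))|(?:\n+(?=\s*[A-Z0-9]))"
)


def segment(note: ClinicalNote) -> list[SentenceSpan]:
    """Split a note into ordered, non-overlapping sentence spans.

    The spans cover all non-whitespace content of the note: reconstructing
    the text from spans plus the inter-span gaps reproduces the original
    byte-for-byte. Empty text yields an empty list; text without any split
    point yields a single span.
    """
    text = note.text
    if not text.strip():
        return []

    cut_points: list[int] = []
    for m in _BOUNDARY_RE.finditer(text):
        end = m.end()
        # Protect known clinical abbreviations: "seen by Dr. Smith" is one
        # sentence even though "Dr." looks terminal.
        prefix = text[: end].rstrip()
        if prefix.endswith(".") and _ABBREV_RE.search(prefix[-12:]):
            continue
        cut_points.append(end)

    spans: list[SentenceSpan] = []
    prev = 0
    for cut in cut_points + [len(text)]:
        chunk = text[prev:cut]
        stripped = chunk.strip()
        if stripped:
            # strip() removes only leading/trailing whitespace, so the
            # trimmed offsets are arithmetic
            start = prev + (len(chunk) - len(chunk.lstrip()))
            end = start + len(chunk.strip())
            spans.append(SentenceSpan(
                note_id=note.note_id,
                index=len(spans),
                start=start,
                end=end,
                text=text[start:end],
            ))
        prev = cut
    return spans


# ---------------------------------------------------------------------------
# Keyword matching
# ---------------------------------------------------------------------------


def _term_pattern(term: str) -> re.Pattern:
    """Word-boundary regex matching a lemma and its inflectional variants.

    Multi-word terms inflect on the final token only ("chronic stress" →
    "chronic stressed" would be odd but harmless; boundaries still apply).
    """
    escaped = re.escape(term)
    suffix_alt = "(?:" + "|".join(s for s in INFLECTION_SUFFIXES if s) + ")?"
    return re.compile(r"(?<![A-Za-z0-9])" + escaped + suffix_alt + r"(?![A-Za-z0-9])",
                      re.IGNORECASE)


_PATTERN_CACHE: dict[str, re.Pattern] = {}


def match_terms(text: str, terms: Sequence[str]) -> list[KeywordMatch]:
    """Find all non-overlapping hits of dictionary lemmas in ``text``.

    Matching is case-insensitive at word boundaries under the fixed suffix
    rule. Overlapping candidates are resolved leftmost-longest; the returned
    matches are sorted by start offset.
    """
    candidates: list[KeywordMatch] = []
    for term in terms:
        pat = _PATTERN_CACHE.get(term)
        if pat is None:
            pat = _PATTERN_CACHE[term] = _term_pattern(term)
        for m in pat.finditer(text):
            candidates.append(KeywordMatch(term=term, surface=m.group(0),
                                           start=m.start(), end=m.end()))
    # leftmost-longest, then lexicographic term for full determinism
    candidates.sort(key=lambda k: (k.start, -(k.end - k.start), k.term))
    out: list[KeywordMatch] = []
    occupied_until = -1
    for cand in candidates:
        if cand.start > occupied_until:
            out.append(cand)
            occupied_until = cand.end - 1
    return out


def match_keywords(span: SentenceSpan | str,
                   keywords: Sequence["KeywordEntry"]) -> list[KeywordMatch]:
    """Locate validated dictionary keywords in a sentence span (or raw text)."""
    text = span.text if isinstance(span, SentenceSpan) else span
    return match_terms(text, [k.term for k in keywords])
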
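"""Data model, I/O, validation and iterative merging of RDoC dictionaries.

A dictionary has two layers: a *keyword* list (lowercase lemmas, each tagged
with one or more RDoC domains and an optional construct such as "acute
threat") and a *sentence* list (domain-labeled example sentences curated by
subject-matter experts). The sentence layer supplies the reference side of
every cosine comparison; the keyword layer supplies the gate — a note
sentence is only compared against dictionary sentences that share a matched
keyword. Because classification gates on a shared keyword, every dictionary
sentence must itself contain at least one keyword under the package-wide
matching rule (:func:`rdocnlp.preprocess.match_terms`).

File dialects
-------------
CSV (SME-editable): a directory holding ``keywords.csv`` with columns
``term, domains, construct`` and ``sentences.csv`` with columns
``id, text, domains, construct, provenance``; domains are pipe-separated;
an optional ``version.txt`` carries the version string.

JSON: a single file ``{"version": ..., "keywords": [...], "sentences": [...]}``
with the same fields.

Dictionaries grow by iteration: experts review output, notice missing
keywords or sentences, and contribute a delta that is merged into the base
(:func:`merge_dictionaries`), with provenance recording the iteration.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal

from .domains import ALL_DOMAINS, RdocDomain, format_domains, parse_domains
from .preprocess import match_terms


class SchemaError(ValueError):
    """A dictionary file is missing a required column or field."""


@dataclass(frozen=True)
class KeywordEntry:
    """A lowercase lemma (or short phrase) tagged with RDoC domains."""

    term: str
    domains: frozenset[RdocDomain]
    construct: str = ""

    def __post_init__(self) -> None:
        if not self.term:
            raise ValueError("keyword term must be non-empty")
        if self.term != self.term.lower():
            raise ValueError(f"keyword term must be lowercase: {self.term!r}")
        if not self.domains:
            raise ValueError(f"keyword {self.term!r} has an empty domain set")


@dataclass(frozen=True)
class SentenceEntry:
    """A domain-labeled dictionary sentence with stable id and provenance.

    Provenance is one of ``literature``, ``sme``, ``artifact`` or an
    iteration tag like ``iteration-2``.
    """

    id: str
    text: str
    domains: frozenset[RdocDomain]
    construct: str = ""
    provenance: str = "sme"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sentence id must be non-empty")
        if not self.text.strip():
            raise ValueError(f"sentence {self.id!r} has empty text")
        if not self.domains:
            raise ValueError(f"sentence {self.id!r} has an empty domain set")


@dataclass(frozen=True)
class Dictionary:
    """A versioned keyword + sentence dictionary."""

    keywords: tuple[KeywordEntry, ...]
    sentences: tuple[SentenceEntry, ...]
    version: str

    def __post_init__(self) -> None:
        if not self.version:
            raise ValueError("dictionary version is required")
        terms = [k.term for k in self.keywords]
        if len(set(terms)) != len(terms):
            dupes = sorted({t for t in terms if terms.count(t) > 1})
            raise ValueError(f"duplicate keyword term(s): {dupes}")
        ids = [s.id for s in self.sentences]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sentence id(s): {dupes}")

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(k.term for k in self.keywords)

    def sentences_for_domain(self, domain: RdocDomain) -> tuple[SentenceEntry, ...]:
        return tuple(s for s in self.sentences if domain in s.domains)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Violation:
    kind: str
    location: str
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __iter__(self):
        return iter(self.violations)

    def __len__(self) -> int:
        return len(self.violations)


def validate_dictionary(d: Dictionary, require_complete: bool = True) -> ValidationReport:
    """Check dictionary invariants; returns findings, never raises on content.

    Findings: sentences containing no dictionary keyword (they could never be
    matched by the gated classifier) and, when ``require_complete``, domains
    with no sentences at all.
    """
    report = ValidationReport()
    terms = list(d.terms)
    for s in d.sentences:
        if not match_terms(s.text, terms):
            report.violations.append(Violation(
                kind="sentence_without_keyword",
                location=f"sentence:{s.id}",
                message=f"sentence {s.id!r} contains no dictionary keyword",
            ))
    if require_complete:
        for domain in ALL_DOMAINS:
            if not any(domain in s.domains for s in d.sentences):
                report.violations.append(Violation(
                    kind="domain_without_sentences",
                    location=f"domain:{domain.value}",
                    message=f"domain without sentences: {domain.value}",
                ))
    return report


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

KEYWORD_COLUMNS = ("term", "domains", "construct")
SENTENCE_COLUMNS = ("id", "text", "domains", "construct", "provenance")


def _require_columns(have: Iterable[str], want: tuple[str, ...], where: str) -> None:
    missing = [c for c in want if c not in set(have)]
    if missing:
        raise SchemaError(f"{where}: missing column(s) {', '.join(missing)}")


def _keyword_from_row(row: dict, where: str) -> KeywordEntry:
    domains = parse_domains(row["domains"])
    if not domains:
        raise ValueError(f"{where}: empty domain set for term {row['term']!r}")
    return KeywordEntry(term=row["term"].strip().lower(), domains=domains,
                        construct=(row.get("construct") or "").strip())


def _sentence_from_row(row: dict, where: str) -> SentenceEntry:
    domains = parse_domains(row["domains"])
    if not domains:
        raise ValueError(f"{where}: empty domain set for sentence {row['id']!r}")
    return SentenceEntry(id=row["id"].strip(), text=row["text"].strip(),
                         domains=domains,
                         construct=(row.get("construct") or "").strip(),
                         provenance=(row.get("provenance") or "sme").strip())


def load_dictionary(path: str | Path,
                    format: Literal["csv", "json"] | None = None) -> Dictionary:
    """Load and validate a dictionary from the CSV directory or JSON dialect.

    Terms are lowercased on load; duplicate terms or sentence ids are
    rejected. ``format`` defaults to ``csv`` for a directory path and
    ``json`` for a file path.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.is_dir() else "json"
    if format == "csv":
        return _load_csv(path)
    if format == "json":
        return _load_json(path)
    raise ValueError(f"unknown dictionary format: {format!r}")


def _load_csv(root: Path) -> Dictionary:
    kw_path, sent_path = root / "keywords.csv", root / "sentences.csv"
    keywords: list[KeywordEntry] = []
    with kw_path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _require_columns(reader.fieldnames or [], KEYWORD_COLUMNS, str(kw_path))
        for i, row in enumerate(reader, start=2):
            keywords.append(_keyword_from_row(row, f"{kw_path}:{i}"))
    sentences: list[SentenceEntry] = []
    with sent_path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _require_columns(reader.fieldnames or [], SENTENCE_COLUMNS, str(sent_path))
        for i, row in enumerate(reader, start=2):
            sentences.append(_sentence_from_row(row, f"{sent_path}:{i}"))
    version_file = root / "version.txt"
    version = version_file.read_text(encoding="utf-8").strip() if version_file.exists() else "unversioned"
    return Dictionary(keywords=tuple(keywords), sentences=tuple(sentences), version=version)


def _load_json(path: Path) -> Dictionary:
    payload = json.loads(path.read_text(encoding="utf-8"))
    for key in ("version", "keywords", "sentences"):
        if key not in payload:
            raise SchemaError(f"{path}: missing field {key!r}")
    keywords = [_keyword_from_row(row, f"{path}:keywords[{i}]")
                for i, row in enumerate(payload["keywords"])]
    sentences = [_sentence_from_row(row, f"{path}:sentences[{i}]")
                 for i, row in enumerate(payload["sentences"])]
    return Dictionary(keywords=tuple(keywords), sentences=tuple(sentences),
                      version=str(payload["version"]))


def write_dictionary(d: Dictionary, path: str | Path,
                     format: Literal["csv", "json"] = "json") -> None:
    """Serialize a dictionary; ``load_dictionary(write(d)) == d`` for both dialects."""
    path = Path(path)
    if format == "json":
        payload = {
            "version": d.version,
            "keywords": [{"term": k.term, "domains": format_domains(k.domains),
                          "construct": k.construct} for k in d.keywords],
            "sentences": [{"id": s.id, "text": s.text,
                           "domains": format_domains(s.domains),
                           "construct": s.construct, "provenance": s.provenance}
                          for s in d.sentences],
        }
        path.write_text(json.dumps(payload, indent=2, ensure_ascii=False) + "\n",
                        encoding="utf-8")
        return
    if format == "csv":
        path.mkdir(parents=True, exist_ok=True)
        with (path / "keywords.csv").open("w", newline="", encoding="utf-8") as fh:
            w = csv.DictWriter(fh, fieldnames=KEYWORD_COLUMNS)
            w.writeheader()
            for k in d.keywords:
                w.writerow({"term": k.term, "domains": format_domains(k.domains),
                            "construct": k.construct})
        with (path / "sentences.csv").open("w", newline="", encoding="utf-8") as fh:
            w = csv.DictWriter(fh, fieldnames=SENTENCE_COLUMNS)
            w.writeheader()
            for s in d.sentences:
                w.writerow({"id": s.id, "text": s.text,
                            "domains": format_domains(s.domains),
                            "construct": s.construct, "provenance": s.provenance})
        (path / "version.txt").write_text(d.version + "\n", encoding="utf-8")
        return
    raise ValueError(f"unknown dictionary format: {format!r}")


# ---------------------------------------------------------------------------
# Merging (iterative dictionary development)
# ---------------------------------------------------------------------------


@dataclass
class MergeReport:
    """What happened during a merge: overridden ids, unioned terms, conflicts."""

    new_keywords: list[str] = field(default_factory=list)
    unioned_keywords: list[str] = field(default_factory=list)
    new_sentences: list[str] = field(default_factory=list)
    overridden_sentences: list[str] = field(default_factory=list)
    conflicts: list[str] = field(default_factory=list)


def merge_dictionaries(base: Dictionary, delta: Dictionary,
                       iteration_tag: str | None = None
                       ) -> tuple[Dictionary, MergeReport]:
    """Merge an expert-contributed delta into a base dictionary.

    Keywords de-duplicate at the term level with domain sets unioned;
    sentences collide on id with the delta winning (recorded). Sentences
    that are textually identical under distinct ids but carry different
    domain labels are flagged as conflicts, not silently merged. New entries
    coming from the delta get ``iteration_tag`` as provenance when given.
    """
    report = MergeReport()

    by_term = {k.term: k for k in base.keywords}
    term_order = [k.term for k in base.keywords]
    for k in delta.keywords:
        if k.term in by_term:
            existing = by_term[k.term]
            union = existing.domains | k.domains
            if union != existing.domains:
                by_term[k.term] = replace(existing, domains=union)
                report.unioned_keywords.append(k.term)
        else:
            by_term[k.term] = k
            term_order.append(k.term)
            report.new_keywords.append(k.term)

    by_id = {s.id: s for s in base.sentences}
    text_labels = {s.text.strip().lower(): (s.id, s.domains) for s in base.sentences}
    order = [s.id for s in base.sentences]
    for s in delta.sentences:
        key = s.text.strip().lower()
        if key in text_labels:
            other_id, other_domains = text_labels[key]
            if other_id != s.id and other_domains != s.domains:
                report.conflicts.append(
                    f"identical text under ids {other_id!r}/{s.id!r} with "
                    f"differing domains")
        if s.id in by_id:
            if by_id[s.id] != s:
                report.overridden_sentences.append(s.id)
            by_id[s.id] = s
        else:
            if iteration_tag:
                s = replace(s, provenance=iteration_tag)
            by_id[s.id] = s
            order.append(s.id)
            report.new_sentences.append(s.id)

    merged = Dictionary(
        keywords=tuple(by_term[t] for t in term_order),
        sentences=tuple(by_id[i] for i in order),
        version=f"{base.version}+{delta.version}" if delta.sentences or delta.keywords
                else base.version,
    )
    return merged, report


# ---------------------------------------------------------------------------
# Starter dictionary
# ---------------------------------------------------------------------------


def load_starter_dictionary() -> Dictionary:
    """Load the starter dictionary shipped with the package.

    The starter content covers all six domains with keywords drawn from the
    PTSD/RDoC literature's construct vocabulary (acute threat, potential
    threat, sustained threat, frustrative non-reward, reduced behavioral
    activation, loss, reward seeking, hyperarousal, prepulse inhibition, ...)
    and a small set of example sentences written for this artifact
    (provenance ``artifact``). It is a schema demonstration and test fixture,
    not a clinically validated dictionary.
    """
    pkg = resources.files("rdocnlp") / "data"
    keywords: list[KeywordEntry] = []
    with (pkg / "starter_keywords.csv").open(encoding="utf-8") as fh:
        for i, row in enumerate(csv.DictReader(fh), start=2):
            keywords.append(_keyword_from_row(row, f"starter_keywords.csv:{i}"))
    sentences: list[SentenceEntry] = []
    with (pkg / "starter_sentences.csv").open(encoding="utf-8") as fh:
        for i, row in enumerate(csv.DictReader(fh), start=2):
            sentences.append(_sentence_from_row(row, f"starter_sentences.csv:{i}"))
    return Dictionary(keywords=tuple(keywords), sentences=tuple(sentences),
                      version="starter-1.0")
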
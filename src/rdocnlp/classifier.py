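"""Keyword-gated multi-label RDoC classification of note sentences.

The classification rule for a note sentence A:

1. **Gate.** A is only considered if it contains at least one dictionary
   keyword. No keyword match → no candidates → no assignment, ever.
2. **Candidates.** The candidate set is every dictionary sentence B that
   shares at least one matched *lemma* with A (lemma-level sharing, not
   identical surface forms: "stressed" in A gates on dictionary sentences
   containing any inflection of "stress").
3. **Similarity.** Each (A, B) pair is scored by cosine similarity of the
   sentence embeddings.
4. **Per-domain best.** For each domain, the best candidate is the maximum
   similarity over candidates labeled with that domain; ties break toward
   the lexicographically lowest dictionary sentence id. All candidates are
   scanned — the result is order-independent.
5. **Assignment.** Every domain whose best similarity reaches the operating
   threshold τ is assigned; a sentence can therefore carry multiple domains.

The default τ = 0.3 is the operating point selected by the macro-F1
threshold sweep (see :mod:`rdocnlp.evaluation`).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .dictionaries import Dictionary, SentenceEntry
from .domains import RdocDomain
from .embedding import EmbeddingBackend, cosine, embed_batch
from .preprocess import ClinicalNote, KeywordMatch, SentenceSpan, match_keywords, segment

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.3


@dataclass(frozen=True)
class DomainBest:
    """Best-scoring dictionary candidate for one domain."""

    similarity: float
    dictionary_sentence_id: str
    shared_term: str


@dataclass(frozen=True)
class SentenceClassification:
    """Multi-label classification of one note sentence at threshold τ."""

    patient_id: str
    note_id: str
    sentence_index: int
    text: str
    candidates_considered: int
    per_domain_best: dict[RdocDomain, DomainBest]
    assigned: frozenset[RdocDomain]
    threshold: float

    @property
    def key(self) -> tuple[str, int]:
        return (self.note_id, self.sentence_index)


def _candidate_index(d: Dictionary) -> dict[str, list[SentenceEntry]]:
    """Map each keyword lemma to the dictionary sentences containing it."""
    index: dict[str, list[SentenceEntry]] = {}
    for entry in d.sentences:
        for hit in match_keywords(entry.text, d.keywords):
            index.setdefault(hit.term, []).append(entry)
    return index


class SentenceClassifier:
    """Reusable classifier binding a dictionary and an embedding backend.

    Precomputes the lemma → dictionary-sentence index and the dictionary
    embeddings once; per-sentence classification then costs one embedding
    plus one cosine per gated candidate.
    """

    def __init__(self, dictionary: Dictionary, backend: EmbeddingBackend,
                 threshold: float = DEFAULT_THRESHOLD) -> None:
        if not 0.0 <= threshold <= 1.0:
            raise ValueError(f"threshold must be in [0, 1], got {threshold}")
        self.dictionary = dictionary
        self.backend = backend
        self.threshold = threshold
        self._by_term = _candidate_index(dictionary)
        texts = [s.text for s in dictionary.sentences]
        vecs = embed_batch(backend, texts) if texts else None
        self._dict_vecs = {s.id: vecs[i] for i, s in enumerate(dictionary.sentences)} \
            if vecs is not None else {}

    def classify_sentence(self, span: SentenceSpan,
                          matches: Sequence[KeywordMatch],
                          patient_id: str = "",
                          threshold: float | None = None) -> SentenceClassification:
        """Classify one segmented sentence given its keyword matches."""
        tau = self.threshold if threshold is None else threshold
        if not 0.0 <= tau <= 1.0:
            raise ValueError(f"threshold must be in [0, 1], got {tau}")

        # keyword gate
        if not matches:
            return SentenceClassification(
                patient_id=patient_id, note_id=span.note_id,
                sentence_index=span.index, text=span.text,
                candidates_considered=0, per_domain_best={},
                assigned=frozenset(), threshold=tau)

        matched_terms = {m.term for m in matches}
        candidates: dict[str, tuple[SentenceEntry, str]] = {}
        for term in sorted(matched_terms):
            for entry in self._by_term.get(term, []):
                # first (lowest) shared term recorded per candidate
                candidates.setdefault(entry.id, (entry, term))

        span_vec = embed_batch(self.backend, [span.text])[0]
        per_domain: dict[RdocDomain, DomainBest] = {}
        for entry_id in sorted(candidates):
            entry, shared = candidates[entry_id]
            sim = cosine(span_vec, self._dict_vecs[entry_id])
            for domain in entry.domains:
                best = per_domain.get(domain)
                # strict > keeps the lowest id on ties (ids scanned sorted)
                if best is None or sim > best.similarity:
                    per_domain[domain] = DomainBest(
                        similarity=sim, dictionary_sentence_id=entry_id,
                        shared_term=shared)

        assigned = frozenset(d for d, b in per_domain.items()
                             if b.similarity >= tau)
        return SentenceClassification(
            patient_id=patient_id, note_id=span.note_id,
            sentence_index=span.index, text=span.text,
            candidates_considered=len(candidates),
            per_domain_best=per_domain, assigned=assigned, threshold=tau)

    def classify_note(self, note: ClinicalNote,
                      threshold: float | None = None) -> list[SentenceClassification]:
        out = []
        for span in segment(note):
            matches = match_keywords(span, self.dictionary.keywords)
            out.append(self.classify_sentence(span, matches,
                                              patient_id=note.patient_id,
                                              threshold=threshold))
        return out


@dataclass
class RunLog:
    """Counts and configuration fingerprint for one corpus run."""

    notes: int = 0
    sentences: int = 0
    gated_sentences: int = 0
    assigned_sentences: int = 0
    per_domain_assignments: dict[str, int] = field(default_factory=dict)
    failed_notes: int = 0
    config: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def classify_corpus(notes: Iterable[ClinicalNote], dictionary: Dictionary,
                    backend: EmbeddingBackend,
                    threshold: float = DEFAULT_THRESHOLD,
                    runlog: RunLog | None = None,
                    ) -> Iterator[SentenceClassification]:
    """Classify every sentence of every note, streaming.

    Threshold validity is checked before any note is touched. Per-note
    failures are logged and the run continues; the caller can inspect
    ``runlog.failed_notes`` (the CLI turns a >1% failure rate into a
    nonzero exit).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    clf = SentenceClassifier(dictionary, backend, threshold)
    log = runlog if runlog is not None else RunLog()
    log.config = {"backend": backend.name, "threshold": threshold,
                  "dictionary_version": dictionary.version,
                  "n_dictionary_sentences": len(dictionary.sentences)}
    for note in notes:
        log.notes += 1
        try:
            results = clf.classify_note(note)
        except Exception:  # pragma: no cover - defensive
            logger.exception("failed to classify note %s", note.note_id)
            log.failed_notes += 1
            continue
        for res in results:
            log.sentences += 1
            if res.candidates_considered > 0:
                log.gated_sentences += 1
            if res.assigned:
                log.assigned_sentences += 1
            for domain in res.assigned:
                log.per_domain_assignments[domain.value] = \
                    log.per_domain_assignments.get(domain.value, 0) + 1
            yield res


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

CLASSIFICATION_COLUMNS = ("patient_id", "note_id", "sentence_index", "domain",
                          "similarity", "dict_sentence_id", "shared_term")


def classifications_to_rows(results: Iterable[SentenceClassification]) -> Iterator[dict]:
    """Flatten classifications into one row per assigned (sentence, domain)."""
    for res in results:
        for domain in sorted(res.assigned, key=lambda d: d.value):
            best = res.per_domain_best[domain]
            yield {
                "patient_id": res.patient_id,
                "note_id": res.note_id,
                "sentence_index": res.sentence_index,
                "domain": domain.value,
                "similarity": round(best.similarity, 6),
                "dict_sentence_id": best.dictionary_sentence_id,
                "shared_term": best.shared_term,
            }


def write_classifications_csv(results: Iterable[SentenceClassification],
                              path: str | Path) -> int:
    import csv

    n = 0
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=CLASSIFICATION_COLUMNS)
        writer.writeheader()
        for row in classifications_to_rows(results):
            writer.writerow(row)
            n += 1
    return n
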
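"""Patient-level aggregation and the two cohort use cases.

Sentence-level classifications roll up into per-patient instance counts
(one instance = one sentence assigned to a domain). A patient shows an
*abnormal instance* of a domain when at least one of their sentences is
assigned to it; cohort percentages (e.g. "share of women with at least one
abnormal negative-valence instance") are proportions of patients with that
flag set. Two analyses build on the rollup:

* **population comparisons** — subgroup summaries (gender, veteran status,
  pre/post psychotherapy) compared via the exact Wilcoxon signed-rank test
  on the six paired domain proportions;
* **disease trajectories** — instance counts inside cumulative follow-up
  windows (1, 2, 4 years by default) anchored at a patient's first
  diagnosis date for an index event (PTSD, SRE or ASUD), with a Friedman
  test across windows using domains as blocks.

Conventions fixed here: a note dated exactly on the first psychotherapy
date counts as *post*; a year is 365.25 days; trajectory windows are
cumulative ``(event_date, event_date + w·365.25 d]`` with a disjoint-slice
option.
"""

from __future__ import annotations

import csv
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Callable, Iterable, Literal, Sequence

from .classifier import SentenceClassification
from .domains import ALL_DOMAINS, RdocDomain
from .preprocess import ClinicalNote
from .stats import (DegenerateSampleError, FriedmanResult, PairedSample,
                    WilcoxonResult, friedman, wilcoxon_signed_rank)

DAYS_PER_YEAR = 365.25
DEFAULT_WINDOWS_YEARS = (1, 2, 4)

EventName = Literal["ptsd", "sre", "asud"]


@dataclass(frozen=True)
class PatientProfile:
    """Structured-EMR attributes for one patient."""

    patient_id: str
    gender: Literal["female", "male", "unknown"] = "unknown"
    veteran: bool | None = None
    first_psychotherapy_date: date | None = None
    first_ptsd_date: date | None = None
    first_sre_date: date | None = None
    first_asud_date: date | None = None

    def event_date(self, event: EventName) -> date | None:
        return {"ptsd": self.first_ptsd_date, "sre": self.first_sre_date,
                "asud": self.first_asud_date}[event]


PROFILE_COLUMNS = ("patient_id", "gender", "veteran", "first_psychotherapy_date",
                   "first_ptsd_date", "first_sre_date", "first_asud_date")


def _opt_date(raw: str | None) -> date | None:
    raw = (raw or "").strip()
    return date.fromisoformat(raw) if raw else None


def read_profiles_csv(path: str | Path) -> dict[str, PatientProfile]:
    """Read patient profiles keyed by patient_id; duplicate ids rejected."""
    out: dict[str, PatientProfile] = {}
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for i, row in enumerate(csv.DictReader(fh), start=2):
            pid = row["patient_id"]
            if pid in out:
                raise ValueError(f"{path}:{i}: duplicate patient_id {pid!r}")
            vet_raw = (row.get("veteran") or "").strip().lower()
            veteran = {"true": True, "1": True, "yes": True,
                       "false": False, "0": False, "no": False}.get(vet_raw)
            out[pid] = PatientProfile(
                patient_id=pid,
                gender=(row.get("gender") or "unknown").strip().lower() or "unknown",
                veteran=veteran,
                first_psychotherapy_date=_opt_date(row.get("first_psychotherapy_date")),
                first_ptsd_date=_opt_date(row.get("first_ptsd_date")),
                first_sre_date=_opt_date(row.get("first_sre_date")),
                first_asud_date=_opt_date(row.get("first_asud_date")),
            )
    return out


def write_profiles_csv(profiles: Iterable[PatientProfile], path: str | Path) -> int:
    n = 0
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=PROFILE_COLUMNS)
        writer.writeheader()
        for p in profiles:
            writer.writerow({
                "patient_id": p.patient_id,
                "gender": p.gender,
                "veteran": "" if p.veteran is None else str(p.veteran).lower(),
                "first_psychotherapy_date": p.first_psychotherapy_date or "",
                "first_ptsd_date": p.first_ptsd_date or "",
                "first_sre_date": p.first_sre_date or "",
                "first_asud_date": p.first_asud_date or "",
            })
            n += 1
    return n


@dataclass
class PatientDomainProfile:
    """Per-patient instance counts with derived abnormality flags."""

    patient_id: str
    counts: dict[RdocDomain, int] = field(default_factory=dict)

    def count(self, domain: RdocDomain) -> int:
        return self.counts.get(domain, 0)

    def abnormal(self, domain: RdocDomain, min_count: int = 1) -> bool:
        return self.count(domain) >= min_count

    def any_domain_abnormal(self, min_count: int = 1) -> bool:
        return any(self.abnormal(d, min_count) for d in ALL_DOMAINS)


def aggregate(classifications: Iterable[SentenceClassification],
              profiles: dict[str, PatientProfile] | None = None,
              ) -> tuple[dict[str, PatientDomainProfile], int]:
    """Roll sentence classifications up to per-patient domain counts.

    Counts are assigned (sentence, domain) pairs per patient per domain.
    When ``profiles`` is given, classifications for unknown patients are
    excluded; the second return value is that exclusion count. Patients
    present in ``profiles`` but with no assignments get all-zero profiles.
    """
    out: dict[str, PatientDomainProfile] = {}
    if profiles is not None:
        out = {pid: PatientDomainProfile(patient_id=pid) for pid in profiles}
    excluded = 0
    for cls in classifications:
        if profiles is not None and cls.patient_id not in profiles:
            excluded += 1
            continue
        prof = out.setdefault(cls.patient_id,
                              PatientDomainProfile(patient_id=cls.patient_id))
        for domain in cls.assigned:
            prof.counts[domain] = prof.counts.get(domain, 0) + 1
    return out, excluded


# ---------------------------------------------------------------------------
# Group summaries and comparisons (use case 1)
# ---------------------------------------------------------------------------


@dataclass
class GroupSummary:
    """Subgroup rollup: per-domain abnormal-patient counts and proportions."""

    label: str
    n: int
    domain_counts: dict[RdocDomain, int]
    any_domain_count: int

    def proportion(self, domain: RdocDomain) -> float:
        if self.n == 0:
            return float("nan")
        return self.domain_counts.get(domain, 0) / self.n

    @property
    def any_domain_proportion(self) -> float:
        return float("nan") if self.n == 0 else self.any_domain_count / self.n

    def proportions(self) -> dict[RdocDomain, float]:
        return {d: self.proportion(d) for d in ALL_DOMAINS}


def group_summary(profiles: dict[str, PatientProfile],
                  domain_profiles: dict[str, PatientDomainProfile],
                  predicate: Callable[[PatientProfile], bool],
                  label: str = "group",
                  min_count: int = 1) -> GroupSummary:
    """Summarize the patients satisfying ``predicate``.

    An empty group yields n = 0 with NaN proportions (flagged, not fatal).
    """
    members = [p for p in profiles.values() if predicate(p)]
    counts = {d: 0 for d in ALL_DOMAINS}
    any_count = 0
    for p in members:
        dp = domain_profiles.get(p.patient_id)
        if dp is None:
            continue
        for d in ALL_DOMAINS:
            if dp.abnormal(d, min_count):
                counts[d] += 1
        if dp.any_domain_abnormal(min_count):
            any_count += 1
    return GroupSummary(label=label, n=len(members), domain_counts=counts,
                        any_domain_count=any_count)


@dataclass
class GroupComparison:
    a: GroupSummary
    b: GroupSummary
    differences: dict[RdocDomain, float]
    domains_favoring_a: int
    wilcoxon: WilcoxonResult | None
    wilcoxon_note: str = ""


def compare_groups(a: GroupSummary, b: GroupSummary) -> GroupComparison:
    """Compare two subgroups via the six paired per-domain proportions.

    The paired vectors are the per-domain abnormal proportions of the two
    groups; the exact Wilcoxon signed-rank test (n = 6 pairs) gives the
    two-sided p. Identical summaries surface the degenerate-sample error as
    a note rather than a result.
    """
    if a.n == 0 or b.n == 0:
        raise ValueError("cannot compare an empty group")
    pa, pb = a.proportions(), b.proportions()
    diffs = {d: pa[d] - pb[d] for d in ALL_DOMAINS}
    favoring_a = sum(1 for d in ALL_DOMAINS if diffs[d] > 0)
    sample = PairedSample(a=tuple(pa[d] for d in ALL_DOMAINS),
                          b=tuple(pb[d] for d in ALL_DOMAINS),
                          labels=tuple(d.value for d in ALL_DOMAINS))
    try:
        wres = wilcoxon_signed_rank(sample)
        note = ""
    except DegenerateSampleError as exc:
        wres, note = None, str(exc)
    return GroupComparison(a=a, b=b, differences=diffs,
                           domains_favoring_a=favoring_a,
                           wilcoxon=wres, wilcoxon_note=note)


def split_pre_post_psychotherapy(notes: Iterable[ClinicalNote],
                                 profiles: dict[str, PatientProfile],
                                 ) -> tuple[list[ClinicalNote], list[ClinicalNote], int]:
    """Partition notes into pre-/post-psychotherapy by each patient's date.

    A note dated strictly before the patient's first psychotherapy date is
    *pre*; on or after it is *post*. Notes of patients without a recorded
    psychotherapy date are excluded; the third return value counts them.
    """
    pre: list[ClinicalNote] = []
    post: list[ClinicalNote] = []
    excluded = 0
    for note in notes:
        prof = profiles.get(note.patient_id)
        if prof is None or prof.first_psychotherapy_date is None:
            excluded += 1
            continue
        (pre if note.date < prof.first_psychotherapy_date else post).append(note)
    return pre, post, excluded


# ---------------------------------------------------------------------------
# Disease trajectories (use case 2)
# ---------------------------------------------------------------------------


@dataclass
class TrajectoryTable:
    """Instance counts and patient proportions per (window, domain)."""

    event: EventName
    windows_years: tuple[int, ...]
    cumulative: bool
    n_patients: int
    instance_counts: dict[tuple[int, RdocDomain], int]
    patient_counts: dict[tuple[int, RdocDomain], int]
    friedman: FriedmanResult | None = None

    def proportion(self, window: int, domain: RdocDomain) -> float:
        if self.n_patients == 0:
            return float("nan")
        return self.patient_counts.get((window, domain), 0) / self.n_patients

    def to_rows(self) -> list[dict]:
        rows = []
        for w in self.windows_years:
            for d in ALL_DOMAINS:
                rows.append({
                    "window_years": w, "domain": d.value,
                    "instances": self.instance_counts.get((w, d), 0),
                    "patients": self.patient_counts.get((w, d), 0),
                    "patient_proportion": round(self.proportion(w, d), 6)
                    if self.n_patients else "",
                })
        return rows


def trajectory(classifications: Sequence[SentenceClassification],
               notes: Iterable[ClinicalNote],
               profiles: dict[str, PatientProfile],
               event: EventName,
               windows_years: Sequence[int] = DEFAULT_WINDOWS_YEARS,
               cumulative: bool = True) -> TrajectoryTable:
    """Event-anchored follow-up analysis of domain instances.

    For each included patient (those with a recorded first-diagnosis date
    for ``event``), assigned sentences are bucketed by the note date's
    offset from the event date. Cumulative windows are
    ``(event, event + w·365.25 d]``; with ``cumulative=False`` each window
    is the disjoint annual slice ending at ``w`` years. The Friedman test
    compares windows (conditions) across domains (blocks) on instance
    counts; it needs ≥ 2 windows and is skipped otherwise.
    """
    note_dates = {n.note_id: n.date for n in notes}
    eligible = {pid: prof.event_date(event) for pid, prof in profiles.items()
                if prof.event_date(event) is not None}

    windows = tuple(sorted(windows_years))
    instance_counts: dict[tuple[int, RdocDomain], int] = {}
    patient_sets: dict[tuple[int, RdocDomain], set[str]] = defaultdict(set)

    for cls in classifications:
        event_date = eligible.get(cls.patient_id)
        if event_date is None or not cls.assigned:
            continue
        note_date = note_dates.get(cls.note_id)
        if note_date is None:
            continue
        offset_days = (note_date - event_date).days
        if offset_days <= 0:
            continue  # windows are half-open at the left: strictly post-event
        for w in windows:
            upper = w * DAYS_PER_YEAR
            lower = 0.0
            if not cumulative:
                idx = windows.index(w)
                lower = windows[idx - 1] * DAYS_PER_YEAR if idx else 0.0
            if lower < offset_days <= upper:
                for domain in cls.assigned:
                    instance_counts[(w, domain)] = \
                        instance_counts.get((w, domain), 0) + 1
                    patient_sets[(w, domain)].add(cls.patient_id)

    table = TrajectoryTable(
        event=event, windows_years=windows, cumulative=cumulative,
        n_patients=len(eligible),
        instance_counts=instance_counts,
        patient_counts={k: len(v) for k, v in patient_sets.items()},
    )
    if len(eligible) == 0:
        return table
    if len(windows) >= 2:
        matrix = tuple(tuple(float(instance_counts.get((w, d), 0))
                             for w in windows) for d in ALL_DOMAINS)
        table.friedman = friedman(matrix)
    return table


# ---------------------------------------------------------------------------
# Keyword frequencies (word-cloud data)
# ---------------------------------------------------------------------------


def word_frequencies(classifications: Iterable[SentenceClassification],
                     matches_by_key: dict[tuple[str, int], Sequence],
                     scope: RdocDomain | None = None) -> list[tuple[str, int]]:
    """Ranked lemma counts among sentences with at least one assignment.

    ``matches_by_key`` maps (note_id, sentence_index) to the sentence's
    keyword matches. With ``scope`` set, only sentences assigned that domain
    contribute. Ranking is by descending count, ties alphabetical — the data
    behind a word cloud, where word size tracks instance count.
    """
    counter: Counter[str] = Counter()
    for cls in classifications:
        if not cls.assigned:
            continue
        if scope is not None and scope not in cls.assigned:
            continue
        for m in matches_by_key.get(cls.key, ()):
            counter[m.term] += 1
    return sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
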
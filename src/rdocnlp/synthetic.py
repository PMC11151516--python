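"""Synthetic EMR cohort generator with sentence-level gold labels.

The generator builds a download-free stand-in for a clinical-note corpus
that carries the statistical structure the cohort analyses assume:

* a patient cohort with configurable female / veteran / psychotherapy
  fractions and first-diagnosis dates for the three trajectory index events
  (PTSD, SRE, ASUD);
* notes containing **planted** sentences — lexical paraphrases of dictionary
  sentences that always keep the keyword surface intact — mixed with
  **traps** (a dictionary keyword dropped into an unrelated sentence, which
  the classifier should gate in but score below threshold) and
  **distractors** (no keyword at all, never gated in);
* subgroup-specific per-domain prevalences: by default women run higher
  than men in every domain, veterans higher than non-veterans in the two
  valence domains, and pre-psychotherapy notes higher than post — the
  direction structure of the population comparisons.

Everything is deterministic for a fixed (seed, config, dictionary): each
patient's random stream is derived from the root seed and the patient index
by seed-sequence splitting, so growing the cohort never reshuffles earlier
patients, and serialized output is byte-identical across reruns.

The paraphrase operator is lexical (synonym substitution plus filler
insertion), not model-based: the substituted fraction of source tokens
never exceeds the intensity, and keyword tokens are never touched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np

from .dictionaries import Dictionary, SentenceEntry
from .domains import ALL_DOMAINS, RdocDomain, format_domains
from .evaluation import GoldLabel
from .cohort import PatientProfile, write_profiles_csv
from .preprocess import ClinicalNote, match_terms, write_notes_jsonl

# Filler phrases appended/prepended by the paraphraser (insertion only —
# they never remove source tokens).
_FILLER_PREFIXES = ("Per chart review", "On follow up", "Overall", "At intake")
_FILLER_SUFFIXES = ("per patient report", "as documented previously",
                    "per collateral history", "since the last appointment")

# Small synonym table for substitution; keys lowercase. Values deliberately
# avoid every starter-dictionary lemma and its inflections.
_SYNONYMS: dict[str, tuple[str, ...]] = {
    "patient": ("pt", "she", "he"),
    "reports": ("describes", "endorses", "notes"),
    "describes": ("reports", "endorses"),
    "expresses": ("voices", "conveys"),
    "persistent": ("ongoing", "continual"),
    "intense": ("severe", "marked"),
    "poorly": ("badly", "fitfully"),
    "several": ("multiple", "many"),
    "easily": ("readily", "quickly"),
    "evident": ("apparent", "noticeable"),
    "marked": ("pronounced", "notable"),
    "observed": ("noted", "seen"),
    "strong": ("powerful", "overwhelming"),
    "little": ("minimal", "scant"),
    "daily": ("every day", "each day"),
    "refuses": ("declines", "resists"),
    "history": ("pattern", "background"),
    "ongoing": ("continuing", "persisting"),
    "worsen": ("intensify", "escalate"),
    "impaired": ("diminished", "degraded"),
    "profound": ("deep", "overwhelming"),
    "distant": ("remote", "detached"),
    "chronic": ("longstanding", "unremitting"),
    "racing": ("pounding", "rapid"),
    "vivid": ("graphic", "intrusive"),
    "loud": ("sudden", "sharp"),
    "fine": ("slight", "subtle"),
    "work": ("her job", "the office"),
    "family": ("relatives", "loved ones"),
    "children": ("kids", "sons and daughters"),
    "friends": ("peers", "companions"),
    "night": ("evening", "overnight"),
    "interview": ("visit", "session"),
    "examination": ("exam", "assessment"),
}

# Trap templates: one dictionary keyword dropped into an administratively
# flavored sentence lexically far from every dictionary sentence.
_TRAP_TEMPLATES = (
    "Routine {kw} screening questionnaire completed at the front desk today",
    "Scheduling called regarding the {kw} clinic referral paperwork",
    "Insurance authorization for the {kw} program remains pending review",
    "Handout about {kw} resources was mailed to the home address",
)

# Distractor sentences: contain no dictionary keyword or inflection of one.
_DISTRACTORS = (
    "Vital signs stable and unremarkable at today's visit",
    "Medication list reconciled with the outside pharmacy records",
    "Laboratory results reviewed and within normal limits",
    "Follow up appointment scheduled in six weeks",
    "Immunizations are up to date per the state registry",
    "Referral placed to nutrition services for dietary counseling",
    "Blood sample drawn and sent for routine chemistry panel",
    "No acute findings on physical examination of the abdomen",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level simulation settings; all probabilities in [0, 1]."""

    seed: int
    n_patients: int = 200
    female_fraction: float = 0.63
    veteran_fraction: float = 0.21
    psychotherapy_fraction: float = 0.5
    sre_rate: float = 0.25
    asud_rate: float = 0.4
    mean_notes_per_patient: float = 3.0
    # per-note probability of planting one sentence of each domain
    base_prevalence: dict[str, float] = field(default_factory=lambda: {
        d.value: 0.10 for d in ALL_DOMAINS})
    female_effect: dict[str, float] = field(default_factory=lambda: {
        d.value: 0.04 for d in ALL_DOMAINS})
    veteran_effect: dict[str, float] = field(default_factory=lambda: {
        RdocDomain.NEGATIVE_VALENCE.value: 0.05,
        RdocDomain.POSITIVE_VALENCE.value: 0.05})
    pre_psychotherapy_effect: dict[str, float] = field(default_factory=lambda: {
        d.value: 0.06 for d in ALL_DOMAINS})
    paraphrase_intensity: float = 0.3
    trap_rate: float = 0.3          # per-note probability of one keyword trap
    distractor_rate: float = 1.5    # expected distractor sentences per note
    start_date: date = date(2010, 1, 1)
    followup_years: float = 4.5

    def __post_init__(self) -> None:
        probs = [self.female_fraction, self.veteran_fraction,
                 self.psychotherapy_fraction, self.sre_rate, self.asud_rate,
                 self.paraphrase_intensity, self.trap_rate,
                 *self.base_prevalence.values(), *self.female_effect.values(),
                 *self.veteran_effect.values(),
                 *self.pre_psychotherapy_effect.values()]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")


@dataclass
class GoldCorpus:
    """Generated notes + profiles + sentence-level truth + expected tallies."""

    notes: list[ClinicalNote]
    profiles: dict[str, PatientProfile]
    gold: list[GoldLabel]
    tally: dict[str, dict[str, int]]       # patient_id -> domain -> planted count
    planted_sources: dict[tuple[str, int], str]  # sentence key -> dict sentence id

    def write(self, out_dir: str | Path) -> None:
        """Write notes JSONL, profiles CSV, gold CSV and tally JSON."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_notes_jsonl(self.notes, out / "notes.jsonl")
        write_profiles_csv(self.profiles.values(), out / "profiles.csv")
        with (out / "gold.csv").open("w", encoding="utf-8") as fh:
            fh.write("note_id,sentence_index,domains\n")
            for g in self.gold:
                fh.write(f"{g.note_id},{g.sentence_index},"
                         f"{format_domains(g.domains)}\n")
        (out / "tally.json").write_text(
            json.dumps(self.tally, indent=2, sort_keys=True) + "\n",
            encoding="utf-8")


def paraphrase(sentence: SentenceEntry, intensity: float,
               rng: np.random.Generator,
               protected_terms: Sequence[str]) -> str:
    """Lexically paraphrase a dictionary sentence.

    Substitutes at most ``intensity × n_tokens`` non-keyword tokens using
    the synonym table and optionally inserts a filler phrase; every token
    matching a protected (keyword) lemma is left untouched, so the keyword
    surface survives verbatim and case-insensitive token overlap with the
    source stays at least ``1 − intensity`` (attaching a filler prefix may
    down-case the original leading token).
    """
    if not 0.0 <= intensity <= 1.0:
        raise ValueError("intensity must be in [0, 1]")
    tokens = sentence.text.split()
    if intensity == 0.0:
        return sentence.text

    protected_spans = match_terms(sentence.text, list(protected_terms))
    protected_surfaces = {m.surface.lower().strip(",.") for m in protected_spans}

    budget = int(intensity * len(tokens))
    eligible = [i for i, tok in enumerate(tokens)
                if tok.lower().strip(",.") in _SYNONYMS
                and tok.lower().strip(",.") not in protected_surfaces]
    if eligible and budget:
        chosen = rng.choice(len(eligible), size=min(budget, len(eligible)),
                            replace=False)
        for idx in sorted(int(c) for c in chosen):
            pos = eligible[idx]
            word = tokens[pos]
            bare = word.lower().strip(",.")
            options = _SYNONYMS[bare]
            repl = options[int(rng.integers(len(options)))]
            # preserve leading capitalization and trailing punctuation
            if word[0].isupper():
                repl = repl[0].upper() + repl[1:]
            trailing = word[len(word.rstrip(',.')):]
            tokens[pos] = repl + trailing
    text = " ".join(tokens)
    # filler insertion never removes source tokens
    style = int(rng.integers(3))
    if style == 0:
        prefix = _FILLER_PREFIXES[int(rng.integers(len(_FILLER_PREFIXES)))]
        text = f"{prefix}, {text[0].lower()}{text[1:]}"
    elif style == 1:
        suffix = _FILLER_SUFFIXES[int(rng.integers(len(_FILLER_SUFFIXES)))]
        text = f"{text} {suffix}"
    return text


def _note_prevalence(config: SimulationConfig, profile: PatientProfile,
                     is_pre_therapy: bool, domain: RdocDomain) -> float:
    p = config.base_prevalence.get(domain.value, 0.0)
    if profile.gender == "female":
        p += config.female_effect.get(domain.value, 0.0)
    if profile.veteran:
        p += config.veteran_effect.get(domain.value, 0.0)
    if is_pre_therapy:
        p += config.pre_psychotherapy_effect.get(domain.value, 0.0)
    return min(max(p, 0.0), 1.0)


def _make_profile(pid: str, config: SimulationConfig,
                  rng: np.random.Generator) -> PatientProfile:
    gender = "female" if rng.random() < config.female_fraction else "male"
    veteran = bool(rng.random() < config.veteran_fraction)
    t0 = config.start_date + timedelta(days=int(rng.integers(0, 1096)))
    therapy = None
    if rng.random() < config.psychotherapy_fraction:
        therapy = t0 + timedelta(days=int(rng.integers(180, 731)))
    sre = t0 + timedelta(days=int(rng.integers(90, 731))) \
        if rng.random() < config.sre_rate else None
    asud = t0 + timedelta(days=int(rng.integers(90, 731))) \
        if rng.random() < config.asud_rate else None
    return PatientProfile(patient_id=pid, gender=gender, veteran=veteran,
                          first_psychotherapy_date=therapy,
                          first_ptsd_date=t0, first_sre_date=sre,
                          first_asud_date=asud)


def generate(config: SimulationConfig, dictionary: Dictionary) -> GoldCorpus:
    """Generate a gold-labeled synthetic corpus under the configured conditions.

    Each note draws, per domain, a Bernoulli planting decision at the
    subgroup-adjusted prevalence; a planted sentence is a paraphrase of a
    uniformly chosen dictionary sentence labeled with that domain. Traps and
    distractors are mixed in and the sentence order shuffled. Domains with
    nonzero prevalence but no dictionary sentences are an error.
    """
    for d in ALL_DOMAINS:
        if config.base_prevalence.get(d.value, 0.0) > 0 \
                and not dictionary.sentences_for_domain(d):
            raise ValueError(f"prevalence targets domain without dictionary "
                             f"sentences: {d.value}")

    terms = list(dictionary.terms)
    notes: list[ClinicalNote] = []
    profiles: dict[str, PatientProfile] = {}
    gold: list[GoldLabel] = []
    tally: dict[str, dict[str, int]] = {}
    sources: dict[tuple[str, int], str] = {}

    for i in range(config.n_patients):
        pid = f"p{i:05d}"
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, i)))
        profile = _make_profile(pid, config, rng)
        profiles[pid] = profile
        tally[pid] = {d.value: 0 for d in ALL_DOMAINS}

        n_notes = max(1, int(rng.poisson(config.mean_notes_per_patient)))
        anchor = profile.first_ptsd_date
        for j in range(n_notes):
            note_id = f"{pid}-n{j}"
            offset = int(rng.integers(-365, int(config.followup_years * 365.25)))
            note_date = anchor + timedelta(days=offset)
            is_pre = (profile.first_psychotherapy_date is not None
                      and note_date < profile.first_psychotherapy_date)

            sentences: list[tuple[str, frozenset[RdocDomain], str]] = []
            for domain in ALL_DOMAINS:
                p = _note_prevalence(config, profile, is_pre, domain)
                if rng.random() >= p:
                    continue
                pool = dictionary.sentences_for_domain(domain)
                entry = pool[int(rng.integers(len(pool)))]
                text = paraphrase(entry, config.paraphrase_intensity, rng, terms)
                sentences.append((text, entry.domains, entry.id))
            if rng.random() < config.trap_rate and terms:
                template = _TRAP_TEMPLATES[int(rng.integers(len(_TRAP_TEMPLATES)))]
                kw = terms[int(rng.integers(len(terms)))]
                sentences.append((template.format(kw=kw), frozenset(), ""))
            for _ in range(int(rng.poisson(config.distractor_rate))):
                sentences.append(
                    (_DISTRACTORS[int(rng.integers(len(_DISTRACTORS)))],
                     frozenset(), ""))
            if not sentences:
                sentences.append(
                    (_DISTRACTORS[int(rng.integers(len(_DISTRACTORS)))],
                     frozenset(), ""))
            order = rng.permutation(len(sentences))
            sentences = [sentences[int(k)] for k in order]

            text = ". ".join(s[0] for s in sentences) + "."
            notes.append(ClinicalNote(patient_id=pid, note_id=note_id,
                                      date=note_date, text=text))
            for idx, (_, domains, source_id) in enumerate(sentences):
                gold.append(GoldLabel(note_id=note_id, sentence_index=idx,
                                      domains=domains, annotator="generator"))
                if source_id:
                    sources[(note_id, idx)] = source_id
                    for d in domains:
                        tally[pid][d.value] += 1

    return GoldCorpus(notes=notes, profiles=profiles, gold=gold,
                      tally=tally, planted_sources=sources)
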
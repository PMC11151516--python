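# Methods

This note documents the model and procedures implemented in `rdocnlp`, the
conventions and numerical choices that were genuinely open, what the
synthetic-data generator does and does not emulate, and known limitations.

## The extraction model

The unit of analysis is the note sentence. A sentence A receives a set of
RDoC domain labels (possibly empty, possibly several) by the rule

    assigned(A, τ) = { d : max_{B ∈ C_d(A)} cos(e(A), e(B)) ≥ τ }

where `e(·)` is a sentence embedding, `C_d(A)` is the set of dictionary
sentences labeled with domain `d` that share at least one matched keyword
lemma with A (the *keyword gate*), and τ is the operating threshold.

Design choices inside this rule:

- **Gate at the lemma level.** The gate requires a shared dictionary lemma,
  not an identical surface form: "stressed" in A gates on any dictionary
  sentence containing an inflection of "stress". This is the weakest gate
  consistent with requiring the keyword to be present in both sentences.
- **Per-domain maximum, not global argmax.** The "optimal match" is taken
  per domain, which is what permits multi-label assignment; a single global
  argmax would forbid it. All candidates are scanned, so the result does
  not depend on dictionary order; ties in the per-domain best break toward
  the lexicographically lowest dictionary sentence id.
- **Gate soundness.** A sentence with no keyword match has no candidates and
  is never assigned any domain, at any threshold.
- **No negation or section filtering.** "Denies anxiety" matches and may be
  assigned. Nothing in the extraction rule inspects negation, family
  history, or note sections; all mentions are counted and the run log
  reports totals so downstream users can audit this behaviour.

### Keyword matching

Matching is case-insensitive at word boundaries. A lemma matches its bare
form plus the fixed suffix set `{s, es, ed, ing}` — a deliberate,
enumerable alternative to a stemmer: every match is explainable
("anxieties" does *not* match "anxiety" because no suffix produces it;
"distress" does not match "stress" because of the word boundary).
Overlapping hits resolve leftmost-longest. All character offsets in the
package are 0-based, half-open.

### Sentence segmentation

A deterministic rule-based splitter tuned for clinical text: terminal
punctuation followed by whitespace ends a sentence, as does a hard line
break followed by a capitalized or numeric token (clinical notes are full
of list fragments); trailing periods of common clinical abbreviations
("Dr.", "pt.", "q.d.", "b.i.d.", …) are protected. Determinism matters
more here than linguistic perfection: spans must reproduce byte-identical
offsets across runs, and the segmentation is a partition — spans plus
inter-span whitespace reconstruct the note exactly.

### Embedding backends

Two backends satisfy one contract (fixed dimension, order-preserving,
deterministic):

- **reference** — the frozen pre-trained sentence encoder
  `all-mpnet-base-v2` (output dimension 768), used exactly as published.
  The package exposes no fine-tuning path by design. It is an optional
  dependency; when absent, construction fails with an error naming the test
  backend as the fallback — there is no silent substitution.
- **test** — a seeded hashed bag-of-words embedder (default dimension 512):
  lowercase alphanumeric tokens are hashed (keyed blake2b) into buckets
  with pseudo-random signs and the count vector is L2-normalized.
  Token-identical sentences embed identically (similarity 1); token-disjoint
  sentences are near-orthogonal up to hash collisions (empirically |cos| <
  0.2 at dimension 1024). It exists so that the entire pipeline, including
  similarity thresholds, is exercisable offline and reproducibly.

Cosine similarity is clamped to [−1, 1] against floating-point rounding; a
zero vector (possible for degenerate inputs) is defined to have similarity
0 with a warning rather than raising.

## Threshold calibration

Gold annotations are per-sentence domain sets. Evaluation reduces each
domain to a binary present/absent problem per sentence. "Macro-F1 per
domain" is ambiguous; both readings are implemented:

- `two_class` (default): mean of the positive-class and negative-class F1
  of the binary reduction;
- `positive_only`: plain positive-class F1.

An F1 undefined because a class has no instances and no predictions scores
1 in the macro average (no mistake was possible), and the event is logged.

The sweep re-thresholds stored per-domain best similarities — embeddings
are computed once per sentence, never per threshold. The operating point is
chosen by the **max-min rule**: the threshold whose worst per-domain F1 is
largest, ties toward the smaller threshold, with a configurable floor
(default 0.80) reported as met/not met. On the published six-domain
calibration grid (thresholds 0.1–0.6) this rule selects 0.3 with minimum
per-domain F1 0.83; it is the only simple selection rule consistent with
that grid, since the 0.4 and 0.5 columns beat 0.3 for some domains but
their column minima (0.76, 0.50) are lower.

## Statistics

**Exact Wilcoxon signed-rank.** Zero differences are dropped (classical
treatment; the Pratt variant is available via `zero_method="pratt"`).
Absolute differences are mid-ranked; W is the sum of positive-difference
ranks. When n ≤ 25 after zero-drop and the magnitudes are tie-free, the
null distribution of W is enumerated exactly over all 2ⁿ sign assignments
(by convolution over the integer ranks), and the two-sided p is
`min(1, 2·min(P(W ≤ w), P(W ≥ w)))` — a dyadic rational k/2ⁿ. Otherwise
the normal approximation with tie and continuity correction is used; the
result records which method was applied. The crossover at n = 25 keeps
enumeration cost (2²⁵) trivial while covering every paired design in this
package (n = 6 domains). Six uniformly one-signed tie-free pairs give
p = 2/2⁶ = 0.03125, the signature of a consistent six-domain effect.

**Friedman rank-sum.** Within-block mid-ranks;
`chi2 = 12/(n·k·(k+1)) · Σ R_j² − 3·n·(k+1)` divided by the standard tie
correction `1 − Σ(t³−t)/(n·k·(k²−1))`; df = k−1; upper-tail chi-square
p-value. All-constant blocks yield chi2 = 0, p = 1 (not an error). The
implementation is cross-checked in the tests against an independent
reference implementation to 1e-10. A 6-block × 3-condition design with a
strictly increasing trend in every block gives chi2 = 12 and p = e⁻⁶.

No multiplicity correction is applied across domains; the comparisons are
reported as-is.

## Cohort conventions

- **Abnormal instance**: ≥ 1 sentence of the patient assigned to the
  domain. The count threshold is configurable (`min_count`), but 1 is the
  default because no finer operationalization is standard.
- **Psychotherapy boundary**: a note dated exactly on the first
  psychotherapy date counts as *post* (a convention had to be fixed; it is
  applied everywhere and tested).
- **Year length**: 365.25 days.
- **Trajectory windows**: cumulative `(event, event + w·365.25 d]`,
  half-open on the left (a note dated on the event day is excluded);
  disjoint annual slices are available as an option. Cumulative counts are
  therefore monotone non-decreasing in window length, which the tests
  assert. The Friedman test for a trajectory uses windows as conditions and
  domains as blocks, on instance counts.
- **Wilcoxon pairing unit** for group comparisons: the six per-domain
  abnormal proportions (n = 6 pairs).

## Dictionaries

A dictionary has a keyword layer and a sentence layer; because
classification gates on a shared keyword, every dictionary sentence must
itself contain at least one keyword under the package matching rule — the
validator reports violations (and domains with no sentences) rather than
raising. Merging supports the expert-in-the-loop iteration cycle: keyword
domain sets union at the term level, sentence id collisions resolve toward
the delta (recorded), textually identical sentences with conflicting labels
under distinct ids are flagged, and new entries can be stamped with an
iteration provenance tag.

The shipped starter dictionary (29 keywords, 25 sentences, 3–5 per domain,
provenance `artifact`) covers all six domains with vocabulary from the
PTSD/RDoC construct literature (acute/potential/sustained threat,
frustrative non-reward, reduced behavioral activation, loss, reward
seeking, sleep–wakefulness, perception, motor action, …). It is a schema
demonstration and test fixture, not a clinically validated instrument;
real deployments should load their own expert-curated dictionaries through
the same CSV/JSON schema.

## The synthetic cohort generator

The generator emulates exactly the structure the analyses consume:

- patient profiles with configurable female fraction (default 0.63, the
  typical skew of a PTSD cohort), veteran fraction (0.21), psychotherapy
  fraction (0.5), and SRE/ASUD first-diagnosis rates (0.25 / 0.40), with a
  first-PTSD date anchoring up to ~4.5 years of follow-up so 1/2/4-year
  windows are populated;
- per note and domain, a Bernoulli decision at a subgroup-adjusted
  prevalence plants a paraphrase of a dictionary sentence of that domain.
  Defaults: base per-note prevalence 0.10 per domain, +0.04 for women in
  every domain, +0.05 for veterans in the two valence domains, +0.06 for
  pre-psychotherapy notes in every domain — the direction structure
  (female > male everywhere, veteran > non-veteran in the valence domains,
  pre > post) that the population analyses are meant to detect;
- the **paraphrase operator** is lexical: it substitutes at most
  `intensity × n_tokens` non-keyword tokens from a synonym table and may
  attach a filler phrase. Keyword tokens are never touched, so the planted
  sentence always passes the gate, and case-insensitive token overlap with
  the source stays ≥ 1 − intensity (default intensity 0.3);
- **traps** (a random keyword inside an administrative template sentence;
  gated in but lexically far from every dictionary sentence) and
  **distractors** (no keyword at all; never gated) exercise both failure
  modes of the gate.

Determinism: each patient's stream derives from
`SeedSequence((root_seed, patient_index))`, so output is byte-identical
across reruns and earlier patients are unchanged when the cohort grows.

What the generator does **not** emulate: real clinical-note style
(templates, headers, OCR noise, abbreviation-dense telegraphic prose),
negated or family-history mentions, label noise in gold annotations, and
semantic paraphrase beyond lexical substitution. Passing the recovery tests
therefore shows the pipeline's mechanics are correct under the stated
planting model — not that the test backend (or any backend) reaches any
particular accuracy on real EMR text.

## Problem sizes used in the shipped experiments

The planted-recovery experiment uses ~200 notes (70 patients) at paraphrase
intensity 0.3, where every domain's sentence-level F1 stays ≥ 0.95 at the
0.3 threshold. The group-comparison experiment uses 5,800 patients, sized
so both gender groups exceed ~2,000 patients — the scale at which the
planted one-sided six-domain effect is recovered in direction with near
certainty, making the exact six-pair Wilcoxon p = 0.03125 reproducible
through the full pipeline. Corpus size for dictionary construction is a
free parameter throughout.

## Known limitations

- No negation, uncertainty, or section handling; prevalence estimates on
  real notes will include negated mentions.
- The fixed inflection suffix set misses irregular morphology by design.
- The starter dictionary is illustrative; all substantive results depend on
  the quality of a user-supplied expert dictionary.
- Similarities are not calibrated probabilities; τ transfers across
  backends only after re-calibration against gold annotations.
- The exact Wilcoxon path requires tie-free magnitudes; tied designs fall
  back to the normal approximation even at small n, where the approximation
  is least accurate.
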
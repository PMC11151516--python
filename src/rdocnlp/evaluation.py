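"""Gold-standard evaluation: per-domain macro-F1, threshold sweep, selection.

Evaluation reduces the multi-label problem to six binary problems (domain
present / absent per sentence) and scores each domain separately. Because
"macro-F1 per domain" admits two readings, both are implemented:

* ``two_class`` (default): the mean of the F1 of the positive class and the
  F1 of the negative class of the binary reduction — the common reading of
  macro-F1 for a per-domain binary task;
* ``positive_only``: the plain positive-class F1, kept for sensitivity
  analysis.

An undefined F1 (a class with no true instances and no predictions) is
scored 1 in the macro average and logged — the classifier made no mistake
on an empty class.

The sweep evaluates a threshold grid against stored per-domain best
similarities (no re-embedding), and the operating point is chosen by the
max-min rule: take the threshold whose *worst* per-domain F1 is largest,
breaking ties toward the smaller threshold. The floor (default 0.80)
expresses the calibration goal that every domain clears a minimum F1.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

from .classifier import SentenceClassification
from .domains import ALL_DOMAINS, RdocDomain, parse_domains

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD_GRID = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6)
DEFAULT_F1_FLOOR = 0.80

F1Mode = Literal["two_class", "positive_only"]


@dataclass(frozen=True)
class GoldLabel:
    """SME annotation for one sentence: the set of domains truly present."""

    note_id: str
    sentence_index: int
    domains: frozenset[RdocDomain]
    annotator: str = ""

    @property
    def key(self) -> tuple[str, int]:
        return (self.note_id, self.sentence_index)


def read_gold_csv(path: str | Path) -> list[GoldLabel]:
    """Read gold labels from CSV (note_id, sentence_index, domains pipe-separated)."""
    out: list[GoldLabel] = []
    seen: set[tuple[str, int]] = set()
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for i, row in enumerate(csv.DictReader(fh), start=2):
            label = GoldLabel(note_id=row["note_id"],
                              sentence_index=int(row["sentence_index"]),
                              domains=parse_domains(row.get("domains", "")),
                              annotator=row.get("annotator", ""))
            if label.key in seen:
                raise ValueError(f"{path}:{i}: duplicate gold key {label.key}")
            seen.add(label.key)
            out.append(label)
    return out


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_counts(gold: Sequence[GoldLabel],
                     pred: Sequence[SentenceClassification],
                     domain: RdocDomain) -> ConfusionCounts:
    """Binary per-domain confusion over the gold-annotated sentences.

    Every predicted key must exist in the gold set; sentences in gold with
    no prediction count as negative predictions.
    """
    gold_by_key = {g.key: g for g in gold}
    missing = sorted({p.key for p in pred} - set(gold_by_key))
    if missing:
        raise KeyError(f"predicted keys missing from gold: {missing[:10]}"
                       + ("..." if len(missing) > 10 else ""))
    pred_pos = {p.key for p in pred if domain in p.assigned}
    tp = fp = fn = tn = 0
    for key, g in gold_by_key.items():
        truth = domain in g.domains
        predicted = key in pred_pos
        if truth and predicted:
            tp += 1
        elif truth:
            fn += 1
        elif predicted:
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _f1(tp: int, fp: int, fn: int) -> float | None:
    """Class F1; None when undefined (no instances and no predictions)."""
    if tp == 0 and fp == 0 and fn == 0:
        return None
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def f1_macro_domain(counts: ConfusionCounts, mode: F1Mode = "two_class") -> float:
    """Per-domain macro-F1 of the binary present/absent reduction."""
    pos = _f1(counts.tp, counts.fp, counts.fn)
    if mode == "positive_only":
        if pos is None:
            logger.info("positive class undefined (no instances, no predictions); "
                        "scoring 1.0")
            return 1.0
        return pos
    # negative class: TN acts as TP, FN as "false positive" of the negative
    # class (predicted negative, truly positive), FP as its false negative
    neg = _f1(counts.tn, counts.fn, counts.fp)
    parts = []
    for name, val in (("positive", pos), ("negative", neg)):
        if val is None:
            logger.info("%s class undefined; scoring 1.0 in macro average", name)
            val = 1.0
        parts.append(val)
    return sum(parts) / 2


# ---------------------------------------------------------------------------
# Threshold sweep (the calibration table)
# ---------------------------------------------------------------------------


@dataclass
class SweepTable:
    """Thresholds × domains grid of macro-F1 values."""

    thresholds: tuple[float, ...]
    scores: dict[RdocDomain, dict[float, float]]

    def column_min(self, threshold: float) -> float:
        return min(self.scores[d][threshold] for d in self.scores)

    def to_rows(self) -> list[dict]:
        rows = []
        for domain in ALL_DOMAINS:
            if domain not in self.scores:
                continue
            row: dict = {"domain": domain.value}
            for t in self.thresholds:
                row[f"{t:g}"] = round(self.scores[domain][t], 6)
            rows.append(row)
        return rows

    def write_csv(self, path: str | Path) -> None:
        rows = self.to_rows()
        fieldnames = ["domain"] + [f"{t:g}" for t in self.thresholds]
        with Path(path).open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=fieldnames)
            writer.writeheader()
            writer.writerows(rows)


def _assign_at(pred: SentenceClassification, tau: float) -> frozenset[RdocDomain]:
    return frozenset(d for d, b in pred.per_domain_best.items()
                     if b.similarity >= tau)


def sweep(gold: Sequence[GoldLabel], pred: Sequence[SentenceClassification],
          thresholds: Sequence[float] = DEFAULT_THRESHOLD_GRID,
          mode: F1Mode = "two_class") -> SweepTable:
    """Evaluate the full thresholds × domains macro-F1 grid.

    Predictions carry their per-domain best similarities, so each cell is a
    pure re-thresholding: assignments are recomputed as ``best ≥ τ`` and
    scored against gold. No re-embedding happens inside the sweep.
    """
    if not gold:
        raise ValueError("empty gold set")
    from dataclasses import replace

    scores: dict[RdocDomain, dict[float, float]] = {d: {} for d in ALL_DOMAINS}
    for tau in thresholds:
        repred = [replace(p, assigned=_assign_at(p, tau), threshold=tau)
                  for p in pred]
        for domain in ALL_DOMAINS:
            counts = confusion_counts(gold, repred, domain)
            scores[domain][tau] = f1_macro_domain(counts, mode=mode)
    return SweepTable(thresholds=tuple(thresholds), scores=scores)


@dataclass(frozen=True)
class ThresholdSelection:
    threshold: float
    min_f1: float
    meets_floor: bool


def select_threshold(table: SweepTable | Mapping[RdocDomain, Mapping[float, float]],
                     floor: float = DEFAULT_F1_FLOOR) -> ThresholdSelection:
    """Pick the operating threshold by the max-min rule.

    Returns the threshold maximizing the minimum per-domain F1; ties go to
    the smallest threshold. ``meets_floor`` reports whether that minimum
    clears the floor.
    """
    if isinstance(table, SweepTable):
        thresholds = table.thresholds
        scores = table.scores
    else:
        scores = dict(table)
        if not scores:
            raise ValueError("empty sweep table")
        thresholds = tuple(sorted(next(iter(scores.values())).keys()))
    if not thresholds:
        raise ValueError("empty sweep table")
    best_tau, best_min = None, -1.0
    for tau in sorted(thresholds):
        col_min = min(scores[d][tau] for d in scores)
        if col_min > best_min:  # strict > keeps the smallest threshold on ties
            best_tau, best_min = tau, col_min
    return ThresholdSelection(threshold=best_tau, min_f1=best_min,
                              meets_floor=best_min >= floor)


def table_from_grid(grid: Mapping[RdocDomain, Sequence[float]],
                    thresholds: Sequence[float] = DEFAULT_THRESHOLD_GRID) -> SweepTable:
    """Build a SweepTable from per-domain score rows (e.g. a published table)."""
    scores = {d: {t: float(v) for t, v in zip(thresholds, row)}
              for d, row in grid.items()}
    return SweepTable(thresholds=tuple(thresholds), scores=scores)
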
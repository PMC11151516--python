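from __future__ import annotations

import numpy as np
import pytest

from rdocnlp.classifier import DomainBest, SentenceClassification
from rdocnlp.domains import ALL_DOMAINS, RdocDomain
from rdocnlp.evaluation import (ConfusionCounts, GoldLabel, confusion_counts,
                                f1_macro_domain, read_gold_csv,
                                select_threshold, sweep, table_from_grid)

NV = RdocDomain.NEGATIVE_VALENCE

#: Published calibration grid: per-domain macro-F1 at thresholds 0.1..0.6.
PUBLISHED_GRID = {
    RdocDomain.AROUSAL_REGULATORY: [0.48, 0.70, 0.90, 0.79, 0.50, 0.47],
    RdocDomain.COGNITIVE: [0.17, 0.47, 0.87, 0.89, 0.83, 0.67],
    RdocDomain.NEGATIVE_VALENCE: [0.17, 0.42, 0.92, 0.95, 0.97, 0.67],
    RdocDomain.POSITIVE_VALENCE: [0.17, 0.54, 0.84, 0.81, 0.77, 0.47],
    RdocDomain.SENSORIMOTOR: [0.17, 0.60, 0.83, 0.86, 0.89, 0.96],
    RdocDomain.SOCIAL_PROCESSES: [0.17, 0.66, 0.86, 0.76, 0.50, 0.17],
}


def _pred(note_id, index, sims: dict[RdocDomain, float], tau=0.3):
    per_domain = {d: DomainBest(similarity=s, dictionary_sentence_id="s1",
                                shared_term="t") for d, s in sims.items()}
    assigned = frozenset(d for d, s in sims.items() if s >= tau)
    return SentenceClassification(
        patient_id="p", note_id=note_id, sentence_index=index, text="",
        candidates_considered=len(sims), per_domain_best=per_domain,
        assigned=assigned, threshold=tau)


def _gold(note_id, index, domains=frozenset()):
    return GoldLabel(note_id=note_id, sentence_index=index,
                     domains=frozenset(domains))


def test_confusion_perfect_predictions():
    gold = [_gold("n", i, {NV} if i < 4 else frozenset()) for i in range(10)]
    pred = [_pred("n", i, {NV: 0.9} if i < 4 else {}) for i in range(10)]
    c = confusion_counts(gold, pred, NV)
    assert (c.tp, c.fp, c.fn, c.tn) == (4, 0, 0, 6)
    assert c.total == 10


def test_confusion_all_empty_predictions():
    gold = [_gold("n", i, {NV} if i < 4 else frozenset()) for i in range(10)]
    pred = [_pred("n", i, {}) for i in range(10)]
    c = confusion_counts(gold, pred, NV)
    assert (c.tp, c.fp, c.fn, c.tn) == (0, 0, 4, 6)


def test_confusion_hand_tally():
    """8 sentences: 3 gold positive (1 missed twice), 1 false positive."""
    gold_pos = [0, 1, 2]
    gold = [_gold("n", i, {NV} if i in gold_pos else frozenset())
            for i in range(8)]
    pred_pos = [0, 5]  # hits 0, misses 1 and 2, false alarm on 5
    pred = [_pred("n", i, {NV: 0.9} if i in pred_pos else {}) for i in range(8)]
    c = confusion_counts(gold, pred, NV)
    assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 2, 4)


def test_confusion_rejects_unknown_keys():
    gold = [_gold("n", 0, {NV})]
    pred = [_pred("n", 0, {NV: 0.9}), _pred("other", 3, {})]
    with pytest.raises(KeyError, match="other"):
        confusion_counts(gold, pred, NV)


def test_f1_macro_perfect_is_one():
    assert f1_macro_domain(ConfusionCounts(4, 0, 0, 6)) == 1.0


def test_f1_macro_two_class_hand_computed():
    # positive F1 = 0, negative F1 = 2*6/(12+4+0) = 0.75, macro 0.375
    assert f1_macro_domain(ConfusionCounts(0, 0, 4, 6)) == pytest.approx(0.375)


def test_f1_macro_all_wrong_balanced_is_zero():
    assert f1_macro_domain(ConfusionCounts(0, 5, 5, 0)) == 0.0


def test_f1_positive_only_mode():
    c = ConfusionCounts(3, 1, 1, 5)
    assert f1_macro_domain(c, mode="positive_only") == pytest.approx(0.75)


def test_f1_undefined_class_scores_one():
    # no positives anywhere: positive class undefined -> 1, negative perfect
    assert f1_macro_domain(ConfusionCounts(0, 0, 0, 10)) == 1.0


def test_f1_agrees_with_sklearn_on_random_tables():
    """Independent textbook oracle over 1,000 random confusion tables."""
    from sklearn.metrics import f1_score

    rng = np.random.default_rng(42)
    for _ in range(1000):
        tp, fp, fn, tn = (int(x) for x in rng.integers(0, 20, size=4))
        if tp + fp + fn + tn == 0:
            continue
        y_true = [1] * tp + [0] * fp + [1] * fn + [0] * tn
        y_pred = [1] * tp + [1] * fp + [0] * fn + [0] * tn
        ours = f1_macro_domain(ConfusionCounts(tp, fp, fn, tn))
        ref = f1_score(y_true, y_pred, labels=[1, 0], average="macro",
                       zero_division=1)
        assert ours == pytest.approx(ref, abs=1e-12)


def test_sweep_degenerate_similarities_perfect_everywhere():
    gold = [_gold("n", i, {NV} if i < 5 else frozenset()) for i in range(10)]
    pred = [_pred("n", i, {NV: 1.0} if i < 5 else {}) for i in range(10)]
    table = sweep(gold, pred, thresholds=(0.1, 0.3, 0.5, 1.0))
    assert all(table.scores[NV][t] == 1.0 for t in table.thresholds)


def test_sweep_recall_drops_as_threshold_crosses_similarity():
    """Two true positives at similarities 0.25 and 0.35."""
    gold = [_gold("n", 0, {NV}), _gold("n", 1, {NV}), _gold("n", 2)]
    pred = [_pred("n", 0, {NV: 0.25}), _pred("n", 1, {NV: 0.35}),
            _pred("n", 2, {})]
    table = sweep(gold, pred, thresholds=(0.2, 0.4), mode="positive_only")
    assert table.scores[NV][0.2] == pytest.approx(1.0)      # recall 2/2
    assert table.scores[NV][0.4] == pytest.approx(0.0)      # recall 0/2
    mid = sweep(gold, pred, thresholds=(0.3,), mode="positive_only")
    assert mid.scores[NV][0.3] == pytest.approx(2 / 3)      # recall 1/2


def test_sweep_rejects_empty_gold():
    with pytest.raises(ValueError, match="empty gold"):
        sweep([], [], thresholds=(0.3,))


def test_select_threshold_on_published_grid():
    """Max-min over the published grid picks 0.3 with min F1 0.83 >= 0.80."""
    table = table_from_grid(PUBLISHED_GRID)
    sel = select_threshold(table, floor=0.80)
    assert sel.threshold == pytest.approx(0.3)
    assert sel.min_f1 == pytest.approx(0.83)
    assert sel.meets_floor


def test_select_threshold_uniform_column_wins():
    grid = {d: [0.5, 1.0, 0.4] for d in ALL_DOMAINS}
    sel = select_threshold(table_from_grid(grid, thresholds=(0.1, 0.2, 0.3)))
    assert sel.threshold == 0.2 and sel.min_f1 == 1.0


def test_select_threshold_tie_goes_to_smaller():
    grid = {d: [0.9, 0.9] for d in ALL_DOMAINS}
    sel = select_threshold(table_from_grid(grid, thresholds=(0.2, 0.5)))
    assert sel.threshold == 0.2


def test_selection_invariant_to_domain_permutation():
    table = table_from_grid(PUBLISHED_GRID)
    permuted = table_from_grid(
        {d: PUBLISHED_GRID[d] for d in reversed(list(PUBLISHED_GRID))})
    a, b = select_threshold(table), select_threshold(permuted)
    assert (a.threshold, a.min_f1) == (b.threshold, b.min_f1)


def test_read_gold_csv_rejects_duplicates(tmp_path):
    p = tmp_path / "gold.csv"
    p.write_text("note_id,sentence_index,domains\nn1,0,negative_valence\nn1,0,\n")
    with pytest.raises(ValueError, match="duplicate"):
        read_gold_csv(p)
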
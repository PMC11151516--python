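from __future__ import annotations

from datetime import date

import pytest

from rdocnlp.classifier import DomainBest, SentenceClassification, classify_corpus
from rdocnlp.cohort import (DegenerateSampleError, GroupSummary, PatientProfile,
                            aggregate, compare_groups, group_summary,
                            read_profiles_csv, split_pre_post_psychotherapy,
                            trajectory, word_frequencies, write_profiles_csv)
from rdocnlp.domains import ALL_DOMAINS, RdocDomain
from rdocnlp.preprocess import ClinicalNote, KeywordMatch

NV = RdocDomain.NEGATIVE_VALENCE
AR = RdocDomain.AROUSAL_REGULATORY


def _cls(patient_id, note_id, index, domains, sim=0.9):
    ds = frozenset(domains)
    return SentenceClassification(
        patient_id=patient_id, note_id=note_id, sentence_index=index, text="",
        candidates_considered=1,
        per_domain_best={d: DomainBest(sim, "s1", "t") for d in ds},
        assigned=ds, threshold=0.3)


def _profile(pid, **kw):
    return PatientProfile(patient_id=pid, **kw)


# -- aggregate -------------------------------------------------------------


def test_aggregate_counts_and_flags():
    cls = [_cls("p1", "n1", i, {NV}) for i in range(3)]
    profiles = {"p1": _profile("p1"), "p2": _profile("p2")}
    dps, excluded = aggregate(cls, profiles)
    assert excluded == 0
    assert dps["p1"].count(NV) == 3
    assert dps["p1"].abnormal(NV) and dps["p1"].any_domain_abnormal()
    assert not dps["p1"].abnormal(AR)
    assert dps["p2"].counts == {} and not dps["p2"].any_domain_abnormal()


def test_aggregate_excludes_unknown_patients():
    cls = [_cls("ghost", "n1", 0, {NV})]
    dps, excluded = aggregate(cls, {"p1": _profile("p1")})
    assert excluded == 1 and dps["p1"].counts == {}


def test_aggregate_matches_generator_tally(starter, backend, small_corpus):
    preds = list(classify_corpus(iter(small_corpus.notes), starter, backend,
                                 threshold=0.3))
    dps, _ = aggregate(preds, small_corpus.profiles)
    total_recovered = sum(sum(dp.counts.values()) for dp in dps.values())
    total_planted = sum(sum(t.values()) for t in small_corpus.tally.values())
    # near-perfect recovery: small slack for paraphrase/trap noise
    assert abs(total_recovered - total_planted) <= 0.05 * total_planted
    perfect = sum(1 for pid, dp in dps.items()
                  if {d.value: dp.count(d) for d in ALL_DOMAINS
                      if dp.count(d)} ==
                  {k: v for k, v in small_corpus.tally[pid].items() if v})
    assert perfect >= 0.9 * len(dps)


# -- group summaries -------------------------------------------------------


def test_group_summary_all_abnormal_gives_proportion_one():
    profiles = {f"p{i}": _profile(f"p{i}", gender="female") for i in range(5)}
    cls = [_cls(pid, f"{pid}-n", 0, set(ALL_DOMAINS)) for pid in profiles]
    dps, _ = aggregate(cls, profiles)
    gs = group_summary(profiles, dps, lambda p: p.gender == "female")
    assert gs.n == 5
    assert all(gs.proportion(d) == 1.0 for d in ALL_DOMAINS)
    assert gs.any_domain_proportion == 1.0


def test_group_summary_single_patient_proportions_are_binary():
    profiles = {"p1": _profile("p1")}
    dps, _ = aggregate([_cls("p1", "n", 0, {NV})], profiles)
    gs = group_summary(profiles, dps, lambda p: True)
    assert gs.proportion(NV) == 1.0
    assert gs.proportion(AR) == 0.0


def test_group_summary_empty_group_flagged():
    gs = group_summary({}, {}, lambda p: True)
    assert gs.n == 0
    assert gs.any_domain_proportion != gs.any_domain_proportion  # NaN


def test_subgroup_counts_sum_to_cohort_counts(starter, backend, small_corpus):
    preds = list(classify_corpus(iter(small_corpus.notes), starter, backend,
                                 threshold=0.3))
    dps, _ = aggregate(preds, small_corpus.profiles)
    whole = group_summary(small_corpus.profiles, dps, lambda p: True)
    female = group_summary(small_corpus.profiles, dps,
                           lambda p: p.gender == "female")
    male = group_summary(small_corpus.profiles, dps,
                         lambda p: p.gender == "male")
    for d in ALL_DOMAINS:
        assert female.domain_counts[d] + male.domain_counts[d] == \
            whole.domain_counts[d]


def test_compare_groups_one_sided_effect_gives_signature_p():
    a = GroupSummary("a", 100,
                     {d: c for d, c in zip(ALL_DOMAINS, [60, 55, 50, 45, 40, 35])},
                     70)
    b = GroupSummary("b", 100,
                     {d: c for d, c in zip(ALL_DOMAINS, [50, 46, 42, 38, 34, 33])},
                     60)
    cmp = compare_groups(a, b)
    assert cmp.domains_favoring_a == 6
    assert cmp.wilcoxon is not None
    assert cmp.wilcoxon.p_two_sided == pytest.approx(0.03125)


def test_compare_groups_identical_summaries_degenerate():
    g = GroupSummary("g", 10, {d: 5 for d in ALL_DOMAINS}, 8)
    cmp = compare_groups(g, g)
    assert cmp.wilcoxon is None
    assert "zero" in cmp.wilcoxon_note


def test_compare_groups_rejects_empty_group():
    g = GroupSummary("g", 10, {d: 5 for d in ALL_DOMAINS}, 8)
    empty = GroupSummary("e", 0, {d: 0 for d in ALL_DOMAINS}, 0)
    with pytest.raises(ValueError, match="empty group"):
        compare_groups(g, empty)


# -- pre/post psychotherapy ------------------------------------------------


def test_pre_post_boundary_rules():
    therapy = date(2015, 6, 1)
    profiles = {"p1": _profile("p1", first_psychotherapy_date=therapy),
                "p2": _profile("p2")}
    notes = [
        ClinicalNote("p1", "before", date(2015, 5, 31), "x"),
        ClinicalNote("p1", "on_day", therapy, "x"),
        ClinicalNote("p1", "after", date(2015, 6, 2), "x"),
        ClinicalNote("p2", "no_therapy", date(2015, 6, 2), "x"),
    ]
    pre, post, excluded = split_pre_post_psychotherapy(notes, profiles)
    assert [n.note_id for n in pre] == ["before"]
    assert [n.note_id for n in post] == ["on_day", "after"]
    assert excluded == 1


def test_pre_post_partition_is_exact(small_corpus):
    pre, post, excluded = split_pre_post_psychotherapy(
        small_corpus.notes, small_corpus.profiles)
    with_date = [n for n in small_corpus.notes
                 if small_corpus.profiles[n.patient_id].first_psychotherapy_date]
    assert len(pre) + len(post) == len(with_date)
    assert excluded == len(small_corpus.notes) - len(with_date)
    assert {n.note_id for n in pre}.isdisjoint({n.note_id for n in post})


# -- trajectories ----------------------------------------------------------


def _traj_setup():
    event = date(2015, 1, 1)
    profiles = {"p1": _profile("p1", first_ptsd_date=event)}
    notes = [ClinicalNote("p1", "n1", date(2018, 1, 1), "x"),   # ~3y post
             ClinicalNote("p1", "n0", date(2014, 12, 1), "x")]  # pre-event
    cls = [_cls("p1", "n1", 0, {NV}), _cls("p1", "n0", 0, {NV})]
    return profiles, notes, cls


def test_trajectory_window_membership():
    profiles, notes, cls = _traj_setup()
    table = trajectory(cls, notes, profiles, "ptsd")
    assert table.instance_counts.get((1, NV), 0) == 0
    assert table.instance_counts.get((2, NV), 0) == 0
    assert table.instance_counts.get((4, NV), 0) == 1  # only the 3y note
    assert table.proportion(4, NV) == 1.0


def test_trajectory_counts_monotone_in_cumulative_windows(starter, backend,
                                                          small_corpus):
    preds = list(classify_corpus(iter(small_corpus.notes), starter, backend,
                                 threshold=0.3))
    table = trajectory(preds, small_corpus.notes, small_corpus.profiles, "ptsd")
    for d in ALL_DOMAINS:
        counts = [table.instance_counts.get((w, d), 0)
                  for w in table.windows_years]
        assert counts == sorted(counts)
    assert table.friedman is not None


def test_trajectory_disjoint_windows_sum_to_cumulative(starter, backend,
                                                       small_corpus):
    preds = list(classify_corpus(iter(small_corpus.notes), starter, backend,
                                 threshold=0.3))
    cum = trajectory(preds, small_corpus.notes, small_corpus.profiles, "ptsd")
    dis = trajectory(preds, small_corpus.notes, small_corpus.profiles, "ptsd",
                     cumulative=False)
    for d in ALL_DOMAINS:
        total = sum(dis.instance_counts.get((w, d), 0)
                    for w in dis.windows_years)
        assert total == cum.instance_counts.get((4, d), 0)


def test_trajectory_no_event_dates_yields_empty_table():
    profiles = {"p1": _profile("p1")}
    table = trajectory([], [], profiles, "sre")
    assert table.n_patients == 0
    assert table.instance_counts == {} and table.friedman is None


# -- word frequencies ------------------------------------------------------


def _match(term):
    return KeywordMatch(term=term, surface=term, start=0, end=len(term))


def test_word_frequencies_counts_and_ranking():
    cls = [_cls("p", "n", i, {NV}) for i in range(30)] + \
          [_cls("p", "m", i, {AR}) for i in range(10)]
    matches = {("n", i): [_match("stress")] for i in range(30)}
    matches.update({("m", i): [_match("sleep")] for i in range(10)})
    ranked = word_frequencies(cls, matches)
    assert ranked == [("stress", 30), ("sleep", 10)]


def test_word_frequencies_ties_alphabetical_and_scope():
    cls = [_cls("p", "n", 0, {NV}), _cls("p", "n", 1, {AR}),
           _cls("p", "n", 2, set())]
    matches = {("n", 0): [_match("worry")], ("n", 1): [_match("sleep")],
               ("n", 2): [_match("stress")]}  # unassigned: never counted
    assert word_frequencies(cls, matches) == [("sleep", 1), ("worry", 1)]
    assert word_frequencies(cls, matches, scope=AR) == [("sleep", 1)]
    assert word_frequencies([], {}) == []


# -- profile I/O -----------------------------------------------------------


def test_profiles_csv_round_trip(tmp_path, small_corpus):
    path = tmp_path / "profiles.csv"
    write_profiles_csv(small_corpus.profiles.values(), path)
    back = read_profiles_csv(path)
    assert back == small_corpus.profiles


def test_profiles_csv_rejects_duplicates(tmp_path):
    path = tmp_path / "profiles.csv"
    path.write_text("patient_id,gender\np1,female\np1,male\n")
    with pytest.raises(ValueError, match="duplicate"):
        read_profiles_csv(path)
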
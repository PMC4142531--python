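"""Drug-ADE record construction and class/SOC aggregation."""

import random

import pandas as pd
import pytest

from aersdm.aers_io import ReacRecord
from aersdm.aggregate import (PT_LEVEL, SOC_LEVEL, NormalizedDrugAde,
                              aggregate_pairs, build_drug_ade_records,
                              class_profile, count_unique_pairs,
                              soc_distribution)
from aersdm.dedup import deduplicate, filter_table
from aersdm.drug_normalizer import build_lexicon, normalize_drug_records
from aersdm.ndfrt_classify import ClassMembership, classify_concept, load_class_table


@pytest.fixture(scope="module")
def pipeline(fixture_set, graph, lexicon, meddra):
    """Run the full pipeline once on the session corpus."""
    aers = fixture_set.aers
    keep = deduplicate(aers.demo)
    mentions = normalize_drug_records(filter_table(aers.drug, keep), lexicon)
    build = build_drug_ade_records(mentions, filter_table(aers.reac, keep),
                                   keep, meddra)
    table = load_class_table(fixture_set.rxnorm.class_tsv_path)
    classifications = {
        rxcui: classify_concept(graph, rxcui, table)
        for rxcui in {r.rxcui for r in build.records}}
    return build, classifications


def _mini_meddra(tmp_path):
    from aersdm.meddra_map import load_meddra
    path = tmp_path / "m.tsv"
    path.write_text("pt_term\tpt_code\tsoc_code\tsoc_name\tprimary_flag\n"
                    "Nausea\t1\t100\tGI\tY\n"
                    "Rash\t2\t200\tSkin\tY\n"
                    "Pruritus\t3\t200\tSkin\tY\n")
    return load_meddra(path)


def _mention(isr, seq, rxcui):
    from aersdm.drug_normalizer import DrugMention
    status = "matched" if rxcui else "unmatched"
    return DrugMention(isr=isr, drug_seq=seq, input_string=f"D{seq}",
                       matched_rxcui=rxcui, matched_name=None if not rxcui else "x",
                       status=status)


def test_cross_product_of_drugs_and_reactions(tmp_path):
    from aersdm.dedup import KeepSet
    meddra = _mini_meddra(tmp_path)
    keep = KeepSet(frozenset({7}), {1: 7})
    mentions = [_mention(7, 1, 11), _mention(7, 2, 22)]
    reacs = [ReacRecord(7, "Nausea"), ReacRecord(7, "Rash"), ReacRecord(7, "Pruritus")]
    build = build_drug_ade_records(mentions, reacs, keep, meddra)
    assert len(build.records) == 6
    assert {(r.rxcui, r.pt_code) for r in build.records} == \
        {(11, 1), (11, 2), (11, 3), (22, 1), (22, 2), (22, 3)}
    assert {r.soc_code for r in build.records if r.pt_code in (2, 3)} == {200}


def test_report_without_matched_drugs_contributes_nothing(tmp_path):
    from aersdm.dedup import KeepSet
    meddra = _mini_meddra(tmp_path)
    keep = KeepSet(frozenset({7}), {1: 7})
    build = build_drug_ade_records([_mention(7, 1, None)],
                                   [ReacRecord(7, "Nausea")], keep, meddra)
    assert build.records == [] and build.n_unmatched_drugs == 1


def test_unmapped_pt_counted_not_raised(tmp_path):
    from aersdm.dedup import KeepSet
    meddra = _mini_meddra(tmp_path)
    keep = KeepSet(frozenset({7}), {1: 7})
    build = build_drug_ade_records([_mention(7, 1, 11)],
                                   [ReacRecord(7, "Mystery event")], keep, meddra)
    assert build.records == [] and build.n_unmapped_pts == 1


def test_fixture_records_equal_planted_pair_list(fixture_set, pipeline):
    build, _ = pipeline
    got = sorted((r.isr, r.rxcui, r.pt_code, r.soc_code) for r in build.records)
    assert got == sorted(fixture_set.aers.planted_records)


def test_unique_pair_counting_at_both_levels():
    records = [NormalizedDrugAde(1, 11, 1, 100), NormalizedDrugAde(2, 11, 1, 100),
               NormalizedDrugAde(1, 11, 2, 100), NormalizedDrugAde(1, 22, 2, 100)]
    assert count_unique_pairs(records, PT_LEVEL) == 3
    assert count_unique_pairs(records, SOC_LEVEL) == 2  # PTs collapse per drug


def test_soc_pairs_never_exceed_pt_pairs(pipeline):
    build, _ = pipeline
    assert count_unique_pairs(build.records, SOC_LEVEL) <= \
        count_unique_pairs(build.records, PT_LEVEL)


def test_aggregation_matches_pandas_groupby_oracle(pipeline):
    build, classifications = pipeline
    axis = "Mechanism of Action"
    for level, code_of in ((PT_LEVEL, lambda r: r.pt_code),
                           (SOC_LEVEL, lambda r: r.soc_code)):
        # a class reached via two anchors still counts once per record
        rows = [(class_code, code_of(r))
                for r in build.records
                for class_code in {m.class_code
                                   for m in classifications.get(r.rxcui, ())
                                   if m.axis == axis}]
        expected = (pd.DataFrame(rows, columns=["class_code", "ade_code"])
                    .groupby(["class_code", "ade_code"]).size())
        got = aggregate_pairs(build.records, classifications, axis, level)
        assert {(p.class_code, p.ade_code): p.count for p in got} == \
            expected.to_dict()
        counts = [p.count for p in got]
        assert counts == sorted(counts, reverse=True)


def test_drug_in_two_classes_increments_both():
    records = [NormalizedDrugAde(1, 11, 1, 100)]
    cls = {11: {ClassMembership(11, "VA Class", "A", "a"),
                ClassMembership(11, "VA Class", "B", "b")}}
    got = aggregate_pairs(records, cls, "VA Class", PT_LEVEL)
    assert {(p.class_code, p.count) for p in got} == {("A", 1), ("B", 1)}


def test_aggregation_invariant_under_record_shuffling(pipeline):
    build, classifications = pipeline
    shuffled = list(build.records)
    random.Random(3).shuffle(shuffled)
    assert aggregate_pairs(shuffled, classifications, "VA Class", PT_LEVEL) == \
        aggregate_pairs(build.records, classifications, "VA Class", PT_LEVEL)


def test_soc_partition_conserves_record_total(pipeline, meddra):
    build, _ = pipeline
    rows = soc_distribution(build.records, meddra)
    assert sum(r.n_records for r in rows) == len(build.records)
    assert rows[0].n_records == max(r.n_records for r in rows)


def test_single_soc_corpus_has_100_percent(tmp_path):
    meddra = _mini_meddra(tmp_path)
    records = [NormalizedDrugAde(1, 11, 2, 200), NormalizedDrugAde(2, 11, 3, 200)]
    (row,) = soc_distribution(records, meddra)
    assert row.pct == 100.0 and row.n_pt_codes == 2 and row.soc_name == "Skin"


def test_class_profile_counts_reports_and_drugs(pipeline, fixture_set):
    build, classifications = pipeline
    axis = "VA Class"
    rows = class_profile(build.records, classifications, axis)
    # brute-force recomputation from the planted record list
    planted = fixture_set.aers.planted_records
    memberships = fixture_set.rxnorm.membership_truth
    expected: dict[str, tuple[set, set]] = {}
    for isr, rxcui, _pt, _soc in planted:
        for m_axis, code, _name in memberships.get(rxcui, ()):
            if m_axis == axis:
                expected.setdefault(code, (set(), set()))
                expected[code][0].add(isr)
                expected[code][1].add(rxcui)
    assert {r.class_code: (r.n_reports, r.n_drugs) for r in rows} == \
        {code: (len(isrs), len(drugs)) for code, (isrs, drugs) in expected.items()}
    assert [r.n_reports for r in rows] == sorted((r.n_reports for r in rows),
                                                 reverse=True)


def test_class_with_fewer_drugs_can_outrank_by_reports():
    records = ([NormalizedDrugAde(i, 11, 1, 100) for i in range(5)]
               + [NormalizedDrugAde(99, 21, 1, 100),
                  NormalizedDrugAde(99, 22, 1, 100)])
    cls = {11: {ClassMembership(11, "Pharmacokinetics", "HEP", "Hepatic excretion")},
           21: {ClassMembership(21, "Pharmacokinetics", "FEC", "Fecal excretion")},
           22: {ClassMembership(22, "Pharmacokinetics", "FEC", "Fecal excretion")}}
    rows = class_profile(records, cls, "Pharmacokinetics")
    assert rows[0].class_code == "HEP"  # one drug, five reports, ranks first
    assert rows[0].n_drugs < rows[1].n_drugs


def test_empty_records_give_empty_profile():
    assert class_profile([], {}, "VA Class") == []
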
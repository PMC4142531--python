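"""Greedy NDF-RT traversal, class extraction and coverage arithmetic."""

import random

import pytest

from conftest import bfs_anchor_oracle, random_typed_graph

from aersdm.ndfrt_classify import (AXES, ClassMembership, class_table_from_graph,
                                   classify, classify_concept, coverage_report,
                                   find_ndfrt_anchors, load_class_table)
from aersdm.rxgraph import RxGraph, UnknownConceptError


def small_brand_graph() -> RxGraph:
    """Five concepts: brand -> clinical drug (NDF-RT) -> ingredient chain."""
    g = RxGraph()
    g.add_concept(1, "Acetyline", "IN", "RXNORM")
    g.add_concept(2, "Acetyline 10 MG Oral Tablet", "SCD", "RXNORM")
    g.add_concept(2, "Acetyline 10 MG Oral Tablet", "SCD", "NDFRT")
    g.add_concept(3, "Branva", "BN", "RXNORM")
    g.add_concept(4, "Branva 10 MG Oral Tablet", "SBD", "RXNORM")
    g.add_concept(5, "Unrelated", "IN", "RXNORM")
    g.add_relation(2, 1, "has_ingredient")
    g.add_relation(3, 1, "tradename_of")
    g.add_relation(4, 2, "tradename_of")
    return g


def test_ndfrt_sourced_query_anchors_itself_at_depth_zero():
    g = small_brand_graph()
    res = find_ndfrt_anchors(g, 2)
    assert res.anchors == {2} and res.depth == 0


def test_branded_drug_reaches_clinical_drug_at_depth_one():
    g = small_brand_graph()
    res = find_ndfrt_anchors(g, 4)
    assert res.anchors == {2} and res.depth == 1
    assert "tradename_of" in res.path_log


def test_unreachable_concept_returns_empty_anchor_set():
    g = small_brand_graph()
    res = find_ndfrt_anchors(g, 5)
    assert res.anchors == frozenset() and res.depth is None


def test_absent_rxcui_raises_distinct_error():
    with pytest.raises(UnknownConceptError):
        find_ndfrt_anchors(small_brand_graph(), 999)


def test_traversal_matches_exhaustive_search_on_random_graphs():
    rng = random.Random(2024)
    for trial in range(12):
        g = random_typed_graph(rng, rng.randint(30, 200))
        for rxcui in g.concepts:
            res = find_ndfrt_anchors(g, rxcui)
            assert (res.depth, res.anchors) == bfs_anchor_oracle(g, rxcui), \
                f"trial {trial}, query {rxcui}"


def test_fixture_anchors_match_planted_truth(fixture_set, graph):
    fx = fixture_set.rxnorm
    for rxcui in fx.drug_rxcuis:
        res = find_ndfrt_anchors(graph, rxcui)
        depth, anchors = fx.anchor_truth[rxcui]
        assert (res.depth, res.anchors) == (depth, anchors)


def test_single_class_row_passes_through():
    g = small_brand_graph()
    table = {2: frozenset({("VA Class", "CV100", "Cardiovascular Agents")})}
    assert classify(g, {2}, table) == {
        ClassMembership(2, "VA Class", "CV100", "Cardiovascular Agents")}


def test_shared_class_across_anchors_deduplicates():
    g = RxGraph()
    g.add_concept(1, "A", "IN", "NDFRT")
    g.add_concept(2, "B", "IN", "NDFRT")
    row = ("Mechanism of Action", "M1", "Some Mechanism")
    table = {1: frozenset({row}), 2: frozenset({row})}
    result = classify(g, {1, 2}, table)
    assert {(m.axis, m.class_code) for m in result} == {("Mechanism of Action", "M1")}
    assert len(result) == 2  # one membership per anchor, same class


def test_clinical_drug_anchor_inherits_ingredient_classes():
    g = small_brand_graph()
    table = {1: frozenset({("Mechanism of Action", "M7", "Channel Blocker")}),
             2: frozenset({("VA Class", "CV100", "Cardiovascular Agents")})}
    got = {(m.axis, m.class_code) for m in classify(g, {2}, table)}
    assert got == {("Mechanism of Action", "M7"), ("VA Class", "CV100")}


def test_fixture_classification_recovers_planted_memberships(fixture_set, graph):
    fx = fixture_set.rxnorm
    table = load_class_table(fx.class_tsv_path)
    for rxcui in fx.drug_rxcuis:
        got = {(m.axis, m.class_code, m.class_name)
               for m in classify_concept(graph, rxcui, table)}
        assert got == fx.membership_truth[rxcui]


def test_class_table_from_rrf_roles_equals_tsv(fixture_set, graph):
    fx = fixture_set.rxnorm
    assert class_table_from_graph(graph) == load_class_table(fx.class_tsv_path)


def test_adding_class_rows_never_removes_memberships(fixture_set, graph):
    fx = fixture_set.rxnorm
    table = dict(load_class_table(fx.class_tsv_path))
    some_anchor = next(iter(table))
    bigger = dict(table)
    bigger[some_anchor] = table[some_anchor] | {("Pharmacokinetics", "PK9", "Renal")}
    for rxcui in fx.drug_rxcuis[:40]:
        before = classify_concept(graph, rxcui, table)
        after = classify_concept(graph, rxcui, bigger)
        assert before <= after


def test_coverage_percentages_against_printed_axis_counts():
    """The a% column: axis counts over 10,221 classified concepts."""
    counts = {
        "Generic Ingredient Combinations": 9813,
        "Chemical Ingredients Class": 9331,
        "Therapeutic Intent": 8069,
        "Mechanism of Action": 8061,
        "Physiologic Effect": 7989,
        "VA Class": 5823,
        "FDA Established Pharmacologic Class": 3049,
        "Therapeutic Category": 2880,
        "Pharmacokinetics": 730,
    }
    total = 10221
    classified = {i: set() for i in range(total)}
    for j, (axis, n) in enumerate(counts.items()):
        start = 0 if j == 0 else total - n  # blocks overlap but union covers all
        for i in range(start, start + n):
            classified[i % total].add(
                ClassMembership(1, axis, f"{axis[:2]}-1", f"{axis} class"))
    rows = {r.axis: r for r in coverage_report(classified)}
    assert [rows[a].a_pct for a in counts] == [96, 91, 79, 79, 78, 57, 30, 28, 7]
    assert all(rows[a].n_rxcuis == n for a, n in counts.items())


def test_single_axis_saturation_gives_100_percent():
    classified = {i: {ClassMembership(1, "VA Class", "C1", "x")} for i in range(5)}
    rows = {r.axis: r for r in coverage_report(classified)}
    assert rows["VA Class"].a_pct == 100


def test_report_coverage_counts_reports_with_classified_drugs():
    classified = {
        10: {ClassMembership(10, "VA Class", "C1", "x")},
        11: {ClassMembership(11, "Pharmacokinetics", "P1", "y")},
    }
    reports = [(1, 10), (1, 11), (2, 10), (3, 99)]  # 99 unclassified
    rows = {r.axis: r for r in coverage_report(classified, reports)}
    assert rows["VA Class"].b_pct == 100      # reports 1 and 2, of 2 classified
    assert rows["Pharmacokinetics"].b_pct == 50


def test_all_axis_labels_are_closed_set():
    with pytest.raises(ValueError):
        ClassMembership(1, "Not An Axis", "C", "x")
    assert len(AXES) == 9
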